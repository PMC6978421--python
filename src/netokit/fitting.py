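"""Curve fitting for pole elongation and fluorescence accumulation.

The core estimator is a continuous two-segment ("bilinear") least-squares fit
with four parameters — offset, pre-changepoint speed, post-changepoint speed,
and the changepoint time — matching how biphasic pole elongation is
quantified. For a fixed changepoint the model is linear in the remaining
three parameters, so the fit profiles the changepoint over a grid of interior
sample times (closed-form least squares at each) and polishes the best
candidates with Nelder-Mead simplex descent over all four parameters.
Model selection between a single line and the bilinear model uses BIC with a
configurable margin. Fluorescence accumulation is fit with the asymptotic
exponential I(t) = I_f - (I_f - I_0) exp(-t/tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .model import NetoParams
from .synth import PoleTrajectory

__all__ = [
    "BilinearFit",
    "LinearFit",
    "ExpFit",
    "ModelChoice",
    "fit_bilinear",
    "fit_linear",
    "select_model",
    "fit_asymptotic_exponential",
]

# simplex settings: tight enough for ~nm-scale data in µm units
_XATOL = 1e-6
_FATOL = 1e-8
_MAXITER = 2000


@dataclass(frozen=True)
class BilinearFit:
    """Continuous two-segment fit result.

    Slopes are unconstrained during optimization (the fit may describe a
    slowdown); classification as a genuine slow-to-fast transition requires
    ``v_fast > v_slow`` post hoc (see :meth:`is_speedup`).
    """

    offset_um: float
    v_slow: float
    v_fast: float
    t_neto_h: float
    rss: float
    n: int
    converged: bool

    def is_speedup(self) -> bool:
        return self.v_fast > self.v_slow

    def to_neto_params(self) -> NetoParams:
        if not self.is_speedup():
            raise ValueError("fit is not a slow-to-fast transition")
        return NetoParams(self.offset_um, self.v_slow, self.v_fast, self.t_neto_h)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return (self.offset_um
                + self.v_slow * np.minimum(t, self.t_neto_h)
                + self.v_fast * np.maximum(0.0, t - self.t_neto_h))


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    rss: float
    n: int

    def predict(self, t):
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ExpFit:
    """Asymptotic-exponential fit I(t) = I_f - (I_f - I_0) exp(-t/tau)."""

    final_intensity: float
    i0_frac: float
    tau_h: float
    tau_ci95_h: float
    rss: float
    adj_r2: float
    n: int
    converged: bool

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        i0 = self.i0_frac * self.final_intensity
        return self.final_intensity - (self.final_intensity - i0) * np.exp(
            -t / self.tau_h)


@dataclass(frozen=True)
class ModelChoice:
    model: str                # "linear" | "bilinear"
    linear: LinearFit
    bilinear: BilinearFit
    bic_linear: float
    bic_bilinear: float

    @property
    def delta_bic(self) -> float:
        return self.bic_linear - self.bic_bilinear


def _validate(traj: PoleTrajectory, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    traj = traj.valid()
    t, y = traj.times_h, traj.lengths_um
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {t.size}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in trajectory")
    if np.ptp(t) == 0:
        raise ValueError("all time points identical")
    return t, y


def _bilinear_design(t: np.ndarray, tc: float) -> np.ndarray:
    return np.column_stack([
        np.ones_like(t),
        np.minimum(t, tc),
        np.maximum(0.0, t - tc),
    ])


def _profile_rss(t: np.ndarray, y: np.ndarray, tc: float
                 ) -> tuple[float, np.ndarray]:
    """Closed-form least squares of the three linear parameters at fixed tc."""
    X = _bilinear_design(t, tc)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), beta


def fit_bilinear(traj: PoleTrajectory,
                 changepoint_grid: np.ndarray | None = None) -> BilinearFit:
    """Least-squares continuous bilinear fit of a pole trajectory.

    The changepoint is profiled over every interior sample time (excluding
    the first and last two points) with closed-form least squares for the
    other three parameters, then the best candidates are polished by
    Nelder-Mead over all four parameters, the changepoint constrained to
    [t_2, t_{n-2}] to avoid boundary degeneracy. Ties between restarts are
    broken toward the earliest changepoint.
    """
    t, y = _validate(traj, 6)
    lo, hi = t[2], t[-3]
    if changepoint_grid is None:
        changepoint_grid = t[2:-2]
    grid = np.asarray(changepoint_grid, dtype=float)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        grid = np.array([0.5 * (lo + hi)])

    cand = sorted(((_profile_rss(t, y, tc)[0], tc) for tc in grid),
                  key=lambda p: (p[0], p[1]))

    def objective(theta):
        off, a, b, tc = theta
        tc_c = min(max(tc, lo), hi)
        pred = off + a * np.minimum(t, tc_c) + b * np.maximum(0.0, t - tc_c)
        r = y - pred
        # quadratic penalty keeps the simplex inside the admissible window
        return r @ r + 1e3 * (tc - tc_c) ** 2

    results = []
    n_restarts = min(3, len(cand))
    for rss0, tc0 in cand[:n_restarts]:
        _, beta = _profile_rss(t, y, tc0)
        res = optimize.minimize(
            objective, x0=[beta[0], beta[1], beta[2], tc0],
            method="Nelder-Mead",
            options={"xatol": _XATOL, "fatol": _FATOL, "maxiter": _MAXITER},
        )
        tc_fit = min(max(float(res.x[3]), lo), hi)
        rss_fit, beta_fit = _profile_rss(t, y, tc_fit)
        results.append((rss_fit, tc_fit, beta_fit, bool(res.success)))

    # ties in RSS (to within the objective tolerance) break to the earliest
    # changepoint
    rss_min = min(r[0] for r in results)
    rss, tc, beta, ok = min(
        (r for r in results if r[0] <= rss_min + _FATOL),
        key=lambda r: r[1],
    )
    return BilinearFit(
        offset_um=float(beta[0]), v_slow=float(beta[1]), v_fast=float(beta[2]),
        t_neto_h=float(tc), rss=rss, n=t.size, converged=ok,
    )


def fit_linear(traj: PoleTrajectory) -> LinearFit:
    """Ordinary least-squares line, exact closed form."""
    t, y = _validate(traj, 2)
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return LinearFit(slope=float(beta[1]), intercept=float(beta[0]),
                     rss=float(r @ r), n=t.size)


def _bic(rss: float, n: int, k: int, floor: float = 1e-300) -> float:
    # Gaussian likelihood; k counts mean parameters plus the noise variance
    rss = max(rss, floor)
    return n * np.log(rss / n) + k * np.log(n)


def select_model(traj: PoleTrajectory, margin: float = 2.0) -> ModelChoice:
    """Choose between a single line and the bilinear model by BIC.

    The bilinear model is selected only when its BIC undercuts the linear
    one by more than ``margin`` (default 2), which keeps the false-changepoint
    rate low on genuinely linear data.
    """
    lin = fit_linear(traj)
    bil = fit_bilinear(traj)
    n = bil.n
    # floor at machine-level residuals so two numerically perfect fits tie
    # (and parsimony then keeps the line)
    scale = max(float(np.ptp(traj.valid().lengths_um)), 1.0)
    floor = n * (1e-10 * scale) ** 2
    bic_lin = _bic(lin.rss, n, 3, floor)   # slope, intercept, sigma^2
    bic_bil = _bic(bil.rss, n, 5, floor)   # + second slope, changepoint
    model = "bilinear" if (bic_lin - bic_bil) > margin else "linear"
    return ModelChoice(model, lin, bil, bic_lin, bic_bil)


def fit_asymptotic_exponential(times_h, intensities) -> ExpFit:
    """Fit I(t) = I_f - (I_f - I_0) exp(-t/tau) by least squares.

    Reports tau with a 95% confidence half-width from the local curvature of
    the objective (linearized covariance) and the adjusted R^2 of the fit.
    Non-convergence (including an unidentifiable tau on a flat trace) is
    flagged, not raised.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.size != y.size:
        raise ValueError("times and intensities must have equal length")
    if t.size < 5:
        raise ValueError("need at least 5 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly increasing")

    def model(tt, i_f, i_0, tau):
        return i_f - (i_f - i_0) * np.exp(-tt / tau)

    y_var = float(np.var(y))
    span = float(t[-1] - t[0])
    failed = ExpFit(float(np.mean(y)), 1.0, np.nan, np.nan,
                    float(np.sum((y - np.mean(y)) ** 2)), np.nan,
                    t.size, False)
    if y_var == 0:
        return failed

    p0 = [float(y[-1]), float(y[0]), max(span / 3.0, 1e-3)]
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return failed

    i_f, i_0, tau = popt
    resid = y - model(t, *popt)
    rss = float(resid @ resid)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    n, p = t.size, 3
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n > p + 1 else np.nan
    tau_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    # tau indistinguishable from infinity (flat trace) is not a convergence
    converged = bool(np.isfinite(tau_se) and tau > 0 and tau < 100 * max(span, 1.0))
    if i_f == 0:
        i0_frac = np.nan
    else:
        i0_frac = float(i_0 / i_f)
    return ExpFit(float(i_f), i0_frac, float(tau), 1.96 * tau_se,
                  rss, adj_r2, n, converged)
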