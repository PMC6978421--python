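"""Closed-form forward models of biphasic ("NETO") polar growth.

Mycobacteria elongate exclusively at their poles. A newly created pole first
grows slowly (or not at all) and then, after a variable lag, switches to fast
growth — "new end take off" (NETO), the term borrowed from fission yeast.
This module provides the continuous bilinear growth law for a single pole,
the asymptotic-exponential accumulation kinetics of the polar scaffold protein
Wag31 (DivIVA), conservation bookkeeping for a photo-converted Wag31 pool,
and a 1D lineage simulator that tracks cell-wall material by the generation
in which it was synthesized.

Units are hours and micrometres throughout; conversions happen only at I/O
boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetoParams",
    "PopulationParams",
    "WagKinetics",
    "WallSegment",
    "Cell",
    "CellLineage",
    "pole_length",
    "pole_elongation",
    "wag31_fraction",
    "redistribute_pool",
    "model_curves",
    "grow_and_divide",
    "wall_age_fractions",
    "total_length",
]


@dataclass(frozen=True)
class NetoParams:
    """Four-parameter biphasic growth law for one pole.

    The pole elongates at ``v_slow`` until ``t_neto_h`` hours after pole
    birth, then at ``v_fast``; the law is continuous at the changepoint.
    ``offset_um`` is the length at the pole-birth reference point.
    """

    offset_um: float
    v_slow: float
    v_fast: float
    t_neto_h: float

    def __post_init__(self) -> None:
        if self.v_slow < 0:
            raise ValueError(f"v_slow must be >= 0, got {self.v_slow}")
        if self.v_fast < self.v_slow:
            raise ValueError(
                f"v_fast ({self.v_fast}) must be >= v_slow ({self.v_slow})"
            )
        if self.t_neto_h < 0:
            raise ValueError(f"t_neto_h must be >= 0, got {self.t_neto_h}")


@dataclass(frozen=True)
class PopulationParams:
    """Population means and SDs defining a species' growth regime."""

    lag_mean_h: float
    lag_sd_h: float
    interdiv_mean_h: float
    interdiv_sd_h: float
    v_slow_mean: float
    v_slow_sd: float
    v_fast_mean: float
    v_fast_sd: float

    def __post_init__(self) -> None:
        for name in ("lag_mean_h", "interdiv_mean_h", "v_slow_mean", "v_fast_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("lag_sd_h", "interdiv_sd_h", "v_slow_sd", "v_fast_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class WagKinetics:
    """Asymptotic-exponential accumulation of Wag31 at a new pole.

    Intensity starts at fraction ``i0_frac`` of its final value at the moment
    of division and saturates with time constant ``tau_h``.
    """

    i0_frac: float
    tau_h: float

    def __post_init__(self) -> None:
        if not 0 <= self.i0_frac < 1:
            raise ValueError(f"i0_frac must be in [0, 1), got {self.i0_frac}")
        if self.tau_h <= 0:
            raise ValueError(f"tau_h must be > 0, got {self.tau_h}")


@dataclass(frozen=True)
class WallSegment:
    """Contiguous piece of cell wall along the 1D axis.

    ``birth_generation`` is the generation index in which the material was
    synthesized; the founding cell's endowment is generation 0 and material
    laid down during the founder's cycle is generation 1.
    """

    start_um: float
    end_um: float
    birth_generation: int

    def __post_init__(self) -> None:
        if not self.start_um < self.end_um:
            raise ValueError(
                f"segment must have start < end, got [{self.start_um}, {self.end_um}]"
            )

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


@dataclass
class Cell:
    """One cell in a lineage, on a shared 1D material axis.

    Segment coordinates are material coordinates: wall material never moves
    once synthesized, poles grow outward from the existing extent. The old
    pole sits at the end given by ``old_pole_side`` (``"low"`` grows toward
    smaller coordinates, ``"high"`` toward larger); the new pole is at the
    opposite end. Pole growth laws carry their own clock: ``old_pole_age_h``
    is the age of the old pole at this cell's birth, so a changepoint drawn
    in the mother can fall inside this cell's cycle.
    """

    cell_id: int
    generation: int
    birth_time_h: float
    division_time_h: float | None
    old_pole: NetoParams
    new_pole: NetoParams
    old_pole_age_h: float
    old_pole_side: str = "low"
    segments: list[WallSegment] = field(default_factory=list)
    parent: int | None = None
    children: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.old_pole_side not in ("low", "high"):
            raise ValueError("old_pole_side must be 'low' or 'high'")

    @property
    def birth_length_um(self) -> float:
        return sum(s.length_um for s in self.segments)

    @property
    def birth_extent_um(self) -> tuple[float, float]:
        return (min(s.start_um for s in self.segments),
                max(s.end_um for s in self.segments))


class CellLineage:
    """Tree of cells with per-pole growth laws and wall-material bookkeeping."""

    def __init__(self) -> None:
        self.cells: dict[int, Cell] = {}
        self._next_id = 0

    def add_cell(self, cell: Cell) -> int:
        self.cells[cell.cell_id] = cell
        self._next_id = max(self._next_id, cell.cell_id + 1)
        return cell.cell_id

    def new_id(self) -> int:
        cid = self._next_id
        self._next_id += 1
        return cid

    @property
    def root(self) -> Cell:
        roots = [c for c in self.cells.values() if c.parent is None]
        if len(roots) != 1:
            raise ValueError(f"lineage has {len(roots)} roots")
        return roots[0]

    def leaves(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.children is None]

    def living_at(self, t: float) -> list[Cell]:
        """Cells alive at absolute time ``t`` (birth <= t < division)."""
        out = []
        for c in self.cells.values():
            died = c.division_time_h if c.children is not None else np.inf
            if c.birth_time_h <= t < died:
                out.append(c)
        return out

    def cell_extent(self, cell: Cell, t: float) -> tuple[float, float]:
        """Material-coordinate interval occupied by ``cell`` at time ``t``."""
        dt = t - cell.birth_time_h
        if dt < 0:
            raise ValueError("cell not yet born")
        d_old = (pole_elongation(cell.old_pole, cell.old_pole_age_h + dt)
                 - pole_elongation(cell.old_pole, cell.old_pole_age_h))
        d_new = pole_elongation(cell.new_pole, dt)
        lo, hi = cell.birth_extent_um
        if cell.old_pole_side == "low":
            return (lo - d_old, hi + d_new)
        return (lo - d_new, hi + d_old)

    def cell_length(self, cell: Cell, t: float) -> float:
        """Length of ``cell`` at absolute time ``t`` (must be alive)."""
        lo, hi = self.cell_extent(cell, t)
        return hi - lo

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def cell_record(c: Cell) -> dict:
            return {
                "birth_time_h": c.birth_time_h,
                "cell_id": c.cell_id,
                "children": list(c.children) if c.children else None,
                "division_time_h": c.division_time_h,
                "generation": c.generation,
                "new_pole": [c.new_pole.offset_um, c.new_pole.v_slow,
                             c.new_pole.v_fast, c.new_pole.t_neto_h],
                "old_pole": [c.old_pole.offset_um, c.old_pole.v_slow,
                             c.old_pole.v_fast, c.old_pole.t_neto_h],
                "old_pole_age_h": c.old_pole_age_h,
                "old_pole_side": c.old_pole_side,
                "parent": c.parent,
                "segments": [[s.start_um, s.end_um, s.birth_generation]
                             for s in c.segments],
            }

        records = [cell_record(self.cells[k]) for k in sorted(self.cells)]
        return json.dumps({"cells": records}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CellLineage":
        data = json.loads(text)
        lin = cls()
        for r in data["cells"]:
            lin.add_cell(Cell(
                cell_id=r["cell_id"],
                generation=r["generation"],
                birth_time_h=r["birth_time_h"],
                division_time_h=r["division_time_h"],
                old_pole=NetoParams(*r["old_pole"]),
                new_pole=NetoParams(*r["new_pole"]),
                old_pole_age_h=r["old_pole_age_h"],
                old_pole_side=r["old_pole_side"],
                segments=[WallSegment(*s) for s in r["segments"]],
                parent=r["parent"],
                children=tuple(r["children"]) if r["children"] else None,
            ))
        return lin

    def segments_to_csv(self) -> str:
        lines = ["cell_id,start_um,end_um,birth_generation"]
        for k in sorted(self.cells):
            for s in self.cells[k].segments:
                lines.append(f"{k},{s.start_um:.9g},{s.end_um:.9g},{s.birth_generation}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Pole growth law
# ---------------------------------------------------------------------------

def pole_length(params: NetoParams, t):
    """Pole length (µm) at time ``t`` hours after pole birth.

    Piecewise-linear and continuous: ``offset + v_slow*min(t, t_neto) +
    v_fast*max(0, t - t_neto)``. Accepts scalars or arrays; negative times
    are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (hours since pole birth)")
    out = (params.offset_um
           + params.v_slow * np.minimum(t_arr, params.t_neto_h)
           + params.v_fast * np.maximum(0.0, t_arr - params.t_neto_h))
    return out if out.ndim else float(out)


def pole_elongation(params: NetoParams, t):
    """Elongation since pole birth (ignores the offset)."""
    return pole_length(params, t) - params.offset_um


def wag31_fraction(k: WagKinetics, t):
    """Wag31 intensity at a new pole as a fraction of its final value.

    ``1 - (1 - i0) * exp(-t / tau)``: starts at ``i0_frac`` at division and
    saturates to 1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0 (hours since division)")
    out = 1.0 - (1.0 - k.i0_frac) * np.exp(-t_arr / k.tau_h)
    return out if out.ndim else float(out)


def redistribute_pool(total_signal: float, n_poles: int) -> float:
    """Equilibrium per-pole share of a conserved photo-converted pool.

    The photo-converted Wag31 pool is conserved (photobleaching negligible)
    and redistributes evenly over all poles, so each division dilutes the
    per-pole signal.
    """
    if n_poles < 1:
        raise ValueError("n_poles must be >= 1")
    if total_signal < 0:
        raise ValueError("total_signal must be >= 0")
    return total_signal / n_poles


def model_curves(model: str, v_slow: float, v_fast: float, t_neto_h: float,
                 interdiv_h: float, n: int = 101) -> dict:
    """Old/new-pole elongation curves over one cell cycle under each model.

    ``unipolar``: the new pole stays at the slow speed for the whole cycle
    (equivalently, its changepoint never arrives). ``bipolar``: both poles at
    the fast speed from birth. ``neto``: biphasic new pole. The old pole is
    linear at ``v_fast`` in every model.

    Returns ``{"t_h", "old_pole_um", "new_pole_um"}``.
    """
    if interdiv_h <= 0:
        raise ValueError("interdiv_h must be > 0")
    t = np.linspace(0.0, interdiv_h, n)
    old = v_fast * t
    if model == "unipolar":
        new = v_slow * t
    elif model == "bipolar":
        new = v_fast * t
    elif model == "neto":
        new = pole_elongation(NetoParams(0.0, v_slow, v_fast, t_neto_h), t)
    else:
        raise ValueError(
            f"unknown model {model!r}; expected 'unipolar', 'bipolar' or 'neto'"
        )
    return {"t_h": t, "old_pole_um": old, "new_pole_um": new}


# ---------------------------------------------------------------------------
# Lineage growth and wall-age partitioning
# ---------------------------------------------------------------------------

def _split_segments(segments: list[WallSegment], plane: float
                    ) -> tuple[list[WallSegment], list[WallSegment]]:
    left: list[WallSegment] = []
    right: list[WallSegment] = []
    for s in segments:
        if s.end_um <= plane:
            left.append(s)
        elif s.start_um >= plane:
            right.append(s)
        else:
            left.append(WallSegment(s.start_um, plane, s.birth_generation))
            right.append(WallSegment(plane, s.end_um, s.birth_generation))
    return left, right


def _draw_params(pop: PopulationParams, rng: np.random.Generator
                 ) -> tuple[NetoParams, float]:
    # local import avoids a cycle; sampling lives with the other generators
    from .synth import sample_population

    [(p, T)] = sample_population(pop, 1, rng)
    return p, T


def grow_and_divide(pop: PopulationParams, n_generations: int,
                    division_asymmetry: float = 0.5,
                    seed: int | np.random.Generator | None = None,
                    initial_length_um: float = 3.0,
                    lineage: CellLineage | None = None) -> CellLineage:
    """Grow a lineage for ``n_generations`` rounds of division.

    Each cell elongates at both poles according to its per-pole biphasic laws
    (new material appended as wall segments tagged with the synthesizing
    generation), then divides at the plane ``division_asymmetry`` of the way
    from the old pole (0.5 = symmetric). NETO timing is drawn independently
    of division timing, and each pole keeps its own clock across divisions,
    so a changepoint may fall in the next generation.

    With zero population SDs the simulation is fully deterministic. The
    founder's old pole is taken to be already past its changepoint (it was an
    old pole in the unobserved mother).
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if not 0 < division_asymmetry < 1:
        raise ValueError("division_asymmetry must be in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed

    if lineage is None:
        lineage = CellLineage()
        new_params, T = _draw_params(pop, rng)
        # founder's old pole: past NETO, at the fast speed from birth
        old_params = NetoParams(0.0, new_params.v_slow, new_params.v_fast, 0.0)
        root = Cell(
            cell_id=lineage.new_id(), generation=0, birth_time_h=0.0,
            division_time_h=T, old_pole=old_params, new_pole=new_params,
            old_pole_age_h=old_params.t_neto_h,
            segments=[WallSegment(0.0, initial_length_um, 0)],
        )
        lineage.add_cell(root)

    for _ in range(n_generations):
        for cell in list(lineage.leaves()):
            _divide_cell(lineage, cell, pop, division_asymmetry, rng)
    return lineage


def _divide_cell(lineage: CellLineage, cell: Cell, pop: PopulationParams,
                 asym: float, rng: np.random.Generator) -> None:
    T = cell.division_time_h - cell.birth_time_h
    mat_gen = cell.generation + 1  # material synthesized during this cycle

    lo0, hi0 = cell.birth_extent_um
    lo_t, hi_t = lineage.cell_extent(cell, cell.division_time_h)
    segments = list(cell.segments)
    if lo_t < lo0:
        segments.insert(0, WallSegment(lo_t, lo0, mat_gen))
    if hi_t > hi0:
        segments.append(WallSegment(hi0, hi_t, mat_gen))

    # plane measured from the old pole toward the new pole
    if cell.old_pole_side == "low":
        plane = lo_t + asym * (hi_t - lo_t)
    else:
        plane = hi_t - asym * (hi_t - lo_t)
    low_segs, high_segs = _split_segments(segments, plane)

    p_low, T_low = _draw_params(pop, rng)
    p_high, T_high = _draw_params(pop, rng)
    t_div = cell.division_time_h

    # each daughter's old pole is the mother pole at its outer end; the pole
    # created at the plane is its new pole
    if cell.old_pole_side == "low":
        low_old, low_age = cell.old_pole, cell.old_pole_age_h + T
        high_old, high_age = cell.new_pole, T
    else:
        low_old, low_age = cell.new_pole, T
        high_old, high_age = cell.old_pole, cell.old_pole_age_h + T

    low = Cell(
        cell_id=lineage.new_id(), generation=mat_gen, birth_time_h=t_div,
        division_time_h=t_div + T_low,
        old_pole=low_old, old_pole_age_h=low_age, old_pole_side="low",
        new_pole=p_low, segments=low_segs, parent=cell.cell_id,
    )
    high = Cell(
        cell_id=lineage.new_id(), generation=mat_gen, birth_time_h=t_div,
        division_time_h=t_div + T_high,
        old_pole=high_old, old_pole_age_h=high_age, old_pole_side="high",
        new_pole=p_high, segments=high_segs, parent=cell.cell_id,
    )
    lineage.add_cell(low)
    lineage.add_cell(high)
    cell.children = (low.cell_id, high.cell_id)


def wall_age_fractions(cell: Cell) -> dict[int, float]:
    """Fraction of a cell's wall material per synthesizing generation.

    Fractions sum to 1.
    """
    total = cell.birth_length_um
    if total <= 0:
        raise ValueError("cell has no wall material")
    out: dict[int, float] = {}
    for s in cell.segments:
        out[s.birth_generation] = out.get(s.birth_generation, 0.0) + s.length_um
    return {g: L / total for g, L in sorted(out.items())}


def total_length(lineage: CellLineage, t: float) -> float:
    """Summed length of all cells alive at absolute time ``t``."""
    return sum(lineage.cell_length(c, t) for c in lineage.living_at(t))
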