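"""Synthetic-data generation: population samples, noisy trajectories, and
rendered time-lapse stacks with ground truth.

The generators emulate the two instrument classes used to observe mycobacterial
polar growth: time-lapse AFM (height maps, ~13 min frame spacing, ~50 nm
measurement precision, surface nanostructures usable as fiducial markers) and
phase-contrast microscopy (dark rods on a bright background). Cells are
rendered as 2D capsule (capped-rod) profiles on a shared axis; wall material
is immobile in the lab frame, so cell bodies and surface texture stay put
while the poles advance, and sibling cells snap apart by ~100 nm at division.
Every generator is reproducible from its seed, and rendered stacks carry their
ground truth (cell extents, fiducial tracks, division events) as annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .model import (
    Cell,
    CellLineage,
    NetoParams,
    PopulationParams,
    WagKinetics,
    WallSegment,
    pole_length,
    wag31_fraction,
)

__all__ = [
    "PoleTrajectory",
    "ImageStack",
    "FiducialTrack",
    "sample_population",
    "simulate_trajectory",
    "simulate_fluorescence",
    "render_timelapse",
    "static_cell_lineage",
    "deterministic_population",
]

#: AFM-like defaults: frame every 13 min, 50 nm measurement noise
DEFAULT_DT_H = 13.0 / 60.0
DEFAULT_SIGMA_UM = 0.05


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PoleTrajectory:
    """Time-stamped length measurements of one pole.

    May span several generations when lengths were chained across fiducial
    handoffs; division times crossed are recorded in ``division_times_h``.
    """

    times_h: np.ndarray
    lengths_um: np.ndarray
    pole_id: str = "pole"
    generation_of_birth: int = 0
    division_times_h: tuple = ()

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.lengths_um = np.asarray(self.lengths_um, dtype=float)
        if self.times_h.shape != self.lengths_um.shape:
            raise ValueError("times and lengths must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times_h.size

    def valid(self) -> "PoleTrajectory":
        """Copy with missing (NaN) measurements dropped."""
        keep = ~np.isnan(self.lengths_um)
        return PoleTrajectory(self.times_h[keep], self.lengths_um[keep],
                              self.pole_id, self.generation_of_birth,
                              self.division_times_h)


@dataclass
class FiducialTrack:
    """Per-frame axial position of one immobile surface structure.

    Positions are in µm along the image x axis; NaN marks frames where the
    fiducial is not usable. Outside of division snaps the position is constant
    up to measurement noise, because the structure lies outside the polar
    growth zones.
    """

    fiducial_id: str
    positions_um: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.positions_um)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class ImageStack:
    """Time-lapse 2D frames with physical calibration and ground truth."""

    frames: np.ndarray            # (n_frames, H, W) float32
    pixel_size_nm: float
    frame_times_h: np.ndarray
    channel: str = "topo"         # topo | phase | fluor
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.frame_times_h = np.asarray(self.frame_times_h, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frames.shape[0] != self.frame_times_h.size:
            raise ValueError("one frame time per frame required")
        if self.frame_times_h.size > 1 and np.any(np.diff(self.frame_times_h) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write(self, tiff_path, annotations_path=None) -> None:
        """Write frames as a multi-page TIFF plus a JSON sidecar."""
        tifffile.imwrite(
            tiff_path, self.frames, photometric="minisblack",
            metadata={"pixel_size_nm": self.pixel_size_nm, "channel": self.channel},
        )
        if annotations_path is not None:
            payload = {
                "annotations": self.annotations,
                "channel": self.channel,
                "frame_times_h": self.frame_times_h.tolist(),
                "pixel_size_nm": self.pixel_size_nm,
            }
            with open(annotations_path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, tiff_path, annotations_path=None,
             pixel_size_nm: float | None = None) -> "ImageStack":
        with tifffile.TiffFile(tiff_path) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if frames.ndim == 2:
            frames = frames[None]
        ann: dict = {}
        channel = meta.get("channel", "topo")
        times = None
        px = meta.get("pixel_size_nm", pixel_size_nm)
        if annotations_path is not None:
            with open(annotations_path) as fh:
                payload = json.load(fh)
            ann = payload.get("annotations", {})
            channel = payload.get("channel", channel)
            times = np.asarray(payload["frame_times_h"])
            px = payload.get("pixel_size_nm", px)
        if px is None:
            raise ValueError(
                "pixel size not found in TIFF metadata; pass pixel_size_nm"
            )
        if times is None:
            times = np.arange(frames.shape[0], dtype=float)
        return cls(frames, float(px), times, channel, ann)


# ---------------------------------------------------------------------------
# Parameter and trajectory sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      n: int) -> np.ndarray:
    """Normal draws truncated at 0 by resampling (no point mass at 0)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def sample_population(pop: PopulationParams, n: int, seed=None
                      ) -> list[tuple[NetoParams, float]]:
    """Draw ``n`` per-pole parameter sets and interdivision times.

    Lag, interdivision time and both speeds are drawn from independent
    normals truncated at zero (resampling negatives); a draw with
    v_fast < v_slow is re-ordered so the biphasic law stays valid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(pop, PopulationParams):
        raise TypeError("pop must be a PopulationParams")
    rng = _rng(seed)
    lag = _truncated_normal(rng, pop.lag_mean_h, pop.lag_sd_h, n)
    interdiv = _truncated_normal(rng, pop.interdiv_mean_h, pop.interdiv_sd_h, n)
    v_slow = _truncated_normal(rng, pop.v_slow_mean, pop.v_slow_sd, n)
    v_fast = _truncated_normal(rng, pop.v_fast_mean, pop.v_fast_sd, n)
    lo = np.minimum(v_slow, v_fast)
    hi = np.maximum(v_slow, v_fast)
    return [(NetoParams(0.0, lo[i], hi[i], lag[i]), float(interdiv[i]))
            for i in range(n)]


def simulate_trajectory(params: NetoParams, duration_h: float,
                        dt_h: float = DEFAULT_DT_H,
                        sigma_um: float = DEFAULT_SIGMA_UM,
                        seed=None, pole_id: str = "pole") -> PoleTrajectory:
    """Noisy samples of the biphasic growth law.

    Lengths are the closed-form model plus iid Gaussian measurement noise;
    defaults match AFM observation (13-min spacing, 50 nm noise SD).
    """
    if dt_h <= 0:
        raise ValueError("dt_h must be > 0")
    if duration_h < 4 * dt_h:
        raise ValueError("duration_h must cover at least 4 sampling intervals")
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    rng = _rng(seed)
    t = np.arange(0.0, duration_h + 0.5 * dt_h, dt_h)
    y = pole_length(params, t)
    if sigma_um > 0:
        y = y + rng.normal(0.0, sigma_um, t.size)
    return PoleTrajectory(t, y, pole_id)


def simulate_fluorescence(k: WagKinetics, times_h, noise_frac: float = 0.0,
                          seed=None, final_intensity: float = 1.0) -> np.ndarray:
    """Wag31 accumulation trace: asymptotic exponential with proportional noise."""
    t = np.asarray(times_h, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly increasing")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    rng = _rng(seed)
    y = wag31_fraction(k, t) * final_intensity
    if noise_frac > 0:
        y = y + rng.normal(0.0, noise_frac * final_intensity, t.size)
    return y


# ---------------------------------------------------------------------------
# Convenience lineages
# ---------------------------------------------------------------------------

def deterministic_population(lag_h: float = 2.9, interdiv_h: float = 3.6,
                             v_slow: float = 0.15, v_fast: float = 0.61
                             ) -> PopulationParams:
    """Zero-SD population at the given means (defaults: M. smegmatis)."""
    return PopulationParams(lag_h, 0.0, interdiv_h, 0.0,
                            v_slow, 0.0, v_fast, 0.0)


def static_cell_lineage(length_um: float = 3.0) -> CellLineage:
    """Single non-growing, non-dividing cell (for precision measurements)."""
    lin = CellLineage()
    frozen = NetoParams(0.0, 0.0, 0.0, 0.0)
    lin.add_cell(Cell(
        cell_id=0, generation=0, birth_time_h=0.0, division_time_h=None,
        old_pole=frozen, new_pole=frozen, old_pole_age_h=0.0,
        segments=[WallSegment(0.0, length_um, 0)],
    ))
    return lin


# ---------------------------------------------------------------------------
# Time-lapse rendering
# ---------------------------------------------------------------------------

def _lineage_division_events(lineage: CellLineage) -> list[Cell]:
    return sorted((c for c in lineage.cells.values() if c.children is not None),
                  key=lambda c: c.division_time_h)


def _lab_shift(lineage: CellLineage, cell: Cell, snap_um: float) -> float:
    """Accumulated snap displacement of ``cell`` from all ancestor divisions.

    At each division the low-side daughter subtree moves by -snap/2 and the
    high-side one by +snap/2 (only the total separation is characterized
    experimentally; an even split is assumed).
    """
    shift = 0.0
    node = cell
    while node.parent is not None:
        parent = lineage.cells[node.parent]
        low_id, _ = parent.children
        shift += -0.5 * snap_um if node.cell_id == low_id else 0.5 * snap_um
        node = parent
    return shift


def _owner_at(lineage: CellLineage, material_um: float, t: float) -> Cell | None:
    """Living cell that inherited the wall material at this coordinate.

    Ownership follows the birth segment lists (divisions partition the
    material), not the momentary extents: a sibling whose pole grows past the
    division plane never takes over material on the other side.
    """
    for c in lineage.living_at(t):
        lo, hi = c.birth_extent_um
        if lo - 1e-9 <= material_um <= hi + 1e-9:
            return c
    # not inherited material: synthesized during a living cell's own cycle
    for c in lineage.living_at(t):
        lo, hi = lineage.cell_extent(c, t)
        if lo - 1e-9 <= material_um <= hi + 1e-9:
            return c
    return None


def _smooth_texture(rng: np.random.Generator, x_um: np.ndarray,
                    corr_um: float, amp: float) -> np.ndarray:
    """Static 1D surface roughness as a function of material coordinate.

    Emulates the nanoscale structures (wave-troughs, scars, blebs) that make
    the cell surface trackable; anchored to material coordinates so it is
    immobile in the lab frame, like the real structures.
    """
    n_modes = 40
    span = x_um.max() - x_um.min() + 1e-9
    k = rng.uniform(2 * np.pi / span, 2 * np.pi / max(corr_um, 1e-3), n_modes)
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    w = rng.normal(size=n_modes)
    tex = (np.sin(np.outer(x_um, k) + phase) @ w) / np.sqrt(n_modes)
    return amp * tex


def render_timelapse(lineage: CellLineage, n_frames: int,
                     pixel_size_nm: float = 30.0,
                     frame_interval_h: float = DEFAULT_DT_H,
                     snap_nm: float = 100.0,
                     noise_sigma: float = 0.02,
                     seed=None,
                     channel: str = "topo",
                     cell_width_um: float = 0.5,
                     fiducial_fractions: tuple = (0.3, 0.7),
                     fiducial_amp: float = 0.45,
                     fiducial_sigma_um: float = 0.08,
                     texture_amp: float = 0.06,
                     texture_corr_um: float = 0.12,
                     junction_resolution_um: float = 0.2,
                     margin_um: float = 1.0,
                     shape: tuple[int, int] | None = None) -> ImageStack:
    """Render a lineage as a time-lapse image stack with embedded ground truth.

    Cells are capsule profiles laid along the x axis; wall material (and the
    surface texture and fiducial bumps riding on it) is immobile in the lab
    frame, poles advance outward, and at each division the two sibling
    subtrees are displaced apart by ``snap_nm`` total (±snap/2 each),
    mimicking the abrupt snapping separation seen at cytokinesis.

    ``channel='topo'`` renders an AFM-like height map (bright rod, dark
    background); ``'phase'`` a phase-contrast-like dark rod on a bright
    background; ``'fluor'`` polar fluorescent spots only. Ground truth (cell
    extents, fiducial tracks, division events) is stored in ``annotations``;
    all positions there are nm in image coordinates, measured at pixel
    centers with pixel (0, 0) centered at the origin.
    """
    if not 10 <= pixel_size_nm <= 100:
        raise ValueError("pixel_size_nm must be in [10, 100]")
    if snap_nm < 0:
        raise ValueError("snap_nm must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if channel not in ("topo", "phase", "fluor"):
        raise ValueError("channel must be 'topo', 'phase' or 'fluor'")
    rng = _rng(seed)
    px_um = pixel_size_nm / 1000.0
    snap_um = snap_nm / 1000.0
    times = np.arange(n_frames) * frame_interval_h

    # lab-frame extent over the whole movie (material coords + snap shifts)
    lo_all, hi_all = np.inf, -np.inf
    for t in times:
        for c in lineage.living_at(t):
            lo, hi = lineage.cell_extent(c, t)
            s = _lab_shift(lineage, c, snap_um)
            lo_all = min(lo_all, lo + s)
            hi_all = max(hi_all, hi + s)
    if not np.isfinite(lo_all):
        raise ValueError("lineage has no living cells during the movie")

    x0_um = lo_all - margin_um  # lab position of pixel column 0
    if shape is None:
        width = int(np.ceil((hi_all - lo_all + 2 * margin_um) / px_um)) + 1
        height = int(np.ceil((cell_width_um + 2 * margin_um) / px_um)) + 1
        shape = (height, width)
    H, W = shape
    y0_um = 0.5 * (H - 1) * px_um  # cell axis through the image center row
    xs = x0_um + np.arange(W) * px_um
    ys = np.arange(H) * px_um

    # immobile surface texture, anchored to material coordinates
    root_lo, root_hi = lineage.root.birth_extent_um
    tex_x = np.arange(lo_all - 1.0, hi_all + 1.0, px_um / 2)
    tex_y = _smooth_texture(rng, tex_x, texture_corr_um, texture_amp)

    # fiducials: fixed material coordinates on the founder's body
    fid_material = [root_lo + f * (root_hi - root_lo) for f in fiducial_fractions]

    frames = np.empty((n_frames, H, W), dtype=np.float32)
    cells_per_frame: list[list[dict]] = []
    fid_positions = np.full((len(fid_material), n_frames), np.nan)
    R = cell_width_um / 2.0
    YY = ys[:, None] - y0_um  # (H, 1)

    for k, t in enumerate(times):
        img = np.zeros((H, W))
        frame_cells = []
        intervals = []
        for c in lineage.living_at(t):
            lo, hi = lineage.cell_extent(c, t)
            s = _lab_shift(lineage, c, snap_um)
            a, b = lo + s, hi + s
            if a < x0_um or b > x0_um + (W - 1) * px_um:
                raise ValueError(
                    f"cell {c.cell_id} exceeds the field of view at frame {k}"
                )
            intervals.append((a, b, s, c))
            frame_cells.append({
                "cell_id": c.cell_id,
                "x_lo_nm": (a - x0_um) * 1000.0,
                "x_hi_nm": (b - x0_um) * 1000.0,
                "y_nm": (y0_um - 0.0) * 1000.0,
            })

        # sibling gaps below the junction resolution (a ~100 nm snap gap is
        # far below optical resolution — the reason snapping, not a visible
        # gap, is what marks division) are not resolved: such neighbours
        # render as one continuous rod, so the junction region is flat and
        # does not flicker frame to frame; the snap remains detectable as
        # the displacement of the textured material on either side
        intervals.sort(key=lambda iv: iv[0])
        merged: list[list[float]] = []
        for a, b, _s, _c in intervals:
            if merged and a <= merged[-1][1] + junction_resolution_um:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])

        for a, b in merged:
            # capsule height profile: sqrt(R^2 - d^2)/R, d = distance to spine
            cx = np.clip(xs, a + R, b - R)
            d2 = (xs - cx) ** 2 + YY ** 2
            prof = np.sqrt(np.clip(R * R - d2, 0.0, None)) / R
            img = np.maximum(img, prof)
        if channel in ("topo", "phase") and texture_amp > 0:
            # texture rides on each cell's material; where siblings overlap,
            # ownership is split at a fixed (birth-extent midpoint) seam so
            # the texture field never morphs between divisions
            tex_lab = np.zeros(W)
            cuts = [xs[0] - 1.0]
            for (ai, bi, si, ci), (aj, bj, sj, cj) in zip(intervals,
                                                          intervals[1:]):
                cuts.append(0.5 * (ci.birth_extent_um[1] + si
                                   + cj.birth_extent_um[0] + sj))
            cuts.append(xs[-1] + 1.0)
            for idx, (a, b, s, _c) in enumerate(intervals):
                # texture fills the whole ownership region: it is invisible
                # where the rod is absent, and already in place (static) when
                # a pole later grows across it
                cols = (xs >= cuts[idx]) & (xs <= cuts[idx + 1])
                tex_lab[cols] = np.interp(xs[cols] - s, tex_x, tex_y)
            img = img * (1.0 + tex_lab[None, :])

        # fiducial bumps ride on whichever cell owns the material point
        for j, m in enumerate(fid_material):
            owner = _owner_at(lineage, m, t)
            if owner is None:
                continue
            s = _lab_shift(lineage, owner, snap_um)
            fx = m + s
            fid_positions[j, k] = (fx - x0_um) * 1000.0
            if channel in ("topo", "phase"):
                bump = fiducial_amp * np.exp(
                    -((xs - fx) ** 2 + YY ** 2) / (2 * fiducial_sigma_um ** 2))
                img = img + bump

        if channel == "phase":
            img = 1.0 - 0.8 * img
        elif channel == "fluor":
            img = _render_fluor(lineage, t, xs, YY, x0_um, snap_um)
        if noise_sigma > 0:
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        frames[k] = img
        cells_per_frame.append(frame_cells)

    events = []
    for c in _lineage_division_events(lineage):
        td = c.division_time_h
        if td <= times[0] or td > times[-1]:
            continue
        frame = int(np.searchsorted(times, td))
        lo_t, hi_t = lineage.cell_extent(c, td)
        if c.old_pole_side == "low":
            plane_mat = lo_t + 0.5 * (hi_t - lo_t)
        else:
            plane_mat = hi_t - 0.5 * (hi_t - lo_t)
        # plane position from the daughter-gap midpoint is plane_mat + shift
        s = _lab_shift(lineage, c, snap_um)
        events.append({
            "frame": frame,
            "mother_cell_id": c.cell_id,
            "plane_x_nm": (plane_mat + s - x0_um) * 1000.0,
            "separation_nm": snap_nm,
            "per_sibling_nm": [-snap_nm / 2.0, snap_nm / 2.0],
        })

    annotations = {
        "cells": cells_per_frame,
        "division_events": events,
        "fiducials": [
            {"fiducial_id": f"fid{j}", "x_nm": fid_positions[j].tolist()}
            for j in range(len(fid_material))
        ],
        "axis_y_nm": y0_um * 1000.0,
        "cell_width_nm": cell_width_um * 1000.0,
    }
    return ImageStack(frames, pixel_size_nm, times, channel, annotations)


def render_colony(lineages: list[CellLineage], n_frames: int,
                  y_spacing_um: float = 2.0, noise_sigma: float = 0.02,
                  seed=None, **kwargs) -> ImageStack:
    """Composite several lineages into one field of view, stacked in y.

    Each lineage is rendered noiselessly on its own axis and the fields are
    pasted one below the other (``y_spacing_um`` extra gap), with a single
    noise realization added to the composite. Annotations are merged with the
    appropriate y offsets; annotation positions stay in nm.
    """
    if not lineages:
        raise ValueError("need at least one lineage")
    rng = _rng(seed)
    stacks = [render_timelapse(lin, n_frames, noise_sigma=0.0, seed=rng,
                               **kwargs) for lin in lineages]
    px_nm = stacks[0].pixel_size_nm
    gap_px = int(round(y_spacing_um * 1000 / px_nm))
    W = max(s.frames.shape[2] for s in stacks)
    heights = [s.frames.shape[1] for s in stacks]
    H = sum(heights) + gap_px * (len(stacks) - 1)
    frames = np.zeros((n_frames, H, W), dtype=np.float32)
    merged = {"cells": [[] for _ in range(n_frames)], "division_events": [],
              "fiducials": [], "colony_axes_y_nm": []}
    y0 = 0
    for idx, s in enumerate(stacks):
        h, w = s.frames.shape[1:]
        frames[:, y0:y0 + h, :w] += s.frames
        dy_nm = y0 * px_nm
        for k in range(n_frames):
            for c in s.annotations["cells"][k]:
                c2 = dict(c)
                c2["cell_id"] = (idx, c["cell_id"])
                c2["y_nm"] = c["y_nm"] + dy_nm
                merged["cells"][k].append(c2)
        for e in s.annotations["division_events"]:
            e2 = dict(e)
            e2["mother_cell_id"] = (idx, e["mother_cell_id"])
            merged["division_events"].append(e2)
        for f in s.annotations["fiducials"]:
            merged["fiducials"].append(
                {"fiducial_id": f"colony{idx}_{f['fiducial_id']}",
                 "x_nm": f["x_nm"]})
        merged["colony_axes_y_nm"].append(s.annotations["axis_y_nm"] + dy_nm)
        y0 += h + gap_px
    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape
                                     ).astype(np.float32)
    return ImageStack(frames, px_nm, stacks[0].frame_times_h,
                      stacks[0].channel, merged)


def _render_fluor(lineage: CellLineage, t: float, xs, YY, x0_um, snap_um,
                  kin: WagKinetics = WagKinetics(0.1, 2.4),
                  spot_sigma_um: float = 0.15) -> np.ndarray:
    """Polar spots: old poles at full brightness, new poles per accumulation age."""
    img = np.zeros((YY.shape[0], xs.shape[0]))
    for c in lineage.living_at(t):
        lo, hi = lineage.cell_extent(c, t)
        s = _lab_shift(lineage, c, snap_um)
        age = t - c.birth_time_h
        new_amp = wag31_fraction(kin, age)
        old_x = (lo if c.old_pole_side == "low" else hi) + s
        new_x = (hi if c.old_pole_side == "low" else lo) + s
        for x_c, amp in ((old_x, 1.0), (new_x, new_amp)):
            img += amp * np.exp(-((xs - x_c) ** 2 + YY ** 2)
                                / (2 * spot_sigma_um ** 2))
    return img


def fiducial_tracks_from_annotations(stack: ImageStack) -> list[FiducialTrack]:
    """Ground-truth fiducial tracks (µm) from a rendered stack's annotations."""
    out = []
    for f in stack.annotations.get("fiducials", []):
        pos = np.asarray(f["x_nm"], dtype=float) / 1000.0
        out.append(FiducialTrack(f["fiducial_id"], pos))
    return out
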