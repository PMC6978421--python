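"""Extraction of growth trajectories and division events from image stacks.

Mirrors how polar growth is measured from time-lapse AFM and phase-contrast
movies: frames are registered by cross-correlation, cells segmented by global
threshold, divisions detected as the abrupt frame-to-frame snapping
separation of sibling cells along the axis, pole elongation measured as the
distance from a subpixel pole-tip localizer to the nearest immobile fiducial
marker (with offsets chained across fiducial handoffs so a pole can be
followed over several generations), and cell-wall age mapped by summing the
per-frame binary masks.

Image convention: the cell's longitudinal axis runs along x (columns);
positions are nm at pixel centers, 0-based, origin at the first pixel center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.registration import phase_cross_correlation

from .synth import FiducialTrack, ImageStack, PoleTrajectory

__all__ = [
    "DivisionEvent",
    "AgeMap",
    "register_stack",
    "segment_cells",
    "detect_divisions",
    "measure_pole_elongation",
    "wall_age_map",
]


@dataclass(frozen=True)
class DivisionEvent:
    """One detected sibling-separation (division) event."""

    frame: int
    separation_nm: float
    plane_x_nm: float
    per_sibling_nm: tuple[float, float]   # (low-side, high-side) displacement
    mother_cell_id: int | None = None

    def __post_init__(self) -> None:
        if self.frame < 1:
            raise ValueError("division needs a predecessor frame (frame >= 1)")
        if self.separation_nm < 0:
            raise ValueError("separation must be >= 0")


@dataclass
class AgeMap:
    """Per-pixel count of frames during which the pixel lay inside a cell."""

    counts: np.ndarray
    pixel_size_nm: float
    n_frames: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.min() < 0 or self.counts.max() > self.n_frames:
            raise ValueError("counts must lie in [0, n_frames]")


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _signal_frame(frame: np.ndarray, channel: str) -> np.ndarray:
    """Bright-cell view of a frame regardless of contrast mode."""
    img = np.asarray(frame, dtype=float)
    if channel == "phase":        # dark rod on bright background
        img = img.max() - img
    return img - np.median(img)


def _axial_profile(frame: np.ndarray, channel: str) -> np.ndarray:
    """Mean intensity per column over the rows occupied by the cell body."""
    img = _signal_frame(frame, channel)
    rows = img.sum(axis=1)
    band = rows >= 0.5 * rows.max()
    if not np.any(band):
        band = slice(None)
    prof = img[band].mean(axis=0)
    # remove residual baseline from the field edges
    edge = np.r_[prof[:5], prof[-5:]]
    return prof - np.median(edge)


def _half_max_crossings(prof: np.ndarray) -> tuple[float, float] | None:
    """Sub-pixel leftmost and rightmost half-maximum crossings (pixels)."""
    top = np.percentile(prof, 98)
    if top <= 0:
        return None
    half = 0.5 * top
    above = np.nonzero(prof >= half)[0]
    if above.size == 0:
        return None
    i = above[0]
    if i == 0:
        left = 0.0
    else:
        left = i - 1 + (half - prof[i - 1]) / (prof[i] - prof[i - 1])
    j = above[-1]
    if j == prof.size - 1:
        right = float(j)
    else:
        right = j + (prof[j] - half) / (prof[j] - prof[j + 1])
    return float(left), float(right)


def _subpixel_shift_1d(ref: np.ndarray, mov: np.ndarray,
                       max_lag: int = 34) -> float | None:
    """Rigid 1D shift (pixels) of ``mov`` relative to ``ref``.

    Normalized cross-correlation over a bounded lag range (divisions move
    material by well under a micrometre per frame) with parabolic subpixel
    refinement of the peak; positive = content moved toward +x. Returns None
    when the window carries no usable structure.
    """
    a = np.asarray(ref, dtype=float) - np.mean(ref)
    b = np.asarray(mov, dtype=float) - np.mean(mov)
    n = a.size
    max_lag = min(max_lag, n - 2)
    if n < 5 or max_lag < 1:
        return None
    lags = np.arange(-max_lag, max_lag + 1)
    c = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            aa, bb = a[lag:], b[:n - lag]
        else:
            aa, bb = a[:n + lag], b[-lag:]
        norm = np.sqrt((aa @ aa) * (bb @ bb))
        c[i] = (aa @ bb) / norm if norm > 0 else 0.0
    j = int(np.argmax(c))
    if c[j] <= 0:
        return None
    if j == 0 or j == c.size - 1:
        return float(-lags[j])
    y0, y1, y2 = c[j - 1], c[j], c[j + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom >= 0 else 0.5 * (y0 - y2) / denom
    # c peaks at lag = -shift for this correlation convention
    return float(-(lags[j] + np.clip(frac, -1, 1)))


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

def register_stack(stack: ImageStack, mode: str = "global",
                   upsample: int = 20) -> tuple[ImageStack, np.ndarray]:
    """Translation-only registration by cross-correlation of consecutive frames.

    Returns the aligned stack (all frames resampled onto frame 0) and the
    cumulative per-frame shifts in pixels (n_frames, 2) as (dy, dx).
    ``per_cell`` mode estimates shifts on the bounding box of the largest
    cell in the first frame.
    """
    if stack.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    if mode not in ("global", "per_cell"):
        raise ValueError("mode must be 'global' or 'per_cell'")

    frames = [_signal_frame(f, stack.channel) for f in stack.frames]
    for k, f in enumerate(frames):
        if np.ptp(f) == 0:
            warnings.warn(f"frame {k} is empty (no contrast)", stacklevel=2)

    window = (slice(None), slice(None))
    if mode == "per_cell":
        labels = segment_cells(stack.frames[0], pixel_size_nm=stack.pixel_size_nm,
                               channel=stack.channel)
        if labels.max() > 0:
            sizes = np.bincount(labels.ravel())[1:]
            obj = ndimage.find_objects(labels == (np.argmax(sizes) + 1))[0]
            pad = 10
            window = (slice(max(obj[0].start - pad, 0), obj[0].stop + pad),
                      slice(max(obj[1].start - pad, 0), obj[1].stop + pad))

    shifts = np.zeros((stack.n_frames, 2))
    for k in range(1, stack.n_frames):
        d, *_ = phase_cross_correlation(frames[k - 1][window], frames[k][window],
                                        upsample_factor=upsample,
                                        normalization=None)
        shifts[k] = shifts[k - 1] + d   # cumulative drift vs frame 0
    aligned = np.stack([
        ndimage.shift(stack.frames[k].astype(float), shifts[k], order=1,
                      mode="nearest")
        for k in range(stack.n_frames)
    ]).astype(np.float32)
    out = ImageStack(aligned, stack.pixel_size_nm, stack.frame_times_h,
                     stack.channel, dict(stack.annotations))
    return out, shifts


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_cells(frame: np.ndarray, threshold="auto",
                  pixel_size_nm: float = 30.0, channel: str = "topo",
                  min_area_um2: float = 0.2) -> np.ndarray:
    """Global-threshold segmentation with small-object removal.

    ``threshold='auto'`` uses Otsu on the bright-cell view of the frame.
    Cells in end-to-end contact merge into one label — separating siblings is
    the division detector's job, not segmentation's. An all-background frame
    yields an empty labeling.
    """
    img = _signal_frame(frame, channel)
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite values")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img) if threshold == "auto" else float(threshold)
    mask = img > thr
    labels = sk_label(mask)
    min_px = int(round(min_area_um2 * 1e6 / pixel_size_nm ** 2))
    if min_px > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_px)[0]
        mask &= ~np.isin(labels, small[small > 0])
        labels = sk_label(mask)
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# Division detection by frame differencing
# ---------------------------------------------------------------------------

def _side_divergence(p0: np.ndarray, p1: np.ndarray, px_nm: float,
                     plane_margin_um: float, tip_margin_um: float,
                     min_window_um: float, plane_step_um: float):
    """Best (most diverging) candidate plane between two consecutive profiles.

    The profile is tiled into windows of body material (windows touching the
    pole caps or inter-cell gaps, where intensity is low or changes as poles
    grow, are discarded) and each tile's rigid axial displacement is
    estimated once by subpixel 1D cross-correlation. For each candidate
    division plane the displacements of the tiles nearest the plane on either
    side are compared; divergence is (right shift - left shift), positive
    when the material moves apart. A snap displaces material locally on both
    sides of the plane, so using the nearest tiles keeps the estimate from
    being diluted by unrelated cells further along the chain.
    """
    tips = _half_max_crossings(p0)
    if tips is None:
        return None
    xl, xr = tips
    margin_px = tip_margin_um * 1000 / px_nm
    plane_px = plane_margin_um * 1000 / px_nm
    min_px = max(int(min_window_um * 1000 / px_nm), 4)
    step = max(int(plane_step_um * 1000 / px_nm), 1)
    # local displacement is bounded: snaps are ~0.1 µm, so a generous
    # quarter-micrometre lag bound rejects aliased correlation peaks
    max_lag = max(4, int(250 / px_nm))

    a = int(np.ceil(xl + margin_px))
    b = int(np.floor(xr - margin_px))
    if b - a < 2 * min_px:
        return None

    # body mask: both frames near full height, excluding pole caps,
    # inter-cell gaps, and the shallow dip of a nearly sealed junction
    top = np.percentile(p0[a:b], 90)
    good = (p0 > 0.75 * top) & (p1 > 0.75 * top)

    width = max(min_px, 20)
    stride = max(width // 2, 1)
    tiles = []   # (center_px, shift_px)
    for s in range(a, b - width + 1, stride):
        if not np.all(good[s:s + width]):
            continue
        sh = _subpixel_shift_1d(p0[s:s + width], p1[s:s + width],
                                max_lag=max_lag)
        if sh is not None:
            tiles.append((s + width / 2.0, sh))
    if len(tiles) < 2:
        return None
    centers = np.array([t[0] for t in tiles])
    shifts = np.array([t[1] for t in tiles])

    best = None
    for p in range(a + min_px, b - min_px + 1, step):
        left = np.nonzero(centers + width / 2 <= p - plane_px)[0]
        right = np.nonzero(centers - width / 2 >= p + plane_px)[0]
        if left.size == 0 or right.size == 0:
            continue
        near_l = left[np.argsort(p - centers[left])][:3]
        near_r = right[np.argsort(centers[right] - p)][:3]
        s_left = float(np.median(shifts[near_l])) * px_nm
        s_right = float(np.median(shifts[near_r])) * px_nm
        div = s_right - s_left
        if best is None or div > best[0]:
            best = (div, p * px_nm, (s_left, s_right))
    return best


def detect_divisions(stack: ImageStack, roi: tuple[slice, slice] | None = None,
                     threshold_factor: float = 3.0,
                     plane_margin_um: float = 0.3,
                     tip_margin_um: float = 0.4,
                     min_window_um: float = 0.45,
                     plane_step_um: float = 0.15,
                     noise_floor_px: float = 0.1) -> list[DivisionEvent]:
    """Detect sibling snapping separations by differential image processing.

    For each consecutive frame pair the cell's axial profile is split at
    candidate planes and the two sides' rigid displacements estimated by 1D
    cross-correlation; a division is called where the sides move apart by
    more than ``threshold_factor`` times the per-frame displacement noise
    (robust MAD scale, estimated from the non-candidate frame pairs). The
    noise scale is floored at ``noise_floor_px`` pixels, the practical
    accuracy limit of subpixel correlation, so a handful of unusually quiet
    frame pairs cannot drive the call threshold below what the estimator can
    genuinely resolve.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = stack.frames if roi is None else stack.frames[(slice(None),) + roi]
    px = stack.pixel_size_nm

    profiles = [_axial_profile(f, stack.channel) for f in frames]
    stats = []   # (frame, divergence_nm, plane_nm, (s_left, s_right))
    for k in range(1, len(profiles)):
        best = _side_divergence(profiles[k - 1], profiles[k], px,
                                plane_margin_um, tip_margin_um,
                                min_window_um, plane_step_um)
        if best is not None:
            stats.append((k, best[0], best[1], best[2]))
    if not stats:
        return []

    d = np.array([s[1] for s in stats])

    floor_nm = noise_floor_px * px

    def threshold(values: np.ndarray) -> float:
        med = np.median(values)
        mad = np.median(np.abs(values - med))
        scale = max(1.4826 * mad, floor_nm)
        return med + threshold_factor * scale

    # two-pass: exclude provisional candidates from the noise estimate
    thr = threshold(d)
    quiet = d[d <= thr]
    if quiet.size >= 3:
        thr = threshold(quiet)
    # slow elongation between frames adds a small common divergence to every
    # frame pair; the quiet-frame median is that baseline, and subtracting it
    # leaves the abrupt part of the separation
    baseline = float(np.median(quiet)) if quiet.size else 0.0

    events = []
    for (k, div, plane, sides) in stats:
        if div > thr:
            events.append(DivisionEvent(
                frame=k, separation_nm=float(max(div - baseline, 0.0)),
                plane_x_nm=float(plane),
                per_sibling_nm=(float(sides[0]), float(sides[1])),
            ))
    return events


# ---------------------------------------------------------------------------
# Pole elongation via fiducial chaining
# ---------------------------------------------------------------------------

def _refine_fiducial(prof: np.ndarray, guess_px: float, px_nm: float,
                     window_um: float = 0.25) -> float | None:
    """Quadratic-interpolated local maximum near the nominal bump position."""
    w = int(round(window_um * 1000 / px_nm))
    i0 = int(round(guess_px))
    a, b = max(i0 - w, 1), min(i0 + w + 1, prof.size - 1)
    if b - a < 3:
        return None
    seg = prof[a:b]
    j = a + int(np.argmax(seg))
    if j <= 0 or j >= prof.size - 1:
        return None
    y0, y1, y2 = prof[j - 1], prof[j], prof[j + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(j + np.clip(frac, -1, 1))


def measure_pole_elongation(stack: ImageStack, fiducials: list[FiducialTrack],
                            pole: str = "new") -> PoleTrajectory:
    """Pole length over time, chained across fiducial handoffs.

    Per frame the pole tip is localized as the subpixel half-maximum crossing
    of the axial profile on the chosen side (``'old'`` = low-x end, ``'new'``
    = high-x end, the renderer's convention), and the fiducial bump nearest
    the pole is re-localized around its track position. The reported length is
    the tip-to-fiducial distance plus the accumulated handoff offsets, so the
    curve is continuous when the reference changes from one fiducial to
    another. Frames with no usable fiducial yield NaN (never interpolated).
    """
    if pole not in ("old", "new", "left", "right"):
        raise ValueError("pole must be 'old'/'left' or 'new'/'right'")
    right_side = pole in ("new", "right")
    sign = 1.0 if right_side else -1.0
    px = stack.pixel_size_nm

    n = stack.n_frames
    lengths = np.full(n, np.nan)
    ref_id: str | None = None
    offset_nm = 0.0
    last_pos: dict[str, float] = {}

    for k in range(n):
        prof = _axial_profile(stack.frames[k], stack.channel)
        tips = _half_max_crossings(prof)
        if tips is None:
            continue
        tip_px = tips[1] if right_side else tips[0]
        tip_nm = tip_px * px

        usable: dict[str, float] = {}
        for f in fiducials:
            if k >= f.positions_um.size or not f.valid[k]:
                continue
            guess_px = f.positions_um[k] * 1000 / px
            refined = _refine_fiducial(prof, guess_px, px)
            pos_nm = (refined * px) if refined is not None \
                else f.positions_um[k] * 1000
            usable[f.fiducial_id] = pos_nm
        if not usable:
            continue
        last_pos.update(usable)

        nearest = min(usable, key=lambda fid: abs(usable[fid] - tip_nm))
        if ref_id is None:
            ref_id = nearest
        elif ref_id not in usable:
            # forced handoff: offset by the distance between old and new
            # reference so the chained curve stays continuous
            old_pos = last_pos.get(ref_id)
            if old_pos is not None:
                # (tip - old)*s + off_old == (tip - new)*s + off_new
                offset_nm += (usable[nearest] - old_pos) * sign
            ref_id = nearest
        lengths[k] = ((tip_nm - usable[ref_id]) * sign + offset_nm) / 1000.0

    return PoleTrajectory(stack.frame_times_h, lengths,
                          pole_id=f"{pole}_pole")


# ---------------------------------------------------------------------------
# Wall-age mapping
# ---------------------------------------------------------------------------

def wall_age_map(stack: ImageStack, threshold="auto",
                 motion_tolerance_px: float = 2.0) -> AgeMap:
    """Sum of per-frame binary masks: per-pixel count of frames inside a cell.

    Assumes a microcolony whose cells do not move relative to each other;
    detected inter-frame drift above ``motion_tolerance_px`` only triggers a
    warning (with the maximum drift found), never a failure.
    """
    if stack.n_frames >= 2:
        drifts = []
        ref = _signal_frame(stack.frames[0], stack.channel)
        for k in range(1, stack.n_frames):
            cur = _signal_frame(stack.frames[k], stack.channel)
            if np.ptp(ref) == 0 or np.ptp(cur) == 0:
                continue
            d, *_ = phase_cross_correlation(ref, cur, upsample_factor=4,
                                            normalization=None)
            drifts.append(float(np.hypot(*d)))
            ref = cur
        if drifts and max(drifts) > motion_tolerance_px:
            warnings.warn(
                f"colony moved up to {max(drifts):.1f} px between frames; "
                "age map may be blurred", stacklevel=2)

    counts = np.zeros(stack.frames.shape[1:], dtype=np.uint16)
    for f in stack.frames:
        labels = segment_cells(f, threshold=threshold,
                               pixel_size_nm=stack.pixel_size_nm,
                               channel=stack.channel)
        counts += (labels > 0).astype(np.uint16)
    return AgeMap(counts, stack.pixel_size_nm, stack.n_frames)
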