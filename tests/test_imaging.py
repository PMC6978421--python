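"""Image-pipeline tests: registration, segmentation, division detection,
fiducial-chained pole measurement, and wall-age mapping, all validated
against rendered ground truth."""

import numpy as np
import pytest

from netokit.fitting import fit_bilinear, fit_linear
from netokit.imaging import (
    AgeMap,
    DivisionEvent,
    detect_divisions,
    measure_pole_elongation,
    register_stack,
    segment_cells,
    wall_age_map,
)
from netokit.model import grow_and_divide
from netokit.synth import (
    ImageStack,
    fiducial_tracks_from_annotations,
    render_colony,
    render_timelapse,
    static_cell_lineage,
)


@pytest.fixture(scope="module")
def dividing_stack():
    """One deterministic M. smegmatis cell dividing at 3.6 h, 30 frames."""
    from netokit.synth import deterministic_population

    lin = grow_and_divide(deterministic_population(), 1, seed=0)
    return render_timelapse(lin, n_frames=30, snap_nm=100.0, seed=1)


@pytest.fixture(scope="module")
def growing_stack():
    """The same cell observed before its division (16 frames)."""
    from netokit.synth import deterministic_population

    lin = grow_and_divide(deterministic_population(), 1, seed=0)
    return render_timelapse(lin, n_frames=16, seed=4)


class TestRegisterStack:
    def test_integer_drift_recovered_exactly(self):
        st = render_timelapse(static_cell_lineage(), n_frames=4, seed=2,
                              noise_sigma=0.0)
        drift = np.array([[0, 0], [1, -2], [3, 1], [-2, 2]])
        frames = np.stack([np.roll(st.frames[k], drift[k], axis=(0, 1))
                           for k in range(4)])
        moved = ImageStack(frames, st.pixel_size_nm, st.frame_times_h, "topo")
        aligned, shifts = register_stack(moved)
        assert np.allclose(shifts, -drift)
        assert np.allclose(aligned.frames[1:], aligned.frames[0], atol=1e-4)

    def test_identical_frames_zero_shift(self):
        st = render_timelapse(static_cell_lineage(), n_frames=3, seed=3,
                              noise_sigma=0.0)
        _, shifts = register_stack(st)
        assert np.allclose(shifts, 0.0)

    def test_subpixel_drift_recovered(self):
        from scipy.ndimage import shift as nd_shift

        st = render_timelapse(static_cell_lineage(), n_frames=2, seed=4,
                              noise_sigma=0.0)
        frames = np.stack([st.frames[0],
                           nd_shift(st.frames[0].astype(float), (0.0, 0.4),
                                    order=3)])
        moved = ImageStack(frames, st.pixel_size_nm, st.frame_times_h, "topo")
        _, shifts = register_stack(moved)
        assert abs(shifts[1, 1] + 0.4) < 0.1

    def test_single_frame_rejected(self):
        st = render_timelapse(static_cell_lineage(), n_frames=1, seed=5)
        with pytest.raises(ValueError):
            register_stack(st)

    def test_empty_frame_warns(self):
        frames = np.zeros((2, 20, 20), dtype=np.float32)
        st = ImageStack(frames, 30.0, np.array([0.0, 0.1]), "topo")
        with pytest.warns(UserWarning, match="empty"):
            register_stack(st)


class TestSegmentCells:
    def test_three_separated_cells(self):
        col = render_colony([static_cell_lineage(2.5), static_cell_lineage(3.0),
                             static_cell_lineage(3.5)], n_frames=1, seed=6)
        labels = segment_cells(col.frames[0], pixel_size_nm=col.pixel_size_nm)
        assert labels.max() == 3
        from skimage.measure import regionprops

        props = sorted(regionprops(labels), key=lambda p: p.centroid[0])
        anns = sorted(col.annotations["cells"][0], key=lambda c: c["y_nm"])
        for p, ann in zip(props, anns):
            cy, cx = p.centroid
            ax = 0.5 * (ann["x_lo_nm"] + ann["x_hi_nm"]) / col.pixel_size_nm
            ay = ann["y_nm"] / col.pixel_size_nm
            assert abs(cx - ax) < 1.0 and abs(cy - ay) < 1.0

    def test_blank_frame_empty_labeling(self):
        labels = segment_cells(np.zeros((30, 30)), pixel_size_nm=30.0)
        assert labels.max() == 0

    def test_touching_siblings_merge(self, dividing_stack):
        # siblings separated by ~100 nm are below segmentation resolution:
        # one label by contract; the division detector resolves them
        labels = segment_cells(dividing_stack.frames[-1],
                               pixel_size_nm=dividing_stack.pixel_size_nm)
        assert labels.max() == 1

    def test_nonfinite_frame_rejected(self):
        frame = np.zeros((20, 20))
        frame[5, 5] = np.nan
        with pytest.raises(ValueError):
            segment_cells(frame)


class TestDetectDivisions:
    def test_single_snap_found_at_correct_frame(self, dividing_stack):
        truth = dividing_stack.annotations["division_events"][0]
        events = detect_divisions(dividing_stack)
        assert len(events) == 1
        ev = events[0]
        assert ev.frame == truth["frame"]
        assert abs(ev.separation_nm - 100.0) < 20.0
        # both siblings move, roughly symmetrically
        assert ev.per_sibling_nm[0] < 0 < ev.per_sibling_nm[1]

    def test_no_false_positives_on_static_stacks(self):
        lin = static_cell_lineage()
        for seed in range(10):
            st = render_timelapse(lin, n_frames=12, seed=100 + seed)
            assert detect_divisions(st) == []

    def test_two_snaps_in_order(self):
        from netokit.model import PopulationParams

        # small interdivision spread staggers the daughters' divisions
        pop = PopulationParams(2.9, 0.0, 2.8, 0.25, 0.15, 0.0, 0.61, 0.0)
        lin = grow_and_divide(pop, 2, seed=5)
        st = render_timelapse(lin, n_frames=30, seed=7)
        truth_frames = sorted(e["frame"] for e in
                              st.annotations["division_events"])
        events = detect_divisions(st)
        frames = [e.frame for e in events]
        assert frames == sorted(frames)
        assert set(frames) <= set(truth_frames)
        assert len(frames) >= 2

    def test_separation_unbiased_across_seeds(self):
        from netokit.synth import deterministic_population

        lin = grow_and_divide(deterministic_population(), 1, seed=0)
        seps = []
        for seed in range(25):
            st = render_timelapse(lin, n_frames=24, snap_nm=100.0,
                                  seed=200 + seed)
            ev = [e for e in detect_divisions(st)]
            if ev:
                seps.append(ev[0].separation_nm)
        seps = np.asarray(seps)
        assert seps.size >= 20
        se = seps.std(ddof=1) / np.sqrt(seps.size)
        assert abs(seps.mean() - 100.0) < 3 * max(se, 1.0)

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            DivisionEvent(frame=0, separation_nm=50.0, plane_x_nm=0.0,
                          per_sibling_nm=(0, 0))
        with pytest.raises(ValueError):
            DivisionEvent(frame=2, separation_nm=-1.0, plane_x_nm=0.0,
                          per_sibling_nm=(0, 0))


class TestMeasurePoleElongation:
    def test_static_cell_precision_under_50nm(self):
        st = render_timelapse(static_cell_lineage(), n_frames=20, seed=8,
                              fiducial_fractions=(0.3,))
        fids = fiducial_tracks_from_annotations(st)
        traj = measure_pole_elongation(st, fids, "new").valid()
        assert traj.n == 20
        assert traj.lengths_um.std() * 1000 <= 50.0

    def test_handoff_offset_keeps_curve_continuous(self, growing_stack):
        fids = fiducial_tracks_from_annotations(growing_stack)
        fids[0].valid[8:] = False
        fids[1].valid[:6] = False
        chained = measure_pole_elongation(growing_stack, fids, "new")
        single = measure_pole_elongation(
            growing_stack, fiducial_tracks_from_annotations(growing_stack)[:1],
            "new")
        # same curve as an uninterrupted reference, up to measurement noise
        diff = chained.lengths_um - single.lengths_um
        assert np.nanstd(diff) * 1000 < 50.0
        # no jump at the handoff frame beyond one normal growth step
        steps = np.abs(np.diff(chained.lengths_um)) * 1000
        assert np.nanmax(steps) < 0.61 * (13 / 60) * 1000 + 50.0

    def test_growing_pole_slope_recovered(self, growing_stack):
        fids = fiducial_tracks_from_annotations(growing_stack)
        old = measure_pole_elongation(growing_stack, fids, "old").valid()
        slope = fit_linear(old).slope
        assert slope == pytest.approx(0.61, rel=0.05)

    def test_missing_fiducial_frames_marked_nan(self, growing_stack):
        fids = fiducial_tracks_from_annotations(growing_stack)
        for f in fids:
            f.valid[5] = False
        traj = measure_pole_elongation(growing_stack, fids, "new")
        assert np.isnan(traj.lengths_um[5])
        assert np.isfinite(traj.lengths_um[4])

    def test_roundtrip_recovers_generative_biphasic_params(self):
        from netokit.synth import deterministic_population

        lin = grow_and_divide(deterministic_population(), 1, seed=0)
        st = render_timelapse(lin, n_frames=30, seed=9)
        fids = fiducial_tracks_from_annotations(st)
        traj = measure_pole_elongation(st, fids, "new").valid()
        fit = fit_bilinear(traj)
        assert fit.v_slow == pytest.approx(0.15, abs=0.1 * 0.61)
        assert fit.v_fast == pytest.approx(0.61, rel=0.10)
        assert fit.t_neto_h == pytest.approx(2.9, rel=0.10)

    def test_drift_invariance_of_register_measure_pipeline(self):
        st = render_timelapse(static_cell_lineage(), n_frames=8, seed=10,
                              fiducial_fractions=(0.4,))
        drift = np.array([[0, 0]] + [[k % 3 - 1, (k * 2) % 5 - 2]
                                     for k in range(1, 8)])
        frames = np.stack([np.roll(st.frames[k], drift[k], axis=(0, 1))
                           for k in range(8)])
        moved = ImageStack(frames, st.pixel_size_nm, st.frame_times_h,
                           "topo", st.annotations)
        aligned, _ = register_stack(moved)
        fids = fiducial_tracks_from_annotations(st)
        base = measure_pole_elongation(st, fids, "new").valid()
        reg = measure_pole_elongation(aligned, fids, "new").valid()
        assert np.allclose(base.lengths_um, reg.lengths_um, atol=0.05)


class TestWallAgeMap:
    def test_nested_growth_counts(self):
        from netokit.synth import deterministic_population

        lin = grow_and_divide(deterministic_population(), 1, seed=0)
        st = render_timelapse(lin, n_frames=3, frame_interval_h=1.0, seed=11,
                              noise_sigma=0.005)
        age = wall_age_map(st)
        assert age.counts.max() == 3          # core present in every frame
        assert 1 in np.unique(age.counts)     # newest pole material: 1 frame

    def test_empty_stack_all_zero(self):
        frames = np.zeros((3, 20, 20), dtype=np.float32)
        st = ImageStack(frames, 30.0, np.array([0.0, 1.0, 2.0]), "topo")
        age = wall_age_map(st)
        assert age.counts.sum() == 0

    def test_total_age_nondecreasing_with_frames(self):
        from netokit.synth import deterministic_population

        lin = grow_and_divide(deterministic_population(), 1, seed=0)
        st = render_timelapse(lin, n_frames=10, seed=12, noise_sigma=0.005)
        totals = []
        for k in range(2, 11):
            sub = ImageStack(st.frames[:k], st.pixel_size_nm,
                             st.frame_times_h[:k], "topo")
            totals.append(int(wall_age_map(sub).counts.sum()))
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_old_pole_tip_younger_than_midline(self):
        # poles carry the newest wall material: mean age at the fast-growing
        # tip is below the mean age at the cell's midline
        from netokit.synth import deterministic_population

        lin = grow_and_divide(deterministic_population(), 1, seed=0)
        st = render_timelapse(lin, n_frames=16, seed=13, noise_sigma=0.005)
        age = wall_age_map(st)
        ann = st.annotations["cells"][-1]
        lo = min(c["x_lo_nm"] for c in ann) / st.pixel_size_nm
        hi = max(c["x_hi_nm"] for c in ann) / st.pixel_size_nm
        mid = 0.5 * (lo + hi)
        row = int(round(st.annotations["axis_y_nm"] / st.pixel_size_nm))
        band = age.counts[row - 2: row + 3]
        tip = band[:, int(lo) + 1: int(lo) + 6].mean()
        center = band[:, int(mid) - 2: int(mid) + 3].mean()
        assert tip < center

    def test_motion_warning(self):
        st = render_timelapse(static_cell_lineage(), n_frames=3, seed=14,
                              noise_sigma=0.0)
        frames = np.stack([st.frames[0],
                           np.roll(st.frames[1], 4, axis=1),
                           np.roll(st.frames[2], 8, axis=1)])
        moved = ImageStack(frames, st.pixel_size_nm, st.frame_times_h, "topo")
        with pytest.warns(UserWarning, match="moved"):
            wall_age_map(moved)

    def test_agemap_invariants(self):
        with pytest.raises(ValueError):
            AgeMap(np.array([[0, 5]]), 30.0, n_frames=3)
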