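"""Forward-model unit and property tests: growth law, Wag31 kinetics,
pool conservation, lineage growth, and wall-age partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netokit.model import (
    CellLineage,
    NetoParams,
    PopulationParams,
    WagKinetics,
    grow_and_divide,
    model_curves,
    pole_elongation,
    pole_length,
    redistribute_pool,
    total_length,
    wag31_fraction,
    wall_age_fractions,
)
from netokit.synth import deterministic_population

MSM = dict(lag_h=2.9, interdiv_h=3.6, v_slow=0.15, v_fast=0.61)


class TestPoleLength:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 0.0),            # offset at pole birth
        (2.9, 0.435),          # slow phase: 0.15 * 2.9
        (3.9, 1.045),          # one hour past the changepoint: 0.435 + 0.61
    ])
    def test_biphasic_values(self, msm_params, t, expected):
        assert pole_length(msm_params, t) == pytest.approx(expected, abs=1e-12)

    def test_matches_numerical_integration_of_speed_profile(self, msm_params):
        tt = np.linspace(0, 6, 200_001)
        speed = np.where(tt < msm_params.t_neto_h, msm_params.v_slow,
                         msm_params.v_fast)
        integral = np.trapezoid(speed, tt)
        assert pole_length(msm_params, 6.0) == pytest.approx(integral, rel=1e-5)

    def test_negative_time_rejected(self, msm_params):
        with pytest.raises(ValueError):
            pole_length(msm_params, -0.1)

    @given(v_slow=st.floats(0, 1), dv=st.floats(0, 1), tc=st.floats(0, 10),
           off=st.floats(-1, 5))
    @settings(deadline=None, max_examples=50)
    def test_continuous_and_nondecreasing(self, v_slow, dv, tc, off):
        p = NetoParams(off, v_slow, v_slow + dv, tc)
        eps = 1e-9
        left = pole_length(p, max(tc - eps, 0))
        right = pole_length(p, tc + eps)
        assert right - left == pytest.approx(0.0, abs=1e-6)
        t = np.linspace(0, 2 * tc + 1, 101)
        y = pole_length(p, t)
        assert np.all(np.diff(y) >= -1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NetoParams(0, -0.1, 0.6, 1.0)
        with pytest.raises(ValueError):
            NetoParams(0, 0.5, 0.4, 1.0)
        with pytest.raises(ValueError):
            NetoParams(0, 0.1, 0.6, -1.0)


class TestWag31:
    def test_initial_fraction(self, wag):
        assert wag31_fraction(wag, 0.0) == pytest.approx(0.10)

    def test_asymptote(self, wag):
        assert wag31_fraction(wag, 1e6) == pytest.approx(1.0)

    def test_level_at_mean_lag(self, wag):
        # ~70% of the final level by the time the pole takes off
        assert wag31_fraction(wag, 2.9) == pytest.approx(0.731, abs=5e-4)

    def test_monotone(self, wag):
        t = np.linspace(0, 20, 400)
        assert np.all(np.diff(wag31_fraction(wag, t)) > 0)

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            WagKinetics(1.0, 2.4)
        with pytest.raises(ValueError):
            WagKinetics(0.1, 0.0)


class TestRedistributePool:
    @pytest.mark.parametrize("total, n, expected", [
        (100.0, 2, 50.0),
        (100.0, 4, 25.0),
        (0.0, 3, 0.0),
    ])
    def test_even_split(self, total, n, expected):
        assert redistribute_pool(total, n) == expected

    @given(total=st.floats(0, 1e6), n=st.integers(1, 64))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, total, n):
        per_pole = redistribute_pool(total, n)
        assert per_pole * n == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_zero_poles_rejected(self):
        with pytest.raises(ValueError):
            redistribute_pool(100.0, 0)


class TestModelCurves:
    def test_bipolar_both_poles_linear(self):
        c = model_curves("bipolar", 0.15, 0.61, 2.9, 3.6)
        assert c["old_pole_um"][-1] == pytest.approx(0.61 * 3.6)
        assert np.allclose(c["old_pole_um"], c["new_pole_um"])

    def test_unipolar_equals_never_taking_off(self):
        c = model_curves("unipolar", 0.15, 0.61, 2.9, 3.6)
        never = NetoParams(0, 0.15, 0.61, 1e9)
        assert np.allclose(c["new_pole_um"], pole_elongation(never, c["t_h"]))

    def test_neto_curve_matches_growth_law(self, msm_params):
        c = model_curves("neto", 0.15, 0.61, 2.9, 3.6)
        assert np.allclose(c["new_pole_um"], pole_elongation(msm_params, c["t_h"]))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            model_curves("tripolar", 0.15, 0.61, 2.9, 3.6)


def brute_force_partition(lag_h, interdiv_h, v_slow, v_fast,
                          birth_um=3.0, asym=0.5, bin_um=1e-3):
    """1-nm discretized oracle of one deterministic growth-division round.

    Returns (low-side new-material fraction, high-side new-material fraction)
    where 'new' is material synthesized during the founder's cycle and the
    low side holds the founder's old pole.
    """
    body = [0] * int(round(birth_um / bin_um))          # generation-0 bins
    n_old = int(round(v_fast * interdiv_h / bin_um))    # old pole: fast all cycle
    new_growth = v_slow * min(lag_h, interdiv_h) + v_fast * max(
        0.0, interdiv_h - lag_h)
    n_new = int(round(new_growth / bin_um))
    cell = [1] * n_old + body + [1] * n_new
    cut = int(round(asym * len(cell)))
    low, high = cell[:cut], cell[cut:]
    return (sum(low) / len(low), sum(high) / len(high))


class TestLineage:
    def test_symmetric_partition_at_msm_means(self, msm_det_pop):
        lin = grow_and_divide(msm_det_pop, 1, seed=0)
        low, high = (lin.cells[i] for i in lin.root.children)
        f_low = wall_age_fractions(low)
        f_high = wall_age_fractions(high)
        oracle_low, oracle_high = brute_force_partition(**MSM)
        # exact interval arithmetic vs 1-nm discretization: < 0.2%
        assert f_low[1] == pytest.approx(oracle_low, abs=2e-3)
        assert f_high[1] == pytest.approx(oracle_high, abs=2e-3)
        # old-pole daughter ~72.5% new material, sibling ~28.5%
        assert f_low[1] == pytest.approx(0.725, abs=5e-3)
        assert f_high[1] == pytest.approx(0.285, abs=5e-3)

    def test_bipolar_limit_identical_daughters(self):
        pop = deterministic_population(lag_h=1e-9, v_slow=0.61, v_fast=0.61)
        lin = grow_and_divide(pop, 1, seed=0)
        a, b = (wall_age_fractions(lin.cells[i]) for i in lin.root.children)
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-9)

    def test_unipolar_limit_partition(self):
        # changepoint beyond the cycle: new pole contributes only slow growth
        pop = deterministic_population(lag_h=100.0)
        lin = grow_and_divide(pop, 1, seed=0)
        low, high = (lin.cells[i] for i in lin.root.children)
        oracle = brute_force_partition(100.0, 3.6, 0.15, 0.61)
        assert wall_age_fractions(low)[1] == pytest.approx(oracle[0], abs=2e-3)
        assert wall_age_fractions(high)[1] == pytest.approx(oracle[1], abs=2e-3)

    def test_wall_age_fractions_sum_to_one(self, msm_pop):
        lin = grow_and_divide(msm_pop, 3, seed=42)
        for cell in lin.cells.values():
            assert sum(wall_age_fractions(cell).values()) == pytest.approx(1.0)

    def test_length_conservation(self, msm_pop):
        lin = grow_and_divide(msm_pop, 3, seed=7)
        t_end = min(c.division_time_h for c in lin.leaves()) - 1e-6
        # integral of all active pole speeds, 1-ms time discretization
        tt = np.linspace(0.0, t_end, 20_000)
        dt = tt[1] - tt[0]
        grown = 0.0
        for c in lin.cells.values():
            t0 = c.birth_time_h
            t1 = c.division_time_h if c.children is not None else np.inf
            sel = (tt >= t0) & (tt < t1)
            ages = tt[sel] - t0
            v_new = np.where(ages < c.new_pole.t_neto_h, c.new_pole.v_slow,
                             c.new_pole.v_fast)
            old_age = ages + c.old_pole_age_h
            v_old = np.where(old_age < c.old_pole.t_neto_h, c.old_pole.v_slow,
                             c.old_pole.v_fast)
            grown += np.sum(v_new + v_old) * dt
        expected = lin.root.birth_length_um + grown
        assert total_length(lin, t_end) == pytest.approx(expected, rel=1e-3)

    def test_division_splits_at_plane_and_conserves_material(self, msm_pop):
        lin = grow_and_divide(msm_pop, 2, seed=3)
        for cell in lin.cells.values():
            if cell.children is None:
                continue
            a, b = (lin.cells[i] for i in cell.children)
            assert a.birth_time_h == cell.division_time_h
            assert b.birth_time_h == cell.division_time_h
            tot = a.birth_length_um + b.birth_length_um
            assert tot == pytest.approx(
                lin.cell_length(cell, cell.division_time_h - 1e-12), abs=1e-6)

    def test_asymmetric_division_plane(self, msm_det_pop):
        lin = grow_and_divide(msm_det_pop, 1, division_asymmetry=0.3, seed=0)
        low, high = (lin.cells[i] for i in lin.root.children)
        total = low.birth_length_um + high.birth_length_um
        # low daughter holds the old pole: 30% of the mother's length
        assert low.birth_length_um / total == pytest.approx(0.3)

    def test_roundtrip_json(self, msm_pop):
        lin = grow_and_divide(msm_pop, 2, seed=9)
        clone = CellLineage.from_json(lin.to_json())
        assert set(clone.cells) == set(lin.cells)
        for k in lin.cells:
            assert clone.cells[k].segments == lin.cells[k].segments
            assert clone.cells[k].old_pole == lin.cells[k].old_pole

    def test_segments_csv_header(self, msm_det_pop):
        lin = grow_and_divide(msm_det_pop, 1, seed=0)
        text = lin.segments_to_csv()
        assert text.splitlines()[0] == "cell_id,start_um,end_um,birth_generation"

    def test_invalid_arguments_rejected(self, msm_pop):
        with pytest.raises(ValueError):
            grow_and_divide(msm_pop, 0, seed=0)
        with pytest.raises(ValueError):
            grow_and_divide(msm_pop, 1, division_asymmetry=1.0, seed=0)

    def test_population_params_validation(self):
        with pytest.raises(ValueError):
            PopulationParams(0.0, 0.8, 3.6, 0.7, 0.15, 0.06, 0.61, 0.13)
        with pytest.raises(ValueError):
            PopulationParams(2.9, -0.8, 3.6, 0.7, 0.15, 0.06, 0.61, 0.13)
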