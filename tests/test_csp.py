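"""Chemical-shift-perturbation computation, thresholds and trajectories."""

import numpy as np
import pandas as pd
import pytest

from hmgdyn import synthetic
from hmgdyn.csp import (
    TitrationSeries,
    compare_conditions,
    csp,
    intensity_ratios,
    thresholds,
    trajectory_compare,
)


def shifts_frame(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index(range(1, n + 1), name="residue")
    return pd.DataFrame({"h": rng.uniform(7.5, 9.5, n),
                         "n": rng.uniform(105.0, 130.0, n)}, index=idx)


class TestCspFormula:
    @pytest.mark.parametrize("dh, dn, expected", [
        (0.0, 0.0, 0.0),
        (0.1, 0.0, 0.1),
        (0.03, 0.6, 0.10440),
    ])
    def test_values(self, dh, dn, expected):
        assert csp(dh, dn) == pytest.approx(expected, abs=1e-5)

    def test_norm_properties(self):
        # zero iff both displacements zero; homogeneous of degree 1
        assert csp(0.0, 0.0) == 0.0
        assert csp(0.02, 0.3) > 0.0
        assert csp(3 * 0.02, 3 * 0.3) == pytest.approx(3 * csp(0.02, 0.3))


class TestThresholds:
    def test_constant_input(self):
        thr = thresholds([0.05] * 20)
        assert thr.trimmed_mean == pytest.approx(0.05)
        assert thr.plus_1sd == pytest.approx(0.05)
        assert thr.plus_2sd == pytest.approx(0.05)

    def test_trim_removes_exactly_the_outliers(self):
        vals = [0.02] * 90 + [1.0] * 10
        thr = thresholds(vals)
        assert thr.trimmed_mean == pytest.approx(0.02)
        assert thr.plus_2sd == pytest.approx(0.02)

    def test_nan_excluded_and_counted(self):
        vals = [0.02] * 19 + [np.nan]
        thr = thresholds(vals)
        assert thr.n_used == 19 - int(np.floor(0.1 * 19))
        assert np.isfinite(thr.plus_2sd)

    def test_ordering_invariance(self, rng):
        vals = rng.uniform(0, 0.4, 50)
        a = thresholds(vals)
        b = thresholds(vals[rng.permutation(50)])
        assert a.trimmed_mean == pytest.approx(b.trimmed_mean)
        assert a.plus_2sd == pytest.approx(b.plus_2sd)

    def test_levels_monotone(self, rng):
        thr = thresholds(rng.uniform(0, 0.4, 50))
        assert thr.trimmed_mean <= thr.plus_1sd <= thr.plus_2sd


class TestGeneratorEndpoints:
    def test_free_state_at_ratio_zero(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound)
        assert np.allclose(series.shifts_h[0], free["h"])
        assert np.allclose(series.shifts_n[0], free["n"])

    def test_bound_state_at_saturation(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound)
        j = series.point_index(1.2)
        assert np.allclose(series.shifts_h.iloc[:, j], bound["h"])

    def test_fast_exchange_midpoint(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound)
        j = series.point_index(0.5)
        expected = 0.5 * (free["h"] + bound["h"])
        assert np.allclose(series.shifts_h.iloc[:, j], expected)

    def test_unsorted_ratios_rejected(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        with pytest.raises(ValueError):
            synthetic.gen_titration_series(free, bound, ratios=[0.0, 0.5, 0.3])


class TestIntensityRatios:
    def test_fast_exchange_keeps_full_intensity(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound, regime="fast")
        out = intensity_ratios(series, 0.0, 0.5)
        assert np.allclose(out["intensity_ratio"], 1.0)

    def test_slow_exchange_tracks_free_population(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound, regime="slow")
        out = intensity_ratios(series, 0.0, 0.5)
        assert np.allclose(out["intensity_ratio"], 0.5)

    def test_saturated_slow_exchange_flagged_broadened(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound, regime="slow")
        out = intensity_ratios(series, 0.0, 1.0)
        assert out["broadened_beyond_detection"].all()
        assert out["intensity_ratio"].isna().all()


class TestTrajectories:
    def test_linear_fast_exchange_angle_zero(self):
        free, bound = shifts_frame(12, 1), shifts_frame(12, 2)
        series = synthetic.gen_titration_series(free, bound)
        out = trajectory_compare(series)
        assert np.allclose(out["angle_deg"], 0.0, atol=1e-6)
        assert np.allclose(out["linearity"], 1.0)

    def test_orthogonal_construction(self):
        idx = pd.Index([1], name="residue")
        ratios = np.array([0.0, 0.3, 1.0])
        # early move purely in 1H, late move purely in 15N
        sh = pd.DataFrame({0: [8.0], 1: [8.02], 2: [8.02]}, index=idx)
        sn = pd.DataFrame({0: [115.0], 1: [115.0], 2: [115.12]}, index=idx)
        series = TitrationSeries(ratios=ratios, shifts_h=sh, shifts_n=sn)
        out = trajectory_compare(series, early=(0.0, 0.3), late=(0.3, 1.0))
        assert out.loc[1, "angle_deg"] == pytest.approx(90.0, abs=1e-6)

    def test_two_mode_titration_round_trip(self):
        free, bound = shifts_frame(10, 1), shifts_frame(10, 2)
        inter = free + np.column_stack([np.full(10, 0.06), np.zeros(10)])
        # bound displaced from intermediate purely along 15N
        bound = inter + np.column_stack([np.zeros(10), np.full(10, 0.9)])
        series = synthetic.gen_titration_series(free, bound,
                                                intermediate_shifts=inter,
                                                switch_ratio=0.3)
        out = trajectory_compare(series, early=(0.0, 0.3), late=(0.5, 1.0))
        assert np.allclose(out["angle_deg"], 90.0, atol=5.0)

    def test_tiny_displacement_flagged_undefined(self):
        free = shifts_frame(5, 1)
        series = synthetic.gen_titration_series(free, free.copy())
        out = trajectory_compare(series)
        assert out["undefined"].all()

    def test_angle_invariant_to_uniform_scaling(self):
        free, bound = shifts_frame(8, 1), shifts_frame(8, 2)
        small = free + 0.1 * (bound - free)
        s1 = synthetic.gen_titration_series(free, bound)
        s2 = synthetic.gen_titration_series(free, small)
        a1 = trajectory_compare(s1)["angle_deg"]
        a2 = trajectory_compare(s2)["angle_deg"]
        # arccos jitter near perfectly collinear trajectories is ~1e-6 deg
        assert np.allclose(a1, a2, atol=1e-4)


class TestCompareConditions:
    def test_identical_tables(self, rng):
        vals = pd.Series(rng.uniform(0, 0.4, 30), index=range(1, 31))
        out = compare_conditions(vals, vals.copy())
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_independent_tables_weakly_correlated(self, rng):
        a = pd.Series(rng.uniform(0, 0.4, 50), index=range(1, 51))
        b = pd.Series(rng.uniform(0, 0.4, 50), index=range(1, 51))
        out = compare_conditions(a, b)
        assert abs(out["spearman_rho"]) < 0.4

    def test_missing_residue_excluded_pairwise(self, rng):
        a = pd.Series(rng.uniform(0, 0.4, 30), index=range(1, 31))
        b = a.drop(7)
        out = compare_conditions(a, b)
        assert 7 not in out["table"].index
        assert len(out["table"]) == 29
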