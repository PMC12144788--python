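import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungturnover import (
    CohortConfig,
    accumulate_moving_window,
    compute_persistence,
    compute_str,
    fit_power,
    labels_by_taxon,
)
from lungturnover.turnover import window_times

from conftest import make_series


def brute_force_curve(presence):
    """Independent oracle: enumerate every window and union its taxa sets."""
    n = presence.shape[1]
    sets = [set(np.flatnonzero(presence[:, j])) for j in range(n)]
    out = []
    for length in range(1, n + 1):
        richness = [
            len(set().union(*sets[start : start + length]))
            for start in range(n - length + 1)
        ]
        out.append(sum(richness) / len(richness))
    return np.array(out)


class TestAccumulation:
    def test_static_community_flat_curve(self):
        presence = np.ones((7, 5), dtype=bool)
        curve = accumulate_moving_window(presence)
        np.testing.assert_array_equal(curve.mean_richness, [7] * 5)
        np.testing.assert_array_equal(curve.n_windows, [5, 4, 3, 2, 1])

    def test_complete_replacement_linear_accumulation(self):
        # 6 samples, 2 unique taxa each, no taxon recurs
        presence = np.zeros((12, 6), dtype=bool)
        for j in range(6):
            presence[2 * j : 2 * j + 2, j] = True
        curve = accumulate_moving_window(presence)
        np.testing.assert_array_equal(curve.mean_richness, [2, 4, 6, 8, 10, 12])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_window_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        presence = rng.random((20, 8)) < 0.3
        presence[0, 0] = True  # at least one occurrence
        curve = accumulate_moving_window(presence)
        np.testing.assert_array_equal(curve.mean_richness, brute_force_curve(presence))

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None)
    def test_mean_richness_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        presence = rng.random((rng.integers(1, 15), rng.integers(2, 10))) < rng.uniform(0.1, 0.9)
        if not presence.any():
            presence[0, 0] = True
        curve = accumulate_moving_window(presence)
        assert np.all(np.diff(curve.mean_richness) >= -1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            accumulate_moving_window(np.zeros((0, 4), dtype=bool))
        with pytest.raises(ValueError):
            accumulate_moving_window(np.zeros((3, 4), dtype=bool))


class TestPowerFit:
    def test_exact_power_law_recovered(self):
        x = np.arange(1.0, 7.0)
        fit = fit_power(x, 3 * x**0.5)
        assert fit.c == pytest.approx(3.0, abs=1e-10)
        assert fit.exponent == pytest.approx(0.5, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert (fit.df_num, fit.df_den) == (1, 4)

    def test_constant_y_degenerate_convention(self):
        fit = fit_power(np.arange(1.0, 6.0), np.full(5, 7.0))
        assert fit.exponent == 0.0
        assert fit.c == 7.0
        assert fit.degenerate
        assert np.isnan(fit.p_value)

    def test_exponent_recovery_under_lognormal_noise(self):
        # oracle: normal equations on log-log, averaged over replicates
        rng = np.random.default_rng(0)
        x = np.linspace(1, 50, 50)
        estimates = []
        for _ in range(200):
            y = 2.0 * x**0.4 * np.exp(rng.normal(0, 0.05, size=50))
            lx, ly = np.log(x), np.log(y)
            lxc = lx - lx.mean()
            estimates.append(fit_power(x, y).exponent)
            assert fit_power(x, y).exponent == pytest.approx(
                float(lxc @ (ly - ly.mean()) / (lxc @ lxc)), abs=1e-10
            )
        assert abs(np.mean(estimates) - 0.4) < 0.01

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2], [1, 2]),
            ([0, 1, 2], [1, 2, 3]),
            ([1, 2, 3], [1, -2, 3]),
        ],
    )
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            fit_power(np.array(x, dtype=float), np.array(y, dtype=float))


class TestComputeStr:
    def test_static_chronic_core_gives_zero_turnover(self, config):
        s = make_series(np.ones((5, 8)))
        labels = labels_by_taxon(compute_persistence(s, config))
        for subset in ("whole", "chronic"):
            fit = compute_str(s, subset, labels, config)
            assert fit.exponent == 0.0
        assert compute_str(s, "intermittent", labels, config) is None

    def test_intermittent_turnover_exceeds_chronic(self, config):
        rng = np.random.default_rng(3)
        chronic = np.ones((4, 12))
        intermittent = np.zeros((24, 12))
        for j in range(12):  # two fresh satellites per sample
            intermittent[2 * j : 2 * j + 2, j] = 1
        s = make_series(np.vstack([chronic, intermittent]), days=range(0, 360, 30))
        labels = labels_by_taxon(compute_persistence(s, config))
        w_int = compute_str(s, "intermittent", labels, config).exponent
        w_chr = compute_str(s, "chronic", labels, config).exponent
        assert w_int > w_chr
        assert w_int == pytest.approx(1.0, abs=1e-10)

    def test_duplicating_taxa_doubles_c_keeps_w(self, config):
        rng = np.random.default_rng(11)
        mat = (rng.random((10, 9)) < 0.4).astype(float)
        mat[0] = 1
        s = make_series(mat)
        s2 = make_series(np.vstack([mat, mat]))
        labels = labels_by_taxon(compute_persistence(s, config))
        labels2 = labels_by_taxon(compute_persistence(s2, config))
        f1 = compute_str(s, "whole", labels, config)
        f2 = compute_str(s2, "whole", labels2, config)
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-12)
        assert f2.c == pytest.approx(2 * f1.c, rel=1e-12)

    def test_matches_hand_computed_log_log_regression(self, config):
        rng = np.random.default_rng(5)
        mat = (rng.random((12, 8)) < 0.35).astype(float)
        mat[0] = 1
        s = make_series(mat)
        labels = labels_by_taxon(compute_persistence(s, config))
        fit = compute_str(s, "whole", labels, config)
        curve = brute_force_curve(mat > 0)
        lx = np.log(np.arange(1, 9))
        ly = np.log(curve)
        lxc = lx - lx.mean()
        slope = float(lxc @ (ly - ly.mean()) / (lxc @ lxc))
        intercept = float(ly.mean() - slope * lx.mean())
        assert fit.exponent == pytest.approx(slope, abs=1e-10)
        assert fit.c == pytest.approx(np.exp(intercept), rel=1e-10)

    def test_days_mode_equals_ordinal_for_even_spacing(self):
        # an even schedule scales the day axis by a constant, leaving the
        # log-log slope unchanged
        rng = np.random.default_rng(8)
        mat = (rng.random((15, 10)) < 0.3).astype(float)
        mat[0] = 1
        s = make_series(mat, days=range(0, 300, 30))
        cfg_s = CohortConfig(str_time_unit="sample_count")
        cfg_d = CohortConfig(str_time_unit="days")
        labels = labels_by_taxon(compute_persistence(s, cfg_s))
        w_s = compute_str(s, "whole", labels, cfg_s).exponent
        w_d = compute_str(s, "whole", labels, cfg_d).exponent
        assert w_d == pytest.approx(w_s, abs=1e-10)

    def test_window_times_days_mode_mean_span_plus_interval(self):
        mat = np.ones((2, 4), dtype=bool)
        curve = accumulate_moving_window(mat)
        days = np.array([0.0, 10.0, 30.0, 60.0])
        x = window_times(curve, "days", days=days)
        mean_interval = 20.0
        expected = [
            0.0 + mean_interval,
            np.mean([10, 20, 30]) + mean_interval,
            np.mean([30, 50]) + mean_interval,
            60 + mean_interval,
        ]
        np.testing.assert_allclose(x, expected)
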