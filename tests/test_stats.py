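"""Consistency statistics: CoV, ICC, gated paired tests, Bland-Altman,
one-sock clinical significance."""

import numpy as np
import pytest
from scipy import stats as sps

from limbcast.stats import (bland_altman, clinical_significance, cov_pct,
                            cov_pct_from_stats, icc, paired_compare,
                            series_with_stats, sock_volume_pct)


def brute_force_icc2(x):
    """Independent oracle: ICC(2,1) from explicitly accumulated ANOVA sums of
    squares (loops, no matrix shortcuts)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (row.mean() - grand) ** 2 for row in x)
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestCov:
    def test_reported_shape_cov_hands_off(self):
        # overall intra-cast shape difference: mean 53523.24, SD 33169.73
        assert cov_pct_from_stats(53523.24, 33169.73) == pytest.approx(61.97, abs=0.005)
        series = series_with_stats(53523.24, 33169.73, n=12, seed=4)
        assert cov_pct(series) == pytest.approx(61.97, abs=0.005)

    @pytest.mark.parametrize("mean,sd,expected", [
        (8906.41, 6400.15, 71.860),   # anteromedial
        (15290.86, 10851.94, 70.970),  # middle
        (16355.30, 10419.91, 63.710),  # posterolateral
    ])
    def test_reported_regional_covs(self, mean, sd, expected):
        assert cov_pct_from_stats(mean, sd) == pytest.approx(expected, abs=0.005)

    def test_constant_series_is_zero(self):
        assert cov_pct([5.0] * 8) == 0.0

    def test_scale_invariance(self, rng):
        x = rng.lognormal(size=30)
        for c in (0.1, 3.0, 1e4):
            assert cov_pct(c * x) == pytest.approx(cov_pct(x), rel=1e-12)

    def test_near_zero_mean_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            cov_pct([1.0, -1.0, 1.2, -0.9])

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            cov_pct([1.0])


class TestICC:
    def test_perfect_agreement_is_one(self):
        x = np.array([[1, 1], [5, 5], [9, 9], [2, 2.0]])
        assert icc(x) == pytest.approx(1.0)

    def test_matches_brute_force_on_small_matrices(self, rng):
        for n in (3, 4, 5):
            x = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * 3
            assert icc(x) == pytest.approx(brute_force_icc2(x), abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        df = pd.DataFrame(x).reset_index().melt(id_vars="index",
                                                var_name="rater", value_name="y")
        ref = pg.intraclass_corr(df, targets="index", raters="rater", ratings="y")
        ref_icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert icc(x) == pytest.approx(ref_icc2, abs=1e-10)

    def test_simulated_variance_components_recover_analytic_value(self, rng):
        # between-SD 10, within-SD 1 -> ICC = 100/101
        subj = rng.normal(0, 10, size=(50, 1))
        x = subj + rng.normal(0, 1, size=(50, 2))
        assert icc(x) == pytest.approx(100 / 101, abs=0.05)

    def test_all_equal_is_undefined(self):
        assert np.isnan(icc(np.ones((4, 2))))

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((2, 2)))


class TestPairedCompare:
    def test_symmetric_differences_give_p_one(self):
        x = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        res = paired_compare(x, y)
        assert res.mean_diff == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        res = paired_compare([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_power_against_half_sd_shift(self, rng):
        # N(0.5, 1) differences, n=200: noncentral-t power ~ 1
        rejections = 0
        for _ in range(20):
            d = rng.normal(0.5, 1.0, 200)
            res = paired_compare(d, np.zeros(200))
            rejections += res.p_value < 0.05
        assert rejections == 20

    def test_heavy_tails_route_to_wilcoxon(self, rng):
        x = rng.standard_cauchy(40)
        res = paired_compare(x, np.zeros(40))
        assert res.test_used == "wilcoxon"

    def test_normal_differences_route_to_t(self, rng):
        x = rng.normal(0, 1, 40)
        res = paired_compare(x, np.zeros(40))
        assert res.test_used == "t"
        t_ref, p_ref = sps.ttest_rel(x, np.zeros(40))
        assert res.statistic == pytest.approx(float(t_ref))
        assert res.p_value == pytest.approx(float(p_ref))

    def test_type_one_error_near_alpha_under_null(self):
        # exchangeable null pairs; the SW-gated procedure must keep its size
        rng = np.random.default_rng(77)
        rejected = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0, 1, 12)
            rejected += paired_compare(x, y).p_value < 0.05
        assert 0.03 <= rejected / n_rep <= 0.07


class TestBlandAltman:
    def test_identical_series(self):
        ba = bland_altman([1, 2, 3.0], [1, 2, 3.0])
        assert ba["bias"] == 0.0 and ba["loa_low"] == 0.0 and ba["loa_high"] == 0.0

    def test_constant_offset(self):
        ba = bland_altman(np.array([6, 7, 8.0]), np.array([1, 2, 3.0]))
        assert ba["bias"] == pytest.approx(5.0)
        assert ba["loa_low"] == pytest.approx(5.0)
        assert ba["loa_high"] == pytest.approx(5.0)

    def test_limits_converge_to_1p96_sd(self, rng):
        d = rng.normal(0, 1, 10_000)
        ba = bland_altman(d, np.zeros_like(d))
        assert ba["loa_high"] == pytest.approx(1.96, abs=0.05)
        assert ba["loa_low"] == pytest.approx(-1.96, abs=0.05)


class TestSockCriterion:
    def test_reported_water_displacement_value(self):
        assert sock_volume_pct(1765.1, 1635.2) == pytest.approx(7.943, abs=1e-3)

    def test_equal_volumes_zero_and_double_hundred(self):
        assert sock_volume_pct(5.0, 5.0) == 0.0
        assert sock_volume_pct(10.0, 5.0) == 100.0

    def test_invalid_baselines(self):
        with pytest.raises(ValueError):
            sock_volume_pct(1.0, 0.0)
        with pytest.raises(ValueError):
            sock_volume_pct(1.0, 2.0)


class TestClinicalSignificance:
    def test_identical_repetitions_forced_below_sock(self, rng):
        rep = rng.uniform(9e5, 1.1e6, 12)
        out = clinical_significance(rep, rep.copy())
        vt = out["volume_test"]
        assert vt.mean_diff == pytest.approx(-0.0794 * rep.mean(), rel=1e-9)
        assert vt.p_value < 0.05
        assert vt.verdict == "below_sock"

    def test_shape_equal_to_sock_volume_is_boundary(self, rng):
        mean_vol = rng.uniform(9e5, 1.1e6, 12)
        shape = 0.0794 * mean_vol
        out = clinical_significance(mean_vol, mean_vol.copy(),
                                    shape_diffs=shape, mean_volumes=mean_vol)
        st = out["shape_test"]
        assert st.mean_diff == pytest.approx(0.0, abs=1e-9)
        assert st.verdict == "at_or_above_sock"

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            clinical_significance([1, 2, 3.0], [1, 2.0])
        with pytest.raises(ValueError):
            clinical_significance([1, 2, 3.0], [1, 2, 3.0],
                                  shape_diffs=[1.0, 2.0], mean_volumes=None)


class TestReportedTableArithmetic:
    def test_method_average_length_and_volume_differences(self):
        # per-repetition means as printed; inter-cast differences re-derived
        h_off_len = (156.70 + 157.05) / 2
        h_on_len = (148.90 + 149.65) / 2
        assert h_off_len - h_on_len == pytest.approx(7.6, abs=0.05)
        h_off_vol = (993910.27 + 997189.23) / 2
        h_on_vol = (1025034.61 + 1012988.99) / 2
        assert h_on_vol - h_off_vol == pytest.approx(23462.04, abs=0.011)
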