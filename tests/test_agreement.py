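"""Agreement statistics: filtering, scaling, outliers, r, ICC, Bland-Altman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from duogait import agreement as A


class TestLowStepExclusion:
    @pytest.mark.parametrize("ins,imu,kept", [(2, 40, False), (3, 40, True),
                                              (40, 2, False), (3, 3, True)])
    def test_boundary_is_exclusive_below_three(self, ins, imu, kept):
        df = pd.DataFrame({"session_id": ["s"], "insole_steps": [ins],
                           "imu_steps": [imu]})
        out, log = A.exclude_low_step_cases(df)
        assert (len(out) == 1) is kept
        assert (len(log) == 0) is kept

    def test_all_above_threshold_is_identity(self):
        df = pd.DataFrame({"session_id": list("abc"),
                           "insole_steps": [3, 10, 40],
                           "imu_steps": [5, 9, 41]})
        out, log = A.exclude_low_step_cases(df)
        pd.testing.assert_frame_equal(out, df)
        assert log == []


class TestScaling:
    def test_endpoints_map_onto_reference_range(self):
        scaled, prm = A.scale_to_reference(np.array([0.0, 1.0]),
                                           np.array([10.0, 20.0]))
        np.testing.assert_allclose(scaled, [10.0, 20.0])
        assert prm["slope"] == 10.0

    def test_identical_distributions_give_identity_map(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        scaled, prm = A.scale_to_reference(x, x)
        np.testing.assert_allclose(scaled, x)
        assert prm["slope"] == pytest.approx(1.0)
        assert prm["intercept"] == pytest.approx(0.0)

    def test_constant_imu_sample_raises_named_error(self):
        with pytest.raises(ValueError, match="cadence"):
            A.scale_to_reference(np.ones(5), np.arange(5.0), feature="cadence")

    @given(st.integers(0, 1000))
    def test_minmax_scaling_preserves_pearson_r(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        scaled, _ = A.scale_to_reference(y, x)
        assert A.pearson(x, scaled) == pytest.approx(A.pearson(x, y), abs=1e-12)


class TestOutliers:
    def test_clean_gaussian_differences_yield_no_flags(self):
        rng = np.random.default_rng(42)
        d = rng.normal(size=50)
        assert A.flag_outliers(d).sum() == 0

    def test_single_displaced_pair_is_flagged(self):
        d = np.linspace(-1.0, 1.0, 40)  # robust z of extremes ~1.7
        d[7] += 10 * d.std()
        mask = A.flag_outliers(d)
        assert mask.sum() == 1 and mask[7]

    def test_degenerate_mad_engages_guard(self):
        assert A.flag_outliers(np.full(10, 3.3)).sum() == 0


class TestPearson:
    def test_perfect_positive_and_negative_correlation(self):
        x = np.arange(10.0)
        assert A.pearson(x, x) == pytest.approx(1.0)
        assert A.pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_brute_force_covariance_ratio(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        # independent oracle: direct evaluation of cov / (sx * sy)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert A.pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            A.pearson(np.ones(5), np.arange(5.0))


def _icc_bruteforce(x, y):
    """Loop-based two-way ANOVA mean squares, written independently."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i][j] - row_means[i] - col_means[j] + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_identical_raters_give_exactly_one(self):
        x = np.random.default_rng(3).normal(size=8)
        assert A.icc_3_1(x, x) == 1.0

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert abs(A.icc_3_1(x, y)) < 0.15

    def test_matches_bruteforce_anova_on_small_fixture(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=6)
        y = x + rng.normal(scale=0.3, size=6)
        assert A.icc_3_1(x, y) == pytest.approx(_icc_bruteforce(x, y),
                                                abs=1e-10)

    def test_matches_pingouin_single_fixed_raters(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        x = rng.normal(size=6)
        y = x + rng.normal(scale=0.3, size=6)
        df = pd.DataFrame({"target": list(range(6)) * 2,
                           "rater": ["ins"] * 6 + ["imu"] * 6,
                           "value": np.r_[x, y]})
        table = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                         ratings="value").set_index("Type")
        assert A.icc_3_1(x, y) == pytest.approx(
            float(table.loc["ICC(C,1)", "ICC"]), abs=1e-10)

    def test_equals_pearson_r_on_standardized_columns(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        assert A.icc_3_1(zx, zy) == pytest.approx(A.pearson(zx, zy), abs=1e-10)

    def test_per_speed_stratification(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.1, size=30)
        groups = np.repeat(["slow", "normal", "fast"], 10)
        overall, per = A.icc_single_fixed(x, y, groups)
        assert set(per) == {"slow", "normal", "fast"}
        assert all(-1 <= v <= 1 for v in per.values())
        assert -1 <= overall <= 1


class TestBlandAltman:
    def test_identical_columns_give_zero_limits(self):
        x = np.random.default_rng(0).normal(size=10)
        ba = A.bland_altman(x, x)
        assert ba.mean_diff == 0 and ba.loa_low == 0 and ba.loa_high == 0

    def test_constant_offset_gives_offset_mean_and_zero_spread(self):
        x = np.arange(10.0)
        ba = A.bland_altman(x + 2.5, x)
        assert ba.mean_diff == pytest.approx(2.5)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_limits_structure(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        ba = A.bland_altman(x, y)
        assert ba.loa_low == pytest.approx(ba.mean_diff - 1.96 * ba.sd_diff)
        assert ba.loa_high == pytest.approx(ba.mean_diff + 1.96 * ba.sd_diff)

    def test_gaussian_coverage_close_to_95_percent(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1000)
        y = x + rng.normal(size=1000)
        ba = A.bland_altman(x, y)
        d = x - y
        coverage = ((d >= ba.loa_low) & (d <= ba.loa_high)).mean()
        assert 0.93 <= coverage <= 0.97


class TestFullComparison:
    def test_shared_truth_cohort_agreement_pattern(self, default_cohort):
        cohort, ins, imu = default_cohort
        paired = A.build_paired_table(ins.dropna(), imu, cohort.manifest)
        result = A.compare_systems(paired)
        table = result.to_frame().set_index("feature")
        for feature in ("walking_cadence", "right_gait_cycle_duration",
                        "left_gait_cycle_duration"):
            assert table.loc[feature, "pearson_r"] >= 0.95
            assert table.loc[feature, "icc"] >= 0.90
        assert (table["pearson_r"].abs() <= 1).all()
        assert (table["icc"] <= 1).all()

    def test_plots_are_written(self, default_cohort, tmp_path):
        cohort, ins, imu = default_cohort
        paired = A.build_paired_table(ins.dropna(), imu, cohort.manifest)
        result = A.compare_systems(paired)
        paths = A.save_agreement_plots(paired, result, tmp_path)
        assert len(paths) == len(A.COMMON_FEATURES)
        for p in paths:
            assert (tmp_path / p.split("/")[-1]).stat().st_size > 0
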