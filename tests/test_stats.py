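"""Normality gate, two-group tests, regression and cohort summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import trichromequant as tq
from trichromequant import stats as tstats
from trichromequant.errors import (
    DegenerateSample,
    DegenerateVariance,
    DegenerateX,
    SampleTooSmall,
    TooFewImages,
)


class TestShapiroWilk:
    def test_calibration_on_normal_samples(self):
        kept = sum(
            tq.shapiro_wilk(np.random.default_rng(s).normal(size=200))[1] > 0.05
            for s in range(100)
        )
        assert kept >= 90

    def test_power_on_exponential_samples(self):
        rejected = sum(
            tq.shapiro_wilk(np.random.default_rng(s).exponential(size=200))[1] < 0.05
            for s in range(100)
        )
        assert rejected >= 99

    def test_degenerate_and_small(self):
        with pytest.raises(DegenerateSample):
            tq.shapiro_wilk([3.0, 3.0, 3.0, 3.0])
        with pytest.raises(SampleTooSmall):
            tq.shapiro_wilk([1.0, 2.0])


class TestStudentsT:
    def test_identical_groups(self):
        t, p = tq.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_shift(self):
        _, p = tq.students_t([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
        assert p < 0.001

    def test_matches_pooled_variance_formula(self):
        a = [2.1, 3.4, 2.9]
        b = [4.0, 5.2, 4.7]
        na, nb = 3, 3
        ma, mb = np.mean(a), np.mean(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        t_manual = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_manual = 2 * sps.t.sf(abs(t_manual), na + nb - 2)
        t, p = tq.students_t(a, b)
        assert t == pytest.approx(t_manual, abs=1e-12)
        assert p == pytest.approx(p_manual, abs=1e-12)

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateVariance):
            tq.students_t([5.0, 5.0], [5.0, 5.0])


def _enumerate_mw_p(a, b):
    """Independent oracle: two-sided exact p by direct pair counting over
    every assignment of the pooled values to the two groups."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    m = n1 * (len(pooled) - n1)
    u_obs = u_stat(a, b)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        if u <= lo + 1e-9 or u >= hi - 1e-9:
            count += 1
        total += 1
    return min(1.0, count / total)


class TestMannWhitney:
    def test_textbook_example(self):
        u, p = tq.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets(self):
        _, p = tq.mann_whitney_u([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == pytest.approx(1.0)

    def test_exact_agrees_with_scipy_on_tie_free_samples(self):
        rng = np.random.default_rng(2)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (6, 6)]:
            a, b = rng.normal(size=n1), rng.normal(0.8, 1, size=n2)
            _, p = tq.mann_whitney_u(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_agrees_with_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(2, 2), (3, 4), (4, 4)]:
            a = rng.integers(0, 4, n1).astype(float)
            b = rng.integers(0, 4, n2).astype(float)
            _, p = tq.mann_whitney_u(a, b)
            assert p == pytest.approx(_enumerate_mw_p(a, b), abs=1e-12)

    def test_asymptotic_branch_used_for_large_samples(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=30), rng.normal(0.5, 1, size=30)
        u, p = tq.mann_whitney_u(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic and p == pytest.approx(ref.pvalue)


class TestCompareFeature:
    def test_two_normal_groups_use_t_test(self):
        rng = np.random.default_rng(10)
        res = tq.compare_feature(
            tq.FeatureSample("f", "A", rng.normal(0, 1, 40)),
            tq.FeatureSample("f", "B", rng.normal(0.2, 1, 40)),
        )
        assert res.test_used == "t_test"
        assert res.group_summaries[0].normal

    def test_skewed_group_triggers_mann_whitney(self):
        rng = np.random.default_rng(10)
        res = tq.compare_feature(
            tq.FeatureSample("f", "A", rng.normal(0, 1, 40)),
            tq.FeatureSample("f", "B", rng.exponential(1, 40) ** 2),
        )
        assert res.test_used == "mann_whitney"
        assert not res.group_summaries[1].normal

    def test_normality_boundary_is_non_normal(self, monkeypatch):
        # p exactly 0.05 must fail the "greater than 0.05" gate
        monkeypatch.setattr(tstats, "shapiro_wilk", lambda x: (0.97, 0.05))
        rng = np.random.default_rng(3)
        res = tq.compare_feature(
            tq.FeatureSample("f", "A", rng.normal(size=20)),
            tq.FeatureSample("f", "B", rng.normal(size=20)),
        )
        assert res.test_used == "mann_whitney"

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        n_sim = 400
        rejections = sum(
            tq.compare_feature(
                tq.FeatureSample("f", "A", rng.normal(size=20)),
                tq.FeatureSample("f", "B", rng.normal(size=20)),
            ).significant
            for _ in range(n_sim)
        )
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_summary_iqr_uses_linear_interpolation(self):
        skewed = np.array([1.0, 2.0, 3.0, 4.0, 50.0, 60.0, 70.0, 2.0, 2.0, 900.0])
        res = tq.compare_feature(
            tq.FeatureSample("f", "A", skewed),
            tq.FeatureSample("f", "B", skewed * 2),
        )
        sa = res.group_summaries[0]
        assert not sa.normal
        assert sa.q1 == pytest.approx(np.percentile(skewed, 25))
        assert sa.q3 == pytest.approx(np.percentile(skewed, 75))
        assert "[" in sa.text and "–" in sa.text


class TestRegression:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        res = tq.linear_regression(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_independent_variables(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        assert tq.linear_regression(x, y).r_squared < 0.05

    def test_four_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 2.5, 4.0, 4.5])
        slope_manual = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        res = tq.linear_regression(x, y)
        assert res.slope == pytest.approx(slope_manual, abs=1e-12)
        assert res.intercept == pytest.approx(y.mean() - slope_manual * x.mean())

    def test_affine_invariance_of_r_squared(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        r2 = tq.linear_regression(x, y).r_squared
        assert tq.linear_regression(3 * x - 7, -2 * y + 11).r_squared == pytest.approx(r2)

    def test_degenerate_x(self):
        with pytest.raises(DegenerateX):
            tq.linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateX):
            tq.linear_regression([1.0, 2.0], [1.0, 2.0])


def _cohort_frame(rng, n_images, blue_area_mu, red_area_mu):
    rows = []
    for i in range(n_images):
        for stain, mu in (("blue_green", blue_area_mu), ("red_pink", red_area_mu)):
            rows.append({
                "image_id": f"img{i}", "stain": stain,
                "mask_area_mm2": 2.2 + rng.normal(0, 0.1),
                "thresh_area_mm2": max(0.01, rng.normal(mu, 0.1)),
                "thresh_to_mask_pct": 50 + rng.normal(0, 5),
                "mask_to_image_pct": 40 + rng.normal(0, 3),
                "mean": 180 + rng.normal(0, 8),
                "median": 182 + rng.normal(0, 8),
                "sd": 30 + rng.normal(0, 2),
                "min": 120 + rng.normal(0, 5),
                "max": 255.0,
                "skewness": rng.normal(0.1, 0.2),
                "kurtosis": rng.normal(-1.0, 0.2),
            })
    return pd.DataFrame(rows)


class TestSummarizeTable:
    def test_designed_area_difference_detected(self):
        rng = np.random.default_rng(0)
        table = tq.summarize_table(_cohort_frame(rng, 15, 1.3, 0.3))
        area_row = table[table["feature"] == "Thresholded area (mm²)"].iloc[0]
        assert area_row["significant"]
        assert table["test"].isin(["t_test", "mann_whitney"]).all()

    def test_identical_stains_never_significant(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = _cohort_frame(rng, 10, 1.0, 1.0)
            # make the two stains identical by construction per image
            blue = df[df["stain"] == "blue_green"].copy()
            red = blue.copy()
            red["stain"] = "red_pink"
            table = tq.summarize_table(pd.concat([blue, red], ignore_index=True))
            assert not table["significant"].any()

    def test_too_few_images(self):
        rng = np.random.default_rng(0)
        with pytest.raises(TooFewImages):
            tq.summarize_table(_cohort_frame(rng, 2, 1.0, 1.0))

    def test_report_lists_test_for_every_feature(self):
        rng = np.random.default_rng(1)
        table = tq.summarize_table(_cohort_frame(rng, 8, 1.0, 0.9))
        report = tq.render_report(table)
        assert len(table) == len(tstats.TABLE_FEATURES)
        assert "test" in table.columns
        assert "Mann–Whitney" in report and "Shapiro" in report
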