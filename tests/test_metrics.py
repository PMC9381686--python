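"""Estimators and intervals: frozen values from the programme round plus
independent-oracle cross-checks."""

import math

import numpy as np
import pytest
from scipy import stats

from fitscreen import (
    chi2_yates,
    compute_all_metrics,
    classify_cohort,
    eir_ratio,
    exact_poisson_ci,
    ic_incidence_rate,
    ic_rate,
    person_years,
    proportion_wald,
    year_split_rates,
)
from fitscreen.metrics import test_sensitivity as sensitivity_estimate
from fitscreen.report import round_half_even

from conftest import random_cohort


def r1(x):
    return round_half_even(x, 1)


def r2(x):
    return round_half_even(x, 2)


class TestWald:
    def test_ppv_of_study_round(self):
        est = proportion_wald(257, 4057)
        assert r1(est.point * 100) == 6.3
        assert (r1(est.ci_low * 100), r1(est.ci_high * 100)) == (5.6, 7.1)

    def test_zero_numerator_clips_at_zero(self):
        est = proportion_wald(0, 100)
        assert est.point == 0.0 and est.ci_low == 0.0

    def test_matches_direct_formula_full_precision(self):
        est = proportion_wald(122, 2212)
        p = 122 / 2212
        z = stats.norm.ppf(0.975)
        half = z * math.sqrt(p * (1 - p) / 2212)
        assert est.point == pytest.approx(p, abs=0)
        assert est.ci_low == pytest.approx(p - half, rel=1e-12)
        assert est.ci_high == pytest.approx(p + half, rel=1e-12)

    def test_matches_statsmodels_normal_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        low, high = proportion_confint(257, 4057, alpha=0.05, method="normal")
        est = proportion_wald(257, 4057)
        assert est.ci_low == pytest.approx(low, rel=1e-10)
        assert est.ci_high == pytest.approx(high, rel=1e-10)

    def test_interval_shrinks_with_sample_size(self):
        widths = [
            proportion_wald(k, n).ci_high - proportion_wald(k, n).ci_low
            for k, n in [(5, 50), (50, 500), (500, 5000)]
        ]
        assert widths == sorted(widths, reverse=True)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion_wald(0, 0)


class TestSensitivity:
    def test_overall_study_round(self):
        est = sensitivity_estimate(257, 124)
        assert est.point == pytest.approx(257 / 381)
        assert (r2(est.ci_low), r2(est.ci_high)) == (0.63, 0.72)

    def test_women_of_study_round(self):
        assert r1(sensitivity_estimate(122, 41).point * 100) == 74.8

    def test_no_missed_cancers_gives_one(self):
        assert sensitivity_estimate(5, 0).point == 1.0

    def test_undefined_without_cancers(self):
        with pytest.raises(ValueError):
            sensitivity_estimate(0, 0)


class TestICRate:
    def test_overall_study_round(self):
        est = ic_rate(134, 142921, 3264)
        assert r1(est.point) == 9.2
        assert (r1(est.ci_low), r1(est.ci_high)) == (7.6, 10.7)

    def test_men_under_65(self):
        assert r1(ic_rate(41, 41113, 838).point) == 9.8

    def test_zero_cancers(self):
        assert ic_rate(0, 10000, 100).point == 0.0


class TestPersonYears:
    def test_study_total_with_subtraction(self):
        assert person_years(214356, 39, subtract_first_year_ics=True) == 428673

    def test_flat_convention(self):
        assert person_years(146185, 39, subtract_first_year_ics=False) == 292370
        assert person_years(146185, 39, subtract_first_year_ics=True) == 292331

    def test_no_first_year_ics_conventions_agree(self):
        assert person_years(1000, 0, subtract_first_year_ics=True) == person_years(
            1000, 0, subtract_first_year_ics=False
        )


class TestIncidence:
    def test_overall_study_round(self):
        est = ic_incidence_rate(134, 292370)
        assert r1(est.point) == 45.8
        assert (r1(est.ci_low), r1(est.ci_high)) == (38.7, 54.3)

    def test_women_under_65(self):
        est = ic_incidence_rate(22, 92486)
        assert r1(est.point) == 23.8
        assert (r1(est.ci_low), r1(est.ci_high)) == (15.7, 36.1)

    def test_unit_rate(self):
        assert ic_incidence_rate(1, 100000).point == pytest.approx(1.0)

    def test_zero_count_has_no_interval(self):
        est = ic_incidence_rate(0, 1000)
        assert est.point == 0.0 and est.method == "none"


def _poisson_tail_limits(count, alpha=0.05, tol=1e-10):
    """Independent oracle: invert the exact Poisson tail sums by bisection."""

    def upper_tail(mean):  # P(X >= count)
        return 1.0 - stats.poisson.cdf(count - 1, mean)

    def lower_tail(mean):  # P(X <= count)
        return stats.poisson.cdf(count, mean)

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if count == 0 else bisect(upper_tail, alpha / 2, 1e-9, count + 1.0)
    high = bisect(lambda m: 1 - lower_tail(m), 1 - alpha / 2, count, 5 * count + 20.0)
    return low, high


class TestExactPoisson:
    def test_zero_count_lower_limit_is_zero(self):
        low, high = exact_poisson_ci(0)
        assert low == 0.0 and high == pytest.approx(-math.log(0.025), rel=1e-6)

    @pytest.mark.parametrize("count,expected", [(22, (13.79, 33.31)), (10, (4.80, 18.39))])
    def test_frozen_limits(self, count, expected):
        low, high = exact_poisson_ci(count)
        assert (round(low, 2), round(high, 2)) == expected

    @pytest.mark.parametrize("count", [1, 3, 10, 22, 46, 134])
    def test_agrees_with_poisson_tail_inversion(self, count):
        low, high = exact_poisson_ci(count)
        olow, ohigh = _poisson_tail_limits(count)
        assert low == pytest.approx(olow, abs=1e-6)
        assert high == pytest.approx(ohigh, abs=1e-6)

    def test_simulated_coverage_at_least_nominal(self):
        """Exact intervals are conservative: >= 95% coverage at several means."""
        rng = np.random.default_rng(20160101)
        for mean in (2.0, 8.0, 30.0, 90.0):
            draws = rng.poisson(mean, size=10000)
            low = np.where(draws == 0, 0.0, stats.chi2.ppf(0.025, 2 * draws) / 2)
            high = stats.chi2.ppf(0.975, 2 * (draws + 1)) / 2
            coverage = np.mean((low <= mean) & (mean <= high))
            assert coverage >= 0.95


class TestEirRatio:
    def test_women_under_65_study_round(self):
        ratio = eir_ratio(22, 92486, 78.3)
        assert r2(ratio.ratio) == 0.30
        assert ratio.expected_count == pytest.approx(78.3 * 92486 / 1e5)

    def test_men_65_plus_study_round(self):
        assert r2(eir_ratio(46, 52968, 198.3).ratio) == 0.44

    def test_ratio_one_when_incidence_equals_reference(self):
        ratio = eir_ratio(50, 100000, 50.0)
        assert ratio.ratio == pytest.approx(1.0)
        assert ratio.ci_low < 1.0 < ratio.ci_high

    def test_interval_is_scaled_exact_poisson(self):
        ratio = eir_ratio(22, 92486, 78.3)
        low, high = exact_poisson_ci(22)
        assert ratio.ci_low == pytest.approx(low / ratio.expected_count)
        assert ratio.ci_high == pytest.approx(high / ratio.expected_count)


class TestChiSquaredYates:
    @pytest.mark.parametrize(
        "table,p,decimals",
        [
            ([[135, 83], [122, 41]], 0.011, 3),       # sensitivity, men vs women
            ([[65, 60], [192, 63]], 0.0000089, 7),    # proximal vs distal
            ([[142, 89], [47, 58]], 0.0061, 4),       # stage I-II vs III-IV
            ([[135, 1710], [122, 2090]], 0.023, 3),   # PPV, men vs women
        ],
    )
    def test_reproduces_printed_p_values(self, table, p, decimals):
        result = chi2_yates(table)
        assert round(result.p_value, decimals) == pytest.approx(p)

    def test_agrees_with_scipy_contingency(self):
        table = [[10, 20], [15, 5]]
        ours = chi2_yates(table)
        stat, p, _, _ = stats.chi2_contingency(np.array(table), correction=True)
        assert ours.statistic == pytest.approx(stat)
        assert ours.p_value == pytest.approx(p)

    def test_proportional_table_has_zero_statistic(self):
        result = chi2_yates([[10, 20], [30, 60]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_yates([[0, 0], [1, 2]])


class TestYearSplit:
    def test_half_denominator_arithmetic(self, report):
        """Year rates recompute from half the full-round denominator."""
        for stratum, splits in report.year_split.items():
            denom = float(
                report.counts.loc[stratum, "fit_negative"]
                + report.counts.loc[stratum, "negative_colonoscopies"]
            )
            for year in ("year1", "year2"):
                split = splits[year]
                assert split["ic_rate"].point == pytest.approx(
                    split["observed"] / (denom / 2) * 1e4
                )
                assert split["ic_incidence"].denominator == denom / 2

    def test_observed_counts_match_study_round(self, report):
        assert report.year_split["M_lt65"]["year2"]["observed"] == 30
        assert report.year_split["M_ge65"]["year1"]["observed"] == 15

    def test_all_first_year_gives_zero_second_year_rate(self):
        import pandas as pd

        row = pd.Series(
            {
                "fit_negative": 1000,
                "negative_colonoscopies": 0,
                "ic_year1": 4,
                "ic_year2": 0,
            }
        )
        split = year_split_rates(row)
        assert split["year2"]["ic_rate"].point == 0.0


class TestComputeAllMetrics:
    def test_stratum_counts_sum_to_overall(self, report):
        counts = report.counts
        strata = [s for s in counts.index if s != "all"]
        for column in counts.columns:
            assert counts.loc[strata, column].sum() == counts.loc["all", column]

    def test_proportions_lie_in_unit_interval(self, report):
        for mapping in (report.participation, report.positivity, report.compliance, report.ppv):
            for est in mapping.values():
                assert 0.0 <= est.point <= 1.0

    def test_sensitivity_complement_identity(self, report):
        """sensitivity + FIT-IC share = 1 within each stratum."""
        for stratum in ("F_lt65", "F_ge65", "M_lt65", "M_ge65"):
            est = report.sensitivity[stratum]
            share = (est.denominator - est.numerator) / est.denominator
            assert est.point + share == pytest.approx(1.0)

    def test_all_zero_cancer_cohort_flags_sensitivity_undefined(self):
        cohort = random_cohort(seed=21, n=120)
        cohort.crc_register = cohort.crc_register.iloc[0:0]
        cohort.colonoscopies["crc_found"] = 0
        report = compute_all_metrics(classify_cohort(cohort))
        assert report.sensitivity["all"] is None
        assert report.ic_rate["all"].point == 0.0
        assert report.counts.loc["all", "ic_total"] == 0

    @pytest.mark.parametrize("seed", [5, 6])
    def test_aggregates_equal_brute_force_recount(self, seed):
        """Each reported numerator/denominator recomputes from the person table."""
        classified = classify_cohort(random_cohort(seed=seed, n=500))
        report = compute_all_metrics(classified)
        df = classified.df
        for stratum in [s for s in report.counts.index if s != "all"]:
            sub = df[df["stratum"] == stratum]
            negatives = int((sub["participant"] & ~sub["fit_positive"]).sum())
            neg_col = int(
                (
                    sub["fit_positive"]
                    & sub["colonoscopy_performed"]
                    & (sub["outcome"] != "sd_crc")
                ).sum()
            )
            ics = int(
                sub["outcome"].isin(["fit_ic", "colonoscopy_ic", "ic_noncompliant"]).sum()
            )
            if stratum in report.ic_rate:
                est = report.ic_rate[stratum]
                assert est.numerator == ics
                assert est.denominator == negatives + neg_col
            assert report.person_years[stratum] == 2 * (negatives + neg_col)
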