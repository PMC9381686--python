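"""Estimators and confidence intervals for one screening round.

Point estimators
----------------
participation   valid FITs / invited
positivity      FIT positives / valid FITs
compliance      screening colonoscopies / FIT positives
PPV             SD-CRC / FIT positives
sensitivity     SD-CRC / (SD-CRC + FIT-IC)         (programmatic test sensitivity)
IC rate         ICs per 10,000 screening negatives (FIT negatives + cancer-free
                screening colonoscopies); all three IC subtypes in the numerator
IC incidence    ICs per 100,000 person-years among screening negatives
rate ratio      IC incidence / EIR (background incidence, treated as fixed)

Interval methods
----------------
Proportions get Wald intervals, incidence rates log-normal intervals
(``rate * exp(+-z / sqrt(count))``), and the rate ratio an exact Poisson
interval on the observed count divided by the expected count
(chi-square-quantile form). Two-sample comparisons use the chi-squared test
with Yates' continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGE_GROUPS, SEXES, STRATA, ScreeningConfig
from .classify import ClassifiedCohort, OutcomeClass


@dataclass(frozen=True)
class RateEstimate:
    """A rate or proportion with its confidence interval.

    ``scale`` multiplies the raw ratio for presentation: 1 for proportions,
    1e4 for the IC rate, 1e5 for incidence per 100,000 person-years.
    """

    numerator: float
    denominator: float
    scale: float
    point: float
    ci_low: float
    ci_high: float
    method: str  # wald | lognormal | exact_poisson | none

    def to_dict(self) -> dict[str, Any]:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "scale": self.scale,
            "point": self.point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
        }


@dataclass(frozen=True)
class RateRatio:
    """Observed/expected rate ratio against a fixed reference rate (EIR)."""

    observed_count: float
    person_years: float
    reference_rate: float  # per 100,000 person-years
    expected_count: float
    ratio: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "observed_count": self.observed_count,
            "person_years": self.person_years,
            "reference_rate": self.reference_rate,
            "expected_count": self.expected_count,
            "ratio": self.ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


@dataclass(frozen=True)
class TestResult2x2:
    """Yates-corrected chi-squared test on a 2x2 table."""

    table: tuple[tuple[float, float], tuple[float, float]]
    statistic: float
    p_value: float
    correction: str = "yates"

    def to_dict(self) -> dict[str, Any]:
        return {
            "table": [list(row) for row in self.table],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "correction": self.correction,
        }


def _z(alpha: float) -> float:
    return float(stats.norm.ppf(1 - alpha / 2))


def proportion_wald(
    numerator: float, denominator: float, alpha: float = 0.05, scale: float = 1.0
) -> RateEstimate:
    """Wald (normal-approximation) interval for a binomial proportion.

    The interval is clipped to [0, 1] before scaling.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    half = _z(alpha) * math.sqrt(p * (1 - p) / denominator)
    return RateEstimate(
        numerator=numerator,
        denominator=denominator,
        scale=scale,
        point=p * scale,
        ci_low=max(0.0, p - half) * scale,
        ci_high=min(1.0, p + half) * scale,
        method="wald",
    )


def test_sensitivity(
    sd_count: float, fit_ic_count: float, alpha: float = 0.05
) -> RateEstimate:
    """Programmatic test sensitivity SD-CRC / (SD-CRC + FIT-IC), Wald interval."""
    total = sd_count + fit_ic_count
    if total <= 0:
        raise ValueError("no cancers: sensitivity undefined")
    return proportion_wald(sd_count, total, alpha)


def ic_rate(
    total_ics: float,
    fit_negatives: float,
    negative_colonoscopies: float,
    alpha: float = 0.05,
) -> RateEstimate:
    """Interval cancers per 10,000 screening negatives (Wald interval).

    The denominator pools FIT negatives with FIT positives whose screening
    colonoscopy was cancer-free; the numerator includes FIT-ICs,
    colonoscopy-ICs and ICs in colonoscopy non-compliers.
    """
    if min(total_ics, fit_negatives, negative_colonoscopies) < 0:
        raise ValueError("counts must be non-negative")
    denominator = fit_negatives + negative_colonoscopies
    return proportion_wald(total_ics, denominator, alpha, scale=1e4)


def person_years(
    n_followed: float,
    first_year_ic_count: float = 0,
    config: ScreeningConfig | None = None,
    *,
    subtract_first_year_ics: bool | None = None,
) -> float:
    """Follow-up person-years: two years each, optionally minus one year per
    interval cancer diagnosed within the first year of invitation.

    The subtraction convention follows ``config.person_year_subtraction``
    unless overridden explicitly.
    """
    if first_year_ic_count > n_followed:
        raise ValueError("first-year ICs cannot exceed persons followed")
    if subtract_first_year_ics is None:
        subtract_first_year_ics = (
            config.person_year_subtraction if config is not None else False
        )
    py = 2.0 * n_followed
    if subtract_first_year_ics:
        py -= first_year_ic_count
    return py


def ic_incidence_rate(
    total_ics: float, person_years_: float, alpha: float = 0.05
) -> RateEstimate:
    """ICs per 100,000 person-years, log-normal interval.

    CI is ``rate * exp(+-z / sqrt(count))``; undefined (method 'none') when the
    count is zero.
    """
    if person_years_ <= 0:
        raise ValueError("person_years must be positive")
    rate = total_ics / person_years_ * 1e5
    if total_ics <= 0:
        return RateEstimate(total_ics, person_years_, 1e5, rate, math.nan, math.nan, "none")
    shift = _z(alpha) / math.sqrt(total_ics)
    return RateEstimate(
        numerator=total_ics,
        denominator=person_years_,
        scale=1e5,
        point=rate,
        ci_low=rate * math.exp(-shift),
        ci_high=rate * math.exp(shift),
        method="lognormal",
    )


def exact_poisson_ci(count: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence limits for a Poisson count, on the count scale.

    ``low = chi2.ppf(alpha/2, 2k) / 2`` (zero when k = 0) and
    ``high = chi2.ppf(1 - alpha/2, 2k + 2) / 2``; equivalently gamma quantiles.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    low = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count)) / 2.0
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1))) / 2.0
    return low, high


def eir_ratio(
    total_ics: float, person_years_: float, eir: float, alpha: float = 0.05
) -> RateRatio:
    """IC incidence divided by the background incidence rate (EIR).

    The EIR is treated as a fixed external rate; the interval is the exact
    Poisson interval of the observed count divided by the expected count
    ``EIR * person_years / 100,000``.
    """
    if eir <= 0 or person_years_ <= 0:
        raise ValueError("eir and person_years must be positive")
    expected = eir * person_years_ / 1e5
    low, high = exact_poisson_ci(total_ics, alpha)
    return RateRatio(
        observed_count=total_ics,
        person_years=person_years_,
        reference_rate=eir,
        expected_count=expected,
        ratio=total_ics / expected,
        ci_low=low / expected,
        ci_high=high / expected,
    )


def chi2_yates(table: Any) -> TestResult2x2:
    """Chi-squared test with Yates' continuity correction on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("cells must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=True)
    return TestResult2x2(
        table=((arr[0, 0], arr[0, 1]), (arr[1, 0], arr[1, 1])),
        statistic=float(statistic),
        p_value=float(p),
    )


def year_split_rates(
    counts_row: pd.Series, eir: float | None = None, alpha: float = 0.05
) -> dict[str, dict[str, Any]]:
    """Per-follow-up-year IC rates for one stratum.

    The negatives denominator for each year is taken as half the full-round
    denominator; each half-denominator individual contributes one person-year,
    so the yearly person-years also equal half the full-round denominator.
    """
    denominator = float(
        counts_row["fit_negative"] + counts_row["negative_colonoscopies"]
    )
    out: dict[str, dict[str, Any]] = {}
    for year, observed_key in (("year1", "ic_year1"), ("year2", "ic_year2")):
        observed = float(counts_row[observed_key])
        half = denominator / 2.0
        entry: dict[str, Any] = {
            "observed": observed,
            "ic_rate": proportion_wald(observed, half, alpha, scale=1e4),
            "ic_incidence": ic_incidence_rate(observed, half, alpha),
        }
        if eir is not None:
            entry["eir_ratio"] = eir_ratio(observed, half, eir, alpha)
        out[year] = entry
    return out


@dataclass
class MetricsReport:
    """Every estimator of the evaluation, at full precision.

    Dictionary keys are stratum keys (``F_lt65`` ...) plus pooled keys:
    ``all``, per-sex ``F``/``M``, per-age ``lt65``/``ge65`` and, for
    sensitivity, ``proximal``/``distal``. Sensitivity entries are ``None``
    where no cancers exist (undefined).
    """

    counts: pd.DataFrame
    participation: dict[str, RateEstimate]
    positivity: dict[str, RateEstimate]
    compliance: dict[str, RateEstimate]
    ppv: dict[str, RateEstimate]
    sensitivity: dict[str, RateEstimate | None]
    ic_rate: dict[str, RateEstimate]
    person_years: dict[str, float]
    total_followup_person_years: float
    ic_incidence: dict[str, RateEstimate]
    eir_ratio: dict[str, RateRatio]
    year_split: dict[str, dict[str, dict[str, Any]]]
    tests: dict[str, TestResult2x2] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        def conv(obj: Any) -> Any:
            if obj is None or isinstance(obj, (int, float, str, bool)):
                return obj
            if isinstance(obj, (RateEstimate, RateRatio, TestResult2x2)):
                return obj.to_dict()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            return obj

        return {
            "counts": {
                str(idx): {k: int(v) for k, v in row.items()}
                for idx, row in self.counts.iterrows()
            },
            "participation": conv(self.participation),
            "positivity": conv(self.positivity),
            "compliance": conv(self.compliance),
            "ppv": conv(self.ppv),
            "sensitivity": conv(self.sensitivity),
            "ic_rate": conv(self.ic_rate),
            "person_years": conv(self.person_years),
            "total_followup_person_years": self.total_followup_person_years,
            "ic_incidence": conv(self.ic_incidence),
            "eir_ratio": conv(self.eir_ratio),
            "year_split": conv(self.year_split),
            "tests": conv(self.tests),
        }


def _denominator(row: pd.Series) -> float:
    return float(row["fit_negative"] + row["negative_colonoscopies"])


def _pooled_rows(counts: pd.DataFrame) -> dict[str, pd.Series]:
    """Stratum rows plus pooled per-sex and per-age rows."""
    rows: dict[str, pd.Series] = {
        str(stratum): counts.loc[stratum]
        for stratum in counts.index
        if stratum != "all"
    }
    for sex in SEXES:
        members = [s for s in rows if s.startswith(f"{sex}_")]
        if members:
            rows[sex] = sum(rows[s] for s in members)  # type: ignore[assignment]
    for age in AGE_GROUPS:
        members = [s for s in STRATA if s.endswith(age) and s in rows]
        if members:
            rows[age] = sum(rows[s] for s in members)  # type: ignore[assignment]
    rows["all"] = counts.loc["all"]
    return rows


def _maybe_sensitivity(row: pd.Series, alpha: float) -> RateEstimate | None:
    total = row["sd_crc"] + row["fit_ic"]
    if total <= 0:
        return None
    return test_sensitivity(float(row["sd_crc"]), float(row["fit_ic"]), alpha)


def compute_all_metrics(
    classified: ClassifiedCohort, config: ScreeningConfig | None = None
) -> MetricsReport:
    """All estimators for a classified cohort, full precision throughout.

    Rounding happens only at rendering time (see :mod:`fitscreen.report`).
    """
    config = config or classified.config
    alpha = config.ci_alpha
    counts = classified.counts()
    rows = _pooled_rows(counts)

    participation = {
        key: proportion_wald(float(r["participants"]), float(r["invited"]), alpha)
        for key, r in rows.items()
        if r["invited"] > 0
    }
    positivity = {
        key: proportion_wald(float(r["fit_positive"]), float(r["participants"]), alpha)
        for key, r in rows.items()
        if r["participants"] > 0
    }
    compliance = {
        key: proportion_wald(float(r["colonoscopies"]), float(r["fit_positive"]), alpha)
        for key, r in rows.items()
        if r["fit_positive"] > 0
    }
    ppv = {
        key: proportion_wald(float(r["sd_crc"]), float(r["fit_positive"]), alpha)
        for key, r in rows.items()
        if r["fit_positive"] > 0
    }
    sensitivity: dict[str, RateEstimate | None] = {
        key: _maybe_sensitivity(r, alpha) for key, r in rows.items()
    }
    # Sensitivity by tumor localization (unknowns excluded from the comparison).
    df = classified.df
    sens_pool = df[df["outcome"].isin([OutcomeClass.SD_CRC.value, OutcomeClass.FIT_IC.value])]
    for loc in ("proximal", "distal"):
        sub = sens_pool[sens_pool["localization"] == loc]
        sd = int((sub["outcome"] == OutcomeClass.SD_CRC).sum())
        ic = int((sub["outcome"] == OutcomeClass.FIT_IC).sum())
        sensitivity[loc] = (
            test_sensitivity(sd, ic, alpha) if sd + ic > 0 else None
        )

    ic_rates = {
        key: ic_rate(
            float(r["ic_total"]),
            float(r["fit_negative"]),
            float(r["negative_colonoscopies"]),
            alpha,
        )
        for key, r in rows.items()
        if _denominator(r) > 0
    }
    pys = {
        key: person_years(
            _denominator(r), float(r["ic_year1"]), config
        )
        for key, r in rows.items()
    }
    total_followup = person_years(
        float(counts.loc["all", "invited"]),
        float(counts.loc["all", "ic_year1"]),
        subtract_first_year_ics=True,
    )
    ic_incidence = {
        key: ic_incidence_rate(float(rows[key]["ic_total"]), pys[key], alpha)
        for key in rows
        if pys[key] > 0
    }
    ratios = {
        stratum: eir_ratio(
            float(rows[stratum]["ic_total"]),
            pys[stratum],
            config.eir_table[stratum],
            alpha,
        )
        for stratum in STRATA
        if stratum in rows and pys[stratum] > 0
    }
    year_split = {
        stratum: year_split_rates(
            rows[stratum], config.eir_table.get(stratum), alpha
        )
        for stratum in STRATA
        if stratum in rows and _denominator(rows[stratum]) > 0
    }

    tests = _standard_tests(df, rows)
    return MetricsReport(
        counts=counts,
        participation=participation,
        positivity=positivity,
        compliance=compliance,
        ppv=ppv,
        sensitivity=sensitivity,
        ic_rate=ic_rates,
        person_years=pys,
        total_followup_person_years=total_followup,
        ic_incidence=ic_incidence,
        eir_ratio=ratios,
        year_split=year_split,
        tests=tests,
    )


def _standard_tests(
    df: pd.DataFrame, rows: dict[str, pd.Series]
) -> dict[str, TestResult2x2]:
    """The between-group comparisons reported for the programme round."""
    tests: dict[str, TestResult2x2] = {}

    def safe(name: str, table: list[list[float]]) -> None:
        arr = np.asarray(table, dtype=float)
        if (arr < 0).any() or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            return
        tests[name] = chi2_yates(arr)

    if "M" in rows and "F" in rows:
        m, f = rows["M"], rows["F"]
        safe(
            "ppv_men_vs_women",
            [
                [m["sd_crc"], m["fit_positive"] - m["sd_crc"]],
                [f["sd_crc"], f["fit_positive"] - f["sd_crc"]],
            ],
        )
        safe(
            "sensitivity_men_vs_women",
            [[m["sd_crc"], m["fit_ic"]], [f["sd_crc"], f["fit_ic"]]],
        )
        safe(
            "ic_rate_men_vs_women",
            [
                [m["ic_total"], _denominator(m) - m["ic_total"]],
                [f["ic_total"], _denominator(f) - f["ic_total"]],
            ],
        )
    if "M_ge65" in rows and "F_ge65" in rows:
        m, f = rows["M_ge65"], rows["F_ge65"]
        safe(
            "sensitivity_ge65_men_vs_women",
            [[m["sd_crc"], m["fit_ic"]], [f["sd_crc"], f["fit_ic"]]],
        )
    if "lt65" in rows and "ge65" in rows:
        y, o = rows["lt65"], rows["ge65"]
        safe(
            "sensitivity_age_groups",
            [[y["sd_crc"], y["fit_ic"]], [o["sd_crc"], o["fit_ic"]]],
        )

    pool = df[df["outcome"].isin([OutcomeClass.SD_CRC.value, OutcomeClass.FIT_IC.value])]
    loc = pool[pool["localization"].isin(["proximal", "distal"])]
    safe(
        "sensitivity_proximal_vs_distal",
        [
            [
                (loc["localization"].eq("proximal") & loc["outcome"].eq(OutcomeClass.SD_CRC)).sum(),
                (loc["localization"].eq("proximal") & loc["outcome"].eq(OutcomeClass.FIT_IC)).sum(),
            ],
            [
                (loc["localization"].eq("distal") & loc["outcome"].eq(OutcomeClass.SD_CRC)).sum(),
                (loc["localization"].eq("distal") & loc["outcome"].eq(OutcomeClass.FIT_IC)).sum(),
            ],
        ],
    )

    def mode_counts(outcome: OutcomeClass, column: str, values: tuple[str, str]) -> list[float]:
        sub = df[df["outcome"] == outcome]
        return [float((sub[column] == v).sum()) for v in values]

    for other, tag in (
        (OutcomeClass.FIT_IC, "fit_ic"),
        (OutcomeClass.NONPARTICIPANT_CRC, "nonparticipant"),
    ):
        sd_sex = mode_counts(OutcomeClass.SD_CRC, "sex", ("F", "M"))
        ot_sex = mode_counts(other, "sex", ("F", "M"))
        safe(f"gender_sd_vs_{tag}", [sd_sex, ot_sex])
        sd_loc = mode_counts(OutcomeClass.SD_CRC, "localization", ("proximal", "distal"))
        ot_loc = mode_counts(other, "localization", ("proximal", "distal"))
        safe(f"localization_sd_vs_{tag}", [sd_loc, ot_loc])
        sd_stage = mode_counts(OutcomeClass.SD_CRC, "stage_group", ("I_II", "III_IV"))
        ot_stage = mode_counts(other, "stage_group", ("I_II", "III_IV"))
        safe(f"stage_sd_vs_{tag}", [sd_stage, ot_stage])
    return tests
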