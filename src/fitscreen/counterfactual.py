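"""Re-evaluation of the round under different positivity cut-offs.

The principal scenario raises the women's cut-off to the men's 80 µg/g.
Participants whose hemoglobin falls below the new cut-off become
FIT-negative; their screening-detected cancers, colonoscopy interval
cancers and cancers after non-compliance are all assumed to have surfaced
as FIT interval cancers within the same window (an assumption that can
overestimate the counterfactual IC rate: some might have stayed
undiagnosed until the next round). Their cancer-free colonoscopies leave
the negative-colonoscopy denominator and the persons join the FIT
negatives. Cancer totals per stratum are conserved; year-of-diagnosis
splits are deliberately not produced for reclassified cohorts, because the
former screening-detected cancers carry no meaningful post-negative-test
diagnosis timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import SEXES, STRATA, ScreeningConfig
from .classify import (
    ClassifiedCohort,
    OutcomeClass,
    _positive_mask,
    classify_cohort,
)
from .cohort import Cohort
from .metrics import (
    RateEstimate,
    RateRatio,
    TestResult2x2,
    chi2_yates,
    eir_ratio,
    ic_rate,
    test_sensitivity,
)

RECLASSIFIED_TO_FIT_IC = (
    OutcomeClass.SD_CRC.value,
    OutcomeClass.COLONOSCOPY_IC.value,
    OutcomeClass.IC_NONCOMPLIANT.value,
)


@dataclass
class CounterfactualResult:
    """Reclassified counts and recomputed metrics under new cut-offs."""

    cutoff_by_sex: dict[str, float]
    counts: pd.DataFrame
    sensitivity: dict[str, RateEstimate | None]
    ic_rate: dict[str, RateEstimate]
    eir_ratio: dict[str, RateRatio]
    tests: dict[str, TestResult2x2] = field(default_factory=dict)
    classified: ClassifiedCohort | None = None

    def to_dict(self) -> dict[str, Any]:
        return {
            "cutoff_by_sex": self.cutoff_by_sex,
            "counts": {
                str(idx): {k: int(v) for k, v in row.items()}
                for idx, row in self.counts.iterrows()
            },
            "sensitivity": {
                k: (v.to_dict() if v is not None else None)
                for k, v in self.sensitivity.items()
            },
            "ic_rate": {k: v.to_dict() for k, v in self.ic_rate.items()},
            "eir_ratio": {k: v.to_dict() for k, v in self.eir_ratio.items()},
            "tests": {k: v.to_dict() for k, v in self.tests.items()},
        }


def apply_uniform_cutoff(
    data: ClassifiedCohort | Cohort,
    cutoff: float | Mapping[str, float] = 80.0,
    config: ScreeningConfig | None = None,
) -> CounterfactualResult:
    """Re-evaluate the round with a new positivity cut-off in both sexes.

    Given a :class:`Cohort` of raw records, the cohort is reclassified from
    scratch under the new configuration. Given an already classified cohort,
    the reclassification shortcut is applied in place: outcomes of affected
    participants (positive before, negative now) are remapped to FIT-IC and
    the denominators adjusted. Both routes agree exactly whenever hemoglobin
    information resolves the new cut-off (a property pinned in the tests).

    Cut-offs may only be raised relative to the classification being
    reinterpreted; lowering one would require colonoscopy outcomes that were
    never observed.
    """
    if isinstance(cutoff, Mapping):
        new_cutoffs = {sex: float(cutoff[sex]) for sex in SEXES}
    else:
        new_cutoffs = {sex: float(cutoff) for sex in SEXES}

    if isinstance(data, Cohort):
        base_config = config or data.config
        new_config = base_config.with_cutoffs(new_cutoffs)
        classified = classify_cohort(data, new_config)
        return _result_from_classified(classified, new_cutoffs)

    classified = data
    base_config = config or classified.config
    for sex in SEXES:
        if new_cutoffs[sex] < base_config.cutoff_by_sex[sex]:
            raise ValueError(
                "cannot lower a cut-off on an already classified cohort; "
                "reclassify the raw cohort instead"
            )
    new_config = base_config.with_cutoffs(new_cutoffs)
    df = classified.df.copy()
    new_positive = _positive_mask(df, new_config)
    affected = df["fit_positive"].to_numpy() & ~new_positive
    df["fit_positive"] = new_positive
    outcome = df["outcome"].to_numpy(dtype=object).copy()
    remap = affected & np.isin(outcome, RECLASSIFIED_TO_FIT_IC)
    outcome[remap] = OutcomeClass.FIT_IC.value
    df["outcome"] = outcome
    shortcut = ClassifiedCohort(df=df, config=new_config)
    return _result_from_classified(shortcut, new_cutoffs)


def _result_from_classified(
    classified: ClassifiedCohort, new_cutoffs: dict[str, float]
) -> CounterfactualResult:
    config = classified.config
    alpha = config.ci_alpha
    counts = classified.counts()

    rows: dict[str, pd.Series] = {
        str(s): counts.loc[s] for s in counts.index if s != "all"
    }
    for sex in SEXES:
        members = [k for k in rows if k.startswith(f"{sex}_")]
        if members:
            rows[sex] = sum(rows[k] for k in members)  # type: ignore[assignment]
    rows["all"] = counts.loc["all"]

    sensitivity: dict[str, RateEstimate | None] = {}
    rates: dict[str, RateEstimate] = {}
    ratios: dict[str, RateRatio] = {}
    for key, row in rows.items():
        total = row["sd_crc"] + row["fit_ic"]
        sensitivity[key] = (
            test_sensitivity(float(row["sd_crc"]), float(row["fit_ic"]), alpha)
            if total > 0
            else None
        )
        denominator = float(row["fit_negative"] + row["negative_colonoscopies"])
        if denominator > 0:
            rates[key] = ic_rate(
                float(row["ic_total"]),
                float(row["fit_negative"]),
                float(row["negative_colonoscopies"]),
                alpha,
            )
            if key in STRATA and key in config.eir_table:
                # Person-years convention for reclassified cohorts: a flat two
                # years per screening negative under the new cut-off.
                ratios[key] = eir_ratio(
                    float(row["ic_total"]),
                    2.0 * denominator,
                    config.eir_table[key],
                    alpha,
                )

    tests: dict[str, TestResult2x2] = {}

    def safe(name: str, table: list[list[float]]) -> None:
        arr = np.asarray(table, dtype=float)
        if (arr < 0).any() or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            return
        tests[name] = chi2_yates(arr)

    if "M" in rows and "F" in rows:
        m, f = rows["M"], rows["F"]
        safe(
            "sensitivity_men_vs_women",
            [[m["sd_crc"], m["fit_ic"]], [f["sd_crc"], f["fit_ic"]]],
        )
        dm = float(m["fit_negative"] + m["negative_colonoscopies"])
        df_ = float(f["fit_negative"] + f["negative_colonoscopies"])
        safe(
            "ic_rate_men_vs_women",
            [[m["ic_total"], dm - m["ic_total"]], [f["ic_total"], df_ - f["ic_total"]]],
        )

    return CounterfactualResult(
        cutoff_by_sex=new_cutoffs,
        counts=counts,
        sensitivity=sensitivity,
        ic_rate=rates,
        eir_ratio=ratios,
        tests=tests,
        classified=classified,
    )
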