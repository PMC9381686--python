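"""WEO outcome classification of one screening round.

Every invitee is assigned exactly one outcome class, following the World
Endoscopy Organization definitions for FIT-based programmes:

* ``SD_CRC`` — screening-detected cancer: positive FIT, screening colonoscopy
  performed, cancer found at that colonoscopy;
* ``FIT_IC`` — interval cancer after a negative FIT;
* ``COLONOSCOPY_IC`` — interval cancer after a positive FIT and a negative
  (cancer-free) screening colonoscopy;
* ``IC_NONCOMPLIANT`` — cancer after a positive FIT in someone who never
  underwent the offered colonoscopy (counts as an interval cancer);
* ``NONPARTICIPANT_CRC`` — cancer in a non-participant (NOT an interval
  cancer);
* ``NO_CRC`` — no registered cancer within the follow-up window.

Cancers diagnosed within the window are additionally binned into follow-up
year 1 (months 0-12, boundary inclusive) or year 2 (months >12-24).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import STRATA, ScreeningConfig
from .cohort import (
    CATEGORY_BOUNDS,
    Cohort,
    CohortValidationError,
    dedupe_invitations,
    months_from_invitation,
)


class OutcomeClass(str, Enum):
    SD_CRC = "sd_crc"
    FIT_IC = "fit_ic"
    COLONOSCOPY_IC = "colonoscopy_ic"
    IC_NONCOMPLIANT = "ic_noncompliant"
    NONPARTICIPANT_CRC = "nonparticipant_crc"
    NO_CRC = "no_crc"


#: Outcome classes that count as interval cancers.
IC_CLASSES = (
    OutcomeClass.FIT_IC,
    OutcomeClass.COLONOSCOPY_IC,
    OutcomeClass.IC_NONCOMPLIANT,
)
#: Outcome classes carrying a registered cancer.
CANCER_CLASSES = IC_CLASSES + (OutcomeClass.SD_CRC, OutcomeClass.NONPARTICIPANT_CRC)


def is_fit_positive(
    sex: str,
    hb_value: float | None = None,
    hb_category: str | None = None,
    config: ScreeningConfig | None = None,
) -> bool:
    """True iff the analyzable FIT meets the sex-specific cut-off (inclusive >=).

    A coarse ``hb_category`` can stand in for the quantitative value as long as
    the cut-off does not fall strictly inside the category's interval: ``ge80``
    is positive for both sexes, ``40to79`` positive only where the cut-off is
    40 µg/g, ``lt40`` negative for both default cut-offs.
    """
    config = config or ScreeningConfig()
    cutoff = config.cutoff_by_sex[sex]
    if hb_value is not None and not (isinstance(hb_value, float) and np.isnan(hb_value)):
        return float(hb_value) >= cutoff
    if hb_category is not None and isinstance(hb_category, str):
        low, high = CATEGORY_BOUNDS[hb_category]
        if low >= cutoff:
            return True
        if high <= cutoff:
            return False
        raise ValueError(
            f"hb_category {hb_category!r} cannot be resolved against cut-off {cutoff}"
        )
    raise ValueError("analyzable FIT record lacks hb_value and hb_category")


def followup_year(months: float) -> str:
    """'year1' for diagnoses within 12 months of invitation, else 'year2'.

    Month 12 itself belongs to year 1. Months outside (0, 24] should have been
    excluded upstream and raise here.
    """
    if not 0 < months <= 24:
        raise ValueError(f"months_from_invitation {months} outside (0, 24]")
    return "year1" if months <= 12 else "year2"


def classify_episode(
    sex: str,
    result_status: str,
    hb_value: float | None,
    hb_category: str | None,
    colonoscopy_performed: bool,
    crc_found_at_colonoscopy: bool,
    crc_in_window: bool,
    config: ScreeningConfig | None = None,
) -> OutcomeClass:
    """Classify one screening episode (reference scalar path).

    ``crc_in_window`` refers to the earliest registered cancer within
    ``followup_months`` of invitation. A colonoscopy flagged ``crc_found``
    without a matching register record is inconsistent input.
    """
    config = config or ScreeningConfig()
    participant = result_status == "analyzable"
    if crc_found_at_colonoscopy and not crc_in_window:
        raise CohortValidationError(
            ["crc_found colonoscopy without a registered cancer in the window"]
        )
    if not participant:
        return OutcomeClass.NONPARTICIPANT_CRC if crc_in_window else OutcomeClass.NO_CRC
    positive = is_fit_positive(sex, hb_value, hb_category, config)
    if not positive:
        return OutcomeClass.FIT_IC if crc_in_window else OutcomeClass.NO_CRC
    if colonoscopy_performed and crc_found_at_colonoscopy:
        return OutcomeClass.SD_CRC
    if not crc_in_window:
        return OutcomeClass.NO_CRC
    if colonoscopy_performed:
        return OutcomeClass.COLONOSCOPY_IC
    return OutcomeClass.IC_NONCOMPLIANT


COUNT_COLUMNS = [
    "invited",
    "participants",
    "fit_positive",
    "fit_negative",
    "colonoscopies",
    "negative_colonoscopies",
    "sd_crc",
    "fit_ic",
    "colonoscopy_ic",
    "ic_noncompliant",
    "nonparticipant_crc",
    "ic_total",
    "ic_year1",
    "ic_year2",
]


@dataclass
class ClassifiedCohort:
    """Per-person outcomes plus the screening configuration.

    ``df`` has one row per deduplicated invitee with columns: person_id, sex,
    age_at_invitation, stratum, participant, fit_positive,
    colonoscopy_performed, crc_found, outcome, months_from_invitation,
    followup_year, localization, stage_group, hb_value, hb_category.
    """

    df: pd.DataFrame
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    def counts(self) -> pd.DataFrame:
        """Aggregate counts per sex x age-group stratum, with an 'all' row."""
        return counts_by_stratum(self.df)

    @property
    def n_invited(self) -> int:
        return len(self.df)


def counts_by_stratum(df: pd.DataFrame) -> pd.DataFrame:
    strata = [s for s in STRATA if s in set(df["stratum"])] or list(STRATA)
    rows = {}
    for stratum in strata:
        rows[stratum] = _count_row(df[df["stratum"] == stratum])
    rows["all"] = _count_row(df)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=COUNT_COLUMNS)
    out.index.name = "stratum"
    return out


def _count_row(df: pd.DataFrame) -> list[int]:
    outcome = df["outcome"]
    participants = int(df["participant"].sum())
    positives = int(df["fit_positive"].sum())
    colonoscopies = int((df["fit_positive"] & df["colonoscopy_performed"]).sum())
    sd = int((outcome == OutcomeClass.SD_CRC).sum())
    fit_ic = int((outcome == OutcomeClass.FIT_IC).sum())
    col_ic = int((outcome == OutcomeClass.COLONOSCOPY_IC).sum())
    nc_ic = int((outcome == OutcomeClass.IC_NONCOMPLIANT).sum())
    np_crc = int((outcome == OutcomeClass.NONPARTICIPANT_CRC).sum())
    is_ic = outcome.isin([c.value for c in IC_CLASSES])
    year1 = int((is_ic & (df["followup_year"] == "year1")).sum())
    return [
        len(df),
        participants,
        positives,
        participants - positives,
        colonoscopies,
        colonoscopies - sd,
        sd,
        fit_ic,
        col_ic,
        nc_ic,
        np_crc,
        fit_ic + col_ic + nc_ic,
        year1,
        fit_ic + col_ic + nc_ic - year1,
    ]


def _positive_mask(
    df: pd.DataFrame, config: ScreeningConfig
) -> np.ndarray:
    """Vectorized FIT positivity for analyzable records (NaN-safe elsewhere)."""
    cutoff = df["sex"].map(config.cutoff_by_sex).to_numpy(dtype=float)
    value = df["hb_value"].to_numpy(dtype=float)
    positive = np.zeros(len(df), dtype=bool)
    has_value = ~np.isnan(value)
    positive[has_value] = value[has_value] >= cutoff[has_value]
    analyzable = (df["result_status"] == "analyzable").to_numpy()
    cat = df["hb_category"].where(df["hb_category"].notna(), None)
    needs_cat = analyzable & ~has_value
    if needs_cat.any():
        lows = np.full(len(df), np.nan)
        highs = np.full(len(df), np.nan)
        for name, (low, high) in CATEGORY_BOUNDS.items():
            mask = needs_cat & (cat == name).to_numpy()
            lows[mask] = low
            highs[mask] = high
        missing = needs_cat & np.isnan(lows)
        if missing.any():
            ids = df.loc[missing, "person_id"].tolist()[:10]
            raise CohortValidationError(
                [f"analyzable FIT without hb information for person {i}" for i in ids]
            )
        ambiguous = needs_cat & (lows < cutoff) & (cutoff < highs)
        if ambiguous.any():
            ids = df.loc[ambiguous, "person_id"].tolist()[:10]
            raise CohortValidationError(
                [
                    f"hb_category cannot be resolved against cut-off for person {i}"
                    for i in ids
                ]
            )
        positive[needs_cat] = lows[needs_cat] >= cutoff[needs_cat]
    positive &= analyzable
    return positive


def classify_cohort(cohort: Cohort, config: ScreeningConfig | None = None) -> ClassifiedCohort:
    """Vectorized classification of every invitee; equals the per-episode path.

    Invitations are deduplicated first; for persons with several registered
    cancers the earliest within the follow-up window is kept; cancers past the
    window are dropped from the analysis.
    """
    config = config or cohort.config
    inv = dedupe_invitations(cohort.invitations)
    df = inv.copy()
    df["stratum"] = [
        config.stratum_of(s, int(a))
        for s, a in zip(df["sex"], df["age_at_invitation"])
    ]

    fit = cohort.fit_results.drop_duplicates("person_id").set_index("person_id")
    df["result_status"] = (
        df["person_id"].map(fit["result_status"]).fillna("not_returned")
    )
    df["hb_value"] = df["person_id"].map(fit["hb_value"])
    df["hb_category"] = df["person_id"].map(fit["hb_category"])
    df["participant"] = df["result_status"] == "analyzable"
    df["fit_positive"] = _positive_mask(df, config)

    col = cohort.colonoscopies.drop_duplicates("person_id").set_index("person_id")
    df["colonoscopy_performed"] = (
        df["person_id"].map(col["performed"]).fillna(0).astype(bool)
    )
    df["crc_found"] = df["person_id"].map(col["crc_found"]).fillna(0).astype(bool)

    crc = cohort.crc_register.copy()
    crc["months_from_invitation"] = months_from_invitation(crc, inv)
    crc = crc[
        (crc["months_from_invitation"] > 0)
        & (crc["months_from_invitation"] <= config.followup_months)
    ]
    crc = crc.sort_values(["person_id", "months_from_invitation"], kind="mergesort")
    crc = crc.drop_duplicates("person_id").set_index("person_id")
    df["months_from_invitation"] = df["person_id"].map(crc["months_from_invitation"])
    df["localization"] = df["person_id"].map(crc["localization"])
    df["stage_group"] = df["person_id"].map(crc["stage_group"])
    has_crc = df["months_from_invitation"].notna()
    df["followup_year"] = pd.Series(
        np.where(
            has_crc,
            np.where(df["months_from_invitation"] <= 12, "year1", "year2"),
            None,
        ),
        index=df.index,
    )

    inconsistent = df["crc_found"] & ~has_crc
    if inconsistent.any():
        ids = df.loc[inconsistent, "person_id"].tolist()[:10]
        raise CohortValidationError(
            [
                f"crc_found colonoscopy without registered in-window cancer: person {i}"
                for i in ids
            ]
        )

    participant = df["participant"].to_numpy()
    positive = df["fit_positive"].to_numpy()
    performed = df["colonoscopy_performed"].to_numpy()
    found = df["crc_found"].to_numpy()
    cancer = has_crc.to_numpy()
    outcome = np.select(
        [
            ~participant & cancer,
            ~participant,
            ~positive & cancer,
            ~positive,
            performed & found,
            ~cancer,
            performed,
        ],
        [
            OutcomeClass.NONPARTICIPANT_CRC.value,
            OutcomeClass.NO_CRC.value,
            OutcomeClass.FIT_IC.value,
            OutcomeClass.NO_CRC.value,
            OutcomeClass.SD_CRC.value,
            OutcomeClass.NO_CRC.value,
            OutcomeClass.COLONOSCOPY_IC.value,
        ],
        default=OutcomeClass.IC_NONCOMPLIANT.value,
    )
    df["outcome"] = outcome
    return ClassifiedCohort(df=df.reset_index(drop=True), config=config)
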