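"""Programme configuration: cut-offs, follow-up window, age grouping, background incidence.

The defaults describe the Stockholm-Gotland biennial FIT programme round of
October 2015 - September 2017: positivity cut-off 40 µg Hb/g feces in women and
80 µg/g in men, two years of follow-up for colorectal cancer (CRC) diagnosis,
invitees grouped into ages 60-64 and 65-69 at invitation, and the experienced
incidence rate (EIR) of CRC per 100,000 person-years observed in the region in
the decade before screening started, per sex and age group.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, Field, model_validator

SEXES = ("F", "M")
AGE_GROUPS = ("lt65", "ge65")
#: Sex x age-group strata in canonical reporting order (women first, young first).
STRATA = ("F_lt65", "F_ge65", "M_lt65", "M_ge65")

STRATUM_LABELS = {
    "F_lt65": "Women <65",
    "F_ge65": "Women ≥65",
    "M_lt65": "Men <65",
    "M_ge65": "Men ≥65",
}

#: Mean regional CRC incidence per 100,000 person-years, 1998-2007 (pre-screening).
DEFAULT_EIR = {"F_lt65": 78.3, "F_ge65": 131.8, "M_lt65": 123.8, "M_ge65": 198.3}


def stratum_of(sex: str, age_at_invitation: int, boundary: int = 65) -> str:
    """Return the ``{sex}_{lt|ge}65`` stratum key for one invitee."""
    group = "lt65" if age_at_invitation < boundary else "ge65"
    return f"{sex}_{group}"


class ScreeningConfig(BaseModel):
    """All tunable parameters of the evaluation.

    Parameters
    ----------
    cutoff_by_sex
        Hemoglobin concentration (µg/g feces) at or above which a FIT is
        positive, per sex. The comparison is inclusive (>=).
    followup_months
        Length of the CRC follow-up window from invitation, in months.
    age_group_boundary
        Age (years, at invitation) splitting the two age groups.
    eir_table
        Background CRC incidence per 100,000 person-years per stratum,
        used as the denominator of the proportional-incidence rate ratio.
    ci_alpha
        Two-sided confidence level is ``1 - ci_alpha``.
    person_year_subtraction
        When True, one person-year is subtracted for every interval cancer
        diagnosed within the first year of invitation; when False each
        follow-up contributes a flat two years. The flat convention
        reproduces the per-stratum incidence rates of the programme report;
        the subtraction convention is the one its total follow-up figure
        uses. See docs/methods.md.
    """

    cutoff_by_sex: dict[str, float] = Field(
        default_factory=lambda: {"F": 40.0, "M": 80.0}
    )
    followup_months: float = 24.0
    age_group_boundary: int = 65
    eir_table: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_EIR))
    ci_alpha: float = 0.05
    person_year_subtraction: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ScreeningConfig":
        for sex in SEXES:
            if sex not in self.cutoff_by_sex:
                raise ValueError(f"cutoff_by_sex missing sex {sex!r}")
            if self.cutoff_by_sex[sex] <= 0:
                raise ValueError("cut-offs must be strictly positive")
        for key, value in self.eir_table.items():
            if key not in STRATA:
                raise ValueError(f"unknown EIR stratum {key!r}")
            if value <= 0:
                raise ValueError("EIR values must be strictly positive")
        if not 0 < self.ci_alpha < 1:
            raise ValueError("ci_alpha must lie in (0, 1)")
        if self.followup_months <= 0:
            raise ValueError("followup_months must be positive")
        return self

    def stratum_of(self, sex: str, age_at_invitation: int) -> str:
        return stratum_of(sex, age_at_invitation, self.age_group_boundary)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreeningConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.model_dump(), handle, sort_keys=True)

    def with_cutoffs(self, cutoff_by_sex: Mapping[str, float]) -> "ScreeningConfig":
        """Copy of this config with replaced positivity cut-offs."""
        return self.model_copy(update={"cutoff_by_sex": dict(cutoff_by_sex)})
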