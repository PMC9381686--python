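"""Aggregate count margins of a screening round.

``CohortMargins`` holds exactly the cell counts a programme report prints:
per sex x age-group stratum the invitation, participation, positivity,
colonoscopy and outcome-class counts (with the women's counts additionally
split at 80 µg/g so that a uniform-cut-off reanalysis is determined), the
year-of-diagnosis split of the interval cancers, and per detection mode the
localization and stage breakdowns. The packaged default,
:func:`default_margins`, is the Stockholm-Gotland 2015-2017 round.

The margins serve two purposes: they validate a report's internal
consistency, and they seed :func:`fitscreen.synthetic.fixture_from_margins`,
which reconstructs an individual-level cohort reproducing every margin
exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .config import STRATA


class MarginsError(ValueError):
    """An internal-consistency identity of the margins is violated."""


@dataclass(frozen=True)
class StratumMargins:
    """Counts for one sex x age-group stratum.

    The ``*_ge80`` fields give the subset of the corresponding count whose FIT
    hemoglobin was at least 80 µg/g; for men under the default cut-offs these
    equal the full counts. ``None`` means "same as the full count".
    """

    invited: int
    valid_fit: int
    fit_positive: int
    colonoscopies: int
    sd_crc: int
    fit_ic: int
    colonoscopy_ic: int
    noncompliant_ic: int
    nonparticipant_crc: int
    ic_year1: int
    fit_positive_ge80: int | None = None
    colonoscopies_ge80: int | None = None
    sd_crc_ge80: int | None = None
    colonoscopy_ic_ge80: int | None = None
    noncompliant_ic_ge80: int | None = None

    def ge80(self, name: str) -> int:
        value = getattr(self, f"{name}_ge80")
        return getattr(self, name) if value is None else value

    @property
    def ic_total(self) -> int:
        return self.fit_ic + self.colonoscopy_ic + self.noncompliant_ic


@dataclass(frozen=True)
class ModeBreakdown:
    """Localization and stage counts for one detection mode (pooled strata)."""

    proximal: int
    distal: int
    unknown_localization: int
    stage_i_ii: int
    stage_iii_iv: int
    unknown_stage: int

    @property
    def total(self) -> int:
        return self.proximal + self.distal + self.unknown_localization


#: Detection modes carrying a registered cancer, in fixture emission order,
#: mapped to the StratumMargins field holding the per-stratum count.
MODE_FIELDS = {
    "sd_crc": "sd_crc",
    "fit_ic": "fit_ic",
    "colonoscopy_ic": "colonoscopy_ic",
    "ic_noncompliant": "noncompliant_ic",
    "nonparticipant_crc": "nonparticipant_crc",
}
CANCER_MODES = tuple(MODE_FIELDS)


@dataclass(frozen=True)
class CohortMargins:
    strata: dict[str, StratumMargins]
    breakdown: dict[str, ModeBreakdown] = field(default_factory=dict)

    def validate(self) -> "CohortMargins":
        problems: list[str] = []
        for key, m in self.strata.items():
            if key not in STRATA:
                problems.append(f"{key}: unknown stratum key")
                continue
            if not 0 <= m.valid_fit <= m.invited:
                problems.append(f"{key}: valid_fit must lie in [0, invited]")
            if not 0 <= m.fit_positive <= m.valid_fit:
                problems.append(f"{key}: fit_positive must lie in [0, valid_fit]")
            if not 0 <= m.colonoscopies <= m.fit_positive:
                problems.append(f"{key}: colonoscopies must lie in [0, fit_positive]")
            if not 0 <= m.sd_crc <= m.colonoscopies:
                problems.append(f"{key}: sd_crc must lie in [0, colonoscopies]")
            if m.colonoscopy_ic > m.colonoscopies - m.sd_crc:
                problems.append(f"{key}: colonoscopy_ic exceeds negative colonoscopies")
            if m.noncompliant_ic > m.fit_positive - m.colonoscopies:
                problems.append(f"{key}: noncompliant_ic exceeds unperformed colonoscopies")
            if m.fit_ic > m.valid_fit - m.fit_positive:
                problems.append(f"{key}: fit_ic exceeds FIT negatives")
            if m.nonparticipant_crc > m.invited - m.valid_fit:
                problems.append(f"{key}: nonparticipant_crc exceeds non-participants")
            if not 0 <= m.ic_year1 <= m.ic_total:
                problems.append(f"{key}: ic_year1 must lie in [0, total ICs]")
            for name in (
                "fit_positive",
                "colonoscopies",
                "sd_crc",
                "colonoscopy_ic",
                "noncompliant_ic",
            ):
                if not 0 <= m.ge80(name) <= getattr(self.strata[key], name):
                    problems.append(f"{key}: {name}_ge80 must lie in [0, {name}]")
            if m.ge80("sd_crc") > m.ge80("colonoscopies"):
                problems.append(f"{key}: sd_crc_ge80 exceeds colonoscopies_ge80")
            if m.ge80("colonoscopies") > m.ge80("fit_positive"):
                problems.append(f"{key}: colonoscopies_ge80 exceeds fit_positive_ge80")
        for mode, b in self.breakdown.items():
            if mode not in CANCER_MODES:
                problems.append(f"{mode}: unknown detection mode")
                continue
            expected = sum(
                getattr(m, MODE_FIELDS[mode]) for m in self.strata.values()
            )
            if b.total != expected:
                problems.append(
                    f"{mode}: localization counts sum to {b.total}, "
                    f"stratum counts to {expected}"
                )
            if b.stage_i_ii + b.stage_iii_iv + b.unknown_stage != expected:
                problems.append(f"{mode}: stage counts do not sum to {expected}")
            if min(asdict(b).values()) < 0:
                problems.append(f"{mode}: negative breakdown cell")
        if problems:
            raise MarginsError("; ".join(problems))
        return self

    def totals(self) -> dict[str, int]:
        keys = (
            "invited",
            "valid_fit",
            "fit_positive",
            "colonoscopies",
            "sd_crc",
            "fit_ic",
            "colonoscopy_ic",
            "noncompliant_ic",
            "nonparticipant_crc",
            "ic_year1",
        )
        out = {k: sum(getattr(m, k) for m in self.strata.values()) for k in keys}
        out["ic_total"] = sum(m.ic_total for m in self.strata.values())
        return out

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "strata": {k: asdict(m) for k, m in self.strata.items()},
            "breakdown": {k: asdict(b) for k, b in self.breakdown.items()},
        }
        with open(path, "w") as handle:
            yaml.safe_dump(data, handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortMargins":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(
            strata={k: StratumMargins(**v) for k, v in data["strata"].items()},
            breakdown={
                k: ModeBreakdown(**v) for k, v in data.get("breakdown", {}).items()
            },
        ).validate()


def default_margins() -> CohortMargins:
    """Printed margins of the Stockholm-Gotland 2015-2017 round.

    Cells not printed in the programme report are filled deterministically:
    non-participant cancers are spread over strata by northwest-corner
    allocation of the sex and age margins (68/0/28/81), the stage split of the
    three non-compliant interval cancers is set to 2 stage I-II / 1 stage
    III-IV, and their localization (2 proximal / 1 distal) follows from the
    overall count of 196 proximal tumors among all 568 cancers.
    """
    strata = {
        "F_lt65": StratumMargins(
            invited=66063, valid_fit=46460, fit_positive=1201, colonoscopies=1043,
            sd_crc=59, fit_ic=20, colonoscopy_ic=2, noncompliant_ic=0,
            nonparticipant_crc=68, ic_year1=7,
            fit_positive_ge80=688, colonoscopies_ge80=609, sd_crc_ge80=42,
            colonoscopy_ic_ge80=1, noncompliant_ic_ge80=0,
        ),
        "F_ge65": StratumMargins(
            invited=42794, valid_fit=31680, fit_positive=1011, colonoscopies=901,
            sd_crc=63, fit_ic=21, colonoscopy_ic=3, noncompliant_ic=1,
            nonparticipant_crc=0, ic_year1=6,
            fit_positive_ge80=542, colonoscopies_ge80=491, sd_crc_ge80=51,
            colonoscopy_ic_ge80=1, noncompliant_ic_ge80=0,
        ),
        "M_lt65": StratumMargins(
            invited=66072, valid_fit=42159, fit_positive=1046, colonoscopies=910,
            sd_crc=72, fit_ic=37, colonoscopy_ic=2, noncompliant_ic=2,
            nonparticipant_crc=28, ic_year1=11,
        ),
        "M_ge65": StratumMargins(
            invited=39427, valid_fit=26679, fit_positive=799, colonoscopies=667,
            sd_crc=63, fit_ic=46, colonoscopy_ic=0, noncompliant_ic=0,
            nonparticipant_crc=81, ic_year1=15,
        ),
    }
    breakdown = {
        "sd_crc": ModeBreakdown(65, 192, 0, 142, 89, 26),
        "fit_ic": ModeBreakdown(60, 63, 1, 47, 58, 19),
        "colonoscopy_ic": ModeBreakdown(2, 5, 0, 5, 1, 1),
        "ic_noncompliant": ModeBreakdown(2, 1, 0, 2, 1, 0),
        "nonparticipant_crc": ModeBreakdown(67, 110, 0, 63, 91, 23),
    }
    return CohortMargins(strata=strata, breakdown=breakdown).validate()
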