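"""Individual-level cohort tables: loading, validation, deduplication.

A cohort is four CSV-backed tables keyed by an opaque ``person_id``:

* ``invitations``: one row per mailed invitation (person_id, sex {F,M},
  age_at_invitation, invitation_date as ISO-8601);
* ``fit_results``: the returned FIT kit, with ``result_status`` in
  {analyzable, not_analyzable, not_returned} and, for analyzable results,
  either a quantitative ``hb_value`` (µg Hb / g feces) or a coarse
  ``hb_category`` in {lt40, 40to79, ge80};
* ``colonoscopies``: screening colonoscopy after a positive FIT
  (``performed``, ``crc_found`` as 0/1);
* ``crc_register``: registered colorectal cancers with either
  ``months_from_invitation`` or a calendar ``diagnosis_date``, plus
  ``localization`` {proximal, distal, unknown} and ``stage_group``
  {I_II, III_IV, unknown}.

Only a person's first dated invitation enters the analysis; failure to
return an analyzable FIT counts as non-participation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import SEXES, ScreeningConfig

INVITATION_COLUMNS = ["person_id", "sex", "age_at_invitation", "invitation_date"]
FIT_COLUMNS = ["person_id", "result_status", "hb_value", "hb_category"]
COLONOSCOPY_COLUMNS = ["person_id", "performed", "crc_found"]
CRC_COLUMNS = [
    "person_id",
    "months_from_invitation",
    "diagnosis_date",
    "localization",
    "stage_group",
]

RESULT_STATUSES = ("analyzable", "not_analyzable", "not_returned")
HB_CATEGORIES = ("lt40", "40to79", "ge80")
LOCALIZATIONS = ("proximal", "distal", "unknown")
STAGE_GROUPS = ("I_II", "III_IV", "unknown")

#: Half-open hemoglobin interval (µg/g) covered by each reporting category.
CATEGORY_BOUNDS = {
    "lt40": (0.0, 40.0),
    "40to79": (40.0, 80.0),
    "ge80": (80.0, np.inf),
}

TABLE_FILES = {
    "invitations": "invitations.csv",
    "fit_results": "fit_results.csv",
    "colonoscopies": "colonoscopies.csv",
    "crc_register": "crc_register.csv",
}

DAYS_PER_MONTH = 365.25 / 12.0


class CohortValidationError(ValueError):
    """Raised when the cohort tables violate the schema; carries every problem found."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("cohort validation failed:\n" + "\n".join(problems))


def hb_category_of(hb_value: float) -> str:
    """Reporting category for a quantitative hemoglobin concentration."""
    if hb_value < 40.0:
        return "lt40"
    if hb_value < 80.0:
        return "40to79"
    return "ge80"


@dataclass
class Cohort:
    """The four registry tables plus the screening configuration."""

    invitations: pd.DataFrame
    fit_results: pd.DataFrame
    colonoscopies: pd.DataFrame
    crc_register: pd.DataFrame
    config: ScreeningConfig = field(default_factory=ScreeningConfig)

    def __post_init__(self) -> None:
        self.invitations = _coerce(self.invitations, INVITATION_COLUMNS)
        self.fit_results = _coerce(self.fit_results, FIT_COLUMNS)
        self.colonoscopies = _coerce(self.colonoscopies, COLONOSCOPY_COLUMNS)
        self.crc_register = _coerce(self.crc_register, CRC_COLUMNS)

    @property
    def n_invited(self) -> int:
        return self.invitations["person_id"].nunique()

    def validate(self) -> "Cohort":
        problems = validate_cohort(self)
        if problems:
            raise CohortValidationError(problems)
        return self

    def with_config(self, config: ScreeningConfig) -> "Cohort":
        return replace(self, config=config)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the four tables (and config.yaml) to ``directory``; returns paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, filename in TABLE_FILES.items():
            path = directory / filename
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        self.config.to_yaml(directory / "config.yaml")
        return paths


def _coerce(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    df = df.copy()
    for column in columns:
        if column not in df.columns:
            df[column] = np.nan
    df = df[columns]
    if "person_id" in df.columns:
        df["person_id"] = df["person_id"].astype(str)
    for column in ("hb_value", "months_from_invitation"):
        if column in df.columns:
            df[column] = pd.to_numeric(df[column], errors="coerce")
    for column in ("performed", "crc_found"):
        if column in df.columns:
            df[column] = pd.to_numeric(df[column], errors="coerce").fillna(0).astype(int)
    if "age_at_invitation" in df.columns:
        df["age_at_invitation"] = pd.to_numeric(
            df["age_at_invitation"], errors="coerce"
        ).astype("Int64")
    return df


def load_cohort(
    paths: str | Path | Mapping[str, str | Path],
    config: ScreeningConfig | None = None,
) -> Cohort:
    """Read and validate the four cohort CSVs.

    ``paths`` is either a directory holding the canonically named files
    (``invitations.csv`` etc.) or a mapping from table name to file path.
    A missing ``fit_results`` / ``colonoscopies`` / ``crc_register`` entry is
    treated as an empty table; ``invitations`` is mandatory and must be
    non-empty.
    """
    if config is None:
        config = ScreeningConfig()
    if isinstance(paths, (str, Path)):
        directory = Path(paths)
        mapping: dict[str, Path] = {
            name: directory / filename for name, filename in TABLE_FILES.items()
        }
        config_path = directory / "config.yaml"
        if config_path.exists():
            config = ScreeningConfig.from_yaml(config_path)
    else:
        mapping = {name: Path(p) for name, p in paths.items()}

    if "invitations" not in mapping or not mapping["invitations"].exists():
        raise FileNotFoundError("invitations table is required")

    tables: dict[str, pd.DataFrame] = {}
    for name, columns in (
        ("invitations", INVITATION_COLUMNS),
        ("fit_results", FIT_COLUMNS),
        ("colonoscopies", COLONOSCOPY_COLUMNS),
        ("crc_register", CRC_COLUMNS),
    ):
        path = mapping.get(name)
        if path is not None and Path(path).exists():
            tables[name] = pd.read_csv(path, dtype={"person_id": str})
        else:
            tables[name] = pd.DataFrame(columns=columns)

    cohort = Cohort(config=config, **tables)
    return cohort.validate()


def dedupe_invitations(invitations: pd.DataFrame) -> pd.DataFrame:
    """Keep one canonical invitation per person: the earliest by date.

    Ties on identical dates are broken by full-row lexicographic order, so the
    result is deterministic and independent of input row order. Idempotent.
    """
    columns = list(invitations.columns)
    order = ["person_id", "invitation_date"] + [
        c for c in columns if c not in ("person_id", "invitation_date")
    ]
    deduped = (
        invitations.sort_values(order, kind="mergesort")
        .drop_duplicates("person_id", keep="first")
        .reset_index(drop=True)
    )
    return deduped[columns]


def participation_status(result_status: str | float | None) -> str:
    """'participant' iff an analyzable FIT result exists.

    Unreturned kits and non-analyzable results both count as non-participation.
    """
    if isinstance(result_status, str) and result_status == "analyzable":
        return "participant"
    return "non_participant"


def months_from_invitation(
    crc: pd.DataFrame, invitations: pd.DataFrame
) -> pd.Series:
    """Months from invitation to diagnosis, deriving from dates where needed."""
    months = pd.to_numeric(crc["months_from_invitation"], errors="coerce")
    if months.isna().any() and "diagnosis_date" in crc.columns:
        needs = months.isna() & crc["diagnosis_date"].notna()
        if needs.any():
            inv_dates = invitations.set_index("person_id")["invitation_date"]
            diag = pd.to_datetime(crc.loc[needs, "diagnosis_date"])
            inv = pd.to_datetime(
                crc.loc[needs, "person_id"].map(inv_dates), errors="coerce"
            )
            months.loc[needs] = (diag - inv).dt.days / DAYS_PER_MONTH
    return months


def validate_cohort(cohort: Cohort) -> list[str]:
    """Schema and referential checks; returns a list of problems (empty when valid).

    Row numbers reported are 1-based positions in the in-memory table.
    """
    problems: list[str] = []
    inv = cohort.invitations
    if len(inv) == 0:
        return ["empty cohort: invitations table has no rows"]

    bad_sex = ~inv["sex"].isin(SEXES)
    for row in _rows(bad_sex):
        problems.append(f"invitations row {row}: sex must be one of {SEXES}")
    bad_age = inv["age_at_invitation"].isna() | ~inv["age_at_invitation"].between(60, 69)
    for row in _rows(bad_age):
        problems.append(f"invitations row {row}: age_at_invitation must be in [60, 69]")
    dup = inv.duplicated(["person_id", "invitation_date"], keep=False)
    for row in _rows(dup):
        problems.append(
            f"invitations row {row}: duplicate (person_id, invitation_date) pair"
        )

    known = set(inv["person_id"])
    for name in ("fit_results", "colonoscopies", "crc_register"):
        table = getattr(cohort, name)
        orphan = ~table["person_id"].isin(known)
        for row in _rows(orphan):
            pid = table["person_id"].iloc[row - 1]
            problems.append(f"{name} row {row}: unknown person_id {pid!r}")

    fit = cohort.fit_results
    bad_status = ~fit["result_status"].isin(RESULT_STATUSES)
    for row in _rows(bad_status):
        problems.append(
            f"fit_results row {row}: result_status must be one of {RESULT_STATUSES}"
        )
    dup_fit = fit.duplicated("person_id", keep=False)
    for row in _rows(dup_fit):
        problems.append(f"fit_results row {row}: more than one FIT record per person")
    analyzable = fit["result_status"] == "analyzable"
    has_value = fit["hb_value"].notna()
    has_cat = fit["hb_category"].notna()
    for row in _rows(analyzable & ~has_value & ~has_cat):
        problems.append(
            f"fit_results row {row}: analyzable result needs hb_value or hb_category"
        )
    for row in _rows(has_value & (fit["hb_value"] < 0)):
        problems.append(f"fit_results row {row}: hb_value must be non-negative")
    for row in _rows(has_cat & ~fit["hb_category"].isin(HB_CATEGORIES)):
        problems.append(
            f"fit_results row {row}: hb_category must be one of {HB_CATEGORIES}"
        )
    both = has_value & has_cat & fit["hb_category"].isin(HB_CATEGORIES)
    if both.any():
        derived = fit.loc[both, "hb_value"].map(hb_category_of)
        for row in _rows(both & (fit["hb_category"].where(both).ne(derived))):
            problems.append(
                f"fit_results row {row}: hb_category disagrees with hb_value"
            )

    col = cohort.colonoscopies
    for row in _rows((col["crc_found"] == 1) & (col["performed"] == 0)):
        problems.append(
            f"colonoscopies row {row}: crc_found requires performed colonoscopy"
        )
    for row in _rows(col.duplicated("person_id", keep=False)):
        problems.append(
            f"colonoscopies row {row}: more than one colonoscopy record per person"
        )

    crc = cohort.crc_register
    months = months_from_invitation(crc, inv)
    for row in _rows(months.isna()):
        problems.append(
            f"crc_register row {row}: months_from_invitation or diagnosis_date required"
        )
    for row in _rows(months.notna() & (months <= 0)):
        problems.append(
            f"crc_register row {row}: months_from_invitation must be positive"
        )
    for row in _rows(~crc["localization"].isin(LOCALIZATIONS)):
        problems.append(
            f"crc_register row {row}: localization must be one of {LOCALIZATIONS}"
        )
    for row in _rows(~crc["stage_group"].isin(STAGE_GROUPS)):
        problems.append(
            f"crc_register row {row}: stage_group must be one of {STAGE_GROUPS}"
        )
    return problems


def _rows(mask: pd.Series, limit: int = 50) -> list[int]:
    positions = np.flatnonzero(np.asarray(mask, dtype=bool)) + 1
    return [int(p) for p in positions[:limit]]
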