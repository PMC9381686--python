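"""Rendered report tables and serialized metrics.

Tables mirror a programme report: participation/PPV per stratum, FIT
results and IC rates per stratum, year-split incidence against the
background rate, the uniform-cut-off reanalysis, sensitivity by subgroup
and localization, and the detection-mode comparison of age, gender,
localization and stage. Output is TSV plus JSON (diff-able in tests);
rounding happens only here: rates to 1 decimal, ratios and sensitivities
to 2 decimals, with half-even tie-breaking.
"""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import TYPE_CHECKING, Any

import pandas as pd

from . import __version__ as _version
from .config import STRATA, STRATUM_LABELS
from .classify import ClassifiedCohort, OutcomeClass
from .metrics import chi2_yates

if TYPE_CHECKING:  # pragma: no cover
    from .counterfactual import CounterfactualResult
    from .model import ScreeningResults


def round_half_even(value: float, ndigits: int = 0) -> float:
    """Round on the decimal representation with half-to-even ties.

    Works from the shortest decimal representation of the float, so exact
    ties like 0.525 round to 0.52 rather than picking up binary noise.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_EVEN))


def fmt1(value: float) -> str:
    return f"{round_half_even(value, 1):.1f}"


def fmt2(value: float) -> str:
    return f"{round_half_even(value, 2):.2f}"


def _ci1(est) -> str:
    return f"{fmt1(est.ci_low)}-{fmt1(est.ci_high)}"


def _ci2(est) -> str:
    return f"{fmt2(est.ci_low)}-{fmt2(est.ci_high)}"


def render_participation_table(results: "ScreeningResults") -> pd.DataFrame:
    r = results.report
    rows = []
    for stratum in list(STRATA) + ["all"]:
        if stratum not in r.participation:
            continue
        c = r.counts.loc[stratum]
        ppv = r.ppv.get(stratum)
        rows.append(
            {
                "group": STRATUM_LABELS.get(stratum, "All"),
                "invited": int(c["invited"]),
                "valid_fit": int(c["participants"]),
                "participation_rate": fmt1(r.participation[stratum].point * 100),
                "fit_positive": int(c["fit_positive"]),
                "positivity_pct": fmt1(r.positivity[stratum].point * 100),
                "colonoscopies": int(c["colonoscopies"]),
                "compliance_pct": fmt1(r.compliance[stratum].point * 100),
                "sd_crc": int(c["sd_crc"]),
                "ppv_pct": fmt1(ppv.point * 100) if ppv else "",
                "ppv_ci": _ci1(
                    type(ppv)(
                        ppv.numerator, ppv.denominator, 100.0,
                        ppv.point * 100, ppv.ci_low * 100, ppv.ci_high * 100,
                        ppv.method,
                    )
                ) if ppv else "",
            }
        )
    return pd.DataFrame(rows)


def render_outcomes_table(results: "ScreeningResults") -> pd.DataFrame:
    r = results.report
    rows = []
    for stratum in list(STRATA) + ["all"]:
        if stratum not in r.ic_rate:
            continue
        c = r.counts.loc[stratum]
        sens = r.sensitivity.get(stratum)
        rows.append(
            {
                "group": STRATUM_LABELS.get(stratum, "All"),
                "fit_participants": int(c["participants"]),
                "fit_negatives": int(c["fit_negative"]),
                "fit_positives": int(c["fit_positive"]),
                "colonoscopies": int(c["colonoscopies"]),
                "sd_crc": int(c["sd_crc"]),
                "fit_ic": int(c["fit_ic"]),
                "colonoscopy_ic": int(c["colonoscopy_ic"]),
                "ic_noncompliant": int(c["ic_noncompliant"]),
                "ic_rate": fmt1(r.ic_rate[stratum].point),
                "ic_rate_ci": _ci1(r.ic_rate[stratum]),
                "sensitivity": fmt2(sens.point) if sens else "",
                "sensitivity_ci": _ci2(sens) if sens else "",
                "ic_incidence": fmt1(r.ic_incidence[stratum].point),
                "ic_incidence_ci": _ci1(r.ic_incidence[stratum]),
            }
        )
    return pd.DataFrame(rows)


def render_year_split_table(results: "ScreeningResults") -> pd.DataFrame:
    r = results.report
    rows = []
    for stratum in STRATA:
        if stratum not in r.year_split:
            continue
        c = r.counts.loc[stratum]
        ratio = r.eir_ratio[stratum]
        row: dict[str, Any] = {
            "group": STRATUM_LABELS.get(stratum, stratum),
            "total_ic": int(c["ic_total"]),
            "ic_incidence": fmt1(r.ic_incidence[stratum].point),
            "eir": results.config.eir_table[stratum],
            "incidence_over_eir": fmt2(ratio.ratio),
            "incidence_over_eir_ci": _ci2(ratio),
        }
        for year in ("year1", "year2"):
            split = r.year_split[stratum][year]
            row[f"{year}_observed"] = int(split["observed"])
            row[f"{year}_ic_rate"] = fmt2(split["ic_rate"].point)
            row[f"{year}_ic_incidence"] = fmt1(split["ic_incidence"].point)
            if "eir_ratio" in split:
                row[f"{year}_incidence_over_eir"] = fmt2(split["eir_ratio"].ratio)
        rows.append(row)
    return pd.DataFrame(rows)


def render_counterfactual_table(cf: "CounterfactualResult") -> pd.DataFrame:
    rows = []
    for stratum in STRATA:
        if stratum not in cf.ic_rate:
            continue
        c = cf.counts.loc[stratum]
        sens = cf.sensitivity.get(stratum)
        ratio = cf.eir_ratio.get(stratum)
        rows.append(
            {
                "group": STRATUM_LABELS.get(stratum, stratum),
                "fit_positive": int(c["fit_positive"]),
                "fit_negative": int(c["fit_negative"]),
                "colonoscopies": int(c["colonoscopies"]),
                "sd_crc": int(c["sd_crc"]),
                "fit_ic": int(c["fit_ic"]),
                "colonoscopy_ic": int(c["colonoscopy_ic"]),
                "ic_noncompliant": int(c["ic_noncompliant"]),
                "sensitivity": fmt2(sens.point) if sens else "",
                "sensitivity_ci": _ci2(sens) if sens else "",
                "ic_rate": fmt1(cf.ic_rate[stratum].point),
                "ic_rate_ci": _ci1(cf.ic_rate[stratum]),
                "incidence_over_eir": fmt2(ratio.ratio) if ratio else "",
                "incidence_over_eir_ci": _ci2(ratio) if ratio else "",
            }
        )
    return pd.DataFrame(rows)


def render_sensitivity_table(results: "ScreeningResults") -> pd.DataFrame:
    r = results.report
    labels = {
        "lt65": "Age 60-64",
        "ge65": "Age 65-69",
        "M": "Men",
        "F": "Women",
        "proximal": "Proximal CRC",
        "distal": "Distal CRC",
    }
    test_for = {
        "lt65": "sensitivity_age_groups",
        "M": "sensitivity_men_vs_women",
        "proximal": "sensitivity_proximal_vs_distal",
    }
    rows = []
    for key, label in labels.items():
        sens = r.sensitivity.get(key)
        if sens is None:
            continue
        row = {
            "group": label,
            "sd_crc": int(sens.numerator),
            "fit_ic": int(sens.denominator - sens.numerator),
            "sensitivity_pct": fmt1(sens.point * 100),
        }
        test = r.tests.get(test_for.get(key, ""))
        row["p_value"] = f"{test.p_value:.2g}" if test else ""
        rows.append(row)
    return pd.DataFrame(rows)


TABLE6_MODES = [
    (OutcomeClass.SD_CRC, "SD-CRC"),
    (OutcomeClass.FIT_IC, "FIT-IC"),
    (OutcomeClass.COLONOSCOPY_IC, "Colonoscopy IC"),
    (OutcomeClass.NONPARTICIPANT_CRC, "CRC in non-participants"),
]


def render_table6(classified: ClassifiedCohort) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Detection-mode comparison of age, gender, localization and stage.

    Percentages are within detection mode; unknown categories are shown but
    excluded from the Yates chi-squared tests (SD-CRC vs FIT-IC for gender,
    localization and stage). Returns the table and the test results.
    """
    df = classified.df
    boundary = classified.config.age_group_boundary
    sub = {
        mode: df[df["outcome"] == mode] for mode, _ in TABLE6_MODES
    }

    def block(label: str, values: list[tuple[str, Any]]) -> list[dict[str, Any]]:
        rows = []
        for value_label, predicate in values:
            row: dict[str, Any] = {"characteristic": label, "value": value_label}
            for mode, mode_label in TABLE6_MODES:
                d = sub[mode]
                n = int(predicate(d).sum())
                total = len(d)
                pct = fmt1(100.0 * n / total) if total else ""
                row[mode_label] = f"{n} ({pct})" if total else "0"
            rows.append(row)
        return rows

    rows: list[dict[str, Any]] = []
    rows += block(
        "age",
        [
            (f"<{boundary}", lambda d: d["age_at_invitation"] < boundary),
            (f">={boundary}", lambda d: d["age_at_invitation"] >= boundary),
        ],
    )
    rows += block(
        "gender",
        [("Women", lambda d: d["sex"] == "F"), ("Men", lambda d: d["sex"] == "M")],
    )
    rows += block(
        "localization",
        [
            ("Proximal", lambda d: d["localization"] == "proximal"),
            ("Distal", lambda d: d["localization"] == "distal"),
            ("Unknown", lambda d: d["localization"] == "unknown"),
        ],
    )
    rows += block(
        "stage",
        [
            ("I&II", lambda d: d["stage_group"] == "I_II"),
            ("III&IV", lambda d: d["stage_group"] == "III_IV"),
            ("Unknown", lambda d: d["stage_group"] == "unknown"),
        ],
    )
    totals = {"characteristic": "total", "value": ""}
    for mode, mode_label in TABLE6_MODES:
        totals[mode_label] = str(len(sub[mode]))
    rows.append(totals)
    table = pd.DataFrame(rows)

    tests: dict[str, Any] = {}
    sd, ic = sub[OutcomeClass.SD_CRC], sub[OutcomeClass.FIT_IC]

    def counts(d: pd.DataFrame, column: str, values: tuple[str, str]) -> list[int]:
        return [int((d[column] == v).sum()) for v in values]

    pairs = [
        ("gender", "sex", ("F", "M")),
        ("localization", "localization", ("proximal", "distal")),
        ("stage", "stage_group", ("I_II", "III_IV")),
    ]
    for name, column, values in pairs:
        table_ = [counts(sd, column, values), counts(ic, column, values)]
        if min(sum(row) for row in table_) > 0:
            tests[f"{name}_sd_vs_fit_ic"] = chi2_yates(table_)
    return table, tests


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(
    results: "ScreeningResults",
    outdir: Path,
    counterfactual_cutoff: float | None = 80.0,
    seed: int | None = None,
    inputs: dict[str, str] | None = None,
) -> dict[str, Path]:
    """Write all rendered tables, the JSON metrics and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths[name] = path

    emit("participation", render_participation_table(results))
    emit("outcomes", render_outcomes_table(results))
    emit("year_split", render_year_split_table(results))
    emit("sensitivity", render_sensitivity_table(results))
    table6, table6_tests = render_table6(results.classified)
    emit("detection_modes", table6)

    metrics = results.report.to_dict()
    metrics["detection_mode_tests"] = {
        k: v.to_dict() for k, v in table6_tests.items()
    }
    if counterfactual_cutoff is not None:
        cf = results.counterfactual(counterfactual_cutoff)
        emit("counterfactual", render_counterfactual_table(cf))
        metrics["counterfactual"] = cf.to_dict()

    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
    paths["metrics"] = metrics_path
    counts_path = outdir / "counts.json"
    counts_path.write_text(
        json.dumps(metrics["counts"], indent=1, sort_keys=True)
    )
    paths["counts"] = counts_path

    classified_path = outdir / "classified_cohort.csv"
    results.classified.df[
        ["person_id", "stratum", "outcome", "followup_year"]
    ].to_csv(classified_path, index=False)
    paths["classified_cohort"] = classified_path

    config_json = results.config.model_dump_json()
    manifest = {
        "package_version": _version,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "config": json.loads(config_json),
        "seed": seed,
        "inputs": inputs or {},
        "n_invited": int(results.counts.loc["all", "invited"]),
        "outputs": {
            name: _sha256(path) for name, path in sorted(paths.items())
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
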