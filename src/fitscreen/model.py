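"""Model/Results surface for the screening-round evaluation.

``ScreeningEvaluation`` is built from a cohort (raw CSV tables, the packaged
margin-exact fixture, or a simulator draw); ``fit()`` classifies every
invitee and computes the full set of estimators, returning a
``ScreeningResults`` object that carries the counts, the rate estimates with
their confidence intervals, the between-group tests, a ``summary()`` table
and the uniform-cut-off counterfactual.

    >>> from fitscreen import ScreeningEvaluation
    >>> res = ScreeningEvaluation.from_margins().fit()
    >>> print(res.summary())            # doctest: +SKIP
    >>> cf = res.counterfactual(80.0)
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import STRATA, STRATUM_LABELS, ScreeningConfig
from .cohort import Cohort, load_cohort
from .classify import ClassifiedCohort, classify_cohort
from .counterfactual import CounterfactualResult, apply_uniform_cutoff
from .margins import CohortMargins
from .metrics import MetricsReport, compute_all_metrics
from .synthetic import SimulationParams, fixture_from_margins, simulate_cohort
from . import report as _report


class ScreeningEvaluation:
    """Evaluation model for one round of FIT-based colorectal cancer screening."""

    def __init__(self, cohort: Cohort, config: ScreeningConfig | None = None):
        self.cohort = cohort if config is None else cohort.with_config(config)
        self.config = self.cohort.config
        #: latent simulator state when the model was built by :meth:`simulate`
        self.truth: pd.DataFrame | None = None

    @classmethod
    def from_csv(
        cls,
        paths: str | Path | Mapping[str, str | Path],
        config: ScreeningConfig | None = None,
    ) -> "ScreeningEvaluation":
        """Build the model from the four registry CSV tables."""
        return cls(load_cohort(paths, config))

    @classmethod
    def from_margins(
        cls,
        margins: CohortMargins | None = None,
        config: ScreeningConfig | None = None,
    ) -> "ScreeningEvaluation":
        """Build the model from aggregate margins via the margin-exact fixture.

        With no arguments this reconstructs the Stockholm-Gotland 2015-2017
        round from its printed margins.
        """
        return cls(fixture_from_margins(margins, config))

    @classmethod
    def simulate(
        cls, params: SimulationParams, config: ScreeningConfig | None = None
    ) -> "ScreeningEvaluation":
        """Build the model from one stochastic simulator draw."""
        cohort, truth = simulate_cohort(params, config)
        model = cls(cohort)
        model.truth = truth
        return model

    def fit(self) -> "ScreeningResults":
        """Classify the cohort and compute every estimator."""
        classified = classify_cohort(self.cohort, self.config)
        report = compute_all_metrics(classified, self.config)
        return ScreeningResults(self, classified, report)


class ScreeningResults:
    """Fitted evaluation: outcome counts, estimates, intervals, diagnostics."""

    def __init__(
        self,
        model: ScreeningEvaluation,
        classified: ClassifiedCohort,
        report: MetricsReport,
    ):
        self.model = model
        self.config = model.config
        self.classified = classified
        self.report = report

    # -- convenience accessors -------------------------------------------------
    @property
    def counts(self) -> pd.DataFrame:
        return self.report.counts

    @property
    def participation(self):
        return self.report.participation

    @property
    def ppv(self):
        return self.report.ppv

    @property
    def sensitivity(self):
        return self.report.sensitivity

    @property
    def ic_rate(self):
        return self.report.ic_rate

    @property
    def ic_incidence(self):
        return self.report.ic_incidence

    @property
    def eir_ratio(self):
        return self.report.eir_ratio

    @property
    def tests(self):
        return self.report.tests

    def counterfactual(
        self, cutoff: float | Mapping[str, float] = 80.0
    ) -> CounterfactualResult:
        """Re-evaluate under a uniform (or per-sex) positivity cut-off."""
        return apply_uniform_cutoff(self.classified, cutoff, self.config)

    def save_tables(self, outdir: str | Path, counterfactual_cutoff: float | None = 80.0):
        """Write the rendered report tables, JSON metrics and manifest."""
        return _report.write_report(self, Path(outdir), counterfactual_cutoff)

    def summary(self) -> str:
        """Human-readable summary of the fitted round."""
        r = self.report
        buf = StringIO()
        fmt1 = _report.fmt1
        fmt2 = _report.fmt2
        n_all = self.counts.loc["all"]
        buf.write("FIT screening round evaluation\n")
        buf.write("==============================\n")
        buf.write(
            f"Invited {int(n_all['invited']):,}; participants "
            f"{int(n_all['participants']):,} "
            f"({fmt1(r.participation['all'].point * 100)}%); "
            f"FIT positives {int(n_all['fit_positive']):,} "
            f"({fmt1(r.positivity['all'].point * 100)}%)\n"
        )
        buf.write(
            f"Cut-offs (µg/g): "
            + ", ".join(f"{s}={v:g}" for s, v in self.config.cutoff_by_sex.items())
            + f"; follow-up {self.config.followup_months:g} months\n"
        )
        sd = int(n_all["sd_crc"])
        buf.write(
            f"SD-CRC {sd}; FIT-IC {int(n_all['fit_ic'])}; colonoscopy IC "
            f"{int(n_all['colonoscopy_ic'])}; IC non-compliant "
            f"{int(n_all['ic_noncompliant'])}; CRC in non-participants "
            f"{int(n_all['nonparticipant_crc'])}\n"
        )
        ppv = r.ppv["all"]
        buf.write(
            f"PPV for CRC: {fmt1(ppv.point * 100)}% "
            f"(95% CI {fmt1(ppv.ci_low * 100)}-{fmt1(ppv.ci_high * 100)})\n"
        )
        sens = r.sensitivity["all"]
        if sens is not None:
            buf.write(
                f"Test sensitivity: {fmt2(sens.point)} "
                f"(95% CI {fmt2(sens.ci_low)}-{fmt2(sens.ci_high)})\n"
            )
        rate = r.ic_rate["all"]
        buf.write(
            f"IC rate: {fmt1(rate.point)} per 10,000 negatives "
            f"(95% CI {fmt1(rate.ci_low)}-{fmt1(rate.ci_high)})\n"
        )
        inc = r.ic_incidence["all"]
        buf.write(
            f"IC incidence: {fmt1(inc.point)} per 100,000 person-years\n"
        )
        buf.write(
            f"Total follow-up: {r.total_followup_person_years:,.0f} person-years\n\n"
        )
        header = (
            f"{'stratum':<12}{'sens':>8}{'IC rate':>10}{'IC inc':>10}"
            f"{'EIR':>8}{'inc/EIR':>10}\n"
        )
        buf.write(header)
        buf.write("-" * (len(header) - 1) + "\n")
        for stratum in STRATA:
            if stratum not in r.ic_rate:
                continue
            sens_s = r.sensitivity.get(stratum)
            ratio = r.eir_ratio.get(stratum)
            buf.write(
                f"{STRATUM_LABELS.get(stratum, stratum):<12}"
                f"{fmt2(sens_s.point) if sens_s else '--':>8}"
                f"{fmt1(r.ic_rate[stratum].point):>10}"
                f"{fmt1(r.ic_incidence[stratum].point):>10}"
                f"{self.config.eir_table.get(stratum, float('nan')):>8}"
                f"{fmt2(ratio.ratio) if ratio else '--':>10}\n"
            )
        return buf.getvalue()
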