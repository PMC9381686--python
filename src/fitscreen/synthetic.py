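"""Synthetic cohorts: a deterministic margin-exact fixture and a stochastic simulator.

``fixture_from_margins`` rebuilds an individual-level cohort from aggregate
margins so that classification and every downstream estimator reproduce the
margins exactly; it involves no randomness. Hemoglobin is recorded as the
coarse reporting category (lt40 / 40to79 / ge80), which is all the default
and uniform-80 cut-offs need. Diagnosis timing is placed mid-bin (6 or 18
months; screening-detected cancers at 3 months), since only bin membership
enters the estimators.

``simulate_cohort`` draws a cohort from a parameterized behavioural model
(participation, hemoglobin distributions, screening-test sensitivity to
prevalent cancer, colonoscopy compliance and miss rate, a de-novo cancer
hazard) for property tests and strategy exploration. The latent disease
state of every invitee is returned as a truth side-channel.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import STRATA, ScreeningConfig
from .cohort import (
    COLONOSCOPY_COLUMNS,
    CRC_COLUMNS,
    FIT_COLUMNS,
    INVITATION_COLUMNS,
    Cohort,
    hb_category_of,
)
from .margins import CANCER_MODES, CohortMargins, default_margins

FIXTURE_INVITATION_DATE = "2016-01-01"
_AGE_BY_GROUP = {"lt65": 62, "ge65": 67}


def _ids(stratum: str, start: int, n: int) -> list[str]:
    return [f"{stratum}-{i:07d}" for i in range(start, start + n)]


def fixture_from_margins(
    margins: CohortMargins | None = None,
    config: ScreeningConfig | None = None,
) -> Cohort:
    """Deterministic individual-level cohort reproducing every margin exactly."""
    margins = (margins or default_margins()).validate()
    config = config or ScreeningConfig()

    inv_frames: list[pd.DataFrame] = []
    fit_frames: list[pd.DataFrame] = []
    col_rows: list[tuple[str, int, int]] = []
    # person lists per detection mode, in stratum order, for attribute assignment
    mode_persons: dict[str, list[str]] = {mode: [] for mode in CANCER_MODES}
    months: dict[str, float] = {}

    for stratum in STRATA:
        if stratum not in margins.strata:
            continue
        m = margins.strata[stratum]
        sex, group = stratum.split("_")
        age = _AGE_BY_GROUP[group]
        cursor = 0

        def take(n: int) -> list[str]:
            nonlocal cursor
            ids = _ids(stratum, cursor, n)
            cursor += n
            return ids

        pos_categories: list[tuple[str, int, int, int, int, int]] = [
            (
                "ge80",
                m.ge80("fit_positive"),
                m.ge80("colonoscopies"),
                m.ge80("sd_crc"),
                m.ge80("colonoscopy_ic"),
                m.ge80("noncompliant_ic"),
            )
        ]
        below = m.fit_positive - m.ge80("fit_positive")
        if below:
            pos_categories.append(
                (
                    "40to79",
                    below,
                    m.colonoscopies - m.ge80("colonoscopies"),
                    m.sd_crc - m.ge80("sd_crc"),
                    m.colonoscopy_ic - m.ge80("colonoscopy_ic"),
                    m.noncompliant_ic - m.ge80("noncompliant_ic"),
                )
            )

        pos_ids: list[str] = []
        pos_cats: list[str] = []
        stratum_colic: list[str] = []
        stratum_nc: list[str] = []
        for cat, n_pos, n_col, n_sd, n_colic, n_nc in pos_categories:
            sd_ids = take(n_sd)
            colic_ids = take(n_colic)
            clean_col_ids = take(n_col - n_sd - n_colic)
            nc_ids = take(n_nc)
            nocol_ids = take(n_pos - n_col - n_nc)
            mode_persons["sd_crc"].extend(sd_ids)
            stratum_colic.extend(colic_ids)
            stratum_nc.extend(nc_ids)
            for pid in sd_ids:
                col_rows.append((pid, 1, 1))
            for pid in colic_ids + clean_col_ids:
                col_rows.append((pid, 1, 0))
            for pid in nc_ids + nocol_ids:
                col_rows.append((pid, 0, 0))
            group_ids = sd_ids + colic_ids + clean_col_ids + nc_ids + nocol_ids
            pos_ids.extend(group_ids)
            pos_cats.extend([cat] * len(group_ids))

        fitic_ids = take(m.fit_ic)
        clean_neg = m.valid_fit - m.fit_positive - m.fit_ic
        neg_clean_ids = take(clean_neg)
        npc_ids = take(m.nonparticipant_crc)
        n_nonpart_clean = m.invited - m.valid_fit - m.nonparticipant_crc
        take(n_nonpart_clean)  # invited, never returned a kit, no cancer

        mode_persons["fit_ic"].extend(fitic_ids)
        mode_persons["colonoscopy_ic"].extend(stratum_colic)
        mode_persons["ic_noncompliant"].extend(stratum_nc)
        mode_persons["nonparticipant_crc"].extend(npc_ids)

        # follow-up year bins: the stratum's ICs in order FIT-IC, colonoscopy-IC,
        # non-compliant; the first ic_year1 of them fall in year 1
        ic_order = fitic_ids + stratum_colic + stratum_nc
        for i, pid in enumerate(ic_order):
            months[pid] = 6.0 if i < m.ic_year1 else 18.0
        for pid in mode_persons["sd_crc"]:
            months.setdefault(pid, 3.0)
        for pid in npc_ids:
            months[pid] = 6.0

        all_ids = _ids(stratum, 0, m.invited)
        inv_frames.append(
            pd.DataFrame(
                {
                    "person_id": all_ids,
                    "sex": sex,
                    "age_at_invitation": age,
                    "invitation_date": FIXTURE_INVITATION_DATE,
                }
            )
        )
        participant_ids = pos_ids + fitic_ids + neg_clean_ids
        fit_frames.append(
            pd.DataFrame(
                {
                    "person_id": participant_ids,
                    "result_status": "analyzable",
                    "hb_value": np.nan,
                    "hb_category": pos_cats
                    + ["lt40"] * (len(fitic_ids) + len(neg_clean_ids)),
                }
            )
        )

    crc = _assign_cancer_attributes(margins, mode_persons, months)
    invitations = pd.concat(inv_frames, ignore_index=True)[INVITATION_COLUMNS]
    fit_results = pd.concat(fit_frames, ignore_index=True)[FIT_COLUMNS]
    colonoscopies = pd.DataFrame(col_rows, columns=COLONOSCOPY_COLUMNS)
    return Cohort(
        invitations=invitations,
        fit_results=fit_results,
        colonoscopies=colonoscopies,
        crc_register=crc,
        config=config,
    ).validate()


def _assign_cancer_attributes(
    margins: CohortMargins,
    mode_persons: dict[str, list[str]],
    months: dict[str, float],
) -> pd.DataFrame:
    """Localization and stage per mode by run-length assignment in person order."""
    rows = []
    for mode in CANCER_MODES:
        persons = mode_persons[mode]
        b = margins.breakdown.get(mode)
        if b is None:
            locs: Iterable[str] = ["unknown"] * len(persons)
            stages: Iterable[str] = ["unknown"] * len(persons)
        else:
            locs = (
                ["proximal"] * b.proximal
                + ["distal"] * b.distal
                + ["unknown"] * b.unknown_localization
            )
            stages = (
                ["I_II"] * b.stage_i_ii
                + ["III_IV"] * b.stage_iii_iv
                + ["unknown"] * b.unknown_stage
            )
        for pid, loc, stage in zip(persons, locs, stages):
            rows.append((pid, months[pid], None, loc, stage))
    return pd.DataFrame(rows, columns=CRC_COLUMNS)


class SimulationParams(BaseModel):
    """Behavioural parameters of the stochastic cohort simulator.

    Defaults emulate the Stockholm-Gotland round: its stratum mix,
    participation and colonoscopy compliance, screening-test sensitivity to
    prevalent cancer near the observed programmatic sensitivities, and a
    prevalence putting the expected cancer yield near the observed counts.
    Hemoglobin for cancer-free participants is log-normal with a sex-specific
    median placed so that roughly 2.5-3% of participants exceed their sex's
    cut-off; the distribution is illustrative (the registers publish no
    hemoglobin distributions). ``seed`` is mandatory: identical seeds give
    byte-identical cohorts.
    """

    n_invited: int = 214356
    stratum_share: dict[str, float] = Field(
        default_factory=lambda: {
            "F_lt65": 66063 / 214356,
            "F_ge65": 42794 / 214356,
            "M_lt65": 66072 / 214356,
            "M_ge65": 39427 / 214356,
        }
    )
    participation: dict[str, float] = Field(
        default_factory=lambda: {
            "F_lt65": 0.703, "F_ge65": 0.740, "M_lt65": 0.638, "M_ge65": 0.677,
        }
    )
    hb_log_mean: dict[str, float] = Field(
        default_factory=lambda: {"F": math.log(4.0), "M": math.log(8.0)}
    )
    hb_log_sd: float = 1.175
    crc_prevalence: dict[str, float] = Field(
        default_factory=lambda: {
            "F_lt65": 0.0017, "F_ge65": 0.0027, "M_lt65": 0.0026, "M_ge65": 0.0041,
        }
    )
    p_fit_positive_given_crc: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.75, "M": 0.62}
    )
    colonoscopy_compliance: float = 0.868
    colonoscopy_miss_prob: float = 0.027
    de_novo_hazard_per_year: float = 2e-4
    proximal_share: float = 0.345
    stage_probs: dict[str, float] = Field(
        default_factory=lambda: {"I_II": 0.46, "III_IV": 0.42, "unknown": 0.12}
    )
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimulationParams":
        probs = (
            list(self.participation.values())
            + list(self.crc_prevalence.values())
            + list(self.p_fit_positive_given_crc.values())
            + [self.colonoscopy_compliance, self.colonoscopy_miss_prob,
               self.proximal_share]
            + list(self.stage_probs.values())
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.de_novo_hazard_per_year < 0:
            raise ValueError("hazard must be non-negative")
        share = sum(self.stratum_share.values())
        if not math.isclose(share, 1.0, abs_tol=1e-6):
            raise ValueError("stratum shares must sum to 1")
        if not math.isclose(sum(self.stage_probs.values()), 1.0, abs_tol=1e-6):
            raise ValueError("stage probabilities must sum to 1")
        return self


def simulate_cohort(
    params: SimulationParams, config: ScreeningConfig | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Draw one cohort; returns ``(cohort, truth)``.

    ``truth`` carries the latent state per invitee (prevalent cancer, de novo
    cancer, hemoglobin) for oracle checks. Prevalent cancers surface as
    SD-CRC / interval cancer / non-participant cancer according to the
    screening pathway; cancer-free invitees can develop a de novo cancer with
    constant hazard, diagnosed at its (exponential) onset time if within the
    follow-up window.
    """
    config = config or ScreeningConfig()
    rng = np.random.default_rng(params.seed)
    n = params.n_invited

    strata = list(params.stratum_share)
    stratum = rng.choice(strata, size=n, p=[params.stratum_share[s] for s in strata])
    sex = np.array([s.split("_")[0] for s in stratum])
    group = np.array([s.split("_")[1] for s in stratum])
    boundary = config.age_group_boundary
    age = np.where(
        group == "lt65",
        rng.integers(60, boundary, size=n),
        rng.integers(boundary, 70, size=n),
    )
    person_id = np.array([f"S-{i:07d}" for i in range(n)])
    cutoff = np.array([config.cutoff_by_sex[s] for s in sex])

    participates = rng.random(n) < np.array(
        [params.participation[s] for s in stratum]
    )
    prevalent = rng.random(n) < np.array(
        [params.crc_prevalence[s] for s in stratum]
    )

    # hemoglobin for participants
    hb = np.full(n, np.nan)
    mu = np.array([params.hb_log_mean[s] for s in sex])
    base = rng.lognormal(mean=mu, sigma=params.hb_log_sd, size=n)
    pos_if_crc = rng.random(n) < np.array(
        [params.p_fit_positive_given_crc[s] for s in sex]
    )
    above = cutoff + rng.exponential(scale=40.0, size=n)
    # uniform strictly below the cut-off (0.1 headroom so rounding cannot
    # push a negative across the threshold)
    below = (cutoff - 0.1) * rng.random(n)
    hb_p = np.where(prevalent, np.where(pos_if_crc, above, below), base)
    hb[participates] = np.round(hb_p[participates], 1)
    positive = participates & (hb >= cutoff)

    performed = positive & (rng.random(n) < params.colonoscopy_compliance)
    found = performed & prevalent & (rng.random(n) >= params.colonoscopy_miss_prob)

    # diagnosis timing (months from invitation)
    months = np.full(n, np.nan)
    sd_mask = found
    months[sd_mask] = np.round(rng.uniform(1.0, 6.0, size=int(sd_mask.sum())), 1)
    missed = prevalent & ~found
    months[missed] = np.round(
        rng.uniform(3.0, config.followup_months, size=int(missed.sum())), 1
    )
    de_novo = np.zeros(n, dtype=bool)
    if params.de_novo_hazard_per_year > 0:
        onset_years = rng.exponential(
            scale=1.0 / params.de_novo_hazard_per_year, size=n
        )
        de_novo = ~prevalent & (onset_years * 12.0 <= config.followup_months)
        months[de_novo] = np.maximum(np.round(onset_years[de_novo] * 12.0, 1), 0.1)

    has_crc = prevalent | de_novo
    k = int(has_crc.sum())
    localization = np.where(
        rng.random(k) < params.proximal_share, "proximal", "distal"
    )
    stages = list(params.stage_probs)
    stage = rng.choice(stages, size=k, p=[params.stage_probs[s] for s in stages])

    invitations = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "age_at_invitation": age,
            "invitation_date": FIXTURE_INVITATION_DATE,
        }
    )
    fit_results = pd.DataFrame(
        {
            "person_id": person_id[participates],
            "result_status": "analyzable",
            "hb_value": hb[participates],
            "hb_category": [hb_category_of(v) for v in hb[participates]],
        }
    )
    colonoscopies = pd.DataFrame(
        {
            "person_id": person_id[positive],
            "performed": performed[positive].astype(int),
            "crc_found": found[positive].astype(int),
        }
    )
    crc_register = pd.DataFrame(
        {
            "person_id": person_id[has_crc],
            "months_from_invitation": months[has_crc],
            "diagnosis_date": None,
            "localization": localization,
            "stage_group": stage,
        }
    )
    truth = pd.DataFrame(
        {
            "person_id": person_id,
            "stratum": stratum,
            "participant": participates,
            "prevalent_crc": prevalent,
            "de_novo_crc": de_novo,
            "fit_positive": positive,
            "hb_value": hb,
        }
    )
    cohort = Cohort(
        invitations=invitations,
        fit_results=fit_results,
        colonoscopies=colonoscopies,
        crc_register=crc_register[CRC_COLUMNS],
        config=config,
    )
    return cohort, truth
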