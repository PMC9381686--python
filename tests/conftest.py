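"""Shared fixtures: the margin-exact study cohort and random-cohort builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fitscreen import (
    ScreeningConfig,
    Cohort,
    classify_cohort,
    compute_all_metrics,
    default_margins,
    fixture_from_margins,
)


@pytest.fixture(scope="session")
def margins():
    return default_margins()


@pytest.fixture(scope="session")
def study_cohort(margins):
    """Individual-level reconstruction of the programme round (214,356 invitees)."""
    return fixture_from_margins(margins)


@pytest.fixture(scope="session")
def classified(study_cohort):
    return classify_cohort(study_cohort)


@pytest.fixture(scope="session")
def report(classified):
    return compute_all_metrics(classified)


def random_cohort(seed: int, n: int = 200, config: ScreeningConfig | None = None) -> Cohort:
    """Messy random cohort with quantitative hemoglobin, for oracle comparisons.

    Includes boundary hemoglobin values, non-analyzable and unreturned kits,
    non-compliant positives and cancers on either side of the window edge.
    """
    config = config or ScreeningConfig()
    rng = np.random.default_rng(seed)
    person_id = np.array([f"P{i:05d}" for i in range(n)])
    sex = rng.choice(["F", "M"], size=n)
    age = rng.integers(60, 70, size=n)
    invitations = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "age_at_invitation": age,
            "invitation_date": "2016-01-01",
        }
    )
    status = rng.choice(
        ["analyzable", "not_analyzable", "not_returned"], size=n, p=[0.7, 0.1, 0.2]
    )
    # mixture with atoms exactly at the cut-offs to exercise the inclusive >=
    hb = np.round(rng.exponential(scale=30.0, size=n), 1)
    hb[rng.random(n) < 0.05] = 40.0
    hb[rng.random(n) < 0.05] = 80.0
    fit = pd.DataFrame(
        {
            "person_id": person_id,
            "result_status": status,
            "hb_value": np.where(status == "analyzable", hb, np.nan),
            "hb_category": None,
        }
    )
    fit = fit[fit["result_status"] != "not_returned"]

    cutoff = np.array([config.cutoff_by_sex[s] for s in sex])
    positive = (status == "analyzable") & (hb >= cutoff)
    performed = positive & (rng.random(n) < 0.85)
    has_crc = rng.random(n) < 0.15
    months = np.round(rng.uniform(0.5, 30.0, size=n), 1)  # some out of window
    in_window = has_crc & (months <= config.followup_months)
    found = performed & in_window & (rng.random(n) < 0.6)
    colonoscopies = pd.DataFrame(
        {
            "person_id": person_id[positive],
            "performed": performed[positive].astype(int),
            "crc_found": found[positive].astype(int),
        }
    )
    crc = pd.DataFrame(
        {
            "person_id": person_id[has_crc],
            "months_from_invitation": months[has_crc],
            "diagnosis_date": None,
            "localization": rng.choice(
                ["proximal", "distal", "unknown"], size=int(has_crc.sum()),
                p=[0.35, 0.6, 0.05],
            ),
            "stage_group": rng.choice(
                ["I_II", "III_IV", "unknown"], size=int(has_crc.sum()),
                p=[0.45, 0.4, 0.15],
            ),
        }
    )
    return Cohort(
        invitations=invitations,
        fit_results=fit,
        colonoscopies=colonoscopies,
        crc_register=crc,
        config=config,
    )
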