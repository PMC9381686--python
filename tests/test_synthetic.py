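"""Fixture generator round-trips and simulator behaviour."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from fitscreen import (
    CohortMargins,
    MarginsError,
    ModeBreakdown,
    ScreeningEvaluation,
    StratumMargins,
    classify_cohort,
    default_margins,
    fixture_from_margins,
    simulate_cohort,
    SimulationParams,
)


class TestDefaultMargins:
    def test_totals_match_programme_round(self, margins):
        totals = margins.totals()
        assert totals["invited"] == 214356
        assert totals["valid_fit"] == 146978
        assert totals["fit_positive"] == 4057
        assert totals["colonoscopies"] == 3521
        assert totals["sd_crc"] == 257
        assert totals["ic_total"] == 134
        assert totals["ic_year1"] == 39

    def test_inconsistent_margins_name_the_identity(self, margins):
        bad_strata = dict(margins.strata)
        m = bad_strata["F_lt65"]
        bad_strata["F_lt65"] = StratumMargins(
            **{
                **{f: getattr(m, f) for f in m.__dataclass_fields__},
                "sd_crc": m.colonoscopies + 1,
                "sd_crc_ge80": None,
            }
        )
        with pytest.raises(MarginsError, match="sd_crc"):
            CohortMargins(strata=bad_strata, breakdown=margins.breakdown).validate()

    def test_yaml_round_trip(self, margins, tmp_path):
        path = tmp_path / "margins.yaml"
        margins.to_yaml(path)
        loaded = CohortMargins.from_yaml(path)
        assert loaded == margins


class TestFixtureRoundTrip:
    def test_headline_margins(self, study_cohort):
        assert study_cohort.n_invited == 214356
        assert len(study_cohort.fit_results) == 146978
        assert (study_cohort.fit_results["hb_category"] != "lt40").sum() == 4057

    def test_classified_counts_equal_margins(self, margins, classified):
        counts = classified.counts()
        field_map = {
            "valid_fit": "participants",
            "fit_positive": "fit_positive",
            "colonoscopies": "colonoscopies",
            "sd_crc": "sd_crc",
            "fit_ic": "fit_ic",
            "colonoscopy_ic": "colonoscopy_ic",
            "noncompliant_ic": "ic_noncompliant",
            "nonparticipant_crc": "nonparticipant_crc",
            "ic_year1": "ic_year1",
            "invited": "invited",
        }
        for stratum, m in margins.strata.items():
            for margin_field, count_col in field_map.items():
                assert counts.loc[stratum, count_col] == getattr(m, margin_field), (
                    stratum,
                    margin_field,
                )

    def test_localization_and_stage_margins(self, margins, classified):
        df = classified.df
        for mode, b in margins.breakdown.items():
            sub = df[df["outcome"] == mode]
            assert (sub["localization"] == "proximal").sum() == b.proximal
            assert (sub["localization"] == "distal").sum() == b.distal
            assert (sub["localization"] == "unknown").sum() == b.unknown_localization
            assert (sub["stage_group"] == "I_II").sum() == b.stage_i_ii
            assert (sub["stage_group"] == "III_IV").sum() == b.stage_iii_iv
            assert (sub["stage_group"] == "unknown").sum() == b.unknown_stage

    def test_deterministic_output(self, study_cohort):
        again = fixture_from_margins(default_margins())
        for table in ("invitations", "fit_results", "colonoscopies", "crc_register"):
            assert getattr(again, table).equals(getattr(study_cohort, table))

    def test_hand_written_small_margins_round_trip(self):
        margins = CohortMargins(
            strata={
                "F_lt65": StratumMargins(
                    invited=30, valid_fit=20, fit_positive=6, colonoscopies=5,
                    sd_crc=2, fit_ic=3, colonoscopy_ic=1, noncompliant_ic=1,
                    nonparticipant_crc=2, ic_year1=2,
                    fit_positive_ge80=3, colonoscopies_ge80=3, sd_crc_ge80=1,
                    colonoscopy_ic_ge80=1, noncompliant_ic_ge80=0,
                ),
                "M_ge65": StratumMargins(
                    invited=20, valid_fit=12, fit_positive=4, colonoscopies=3,
                    sd_crc=1, fit_ic=2, colonoscopy_ic=0, noncompliant_ic=1,
                    nonparticipant_crc=1, ic_year1=3,
                ),
            },
        ).validate()
        counts = classify_cohort(fixture_from_margins(margins)).counts()
        for stratum, m in margins.strata.items():
            assert counts.loc[stratum, "sd_crc"] == m.sd_crc
            assert counts.loc[stratum, "fit_ic"] == m.fit_ic
            assert counts.loc[stratum, "colonoscopy_ic"] == m.colonoscopy_ic
            assert counts.loc[stratum, "ic_noncompliant"] == m.noncompliant_ic
            assert counts.loc[stratum, "nonparticipant_crc"] == m.nonparticipant_crc
            assert counts.loc[stratum, "ic_year1"] == m.ic_year1

    @given(
        invited=st.integers(20, 60),
        data=st.data(),
    )
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_random_consistent_margins_round_trip(self, invited, data):
        valid = data.draw(st.integers(5, invited))
        pos = data.draw(st.integers(2, min(valid, 10)))
        col = data.draw(st.integers(1, pos))
        sd = data.draw(st.integers(0, col))
        colic = data.draw(st.integers(0, col - sd))
        nc = data.draw(st.integers(0, pos - col))
        fit_ic = data.draw(st.integers(0, min(3, valid - pos)))
        npc = data.draw(st.integers(0, min(3, invited - valid)))
        year1 = data.draw(st.integers(0, fit_ic + colic + nc))
        margins = CohortMargins(
            strata={
                "M_lt65": StratumMargins(
                    invited=invited, valid_fit=valid, fit_positive=pos,
                    colonoscopies=col, sd_crc=sd, fit_ic=fit_ic,
                    colonoscopy_ic=colic, noncompliant_ic=nc,
                    nonparticipant_crc=npc, ic_year1=year1,
                )
            },
        ).validate()
        counts = classify_cohort(fixture_from_margins(margins)).counts()
        row = counts.loc["M_lt65"]
        assert row["sd_crc"] == sd and row["fit_ic"] == fit_ic
        assert row["colonoscopy_ic"] == colic and row["ic_noncompliant"] == nc
        assert row["ic_year1"] == year1 and row["nonparticipant_crc"] == npc


class TestSimulator:
    def test_identical_seed_identical_cohort(self, tmp_path):
        params = SimulationParams(n_invited=3000, seed=42)
        a, truth_a = simulate_cohort(params)
        b, truth_b = simulate_cohort(SimulationParams(n_invited=3000, seed=42))
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        a.write(dir_a)
        b.write(dir_b)
        for name in ("invitations.csv", "fit_results.csv", "colonoscopies.csv", "crc_register.csv"):
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes()
        assert truth_a.equals(truth_b)

    def test_different_seed_differs(self):
        a, _ = simulate_cohort(SimulationParams(n_invited=3000, seed=1))
        b, _ = simulate_cohort(SimulationParams(n_invited=3000, seed=2))
        assert not a.fit_results["hb_value"].equals(b.fit_results["hb_value"])

    def test_no_miss_no_hazard_means_no_colonoscopy_ics(self):
        params = SimulationParams(
            n_invited=20000, seed=5, colonoscopy_miss_prob=0.0,
            de_novo_hazard_per_year=0.0,
        )
        cohort, _ = simulate_cohort(params)
        counts = classify_cohort(cohort).counts()
        assert counts.loc["all", "colonoscopy_ic"] == 0

    def test_perfect_test_means_no_fit_ics_from_prevalent_cancer(self):
        params = SimulationParams(
            n_invited=20000, seed=6, de_novo_hazard_per_year=0.0,
            p_fit_positive_given_crc={"F": 1.0, "M": 1.0},
        )
        cohort, _ = simulate_cohort(params)
        counts = classify_cohort(cohort).counts()
        assert counts.loc["all", "fit_ic"] == 0

    def test_sensitivity_recovers_simulated_test_positivity(self):
        """With full compliance, no misses and no de novo cancers the
        programmatic sensitivity estimates P(FIT+ | prevalent CRC)."""
        p_true = 0.7
        params = SimulationParams(
            n_invited=200000, seed=20150931 % 2**31,
            colonoscopy_compliance=1.0, colonoscopy_miss_prob=0.0,
            de_novo_hazard_per_year=0.0,
            p_fit_positive_given_crc={"F": p_true, "M": p_true},
            crc_prevalence={
                "F_lt65": 0.003, "F_ge65": 0.003, "M_lt65": 0.003, "M_ge65": 0.003,
            },
        )
        results = ScreeningEvaluation.simulate(params).fit()
        est = results.sensitivity["all"]
        n_cancers = est.denominator
        se = math.sqrt(p_true * (1 - p_true) / n_cancers)
        assert abs(est.point - p_true) <= 3 * se

    def test_ic_incidence_matches_configured_hazard(self):
        """With no prevalent cancer, participation 1 and hazard h per
        person-year, IC incidence approaches h per 100,000 person-years and
        the proportional incidence against an EIR of h equals ~1."""
        h = 1e-3
        from fitscreen import ScreeningConfig

        config = ScreeningConfig(
            eir_table={k: h * 1e5 for k in ("F_lt65", "F_ge65", "M_lt65", "M_ge65")}
        )
        params = SimulationParams(
            n_invited=200000, seed=77,
            participation={k: 1.0 for k in ("F_lt65", "F_ge65", "M_lt65", "M_ge65")},
            crc_prevalence={k: 0.0 for k in ("F_lt65", "F_ge65", "M_lt65", "M_ge65")},
            de_novo_hazard_per_year=h,
        )
        results = ScreeningEvaluation.simulate(params, config).fit()
        observed = sum(r.observed_count for r in results.eir_ratio.values())
        expected = sum(r.expected_count for r in results.eir_ratio.values())
        ratio = observed / expected
        se = 1.0 / math.sqrt(observed)
        assert abs(ratio - 1.0) <= 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_invited=100, seed=1, colonoscopy_compliance=1.5)

    def test_seed_is_mandatory(self):
        with pytest.raises(Exception):
            SimulationParams(n_invited=100)
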