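# Methods

## Setting and data model

The package evaluates one round of an invitational FIT-based colorectal
cancer screening programme. An invitee's episode is described by four
records keyed on an opaque person id: the invitation (sex, age at
invitation, date), the returned FIT kit (analyzable / not analyzable / not
returned; hemoglobin in µg Hb per g feces, either quantitative or as the
coarse category lt40 / 40to79 / ge80), the screening colonoscopy offered
after a positive FIT (performed, cancer found), and cancer-register records
(months from invitation or a diagnosis date, localization, stage group).
Only a person's first dated invitation counts; ties on the date are broken
by full-row lexicographic order so deduplication is deterministic and
independent of input order. Failure to return an analyzable kit is
non-participation. Invitees are stratified by sex and age at invitation
(below / at-or-above the 65-year boundary); the reference configuration is
the Stockholm-Gotland 2015–2017 round: cut-offs 40 µg/g (women) / 80 µg/g
(men), comparison inclusive (≥), 24 months of follow-up.

## Outcome classification

Classification follows the WEO definitions and is a decision list evaluated
per invitee: non-participants with an in-window cancer are
`nonparticipant_crc` (never an interval cancer); FIT-negative participants
with a cancer are `fit_ic`; FIT-positive participants whose performed
screening colonoscopy found the cancer are `sd_crc`; with a performed but
cancer-free colonoscopy and a later in-window diagnosis, `colonoscopy_ic`;
with no colonoscopy performed, `ic_noncompliant`; everyone else `no_crc`.
The classes are exhaustive and mutually exclusive by construction. A cancer
found at the screening colonoscopy is SD-CRC on the strength of the
colonoscopy record's flag; diagnosis-date bookkeeping relative to the
colonoscopy date is not consulted, and a `crc_found` flag without a
matching register record is rejected as inconsistent input. Where a person
has several register records, the earliest in-window diagnosis is kept;
records beyond the window are dropped. Diagnoses at exactly month 12
belong to follow-up year 1.

All three IC subtypes count in IC numerators. The IC-rate denominator is
FIT negatives plus FIT positives with a cancer-free screening colonoscopy;
non-compliant positives are therefore in the numerator population but not
the denominator, which reproduces the per-stratum IC rates of the reference
round (e.g. 9.8 and 17.4 per 10,000 for men).

## Estimators and intervals

The interval methods are not dictated by the outcome definitions; the
choices below reproduce every printed interval of the reference round and
are applied uniformly:

- proportions (participation, positivity, compliance, PPV, test
  sensitivity, IC rate): Wald, p̂ ± z·√(p̂(1−p̂)/n), clipped to [0, 1];
- incidence rates: log-normal, rate·exp(±z/√k), undefined at k = 0;
- the proportional-incidence ratio: exact Poisson (Garwood) limits on the
  observed count, χ²(α/2, 2k)/2 to χ²(1−α/2, 2k+2)/2, divided by the
  expected count E = EIR·PY/10⁵ with the EIR treated as fixed;
- 2×2 comparisons: chi-squared with Yates' continuity correction.

Sensitivity by tumor localization restricts both numerator and denominator
to SD-CRC and FIT-IC with known localization. All arithmetic is carried at
full precision; rounding happens only at rendering (rates to 1 decimal,
ratios and sensitivities to 2), with half-to-even ties on the decimal
representation — the convention of R's `round`, which matters for exact
ties such as the counterfactual women-under-65 sensitivity 42/80 = 0.525
(printed 0.52).

### Person-years

Follow-up is two years per person, or one year for a person whose interval
cancer is diagnosed within the first year. The reference round applies this
inconsistently: its total follow-up figure (428,673 = 2·214,356 − 39)
subtracts the first-year ICs over the *invited* cohort, while its
per-stratum incidence rates use a flat two years per screening negative
(e.g. 45.8 per 10⁵ PY = 134/292,370, where 292,370 = 2·146,185 with no
subtraction). The package therefore defaults `person_year_subtraction` to
off for stratum incidence rates and uses the subtraction convention for the
total-follow-up figure; the flag flips the convention everywhere it
applies.

### Year-split rates

Yearly denominators take half the full-round negatives, one person-year
each. Published year-split cells deviate slightly from this stated
arithmetic (3.02 vs computed 3.03, 6.47 vs 6.49, 112.7 vs 113.3); the
formula as stated is implemented and the computed values pinned in tests.
Similarly, the men's overall IC rate computes to 12.71 (87/68,435 per
10,000) against a printed 12.6, the printed overall sensitivity 0.68 is a
one-ulp rounding slip of 257/381 = 0.6745 (its own CI 0.63–0.72 matches the
computed point), and the published ratio CI bounds (e.g. 0.18–0.49) are not
reproducible as exact-Poisson-over-expected (computed 0.19–0.46) nor as
log-normal limits; the package reports its computed intervals.

## Counterfactual cut-off analysis

Raising cut-offs admits a shortcut on the classified cohort: participants
whose hemoglobin falls below the new cut-off flip to FIT-negative, their
SD-CRCs, colonoscopy ICs and non-compliant cancers are reclassified as
FIT-ICs, their cancer-free colonoscopies leave the negatives denominator,
and every estimator is recomputed. This implements literally the assumption
that all such cancers would have surfaced as interval cancers within the
same window — which can overestimate the counterfactual IC rate, since some
might have remained undiagnosed until the next round. The shortcut is
proven equivalent (in tests, exactly) to re-running the classifier from raw
records under the new configuration whenever the stored hemoglobin
information resolves the new cut-off; coarse categories resolve exactly the
cut-offs 40 and 80. Lowering a cut-off is only possible from raw records,
because it requires colonoscopy outcomes never observed; the shortcut
refuses it. Proportional incidence in the counterfactual uses a flat two
person-years per screening negative under the new cut-off. Year-split
subcategories are not produced for reclassified cohorts: former SD-CRCs
have no meaningful post-negative-test diagnosis timing.

## Synthetic cohorts

### Margin-exact fixture

`fixture_from_margins` rebuilds an individual-level cohort from aggregate
margins — per stratum: invited, valid FITs, positives (women additionally
split at 80 µg/g through colonoscopies, SD-CRCs, colonoscopy ICs and
non-compliant ICs, so the uniform-80 reanalysis is fully determined),
outcome-class counts and the year-1 IC count; per detection mode: the
localization and stage breakdowns. Persons are laid out deterministically
(no randomness): within each stratum and hemoglobin category, the cancers
first, then cancer-free colonoscopies, then the remaining positives,
negatives and non-participants. Hemoglobin is stored as the coarse
category; diagnosis timing sits mid-bin (6/18 months, SD-CRCs at 3 months)
since only bin membership is consumed; invitation dates are a single
constant (the dedup path is exercised by dedicated unit fixtures). Margins
are validated against their internal identities before generation, and the
round-trip property — classify + recount = margins — is tested for the
packaged margins and for random consistent margins.

Cells the reference round never printed are filled deterministically and
make no contribution to any reported estimate: the sex × age allocation of
the 177 non-participant cancers (northwest-corner: 68/0/28/81), the
localization (2 proximal / 1 distal, forced by the overall 196-proximal
margin) and stage (2 / 1, free) of the three non-compliant ICs, the
within-mode joint distribution of localization × stage × stratum × year
(run-length assignment in person order), and the mode × year composition of
each stratum's IC year split (FIT-ICs take the year-1 slots first).

### Stochastic simulator

`simulate_cohort` draws invitees with configurable stratum mix,
participation, and prevalent-cancer probability per stratum; a prevalent
cancer is FIT-positive with probability P(FIT+ | CRC) per sex (the
screening-test sensitivity parameter), cancer-free participants draw
hemoglobin from a sex-specific log-normal (medians 4 and 8 µg/g, log-SD
1.175, placing ≈2.5% of each sex above its cut-off — illustrative, as no
registry publishes hemoglobin distributions); colonoscopy compliance and a
miss probability govern the positive pathway; cancer-free invitees acquire
de novo cancers with a constant hazard per person-year, diagnosed at onset
if within the window. Defaults approximate the reference round (its
stratum shares, participation 0.64–0.74, compliance 0.868, miss ≈ 7/264,
prevalence ≈ (SD+FIT-IC)/valid per stratum, sensitivity 0.75/0.62 by sex).
The simulator is seeded and byte-reproducible. What it does *not* emulate:
hemoglobin-dependent cancer detectability (positivity given cancer is a
coin flip, not a threshold on a tumor-specific hemoglobin distribution),
migration and death censoring, repeat rounds, and reminder logistics — so
passing parameter-recovery tests demonstrate estimator correctness under
the model's assumptions, not registry realism. Parameter recovery is
tested at n = 200,000: with full compliance, no misses and no de novo
hazard, programmatic sensitivity recovers P(FIT+ | CRC) within 3 binomial
standard errors; with prevalence zero and hazard h, proportional incidence
against an EIR of h·10⁵ recovers 1 within 3 Poisson standard errors.

## Numerical and design notes

- Cut-off comparisons are inclusive (≥); a coarse hemoglobin category is
  accepted wherever no cut-off falls strictly inside its interval, and
  rejected (not guessed) otherwise.
- Degenerate inputs: sensitivity is reported as undefined (`None`) when a
  stratum has no SD-CRC + FIT-IC; zero-count incidence has no interval;
  2×2 tests are skipped on zero margins; empty cohorts and orphan or
  inconsistent records fail validation with row-numbered messages.
- The evaluation pipeline is a pure function of (records, configuration):
  reruns are byte-identical, and the report writer emits a manifest with
  config and output hashes.
- Problem sizes in the test suite: the full 214,356-person reconstruction
  is built once per session (≈2 s); property tests use 200–500-person
  random cohorts; simulator calibration checks use 200,000 invitees;
  interval-coverage checks use 10,000 Poisson draws per mean. The whole
  suite runs in well under a minute on one CPU.
- Scope limits: single round only (no carry-over of undiagnosed lesions to
  a next round), stage consumed as a category (no TNM logic), no mortality
  endpoints, no multiple-testing adjustment (none is applied in this style
  of programme report), and counterfactuals never alter participation or
  compliance behaviour.
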