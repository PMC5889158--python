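# Methods

This note records the modeling and numerical decisions behind the package:
what the pipeline assumes, what the synthetic generator does and does not
emulate, and where genuinely open design choices were settled.

## Study design and windows

All per-patient time is measured in integer day offsets from the index
date (day 0 = the first-ever biologic dispense). Windows are half-open:
pre-index `[-365, 0)`, follow-up `[0, 365)`, follow-up year k
`[365(k-1), 365k)`. Coverage intervals in the enrollment table are closed
date intervals; an enrollment *break* between two intervals is the count of
uncovered days strictly between them, and a break is tolerated when it is
strictly shorter than 30 days (a 30-day break fails). Uncovered spans at a
window's edges are treated as breaks under the same tolerance — a break is
a break regardless of where it falls in the window.

New-user status is absolute within the data: any biologic dispense before
the index period disqualifies, regardless of how far back it occurred.
Diagnosis-based exclusions scan the full data horizon (2009-01-01 to
2013-12-31). Two distinct biologic agents dispensed on the index date make
the index agent undecidable; such patients are excluded and logged, since
no principled tie-break exists.

The catastrophic-illness certification must predate (or equal) the index
date by default. The registry does not state when certification must occur
relative to indexing, so the requirement is a config switch
(`require_card_before_index`).

## The five-criterion classifier

* **PDC** uses the union of `[dispense, dispense + days_supplied)`
  intervals clipped to the follow-up window, over a fixed 365-day
  denominator. There is no stockpiling adjustment: overlapping supplies
  collapse rather than shift forward. This is the simplest defensible PDC
  and makes the statistic insensitive to how a given total supply is split
  across dispenses (a tested invariant). The threshold comparison is
  strict: exactly 292/365 = 0.80 is adherent.
* **Switch/add** triggers on any dispense of a non-index biologic agent in
  the window; **new csDMARD** requires a compound with zero dispenses in
  the pre-index window *or on the index date* (a drug co-initiated with the
  biologic is part of the starting regimen, not an escalation).
* **Glucocorticoid injections**: the default threshold is 2 ("more than
  one"); a documented variant reading of the rule uses ≥ 1, so the
  threshold is exposed as `gc_injection_min_count`.
* **Oral glucocorticoid increase** compares mean daily
  prednisone-equivalent dose, attributing each dispense's total milligrams
  to its dispense date. The first 90 follow-up days are excluded because
  bridging steroids at biologic start are routine; the margin above the
  pre-index mean defaults to 0 % (any strict increase, including new use
  over zero). Both are configurable; neither window nor margin is
  standardized in the literature. Cross-drug doses are normalized with the
  usual potency table (5 mg prednisone ≡ 5 mg prednisolone ≡ 4 mg
  methylprednisolone ≡ 0.75 mg dexamethasone ≡ 20 mg hydrocortisone).
* **Censoring**: a patient whose enrollment spell (bridging breaks < 30
  days, truncated at death) ends before day 364 is censored at the first
  unobserved day. Criteria 2–4 are event-dated and can flag a censored
  patient before the censor day; the two year-summary criteria (adherence,
  oral steroid dose) require complete follow-up and are not evaluated for
  censored patients. *Unknown* therefore means: censored with nothing met
  beforehand. "Meeting none of the five criteria" defines *stable* — the
  only self-consistent reading of the published decision rule.
* For first-met attribution each criterion needs a date: event criteria
  use their event day (the second injection's day for criterion 4), low
  adherence uses the last follow-up day (it is only assessable when the
  window closes), and the dose increase uses the first comparison-window
  dispense. Ties break by the fixed criterion order 1–5.

## Charlson comorbidity

The Deyo ICD-9-CM adaptation, shipped as an editable prefix table: 17
categories, weights {1, 2, 3, 6}, with severe diabetes / liver disease /
metastatic cancer suppressing their milder counterparts. Lookback is the
pre-index year plus the index date, and a single claim in any setting
triggers a category (no two-outpatient confirmation rule — the simplest
rule absent stronger guidance, exposed via config only through the
lookback). Every cohort patient triggers the rheumatic-disease category
through RA itself, so cohort means are ≥ 1; `cci_count_ra=False` removes
that category for sensitivity analyses. Malignancy categories stay in the
map even though cohort exclusions make them unreachable, for reusability.

## Outcome aggregation

Hospital days per admission are discharge − admission dates with a minimum
of 1 for same-day stays. A patient contributes to follow-up year k only if
continuously enrolled through the whole year-k window; this, not
annualization of partial years, is what shrinks the per-year denominators.
Cost categories: the non-medication lines of claims go to their setting
(inpatient / outpatient / ED); all pharmacy costs plus the medication
lines of medical claims form the medication category; the total is the sum
of the four — conservation is enforced per patient, never re-entered.
Money is integer NT$ cents internally (exact sums), converted to USD at
1 TWD = 0.033 USD; all reported figures round half-up to whole dollars and
whole percent. Time-to-switch is the conditional mean among switchers; an
empty switcher set is reported as absent, not zero.

## The synthetic generator

The generator's defaults are the study conditions, not tuning knobs. The
`paper_preset()` scenario plants, exactly: 818 cohort patients (258 stable
/ 540 IR / 20 unknown), a 375/443 adalimumab/etanercept index mix, 79/56
three-year switchers with destination counts fixed per agent, and per-year
enrollment retention (798/785/741 overall). Continuous targets are planted
as distributional means: per cohort-year resource-use means (Poisson
counts; length of stay 1 + Poisson), per cohort-year cost means (log-normal
with SD matched for the always-positive outpatient and medication
categories; for the zero-inflated inpatient/ED categories the draw is
conditional on use with a fixed dispersion and only the cell mean is
matched, since the printed SDs are dominated by the zero mass), criterion
marginals among IR patients (exact-count assignment guaranteeing every IR
patient at least one flag), per-cohort demographics, Charlson intensity
(1 + Poisson extra weight-1 categories), and switch-day distributions whose
conditional means are matched exactly (782.4 / 755.6 days).

Every planted flag is realized by concrete claims, and a non-interference
guarantee holds by construction: stable patients' coverage never drops
below the threshold (integer covered-days in [292, 365]), they receive no
non-index biologic, no new compound (background methotrexate always has
pre-index dispenses), at most bridging steroids or a tapering dose, and no
injections. Low-adherence coverage lies in [73, 291] days, one full day
below the threshold, so floating-point day arithmetic cannot flip a label.
Unknown patients are censored uniformly on days 30–334 with no prior
criterion. A handful of decoy patients each violate exactly one selection
rule so the attrition table is exercised; they never reach the cohort.

What the generator does **not** emulate: disease progression, correlation
between comorbidity burden and cost beyond cohort-level means, seasonal or
provider effects, realistic dispersion for count outcomes (printed SDs of
utilization are not reproduced, means are), and any dependence of
censoring on health status beyond the planted retention counts. Passing
plant-and-recover tests therefore demonstrates that the pipeline computes
the intended quantities correctly — not that the algorithm is valid on
real claims, where coding practice and confounding are the hard part.

The cohort-level criterion-attribution shares used for calibration
(36/20/17/8/3 percent) overlap within patients and exceed the 66 % IR
rate in sum; how the original analysis handled the denominator is
unknowable from the printed figures, so the preset plants them as
overlapping cohort-level marginals and reports both marginal and first-met
attributions, clearly labeled.

## Problem sizes and determinism

The test suite runs the full 818-patient preset once (a few seconds) and
uses 50–300-patient scenarios for determinism, nuisance-robustness and
round-trip properties; the adherence statistic is verified against a
per-day boolean enumeration oracle on 1,000 random dispense sets. All
randomness flows from a single integer seed through one generator, so
equal seeds give byte-identical bundles; stochastic recovery tests assert
agreement within three standard errors at the preset sample sizes.

## Known limitations

* ICD-9-CM only; no ICD-10 mapping.
* The classifier is a claims proxy — no DAS28 or clinical response, and an
  oral-steroid escalation for, say, COPD is indistinguishable from one for
  RA.
* PDC uses a fixed denominator rather than a censor-adjusted one; the
  unknown category absorbs censored patients instead.
* No statistical inference (the analysis is descriptive); no survival
  analysis of switching; no propensity adjustment.
* Costs are planted and summarized as means; the package does not model
  patient-level cost trajectories.
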