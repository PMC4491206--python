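# Methods

This note documents the models and procedures `pedopitox` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Cohort and follow-up

Eligibility is evaluated **per opioid fill**: the child must be 2–17 completed
years old on the fill date (inclusive bounds; `age_at` counts the birthday as
completing a year), the fill date must lie in the study window and inside an
enrollment span, and no encounter in the `lookback_days` (default 365) before
the fill may carry a code from a configured exclusion group (serious illness,
organ transplant, institutional residence, drug abuse). The lookback interval
is `[fill − lookback, fill)` — anchored at the fill because each fill starts
its own follow-up; a fill that fails any check is dropped individually, and a
child with no surviving fills leaves the cohort. Naloxone receipt is
explicitly not an exclusion. A `require_continuous_enrollment` toggle
(default off) additionally demands one enrollment span covering the entire
lookback; span containment of the fill date is always required.

## Risk windows and time strata

Day-counting convention: the fill day is supply day 1, so
`supply_end = fill_date + days_supply − 1`; the window is the inclusive
interval `[fill_date, supply_end + 14]`. The *early* stratum runs through
`supply_end + 7`, the *late* stratum covers days 8–14 after supply end. The
14-day tail exists because toxicity can be delayed and as-needed dosing can
extend actual use past the dispensed supply. Overlapping windows from
successive fills are kept separate; an event covered by several windows is
attributed to the **most recent fill on or before the event date** whose
window contains it, and at most one potential case is emitted per
(child, event date). A death on the same date as a qualifying encounter
supersedes the encounter-based case, since death review is unconditional.

## Screening categories and precedence

ICD-9-CM codes are canonicalized (uppercase, trimmed, dot-stripped) and
matched against configured patterns, prefix-mode by default because ICD-9
families are hierarchical. Primary and secondary diagnosis positions are
treated identically. For each external-cause category (intentional overdose,
unintentional overdose, adverse effect in therapeutic use) the trigger is:
any group A (opioid/unspecified analgesic) or group C (unspecified
medication) code present and **no** group B (specific non-opioid drug) code
anywhere on the encounter. The B-subtraction is applied uniformly to all
three e-code categories: an event already attributed to a specific other drug
is unlikely to be adjudicated as opioid toxicity, and the rule is inert when
a category's B list is empty. Symptom screening (CNS or respiratory
depression diagnosis codes) needs no external-cause code.

When several categories fire, precedence is

    intentional > unintentional > adverse effect > symptom-only

— most-specific-intent first. The strata in the validation tables are
mutually exclusive, but no explicit tie-break rule is published, so the
precedence order is a package choice and is a parameter of
`classify_encounter`. Deliberately *not* screened (mirroring the validated
design): naloxone administration, metabolic-disorder symptoms,
dermatologic/GI symptoms without an adverse-effect code, and less specific
CNS/respiratory symptom codes such as dizziness.

The shipped code lists are a **reconstruction** assembled from the standard
ICD-9-CM families (965.0x opiate poisoning; E850/E858 accidental and E980
undetermined poisoning; E950 self-inflicted poisoning; E935/E947 adverse
effects in therapeutic use; coma/altered-consciousness and
apnea/respiratory-failure diagnosis codes). They are configuration, not
source: every report records the registry `version`, and studies should
substitute their own validated lists.

## Adjudication rules

`adjudicate` is a total function on a structured chart abstraction:

* **Group 1** — compatible signs/symptoms attributed by the treating
  physician to an opioid with no other process implicated, *or* direct
  intervention/escalation of care for potential opioid toxicity.
* **Group 2** — compatible signs/symptoms, not clearly attributed to the
  opioid but not attributed to another cause, with a supporting temporal
  sequence.
* **Group 3** — everything else (attributed to another cause; no temporal
  support; nothing compatible).

The abstraction schema is the minimal set of booleans sufficient to express
these criteria; the published adjudication form itself is not reproducible
from the available text, so the prose criteria are normative here. Severity
of confirmed cases uses the explicit dominance order
death > high (hospitalization/escalation) > intermediate (primary reason for
an ED visit) > low (incidental); the source lists the categories without a
tie-break, so dominance is a package choice. Exposure circumstances (intent)
and opioid source are closed vocabularies passed through unchanged —
`unspecified` is preserved, never imputed. Drug-screen results are
deliberately not inputs. `consensus` returns the agreed group or, on
disagreement, the supplied committee label with a disagreement flag; it never
auto-resolves.

## Validation statistics

PPV cells use the exact Clopper–Pearson interval
(`statsmodels.stats.proportion.proportion_confint(method="beta")`); an empty
stratum is *undefined*, not 0%. Cases whose records were not found or held
too little information are removed from every denominator
(`n_adjudicable = n_screened − n_no_information − n_not_found`), and the
report enforces that category and time-stratum totals sum to the overall
cell. Reported percentages are rounded to one decimal; tests compare
unrounded values, because printed one-decimal figures can carry rounding
slack of ±0.1 point. Cohen's kappa is unweighted over the three adjudication
groups, with observed and expected agreement exposed; κ is undefined (None)
when both raters are constant and identical (pₑ = 1). A symptom case that
carries both CNS and respiratory triggers is counted in both subtype cells
(subtype cells are therefore not forced to partition the symptom stratum,
though the default generator emits single-subtype cases only).

## Synthetic generator

The generator emulates the *validation conditions*, not pediatric
epidemiology. Defaults: ages truncated-normal (mean 11.3, SD 5.0, clipped to
2–17 calendar years at the first fill), 57% female, fills per child
1 + Poisson(0.5), days supply in {3,5,7,10,14} weighted toward short courses,
planted cases in the observed category mix (30:31:58:47:2), confirmation
probabilities equal to the observed per-stratum PPVs (50.0%, 80.6%, 56.9%,
CNS 28.1%, respiratory 20.0%, deaths 0%), early/late window positions in the
observed 121:47 split, record availability 86.2% (11.8% not found, 2.1%
insufficient), and reviewer agreement 91.7%.

Two defaults deserve explanation:

* **Planted event rate.** The underlying cohort size behind the observed
  case counts is not published, so no rate is stated anywhere; real-world
  incidence (≪1% per child) would leave stratified PPV estimates hopelessly
  noisy at feasible simulation sizes. The default plants a case for 30% of
  children, chosen once so that a 20,000-child run yields roughly 900–1,800
  adjudicable cases per category and the binomial standard error of each
  stratum PPV is ~1–2 points. The generator is a calibration harness; the
  rate is a resolution knob, not an epidemiologic claim.
* **Stratum confirmation tilt.** Confirmation probability is
  `min(1, p_stratum × m_position)` with default multipliers
  m_early = (69/121)/(85/168) ≈ 1.127 and m_late = (16/47)/(85/168) ≈ 0.673.
  Because the early fraction is 121/168 and
  (121/168)·m_early + (47/168)·m_late = 1 exactly, the per-category
  confirmation probabilities are preserved while the early/late PPVs land on
  the observed 57%/34% split. Setting both multipliers to 1 removes the
  tilt.

Planted encounters draw their codes from the **active registry** (a prefix
pattern string is itself a code of its family), so custom code sets remain
fully testable; generation fails fast if a filler/decoy code collides with
any screening or exclusion group. Reviewer 1's abstraction realizes the
planted group exactly; reviewer 2 reproduces it with probability
`reviewer_agreement` and otherwise realizes a uniformly different group; the
committee label (used only on disagreement) is reviewer 1's result, so the
final adjudication always equals the planted group and planted confirmation
probabilities are recovered as clean binomial draws.

What the generator does **not** emulate: code co-occurrence and comorbidity
structure, seasonal or secular utilization trends, dose/duration effects,
correlated repeat events within a child (at most one planted case per child),
and any dependence of record availability on calendar year. Passing tests
therefore demonstrate that the pipeline's logic and statistics are correct
and calibrated under the stated conditions — not that the shipped code lists
achieve any particular PPV on real claims.

A consequence of the simplified reviewer model: at the default 91.7%
agreement the simulated κ is ≈ 0.87 rather than 0.83, because chance
agreement depends on the group marginals, and the generator's planted group
distribution is less concentrated than the one observed in the 156-pair
reliability sample (pₑ ≈ 0.37 vs 0.506). The worked-example check
κ(0.917, 0.506) = 0.83 uses the observed marginals directly.

## Problem sizes and numerics

The test suite runs the full pipeline at 2,000 and 20,000 children (seconds
each); `scripts/acceptance.py` uses 20,000 children, the size at which every
stratum's empirical PPV sits within ~3 points (≈2 binomial SEs) of its
planted value. All randomness flows from a single integer seed through one
`numpy` generator, so every artifact is bit-reproducible. Dates are whole
calendar days throughout; there are no floating-point comparisons anywhere in
the screening logic.

## Known limitations

* The default code lists are a reconstruction; PPVs on real data depend
  entirely on the deployed list.
* Sensitivity, specificity and NPV are out of reach by design: screen-negative
  encounters are never adjudicated, so only PPV is estimable.
* The adjudication engine is deterministic given the abstraction; all
  clinical judgment lives upstream in chart abstraction, which the package
  does not automate.
* Episode semantics: one potential case per (child, event date). If a single
  toxicity episode spans several encounter dates it is counted once per date
  with a qualifying encounter.
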