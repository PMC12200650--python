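# Methods notes

## Scope and data model

The package analyses longitudinal primary-care prescription records shaped
like CPRD Aurum extracts: a patient/registration table, an opioid
prescription-issue table (date, product, quantity, daily dose, optional
duration) and a coded clinical-event table (CNCP, cancer, NMSC,
comorbidities, and concurrent-drug classes). Real CPRD data are
access-restricted, so the package ships a synthetic generator with the same
statistical structure plus planted ground truth; the statistical layer can
also be run directly on the packaged table of published annual counts
(2009–2019 UK primary care).

All calendar arithmetic is in whole days with fixed conventions — 12
months = 365 d, 6 months = 183 d, 5 years = 1825 d, 10 years = 3650 d —
ignoring leap days. This keeps every eligibility window an exactly testable
constant; the bias relative to true calendar months is at most a few days
per decade and far below the resolution of annual rates.

## Phenotype definitions

* **Incident opioid user**: an opioid issue with no opioid issue in the
  preceding 365 days (new-user washout), in an adult (index year − birth
  year ≥ 18; the data model records year of birth only) with ≥365 days of
  prior registration. A patient may contribute several index events, each
  with its own washout, and events are attributed to the index year.
* **L-TOT**: evaluated over days 30–364 after index (the first 30 days are
  excluded from *both* criteria; the defining sentence is ambiguous on this
  point and the choice is isolated in one constants object).
  Criterion A counts prescription issue dates inside the window falling
  within any 90-consecutive-day span (spans float freely; issues outside
  the window never count). Criterion B counts *distinct* window days
  covered by ≥1 supply interval, so overlapping supplies are not
  double-counted. Supply intervals are closed (issue day and last day both
  covered).
* **Discontinuation**: an opioid-free gap of ≥180 days whose first day lies
  in days 365–729 after index ("in the following one year" of the L-TOT
  year), with the whole 180-day confirmation window inside the patient's
  observable data, i.e. before min(registration end, data horizon). The
  data horizon extends 550 days past the study end so that late-study L-TOT
  episodes can still confirm a discontinuation; gaps that start before day
  365 or after day 729 never qualify, and censored gaps return no event
  rather than a guess.

Exclusions: methadone and sublingual buprenorphine issues are removed
before any phenotyping (dependence-treatment indication); transdermal
buprenorphine is a distinct product and retained. CNCP may be coded any
time before or up to 183 days after index; any non-NMSC cancer code in the
3650 days up to the index excludes the event, and a cancer code after
index censors follow-up.

## Drug preparation

The cleaning stage uses population-level imputation: missing or implausible
quantity/daily dose are replaced by the product-level median of plausible
observed values, falling back to the formulary's typical values when a
product has no usable records; every imputation is flagged and counted.
Plausibility defaults: quantity ∈ [1, 1000] units, daily dose ∈ (0, 24]
units/day, duration ∈ [1, 90] d. Supply days prefer an explicit plausible
duration and otherwise use ceil(quantity / daily dose), clamped to
[1, 90] — the clamp prevents data-entry outliers from fabricating months of
exposure. Daily MME = daily dose units × strength (mg) × per-product
conversion factor (morphine 1.0, codeine/dihydrocodeine/tramadol 0.1,
oxycodone 1.5, …); factors live in the product table, not in code. The
exact internals of published preparation algorithms are not public, so
these rules are this package's own, chosen to be order-preserving,
idempotent and fully unit-testable.

## Segmented interrupted-time-series model

Annual numerator counts are modelled with a log-link count regression and
offset ln(denominator):

    ln mu_y = b0 + b1*t + b2*I + b3*X + ln(D_y)

with t = y − first_year, I = 1{y > 2014}, X = (y − 2015)·I. Centering the
interaction at 2015 makes exp(b2) *exactly* the ratio of the fitted 2015
level to the 2009–2013 linear projection at 2015 (verified as an algebraic
identity in the tests), and exp(b3) the post/pre annual slope ratio. 2014
is excluded from the primary fit (partial-exposure year of the tramadol
rescheduling policy); the sensitivity fit retains it in the pre-break
segment (I = 1 strictly for years > 2014).

The primary family is NB2 negative binomial (variance μ + αμ²) with MLE
dispersion. Numerics: a Poisson fit supplies starting values; the NB
likelihood is maximised by Nelder–Mead and polished with BFGS, because
Newton steps diverge in α when a series is nearly equidispersed. If α̂
collapses below 1e-8, the dispersion SE is degenerate, or the NB fit fails,
the model falls back to Poisson and records the family used — at α → 0 the
two likelihoods coincide, so the fallback changes nothing but the label.
Confidence intervals are Wald on the log scale, exp(β ± z·SE); significance
is two-sided Wald p < 0.05.

The breakpoint scan is a likelihood-ratio scan: for each candidate year b,
2·(llᵦ − ll₀) of the segmented Poisson model against the single-trend
model, requiring ≥3 years on each side. Published UK analyses fixed the
break at 2014 from policy context and a structural-break analysis of a
longer (2000–2020) national series; on the 11-year packaged series alone
the scan's maximum sits at 2016, where the incident-user decline steepens —
the scan is a diagnostic, not the source of the 2014 break, which is fixed
a priori in the model specification.

## Synthetic generator: what it emulates and what it does not

The generator plants incident episodes as explicit templates so that the
truth is stored next to the data. Episode hazards follow a per-year
schedule calibrated to ≈1.25× the published annual incidence rates — the
inflation offsets the fact that patients inside an episode or its washout
are not at risk — so realized incidence falls in the published 14–23% band
at the default scale (~13k registered patients/year, ≈100× smaller than
the national database). An episode is L-TOT with probability 0.114 and,
if L-TOT, discontinues with probability 0.048 (the published headline
proportions); post-break step/slope multipliers are available for
model-structure experiments and default to 1 because the default hazard
schedule already encodes the observed trajectory.

Refill templates are deliberately unambiguous: L-TOT episodes issue 28-day
supplies every 28 days from day 0 (discontinuers stop so that the gap
starts on day 366 and confirms on day 545; persisters continue past day
730), and non-L-TOT episodes place at most two short supplies with at most
one issue in the evaluation window. Episodes are planted only where the
full pattern and confirmation window fit inside registration, and the
final refill of a discontinuer carries an explicit duration so injected
missingness cannot move the gap start. Missing and implausible values are
injected by masking after generation at configurable rates; product-level
medians restore the planted values exactly because each product's planted
quantity is constant. Formulary weights (≈81% weak opioids) put the
synthetic L-TOT cohort's mean daily dose near 20 MME mg/day.

Consequently, planted-truth tests demonstrate that the phenotyper
implements its definitions exactly — they do not demonstrate robustness to
real-data pathologies the generator omits: no true clinical coding
vocabularies, no dose tapering, no overlapping multi-product regimens
straddling window boundaries, no regional weighting, no informative
censoring, and post-index cancer censoring is exercised only in hand-built
unit tests. The oracle-agreement property test (randomised prescription
histories vs an exhaustive day-grid evaluator) covers the boundary
geometry the planted patterns avoid.

## Parameter-recovery simulation

Counts are simulated from the segmented NB model at the published
incident-user offsets with the published L-TOT coefficient magnitudes, and
refitted per replicate. The simulation dispersion is calibrated to what
the L-TOT series itself estimates (α ≈ 1e-6, i.e. near-equidispersion):
with only 10 retained annual observations, Wald intervals based on an MLE
dispersion are known to undercover substantially when the true dispersion
is large, and the observed series give no support for such a regime (all
three fitted α̂ ≤ 4e-4). At this calibration the measured 95%-CI coverage
of the pre-break trend is ≈0.95 over 500 replicates.

## Degenerate inputs and tie-breaks

Zero patients yields schema-complete empty tables; an empty prescription
list is classified not-L-TOT; censoring ties resolve by the fixed reason
order death > cancer > transfer > last collection > study end; numerators
exceeding denominators raise rather than silently clip; zero denominators
name the offending year. The annual registered denominator counts patients
registered ≥1 day in the year with ≥365 days of registration by year end —
one of several places (denominator definition, episode-vs-patient
counting, criterion-A span anchoring, weak/short-acting aggregation rule =
all first-year products) where the underlying reports are silent and this
package documents its own fixed choice.

## Problem sizes

Defaults are chosen so the whole pipeline is interactive: 16k patients
(~30k planted episodes) generate in ~3 s and phenotype in ~10 s; the
oracle-agreement check runs 10⁴ randomized instances and the coverage
simulation 500 replicates, each in well under a minute.
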