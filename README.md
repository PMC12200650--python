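# opioid-trends

Phenotyping and trend analysis of opioid utilisation in UK-primary-care-like
electronic health records, focused on **long-term opioid therapy (L-TOT)**
among people with **chronic non-cancer pain (CNCP)** and its subsequent
**discontinuation**.

The package is written for pharmacoepidemiologists who want a fully testable
implementation of this analysis without access-restricted data: every stage
runs against a built-in synthetic CPRD-Aurum-like generator that plants
ground-truth episode labels, and the statistical layer can additionally be
exercised directly on a packaged table of published annual counts (UK
primary care, 2009–2019).

## What it computes

1. **Drug preparation** — opioid prescription issues are cleaned
   (product-level median imputation of missing/implausible quantity and
   daily dose), supply days derived (explicit duration, else
   ceil(quantity/daily dose), clamped to 90), and daily doses converted to
   oral morphine milligram equivalents (MME). Methadone and sublingual
   buprenorphine are excluded (dependence-treatment indication).
2. **Cohort** — incident opioid users by the new-user design: an index date
   is an opioid issue with no opioid issue in the prior 365 days, in adults
   with ≥365 days of prior registration, a CNCP code any time before or ≤183
   days after index, and no non-NMSC cancer in the prior 10 years. Follow-up
   ends at the earliest of death, cancer, transfer, last collection, or
   31 Dec of the final study year.
3. **Phenotyping** — L-TOT: ≥3 issues within a 90-day span **or** ≥90
   supply-covered days, evaluated over days 30–364 after index.
   Discontinuation: an opioid-free gap of ≥180 days starting in days
   365–729, fully observable in the data. A brute-force day-grid oracle
   ships alongside the production classifier.
4. **Trends** — the three annual rate series (incident users / registered
   patients, L-TOT / incident, discontinuers / L-TOT) are fitted with
   segmented negative-binomial regressions with offset ln(denominator):

   ln μ_y = β0 + β1·t + β2·I + β3·X + ln(D_y),   t = y−2009,
   I = 1{y>2014}, X = (y−2015)·I

   so exp(β1) is the 2009–2013 annual rate ratio, exp(β2) the
   observed-vs-projected step at 2015 and exp(β3) the 2015–2019 slope change.
   The break year 2014 is excluded from the primary fit; sensitivity
   analyses keep it and/or use Poisson. A likelihood-ratio breakpoint scan
   and a pre-trend counterfactual projection are included.

## Worked example

```
$ python analysis/04_fit_trends.py
reference-count fits (IRR [95% CI]):
  incident       time         1.001 (0.988, 1.014)
  incident       indicator    0.988 (0.928, 1.052)
  incident       interaction  0.913 (0.897, 0.930) *
  ltot           time         0.974 (0.971, 0.978) *
  ltot           indicator    1.026 (1.009, 1.045) *
  ltot           interaction  1.024 (1.019, 1.030) *
  discontinuers  time         0.987 (0.972, 1.003)
  discontinuers  indicator    0.990 (0.916, 1.070)
  discontinuers  interaction  0.974 (0.951, 0.998) *
sensitivity, discontinuers with 2014 retained: exp(b1)=0.980
sensitivity, Poisson family: exp(b1)=0.987
```

Reading the L-TOT rows: among incident opioid users with CNCP, the rate of
transition to long-term therapy fell by 2.6% per year over 2009–2013
(IRR 0.974), stepped **up** by 2.6% in 2015 relative to the pre-trend
projection (1.026), and its slope flattened thereafter (slope-change IRR
1.024 against a 0.974 pre-trend ≈ no net decline) — while discontinuation
of long-term therapy, already rare, declined significantly faster after
2015 (0.974). Asterisks mark two-sided Wald p < 0.05.

The full synthetic pipeline is driven by the numbered scripts:

```
python analysis/01_simulate.py            # synthetic tables + planted truth
python analysis/02_phenotype.py           # cleaning -> cohort -> phenotypes
python analysis/03_covariates.py          # Table-1-style baseline summary
python analysis/04_fit_trends.py          # segmented ITS fits + figure
python analysis/05_parameter_recovery.py  # Wald-CI coverage simulation
```

or equivalently the `opioid-trends simulate|phenotype|trends|report` CLI.
On the default study conditions (~13k registered patients/year) the
phenotyper recovers the generator's planted episode labels exactly, and the
planted transition probabilities (11.4% L-TOT, 4.8% discontinuation) are
recovered within exact binomial bounds.

## Layout

```
src/opioid_trends/   library: synthetic, drug_prep, cohort, phenotyping,
                     covariates, its, pipeline, plotting, cli, datasets
analysis/            numbered narrative drivers (write under results/)
tests/               pytest suite incl. oracle-agreement and coverage checks
docs/methods.md      modelling and design notes
```
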