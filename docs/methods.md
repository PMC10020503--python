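# Methods

This note records the statistical model behind `herbsurv`, the design
choices made where the underlying study design leaves the details open,
and what the synthetic-data validation does and does not demonstrate.

## Study design being modelled

The pipeline reproduces the architecture of a retrospective claims-based
cohort study of CHM use in HIV/AIDS patients with neurological diseases:
subjects are identified from diagnosis claims, classified by exposure
(≥14 cumulative days of CHM in the year after neurological diagnosis),
matched 1:2 on a propensity score, and followed from an index date to
death or administrative censoring (2019-12-31). Mortality is analysed
overall and cause-specifically (infections/parasites and circulatory
deaths), and CHM co-prescription patterns are mined as association
rules over patient-day transactions.

## Case rules and the exclusion cascade

A diagnosis "counts" when the one-inpatient-or-three-outpatient rule is
met within a 365-day window; the onset is the first matched event date
whose forward window qualifies. Code matching is prefix-based at the
rubric level (a listed 3-digit code includes all sub-rubrics), the
convention of claims-database studies, because code lists mix 3-, 4- and
5-digit patterns. Exclusions apply in a fixed cascade — neurological
disease before HIV, missing age or sex, 1–13 cumulative CHM days, any
in-study malignancy (ICD-9 140–208) — and every excluded subject is
counted in exactly the first bin that applies, so bins are disjoint and
sum to identified-minus-retained. A patient whose cumulative CHM days
reach exactly 14 is treated as a user (the threshold is inclusive),
consistent with reading the below-14-days rule as the exclusion; the
threshold is configurable.

## Index dates and immortal time

A user's index date is the day after the prescription-day on which the
running cumulative CHM total first reaches 14 days (same-day rows
accumulate together). Non-users have no natural index date; granting
them follow-up from their neurological diagnosis would hand users
guaranteed survival over the exposure-accrual window (immortal-time
bias). The default is a landmark: non-user index = neurological
diagnosis date + the cohort median user lag (lower median of
index-minus-neuro-date over retained users), configurable to
`neuro_date` for comparison. Subjects who die on or before their
assigned index date are excluded defensively (`died_before_index` bin);
generated bundles never populate it because the generator draws
non-user death times from the identical landmark.

## Covariates

- **Charlson comorbidity index**: Quan's ICD-9-CM enumeration, shipped
  as an editable YAML file with the original Charlson weights and the
  usual severity hierarchy (complicated diabetes over diabetes,
  moderate/severe liver over mild, metastatic over solid tumour).
  V-codes are omitted because the code grammar is numeric rubrics only;
  the affected entries are rare facility/status codes. The comorbidity
  *number* groups (0 / 1–2 / ≥3) count distinct categories after the
  hierarchy; the *score* sums weights. Both are computed from diagnoses
  strictly before the HIV onset date.
- **Age** is banded (<30, 30–40, ≥40) at the neurological diagnosis
  date; the band boundaries are the ones the analysis stratifies on, and
  the reference date is a design choice (the study design does not pin
  it down).
- **ART exposure** is the per-class (NRTI, PI, NNRTI, INSTI, combined)
  sum of defined daily doses over the index duration (HIV onset to
  neurological diagnosis).
- **Opportunistic-infection flags** (six code lists) count any matching
  visit before the index date; configurable.
- **Cause of death** is mapped at ICD chapter level (both ICD-9 and
  ICD-10), with viral hepatitis/liver disease taking precedence over the
  enclosing infectious-disease chapter; anything unmatched, including
  unparseable codes, is `other`. The mapping is total by construction.

## Propensity model and matching

Exposure is modelled by maximum-likelihood logistic regression
(Newton–Raphson on internally standardised covariates; convergence when
the maximum score component falls below 1e-8, at most 50 iterations) on
female, age-band indicators, Charlson score, and index duration. Age
enters as band indicators because the analysis treats age as banded.
Matching is greedy nearest neighbour on logit(PS): users in seeded
random order, controls consumed without replacement, caliper
0.2·SD(logit PS) (the standard recommendation); users lacking k
in-caliper controls are dropped, which naturally reproduces
matched-cohort attrition. Alternatives (optimal matching, IPTW) are out
of scope.

## Survival machinery

Kaplan–Meier uses the product-limit form over distinct event times with
Greenwood's variance; subjects censored exactly at an event time remain
at risk at that time. The log-rank test is the standard two-group
statistic with hypergeometric variance, referred to χ²(1). The Cox
model maximises the partial likelihood by Newton–Raphson with
step-halving; Efron's tie correction is the default (Breslow optional;
the two coincide on tie-free data). Convergence requires the maximum
score component below 1e-9 (at most 60 iterations); covariates are
standardised internally and estimates mapped back. Confidence intervals
are Wald at the fixed 95% level (normal quantile 1.959964). Matched-set
correlation is ignored in the default fit, matching how such studies
report plain Cox models after matching.

The cause-specific analysis follows the source design literally:
deaths from the selected categories are events, censored subjects stay
censored, and deaths from any *other* category are **removed from the
analysis set** — not censored. This is not a competing-risks analysis;
a Fine–Gray subdistribution model is deliberately out of scope, and the
removal design overstates survival relative to cumulative-incidence
methods. It is implemented this way because it is the design being
reproduced.

## Synthetic claims generator

The generator is the package's validation instrument. Per patient it
draws demographics, an HIV onset uniform over 2010–2017 (with claims
emitted to satisfy or deliberately fail the visit rule), a neurological
diagnosis with probability 0.5 at a lognormal lag matched to mean 786 /
SD 804 days (a distributional assumption; only the first two moments are
anchored), a Charlson group (0.77/0.18/0.05), CHM exposure with mild
planted confounding (odds multiplied by 1.0/0.65/0.45 across age bands
and 1.0/1.35/1.6 across Charlson groups), a cumulative-CHM-days target
(15% below the 14-day threshold, otherwise 14 + a lognormal body capped
at 150), and a death time from an exponential proportional-hazards law
with baseline 2·10⁻⁴ events/person-day and true log hazard ratios
ln 0.30 (CHM), ln 1.26 / ln 3.79 (age bands), ln 2.80 (female), ln 1.38 /
ln 1.91 (Charlson groups). Death cause categories are drawn so that
roughly half of deaths are infections/parasites or circulatory.
Randomness is organised as one master seed with per-patient substreams
(`default_rng([seed, stream, i])`), so enlarging the bundle never
perturbs earlier patients' claims; the only cohort-level coupling is the
non-user landmark (a median over users), recomputed per bundle.

Exclusion traffic defaults (2% failing the HIV visit rule, 3%
neuro-before-HIV, 0.2% missing demographics, 15% of CHM-exposed below
threshold, 1% malignancy) keep every exclusion bin non-empty while
leaving a cohort of roughly 45% of patients, large enough that a
20,000-patient draw supports tight parameter-recovery checks
(≈2,250 matched users, ≈2,000 events). The baseline hazard was chosen
once to give realistic multi-year mortality in this population with
enough events for those checks.

**Transactions.** CHM dispensings are drawn per patient-day. The product
catalog mirrors a published prescription-frequency table (eleven named
herbs/formulas with per-transaction propensities equal to published
frequency/7,376) plus twelve anonymous background formulas for the
market's long tail. Planted pairs (the five published rules, with their
published lifts as co-occurrence boosts) enter through a joint-inclusion
probability solved by fixed point so the pair's overall joint
probability equals boost·pₓ·p_y; remaining marginal mass is drawn
independently, and a transaction that draws empty is padded with one
background product so transactions are never empty while named-product
marginals and planted lifts stay at their configured values. With
several pairs sharing a product the fixed point is solved under an
independence approximation across mechanisms; the induced error is well
inside sampling noise at the tested scales. A boost of 1 reduces
exactly to independence.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the pipeline recovers *known* structure:
planted exclusion counts bin-for-bin, planted co-occurrence boosts as
empirical lifts, the planted conditional hazard ratio after matching
and adjustment, and calibrated error rates (log-rank type-I within
[0.04, 0.06]; adjusted log-HR bias below 0.03). They do not demonstrate
robustness to features real claims have and the generator lacks:
miscoded or rule-out diagnoses, exposure misclassification, hazards
that vary over calendar time or violate proportionality, informative
censoring, clustered care-seeking, or unmeasured confounding. The
generator's confounding is mild and fully captured by the matching
covariates by construction; real confounding need not be.

## Numerical conventions

Percentages and lifts are rendered half-up to two decimals; dosages
(mean daily dose × mean duration × prescription count) to whole grams;
p-values to three decimals with a `<0.001` floor. Rule ranking breaks
ties by support, then lift, then lexicographic order; rule orientation
puts the smaller-marginal product on the left (maximising confidence),
with lexicographic tie-break. Network clusters are connected components
(community detection is unnecessary at these sizes), numbered by
decreasing size. Degenerate inputs raise typed errors (configuration /
data / numerical) that the CLI maps to exit codes 2/3/4.

## Problem sizes used in validation

The bundled checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances they assert: 50,000–60,000 transactions for
lift recovery (±0.3), 20,000 patients for hazard-ratio recovery
(tolerance band [0.25, 0.36] around the true 0.30), 2,000 replicates
for test calibration, and 100 replicates of n=5,000 for bias. Fixtures
for oracle-equivalence checks use 200–500 rows, where exact agreement
with reference implementations is meaningful and fast.
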