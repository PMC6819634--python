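# Methods

## The problem

A lifetime ("have you **ever** …") yes/no survey item should never move
from YES to NO across repeated administrations. When it does, at least one
answer was wrong. This package analyses that phenomenon for the
intimate-partner-violence (IPV) item asked of a six-wave women's cohort
(waves labelled 1996, 2004, 2007, 2010, 2013, 2016; the source study's
surveys 1, 4, 5, 6, 7, 8): it classifies each woman's answered sequence
into consistency classes, relates class membership to longitudinal
covariates, and provides a generative model that makes the implied
measurement-error mechanism explicit and testable.

## Consistency classification

Eligibility requires an answer to the IPV item at wave 1 and at least two
of waves 2–6 (hence ≥ 3 answers). Writing r for the answered subsequence,
n = |r|, y = #YES, and calling a YES followed by a later NO a *drop*:

| class | rule |
|---|---|
| Consistent IPV | no drop, y = n |
| Consistent later IPV | no drop, 0 < y < n (a NO-block then a YES-block) |
| Consistent never IPV | no drop, y = 0 |
| Mainly IPV | drop, y = n − 1 |
| Mainly no IPV | drop, y = 1 |
| Mixed IPV | drop, otherwise |

Three reading choices were genuinely open and are resolved as follows:

* **Monotone precedence.** NYY has exactly one NO but contains no drop, so
  it is Consistent later IPV, never Mainly IPV. This is required for the
  canonical examples (NYY vs YNY/YYN) to be coherent.
* **YYN.** The source's example lists place YYN under both the
  single-discrepancy and the mixed headings; we classify it by the
  exactly-one-NO rule (Mainly IPV) and treat the second listing as a typo.
* **One-directional multi-discrepancy sequences** such as YYNN (two YES,
  two NO, no alternation) fall to Mixed IPV: the named single-discrepancy
  classes require exactly one minority answer, and Mixed is the residual.

Under these rules the six classes partition every fully-answered string;
`enumerate_class_counts` verifies this exhaustively for n = 3..6 against
the closed forms (1, n−1, 1, n−1, n−1, 2ⁿ−3n+1). Mixed requires at least
two YES and two NO, hence at least four answers — the structural 0.0 in the
three-answer row of the answered-count table.

Percentages follow the printed convention: one decimal, rounded half-up
(587/10,966 → 5.4; the abstract's 5.3 for the same count is a truncation we
do not follow). Within-inconsistent shares are whole percentages.

## Derived covariates

* **Relationship trajectory** (never / remained / became-partnered /
  became-separated-or-divorced) uses the first and last non-missing status
  plus an ever-separated/divorced flag. Multi-transition histories resolve
  by endpoints; widowed and single count as "not separated/divorced", and
  "became partnered" means exiting separated/divorced status regardless of
  the destination state. The full truth table is in the data dictionary.
* **Stress over time**: highly stressed at ≥ half (inclusive tie) of the
  waves where the item was answered; the denominator is the item's own
  non-missing count, the stricter reading of "completed surveys".
* **Design weight**: rural and remote strata were deliberately sampled at
  twice the urban rate, so major-city records weigh 1.0 and all other
  strata 0.5 (configurable). Weights enter descriptive percentages only —
  they are scale-invariant there — while the regression is unweighted by
  default, matching the published tables; a weight vector can be supplied.

## Regression

Baseline-category multinomial logit with Consistent IPV as the reference
outcome, dummy-coded covariates with the published reference levels, Wald
95% CIs on the log-odds scale (z = 1.959964), complete-case records only
(dropped counts reported). The unweighted fit is delegated to statsmodels'
`MNLogit` (Newton, gradient tolerance 1e-8, max 200 iterations); the
weighted variant is an in-package Newton–Raphson on the weighted
likelihood with analytic gradient and observed information, step-halved to
keep the likelihood monotone, and shown in tests to agree with statsmodels
at unit weights. Covariate levels with zero cells against any outcome are
reported, never silently dropped; levels entirely absent from the data are
excluded from the numeric fit and returned with NaN coefficients. The 0.05
significance threshold only annotates the output table. The sensitivity
model refits on women who answered all six waves, with the survey-count
covariate removed.

The published odds-ratio tables come from access-restricted data and are
not reproduction targets; the regression machinery is instead validated by
(i) a saturated two-class fit equalling the contingency-table cross-product
ratio, (ii) collapse to binary logistic regression, (iii) CI coverage of
coefficients injected into simulated outcomes, and (iv) null-covariate
coverage of OR = 1. Within one dataset the five contrasts share the
reference-class count, so their estimates co-move; coverage statements are
therefore pooled over replicate datasets.

## Synthetic cohort

The generator encodes the mechanism the consistency analysis presumes:

* **Truth is absorbing.** A woman either never experiences IPV or has an
  onset wave (0 = before wave 1; mass on later waves decays
  geometrically). "Ever" can never become false, so *every* observed drop
  is a reporting error.
* **Reporting error.** At each answered wave she reports YES with
  probability 1 − fn if her history is positive, else with probability fp.
* **Attrition** mixes monotone dropout (waves 1..k) with intermittent
  skipping (wave 1 plus a uniform random subset), weight 0.55 monotone;
  the answered-count margins default to the published 8.5/10.7/15.7/65.1
  split of eligible women, with ~19.9% ineligible mass (wave-1-only 69%,
  wave-1 + one later wave, or wave-1 missing). Ineligibility odds are
  tilted ×1.6 for ever-IPV women, which reproduces the observed pattern of
  higher wave-1 prevalence among excluded women (≈19% vs ≈14% at the
  defaults) without forcing those margins.
* **Covariates.** A binary latent stress propensity S (5% among
  never-IPV, 25% among ever-IPV women) drives the per-wave partner-stress
  items and shifts fn, fp and dropout on the logit scale; income stress and
  relationship-trajectory types depend on the latent IPV state directly.
  This is the minimal mechanism that induces realistic covariate-by-class
  tables (e.g. the consistent-never column showing the highest
  never-separated/divorced share).

`exact_class_distribution` marginalises the model exactly — latent state
(ever × onset × S) × answered-wave pattern × response string, conditioned
on eligibility — in a few milliseconds, so simulator output can be tested
against exact probabilities at three binomial standard errors rather than
against itself.

**Cross-sectional bias** is defined as P(YES | answered wave w) − P(true
lifetime IPV to date | answered wave w). Conditioning *both* terms on
answering the wave isolates measurement error from attrition-driven
selection, which is what makes the error-free model's bias exactly zero at
every wave; with the calibrated rates the single-wave estimate understates
true lifetime-to-date prevalence by about 2 percentage points at every
wave.

**Calibration.** `calibrate_error_rates` grid-searches (fp, fn, prevalence,
pre-study onset share) and refines by Nelder–Mead on logit-transformed
parameters, minimising squared percentage-point distance between the exact
distribution and a target six-class table. The shipped `paper_like` preset
was calibrated against the published percentages
(7.5/3.2/76.9/2.4/5.4/4.7) with the stress-subgroup shifts fixed at
β_fn = 2.5, β_fp = 1.5: base rates fp ≈ 0.012, fn ≈ 0.085 (the high-stress
subgroup carries fn ≈ 0.5), prevalence ≈ 0.19, achieved squared distance
2.17 (largest single-cell error ≈ 1.1 pp, on the Mixed class — a
two-parameter error model cannot fully reproduce Mixed exceeding Mainly
IPV). These values are *illustrative*: the real data cannot identify its
error rates, and nothing here estimates them. The `null_model` preset sets
fp = fn = 0.

Default seed 20191029; the same (params, seed) pair yields a bit-identical
cohort.

## What the synthetic cohort does and does not show

It emulates: lifetime-item semantics, the two error types, realistic
attrition margins and their correlation with IPV, covariate–class
associations of the observed sign. It does not model: true IPV cessation
or recall windows, intentional over-/under-reporting motives, informative
nonresponse beyond the declared effects, or the sampling frame. Passing
tests therefore demonstrate the pipeline's correctness and the internal
coherence of the error-model interpretation — not that the calibrated
rates describe the real cohort.

## Problem sizes and numerics

Oracle-equivalence runs use cohorts of 100,000 (acceptance) and 12,000 to
30,000 (tests); parameter recovery uses 100 replicates of n = 5,000; the
worked example simulates 20,000 women. Newton convergence is declared at
gradient max-norm 1e-8; probabilities of 0 or 1 are left fixed by logit
shifts (no error mass is created where none was specified); class
probabilities in the fit are clipped at 1e-300 before logs. Degenerate
inputs (empty cohorts, all-missing covariate vectors, empty six-wave
subsets, absent reference outcome) raise explicit errors; classification
itself is a total function.
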