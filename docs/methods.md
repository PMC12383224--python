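# Methods

## Measurement models

**Battery and recoding.** The battery is the standard 2×2 set: norm
(prohibited / favors action) × consequences (benefits outweigh costs or
not), six stories per cell, 24 scenarios, presented in a pre-randomized
order in which adjacent scenarios never share a story.  Cells are coded PB,
PC, AB, AC (norm first, consequences second).  "Norm-allowed" is treated as
a prescriptive norm — the norm favors acting — which is how the standard
scenario set is constructed; under a merely permissive reading the AB/AC
contrasts would not identify norm sensitivity.  Ratings are collected on a
1–6 acceptability scale; the dichotomized analyses recode 4–6 as approval
and 1–3 as disapproval.

**Process dissociation.** With two observations (rejection rates of the
congruent PC and incongruent PB cells) and two parameters, the inversion
`U = r_cong − r_incong`, `D = r_incong / (1 − U)` is exact: the forward
model reproduces both inputs to machine precision, which the test suite
verifies property-wise.  `U = 1` leaves D undefined; the estimate is
flagged rather than dropped silently.  Norm-allowed cells play no role in
PD by construction.

**CNI tree.** The sequential tree (consequences → norms → generalized
action preference) gives four cell action probabilities with three
parameters, hence one residual degree of freedom.  Estimation is
product-binomial maximum likelihood over [0,1]³.  When the observed
proportions satisfy the tree's single cell constraint
(`p_AB − p_PB = p_AC − p_PC`) and the algebraic inverse lands inside the
cube, that inverse is the saturated MLE and G² = 0 exactly; otherwise
L-BFGS-B (analytic gradient, probabilities clipped to [1e−9, 1−1e−9])
is run from the clamped algebraic initializer plus 20 seeded uniform
restarts, convergence tolerance 1e−12 on the objective.  An acceptance-
suite oracle verifies the returned likelihood is never below an exhaustive
0.005-step grid search.  G² is referred to χ²(1); participants with
p < .05 are flagged for exclusion from CNI-level correlations.  The
exclusion direction is implemented as *small* p = misfit (a
goodness-of-fit test rejects when the model fits poorly), and boundary
estimates (within 1e−6 of 0/1) are flagged, with parameters downstream of
a saturating branch (N, I when C ≈ 1; I when N ≈ 1) marked unidentified
rather than excluded.

**CAN decomposition.** Linear contrasts of the four cell values on either
scale.  Continuous CAN operates in raw rating units (A near the 3.5
midpoint for neutral responding) with no renormalization, so its values are
directly comparable to published continuous-scale summaries.  For
noise-free tree data the bridge identities `C_can = C`,
`N_can = (1−C)·N`, `A_can = C/2 + (1−C)N/2 + (1−C)(1−N)(1−I)` hold exactly
(checked on an 11³ grid).

## Association statistics

Partial correlation residualizes both variables on an intercept plus
covariates by least squares and correlates the residuals;
`df = n − 2 − k`.  Gender enters as a 0/1 indicator (direction irrelevant
to |r|).  Powers: t-tests use the noncentral-t distribution, two-tailed by
default; correlations use the Fisher-z approximation with
`SE = 1/√(n − k − 3)`, one-tailed by default.  These tail conventions are
the ones that reproduce the published power values from their printed
inputs (0.87 for d = 0.44 at n = 92/105; 1.00 for d = 0.52 at n = 208;
0.40 for r = 0.10 at n = 197 with one covariate); both are exposed as
flags.  The pooled-SD group d computed from two-decimal printed summaries
(0.47 ± 0.14 vs. 0.41 ± 0.14) is 0.43; the published 0.44 evidently came
from unrounded summaries, and tests assert the value derivable from the
printed inputs.  All comparisons against published values are made after
rounding to two decimals, the published reporting precision.

## Synthetic cohorts

The generator emulates the replication cohort: n = 208; PSS-10 totals
`round(clip(12.15 + 6.84·stress, 0, 40))` with latent stress ~ N(0,1),
decomposed into item scores that sum exactly to the total (greedy even
spread, remainder on early items; reverse-keyed items inverted for storage
so instrument scoring recovers the total); age 32.07 ± 12.35 clipped to
17–89; 56.7% female.  Demographics are realism only — nothing downstream
depends on them.  True decision parameters are inverse-logit Gaussians,
means logit(0.20)/logit(0.25)/logit(0.41) for C/N/I (echoing the reported
cohort means), SD 0.5 logits, plus `coupling·stress` on the logit scale;
coupling defaults to zero, the null regime in which chronic stress has no
effect on moral decision parameters.

Binary responses are Bernoulli draws from the participant's tree cell
probabilities.  Likert responses use a probit-latent threshold model:
`latent = Φ⁻¹(p_cell) + N(0, σ)`, cut at five thresholds
(−1.8, −0.8, 0, 0.8, 1.8).  The middle cutpoint is 0, so recoding at the
3/4 boundary accepts with probability `Φ(Φ⁻¹(p)/σ)` — exactly `p` at the
default σ = 1.  This makes dichotomization exactly calibrated to the
binary tree, a deliberate choice: the dichotomization study then isolates
the information loss of recoding itself, not a miscalibration artifact.
What the generator does **not** emulate: story-level difficulty effects,
response times, acute-stress dynamics, or any non-tree response process —
so passing tests show internal consistency of the estimators and
calibration of the tests under the assumed model, not validity on real
respondents.

## Replicate-level studies

**Dichotomization Type-I study.** Each replicate simulates one Likert
cohort under null coupling, scores it both ways (recoded CAN vs.
continuous CAN — identical underlying cohorts, isolating the scoring
rule), and tests the gender-adjusted stress–parameter partial correlations
at α = .05.  The study uses a vectorized sampling path built on the same
tree and contrast code as the estimators so 2000 replicates run in
seconds.  Reported: per-arm, per-parameter rejection rates with binomial
Monte-Carlo standard errors; the acceptance suite checks that the
continuous arm is calibrated (0.05 ± 2·SE) and that the dichotomized arm
does not reject less often beyond Monte-Carlo error, and that null
p-values are uniform (KS at α = .01).

**Recovery study.** Replicates draw binomial cell counts for a single
respondent at fixed true (C, N, I) = (0.2, 0.25, 0.4) and battery sizes 6,
24, 96 items per category (500 replicates each in the acceptance suite).
CNI truths are the generator values; CAN truths the bridge values.
Checks: |bias| < 0.02 for all CNI parameters at 96 items, RMSE strictly
decreasing in battery size.

## Numerical and design notes

* PSS-10 reverse-keyed items default to positions {4,5,7,8}; PSS-14 to
  {4,5,6,7,9,10,13} (standard instrument keying); both configurable.  The
  13-item social-desirability key is fully configurable with no default
  claimed as the instrument's true key; the simulator defines its own.
* Median-split ties go to the low group (deterministic, documented); the
  split is provided to reproduce the practice the analyses critique, and
  degenerates (all scores equal) raise rather than split arbitrarily.
* Screening applies rules in a fixed order — acute stress, attention
  check, incomplete battery — logging one reason per exclusion; incomplete
  cases are excluded listwise (no imputation).
* Cronbach's α is provided as a one-line descriptive only.
* `cni_invert` verifies feasibility by forward evaluation, not range
  checks alone: quadruples violating the tree's cell constraint (e.g.,
  (1, 0, 0, 1)) are reported infeasible even when the raw contrast
  formulas land inside [0, 1].
* Run seeds split into per-stage child streams (numpy `SeedSequence`
  spawning), so participant draws, binary sampling, and Likert sampling
  are individually reproducible; identical configs give byte-identical
  datasets.
* Problem sizes for the replicate studies (2000 Type-I replicates at
  n = 208; 500 recovery replicates per battery size; 50 grid-oracle
  fixtures at step 0.005) are the package's standard settings and match
  what the test suite runs.

## Known limitations

Only the three CAN parameters shared with the CNI literature (C, A, N) are
computed; richer published extensions of the algebraic approach are out of
scope.  No hierarchical/Bayesian tree estimation, no tree-order variants,
no multiple-testing correction (none is applied in the analyses being
mirrored), and no loader for the original study's deposited data — the
pipeline accepts any dataset in the documented CSV dialect, but shipped
analyses run on synthetic cohorts.  With 6 items per category the
individual-level CNI estimates are noisy and frequently saturated or at
the boundary; cohort-level conclusions are the supported use.
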