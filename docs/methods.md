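# Methods

## The instrument and its codings

The Nine-Questions Depression-Rating Scale (9Q) asks, for each of nine
depressive symptoms over the previous two weeks, an intensity (0 none, 1
mild, 2 moderate, 3 severe) and — when the symptom is present — a frequency
(1 several days, 2 more than a week, 3 nearly every day). Classical scoring
multiplies the two codes per item and sums, giving a 0–81 total. The product
takes exactly seven values {0, 1, 2, 3, 4, 6, 9}; for model fitting these are
relabelled with the ordinal categories 0–6.

The product is lossy: mild-nearly-every-day (1×3) and
severe-for-several-days (3×1) both score 3. The package therefore also
carries a *nominal* coding with ten combination labels {0, 11, 12, 13, 21,
22, 23, 31, 32, 33} (tens digit intensity, units digit frequency) that keeps
such pairs distinct. The labels carry no ordering.

## Models

Both models relate a respondent's latent severity θ to their category
probabilities, assuming unidimensionality and conditional independence of
items given θ.

**Graded-response model (GRM)**, for the ordinal product categories. Item *i*
has a discrimination *a_i* > 0 and strictly increasing thresholds
*b_i1* < … < *b_i6*. With σ the logistic function,

    P(X_i ≥ k | θ) = σ(a_i (θ − b_ik)),
    P(X_i = k | θ) = σ(a_i (θ − b_ik)) − σ(a_i (θ − b_i,k+1)),

with b_i0 = −∞ and b_i7 = +∞. The threshold b_ik is the severity at which
endorsing category k or higher becomes even odds.

**Nominal-response model (NRM)**, for the combination labels. Each category
*sf* of item *i* has a slope *a_i(sf)* and intercept *c_i(sf)* and

    P(X_i = sf | θ) = exp(a_i(sf) θ + c_i(sf)) / Σ_m exp(a_i(m) θ + c_i(m)).

The no-symptom category 0 is the reference, fixed at a = c = 0; the softmax
is otherwise invariant to adding constants, so some pin is required. If
category 0 is never observed in a fitting scope the first observed category
is pinned instead and slot 0 stays NaN.

## Estimation

Parameters are estimated by marginal maximum likelihood: θ is integrated out
against a fixed N(0,1) prior (the identification choice; the prior's mean
and variance are not re-estimated). The integral is approximated on a
quadrature grid — by default 61 equally spaced nodes on [−6, 6] with
normal-density weights renormalised to sum to one. Tests and simulations in
this repository often use coarser grids (31–41 nodes on [−5, 5.5]);
likelihood differences between such grids are far below every decision
threshold used (the suite checks 49-node vs 201-node agreement at 1e-6).

The EM loop: the E-step computes each respondent's posterior weights over
the grid nodes and accumulates expected per-category counts per item; the
M-step maximises each item's expected complete-data log-likelihood with
L-BFGS-B and analytic gradients. GRM thresholds are optimised through the
order-preserving map b₁ = t₁, b_k = b_{k−1} + exp(t_k), so ordering can
never be violated; the M-step is capped (40 inner iterations) which keeps
every step an ascent (generalised EM), and the observed marginal
log-likelihood is monotone along the trace (asserted to 1e-8 slack in the
suite). Convergence requires |Δ loglik| < 1e-6 and max |Δ parameter| < 1e-4
within 500 iterations (tests use 1e-5/300 where speed matters);
non-convergence flags the result rather than raising.

Starting values come from empirical category proportions: GRM slopes start
at 1 with thresholds at −logit of the cumulative endorsement rates; NRM
intercepts start at log count ratios with slopes spread ±0.5 by category
order. Discriminations are bounded in magnitude by 30 — the published 9QSF
calibration contains slopes up to ≈22.6, so the cap must sit above that —
and a fit touching the cap warns, naming the item (sparse categories are the
usual cause).

Categories never observed in a fitting scope are collapsed out of that
scope's likelihood and exported as NaN. On re-use (scoring, EAP, item fit) a
NaN threshold bands the category with its nearest estimated neighbour below;
NaN NRM cells are either filled by the substitution rule (below) or rejected
if a response actually lands there.

EAP severity estimates are posterior means on the grid; AIC/BIC use their
defining formulas (−2ℓ + 2p and −2ℓ + p ln N).

## Gender DIF

An item functions differentially when men and women at the same θ respond
with different probabilities. Each item is tested with every other item
anchored (constrained equal across genders) through a nested chain:

* all shared (baseline) ⊂ slope shared, thresholds/intercepts gender-free
  ⊂ everything gender-free.

Uniform DIF (a location shift — confounding) is the LRT of the middle model
against the baseline; non-uniform DIF (a slope difference — effect
modification) is the LRT of the free model against the middle one. Items are
flagged at raw p < 0.05 per convention; a Benjamini–Hochberg option exists
but is off by default. No iterative anchor purification is attempted. Warm
starts (each model initialised from its constrained neighbour) keep the
nine-item scan fast without affecting the optima.

The DIF-adjusted parameter set refits jointly with gender-specific
*thresholds* (slope shared) for flagged GRM items, and fully gender-specific
slopes and intercepts for flagged NRM items; non-flagged items stay shared.

**Finite-sample caveat.** The LRT's chi-square reference assumes adequately
filled cells. With the 9Q's heavily skewed endorsements, the top categories
of the smaller (male) stratum can hold 0–3 respondents at realistic sample
sizes, and the uniform-DIF test then over-rejects: in our simulations the
type-I error at α = 0.05 was ≈0.07 for item 2 at n = 1,000 but ≈0.21 at
n = 500, and ≈0.16 for the sparse item 5 even at n = 1,000. The operating
characteristics asserted in the acceptance suite therefore use item 2 — the
instrument's canonical DIF item — at n = 1,000. DIF conclusions for
sparse-celled items at small n should be treated with caution.

### Sparse-cell substitution (NRM)

Per-gender NRM fits leave cells with no endorsements unestimated. The
completion rule: copy the other gender's estimated value when it exists
(provenance tag `other-gender`); when a cell is empty for both genders, copy
the previous frequency at the same intensity (tag `previous-frequency`),
resolving in ascending frequency order so runs of empty cells inherit
transitively. Category 0 is never substituted. A frequency-1 cell empty in
both genders has no source: the strict mode raises, while the adjusted-fit
path leaves it NaN with a warning — a category that no respondent ever
endorses needs no weight, and the scorer rejects any later response landing
in it. Substitution is only applied to the gender-specific (DIF) items;
shared items are estimated from the pooled sample and have no gender-wise
gaps.

## Weighted scoring

The GRM weighted score treats the discrimination as the item weight and the
endorsed category's threshold as the category weight:

    raw_j = Σ_i a_i · b_i,k(i,j)   (0 when category 0 is endorsed),
    score_j = 81 · raw_j / Σ_i a_i · b_i6.

The denominator is the *plausible maximum* — the raw score of a respondent
endorsing every top category — so the weighted scale shares the anchors 0
and 81 with the unweighted total. A respondent-specific denominator would
collapse every score to the unit interval's endpoints, so the constant
maximum is the only coherent reading. With DIF-adjusted parameters both
numerator and denominator resolve through the respondent's own gender, so
each gender spans exactly [0, 81]; a pooled common denominator is available
behind a config switch.

The NRM weighted score uses a_i(sf) + c_i(sf) as the weight of endorsed
category *sf* (0 for the reference) and the sum of per-item maxima as the
plausible maximum. Two consequences are reported rather than hidden. First,
weights can be negative (the published calibration contains a = −0.121 and
c = −46.399), so raw and rescaled NRM scores may fall below 0; nothing is
clamped and out-of-range rows are flagged. Second, the weight depends on the
softmax pin: under the reference-0 identification, a + c is the log-odds of
the category against "no symptoms" at θ = 1, which is *negative* for every
category whenever no-symptom responses still dominate at θ = 1. Fitting the
NRM to cohorts generated from the GRM calibration lands in exactly that
regime — every weight negative, the plausible maximum 0 — and the scorer
raises on such a degenerate maximum (the pipeline skips the method with a
warning). The published 9QSF calibration, taken as given, lies in the
opposite regime and scores cleanly. This fragility of slope-plus-intercept
weighting is a genuine property of the scheme, not an implementation
artefact, and is the reason the nominal-model variant should be read as the
secondary method.

## Evaluation

Scores are compared across the clinician-style severity groups with a
one-way fixed-effects ANOVA (overall) and equal-variance two-group F
statistics (pairwise; identically the squared independent-samples t — the
suite verifies the identity against scipy at 1e-10). Relative precision is
the ratio of a method's F to the unweighted reference's F for the same
comparison; RP > 1 means sharper severity separation, and RP is invariant to
affine rescaling of a method's scores. Overall ANOVA p-values are reported
raw and Bonferroni-adjusted with m = 6 (the number of pairwise severity
comparisons). Welch pairwise tests are available behind a flag but are not
the default, matching the equal-variance F convention of the evaluation
table.

## Synthetic cohorts

The generator emulates the study conditions: cohort size 1,355 (split
1000/355 into developmental/validation by gender-stratified sampling),
female fraction 0.679, θ ~ N(0,1), and severity labels cut at fixed θ
quantiles (1.041, 1.538, 2.005) that reproduce the validation cohort's
none/mild/moderate/severe composition 302/31/14/8 in expectation. Generating
parameters default to the published calibrations shipped with the package.
Uniform DIF is injected as additive threshold shifts for one gender; the
NRM generator can force chosen cells empty (draws demote to the previous
frequency) to exercise the substitution rule. All draws are
`numpy.random.default_rng(seed)`-deterministic, and generated cohorts
round-trip through the response CSV schema unchanged.

What the generator does *not* emulate: real severity labels come from
clinical assessment, not θ cuts, so label noise is absent; there is no
multidimensionality, no local dependence, no age structure, and no
item-level missingness beyond whole-record incompleteness. Passing tests
demonstrate internal consistency of the machinery under the stated models,
not clinical validity on real cohorts.

## Problem sizes used by the test-suite

Parameter-recovery checks fit one n = 2,000 cohort; the DIF
operating-characteristics check runs 200 null and 40 shifted replicates at
n = 1,000 on a 31-node grid; the item-fit calibration uses 40 replicates at
n = 2,000 evaluated at the generating parameters (no refit). These sizes
give comfortable margins on every asserted bound while keeping the full
suite in the tens of minutes on one CPU.

## Known limitations

* The chi2W-style item-fit statistic is this package's own df = 1
  construction: a linear-trend Wald contrast of observed minus
  posterior-expected item scores across deciles of the rest-score EAP
  (excluding the tested item makes the residual exactly mean-zero under the
  fitted model, and the trend contrast targets slope misfit). Published
  per-item values from other implementations are reproduced only in the
  df = 1 tail-consistency sense, not numerically.
* The single-factor CFA treats ordinal item scores as continuous with an ML
  discrepancy on the Pearson covariance matrix; polychoric estimation is out
  of scope.
* IRT-LR DIF p-values are anti-conservative for sparse-celled items at
  moderate n (see the caveat above).
* The NRM weighted score inherits the identification fragility described
  under *Weighted scoring*.
* No Bayesian estimation, no multidimensional traits, no anchor
  purification, no clinical cut-points.
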