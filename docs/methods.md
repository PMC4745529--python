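# Methods

## Measurement model

Responses form a households × items 0/1 matrix X. The dichotomous Rasch
model puts

    logit P(X_vi = 1) = theta_v − eta_i = theta_v + beta_i,

with household ability `theta_v` (higher = more food secure) and item
difficulty `eta_i`; the package stores easiness `beta_i = −eta_i` internally
and derives difficulty on report, so the two conventions are exactly
negatives of each other and share standard errors. Assumptions inherited
from the model: a unidimensional trait, local independence of items given
the trait, and equal item discrimination. No covariates enter the model.

## Item calibration (CML)

The raw score `r_v = Σ_i X_vi` is sufficient for `theta_v`. Conditioning on
it gives the conditional log-likelihood

    l(beta) = Σ_i s_i beta_i − Σ_r n_r log gamma_r(exp(beta)),

with item totals `s_i` and score frequencies `n_r` taken over non-extreme
households only — patterns with r = 0 or r = k have conditional probability
one and carry no item information, so they are excluded from calibration and
their counts logged. `gamma_r` is the order-r elementary symmetric function
(ESF) of `eps_i = exp(beta_i)`.

The location of `beta` is not identified (l is shift-invariant), so the
scale origin is fixed by Σ beta_i = 0 and the optimization runs in the
orthonormal Helmert basis of that subspace: a damped Newton iteration with
the analytic gradient `s_i − Σ_r n_r eps_i gamma_{r−1}^{(i)}/gamma_r` and
the observed-information Hessian built from singly- and pairwise-excluded
ESFs. Standard errors come from the inverse information projected onto the
sum-zero subspace.

Numerical choices:

- **ESFs in log space.** The summation recursion
  `gamma_r ← gamma_r + eps·gamma_{r−1}` is carried out with `logaddexp`,
  which is stable for |beta| far beyond survey scales (hundreds of logits);
  the cancelling difference recursion is never used, at any derivative
  order. Leave-one-out and leave-two-out ESFs are recomputed by the same
  recursion (O(k²)–O(k³) work, negligible at k = 18).
- **Convergence** at projected-gradient norm 1e-6 (the score equations hold
  to that accuracy). The backtracking line search accepts any step that does
  not lower the likelihood by more than ~1e-9·|l| — near the optimum the
  true gain falls below float64 resolution of l, and demanding a measurable
  increase would block the final (tiny) Newton steps.
- Items affirmed by no or by all non-extreme households have no finite
  estimate and raise an explicit error listing the item ids; starting point
  is beta = 0; typical fits converge in 4–7 iterations.

## Person measurement and classification

Raw-score sufficiency means every household with the same score gets the
same ability: for 0 < r < k, `theta_r` solves the monotone score equation
`Σ_i expit(theta + beta_i) = r` (bracketed Brent iteration, |residual| <
1e-8), with SE `1/sqrt(Σ_i P_i(1−P_i))`. Extreme scores have no finite ML
estimate; the default policy excludes those households from ability
statistics (their counts are preserved in the classification bookkeeping),
and an optional `half_adjust` policy scores them at r = 0.5 and k − 0.5.
Households with missing items (possible only under the don't-know→missing
coding policy) are scored on their answered subset and flagged.

Classification is by sign: theta ≥ 0 food secure, theta < 0 food insecure.
District summaries report mean, SE of the mean (sd/√n over scored
households), median, mode (most frequent theta value — well defined because
theta is raw-score-discrete; smallest value on ties), SD, variance,
small-sample-corrected skewness and excess kurtosis (pandas/Excel
convention), range, min, max, and a normal-quantile 95% half-width
(1.96·SE).

## Fit diagnostics

**Outfit.** Standardized residuals `z_vi = (X_vi − P_vi)/sqrt(P_vi(1−P_vi))`
with `P_vi` evaluated at the household's ML theta; probabilities are clipped
at 1e-12 with a warning if ever degenerate. Per item, the chi-square
`Σ_v z²` over the n_used scored households is divided by df = n_used − 1 to
give the mean-square (MSQ), with the conventional acceptance band 0.5–1.5; a
Wilson–Hilferty standardized form is reported alongside, using the
model-implied variance `Σ_v[(1−3PQ)/(PQ) − 1]/df²`.

A point worth knowing when reading simulations: with ML person estimates the
per-household residuals sum to zero by construction (the score equation
matches each household's raw score exactly), so part of the within-household
variance is absorbed and the model-true expectation of the MSQ is slightly
**below** 1 — exact conditional-moment computation under the Tororo preset
gives per-item expectations 0.87–0.93 (mean ≈ 0.91). Field data calibrated
with the same conventions show averages in the same region. The MSQ of
individual extreme items is also heavy-tailed on a single dataset: one
improbable response at a near-extreme score contributes z² ≈ P/Q, which can
move an item's MSQ by more than the 0.5–1.5 band width. Replicated averages
are the stable quantity; single-dataset extremes are not.

**Subgroup homogeneity.** Households are split at the median raw score
(ties to the lower group, matching the "greater than the median vs less or
equal" rule), items are recalibrated by CML within each subgroup, and

    LR = 2 (l_low + l_high − l_full)

is referred to chi-square with (k_used − 1) degrees of freedom, k_used the
number of items estimable in both subgroups (items inestimable in either
are dropped from all three fits and logged; subgroup scores are recomputed
on the retained item set). No small-sample correction is applied; at the
preset sample sizes the empirical size at alpha = 0.05 is ≈ 5% (within
Monte-Carlo error over 500 replicates). Paired subgroup estimates and
1.96·sqrt(SE_low² + SE_high²) bands are exported for the scatter plot.

**ICCs.** `P_i(theta) = expit(theta − eta_i)` on a grid; curves shift right
with difficulty and never cross (equal slopes — the defining Rasch
property).

## Response coding

Three response classes: frequency items E1–E6 (often/sometimes → 1,
never → 0); yes/no items (yes → 1, no → 0); how-often follow-ups E8, E13,
E16 (almost every month / some months → 1, only 1–2 months → 0). Coding is
idempotent on already-binary cells. Choices the instrument leaves open:

- **"Don't know"** is coded 0 by default (conservative, standard
  food-security practice), configurable to missing.
- **Gated follow-ups** are forced to 0 when their gate question (E7, E12,
  E15) is negative — a skipped follow-up is not an affirmation — keeping the
  matrix complete as the conditional likelihood assumes. A follow-up coded
  while its gate is missing is honored, with a warning.
- **Child items for childless households**: never/no answers code to 0, the
  same as any negative response.
- All-missing rows are dropped and logged; per-item level counts, dropped
  ids and warnings form the coding log.

## Synthetic data

The generator draws `theta_v ~ Normal(mu, sigma²)` i.i.d. and
`X_vi ~ Bernoulli(expit(a_i(theta_v + beta_i)))` with unit slopes `a_i`
under the Rasch model; non-unit slopes on selected items manufacture
over/under-discrimination misfit for power studies (slope 3 reliably drives
an item's outfit MSQ below 0.9 at n = 1000; slope 0.3 above 1.1). One
integer seed feeds a single PCG64 stream, abilities first then the n × k
response uniforms in household-major order, so (config, seed) reproduces a
matrix bit for bit; the generator family is recorded in output metadata.

The `tororo` (n = 577, mu = 0.137, sigma = 2.040) and `busia` (n = 598,
mu = 0.768, sigma = 2.078) presets embed the published district calibrations
as generating truth; easiness vectors are recentered to exact sum-zero
(the Busia column loses 0.001 to printed rounding). A nonzero ability mean
generalizes the model's zero-mean statement because observed district score
distributions are not centered at the scale origin; CML calibration is
invariant to this, person summaries are not.

What the generator deliberately does not emulate: the survey's sampling
design and household demographics, inter-item local dependence (gate pairs
are generated independently), and the mild negative skew of real district
score distributions (presets are normal approximations from first and
second moments). Passing recovery and calibration tests therefore
demonstrates correctness of the estimation machinery under the model's own
assumptions, not robustness to their violation. A raw-survey emitter maps
binary matrices back to representative categorical levels (affirmative
follow-ups force their gate to "yes"), giving a round-trip fixture for the
coder; the round trip is exact for gate-consistent matrices.

## Problem sizes used in the checks

Replicated studies use the preset sample sizes as-is: 200 replicates per
district for parameter recovery and outfit averaging, 500 replicates for the
homogeneity-test size, matching the scale at which the reference
calibrations were produced. Oracle tests (ESF subset enumeration, grid
search, bisection, quadrature) run at k ≤ 10 or on closed-form cases where
exhaustive computation is exact.

## Known limitations

- Dichotomous items only; no partial-credit/polytomous extension.
- No DIF analysis or covariate adjustment (the model has no covariates).
- CML drops households with missing items from calibration (complete-case);
  missingness is only expected under the don't-know→missing policy.
- Outfit is reported without bias correction for the score-conditioning
  effect described above; compare replicated averages against ≈ 0.91, not 1.
- Person estimates are ML; no Warm/EAP shrinkage, so |theta| at near-extreme
  scores is biased outward and district SDs based on scored households
  understate slightly the generating ability SD (extreme-score exclusion
  truncates the tails).
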