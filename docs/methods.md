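# Methods

## Model

Two coupled pieces, fitted jointly.

**Outcome (treatment-selection) regression.** A Gaussian linear model for
the continuous outcome with an intercept, a binary treatment main effect,
dummy-coded categorical mains (lowest category code is the reference),
restricted cubic spline bases on every continuous predictor, and
treatment interactions with every dummy and spline column. The design-row
column order is fixed and serialised with the model. The spline basis is
the natural-spline parameterisation: first column the covariate itself,
remaining columns the cubic terms normalised by the squared boundary-knot
span, constrained to zero second derivative outside the boundary knots.
Setting the knot count to zero selects a pure-linear basis (one column
per covariate), which also makes the generating model of the synthetic
scenario a special case of the fitted model.

**Covariate model.** A truncated Dirichlet process mixture over the
predictors: multivariate Gaussian components for the continuous block and
independent categorical distributions per categorical covariate,
independence holding conditional on the latent allocation. Weights follow
truncated stick-breaking with concentration α. The treatment indicator is
not modelled (it is always observed, and no generative model for it is
needed for CATE prediction).

The joint posterior multiplies the outcome likelihood, the DPMM density
of the (observed + imputed) covariates and the priors; missing covariate
cells are first-class unknowns. Rows with missing outcome or treatment
are excluded from training.

## Priors and defaults

| quantity | default | notes |
| --- | --- | --- |
| NIW base measure | m₀ = 0, κ₀ = 0.1, ν₀ = J_C + 2, S₀ = I | on standardised covariates |
| categorical base | symmetric Dirichlet(1) | per covariate |
| concentration α | Gamma(2, 1), sampled | fixed-α mode available |
| truncation K | 20 | post-fit occupancy check warns if the last-ranked component exceeds 1% of n |
| knots | 3 per continuous covariate at the 10/50/90% quantiles | 4 or 5 knots use the standard 5/35/65/95 and 5/27.5/50/72.5/95 rules; knots are computed once from observed values and frozen |
| ridge scale τ | 2.5 | shared Gaussian prior scale for all coefficients except the unpenalised intercept |
| σ prior | half-Cauchy(0, 5), Metropolis on log σ | inverse-gamma conjugate option for exactness tests |

Continuous covariates *and* the outcome are standardised internally to
the training mean/SD of observed cells; the constants are stored with the
model and applied to every later query, and all reported predictions are
de-standardised. This makes the identity-scale NIW base measure and the
τ = 2.5 ridge scale weakly informative regardless of the data's units.

## Sampler

Per iteration, in fixed order: allocations (exact categorical
conditional, Gumbel-max sampled) → stick fractions (Beta conditional) →
component parameters (NIW / Dirichlet conjugate draws; empty components
draw from the prior) → label-swap moves → concentration (Gamma
conditional implied by the truncated stick-breaking likelihood) →
missing-data sweep → regression block (Gaussian conditional for the
coefficients given σ, then the σ step). Initial state: uniform random
allocations, prior-drawn component parameters, missing cells at the
observed mean/mode, regression at the ridge solution with σ = 1. Chains
are seeded from a SeedSequence spawn of the user seed; the entire fit is
bit-reproducible given (data, config, seed).

**Label-swap moves.** The truncated stick-breaking representation is not
exchangeable in the component labels: the same partition of the data
carries different stick configurations — and hence a different
conditional for α — depending on where the occupied labels sit. Plain
blocked Gibbs never moves labels, so chains can freeze in arbitrary
arrangements, which in our experiments inflated α several-fold, seeded
spurious small clusters and broke between-chain convergence of α. After
each parameter update we therefore apply K−1 Metropolis label-swap
proposals between random neighbouring components: either the full swap
including the two stick fractions (acceptance
`min(1, exp(n_k log(1−V_{k+1}) − n_{k+1} log(1−V_k)))`) or a
parameters+allocations-only swap (acceptance
`(p_k/p_{k+1})^{n_{k+1}−n_k}`). Both are exact moves on the joint
posterior; they are exercised by the joint-distribution (Geweke-style)
test in the suite.

**Missing-data sweep.** For every incomplete individual the allocation is
refreshed first, so proposals use the freshest cluster assignment. All
missing continuous dims of one individual are then proposed jointly from
the conditional Gaussian of their component given the observed dims;
because that conditional is exactly the DPMM factor of the full
conditional, it cancels in the Metropolis–Hastings ratio and the
acceptance probability is `min(1, exp(Δ outcome log-likelihood))` — with
the side effect that zeroing an imputed covariate's outcome coefficients
makes the update an exact conditional draw (a tested identity). Missing
categorical cells are updated by exact enumeration over their levels
(level counts are small). For speed the sweep groups individuals by
missingness pattern and component and vectorises each group; the grouped
kernels sample the same full conditionals as the documented per-row
operations, only the order in which the rng stream is consumed differs.

**Prediction-time integration.** A new patient has no outcome, so the
outcome factor is absent by construction: per retained posterior draw, a
component is sampled from the weights *re-weighted by the observed-dim
likelihoods* (the exact conditional mixture), missing continuous dims
from the conditional Gaussian and categorical dims from that component's
category probabilities. Within a draw both treatment arms reuse the same
imputed covariates, so CATE draws are pure treatment contrasts. The CATE
sign convention is arm 1 minus arm 0; for an outcome where lower is
better, negative CATE favours arm 1. All reported probabilities are draw
fractions (Monte-Carlo SE ≤ 0.008 at the default 4000 retained draws).

**Variable influence.** For each missing variable, its conditional
predictive draws (pooled across posterior draws, given the observed
covariates) supply the 5/50/95% quantiles — for categorical variables,
the categories with conditional probability ≥ 5% instead, since
quantiles of unordered categories are undefined. The prediction is re-run
with the variable clamped at each value, the *other* missing variables
still integrated out using common random numbers across the clamped
values, so the between-value spread isolates the clamped variable's
effect (and an irrelevant variable gets exactly zero spread). Variables
are ranked by the widest between-value shift of the posterior-mean
response across arms; pooling quantiles across draws (rather than per
draw) was a free choice and is the simpler estimand.

## Synthetic scenario

The packaged generator emulates a second-line type 2 diabetes cohort:
three latent patient subgroups (weights 0.5/0.3/0.2) over four continuous
biomarkers on realistic scales — baseline HbA1c (marginal mean ≈ 74
mmol/mol, SD ≈ 11), eGFR (≈ 82), logged ALT (≈ 3.3), BMI (≈ 32) — and
two 4-level drug-count covariates with subgroup-specific profiles.
Subgroups are separated by ~3–4 within-component SDs so the 3-component
structure is identifiable, which is what the recovery checks assert.
Treatment is Bernoulli(0.4); the outcome applies a linear coefficient set
with a dominant treatment-by-baseline-HbA1c interaction (−0.15 per
mmol/mol, so the CATE swings by roughly ±5 mmol/mol across the HbA1c
range) plus smaller interactions on the other covariates, residual SD 8.
Missingness is MAR: 20% each on eGFR and logged ALT, with logistic
dependence on the always-observed baseline HbA1c and BMI respectively;
the logistic intercept is solved numerically so the realised marginal
rate equals the configured rate. Treatment and outcome are never masked,
and pre-masking values are retained for calibration oracles.

What the generator does *not* emulate: longitudinal structure, informative
treatment assignment (confounding), measurement error, MNAR mechanisms,
EHR coding artefacts, or non-Gaussian within-subgroup shapes. Passing
recovery and calibration tests therefore demonstrates the correctness of
the inference machinery under the model's own assumptions, not robustness
to real-data violations of them.

## Validation performed by the suite and acceptance script

All quantities are recomputed at run time; sizes were chosen to keep the
full suite and the script each within a few minutes on one CPU.

- conjugate oracle: K = 1, one covariate, n = 50 — Gibbs moments match
  the Normal–inverse-Wishart closed form;
- joint-distribution (Geweke-style) test on a tiny model (one continuous
  + one binary covariate, n = 5, K = 3): forward simulation vs
  successive-conditional simulation agree on finite-variance test
  functions of μ, Σ, φ, α (family-wise 1% level, batch-means SEs);
- DPMM recovery at n = 1000, K = 20: top-3 ranked occupancy ≥ 95%,
  posterior-predictive marginal moments within 3 SEs of the cohort;
- regression recovery: 20 complete-data replicates at n = 500 — 95%
  credible intervals cover every generating coefficient (transformed
  exactly into the standardised parameterisation) in ≥ 16 of 20;
- imputation calibration: 90% posterior predictive intervals for ~400
  MAR-masked cells achieve 80–97% empirical coverage;
- likelihood-cancellation identity (acceptance rate exactly 1, KS test
  against the analytic conditional);
- CATE recovery within 3 posterior SDs of the analytic truth for 10
  random complete profiles;
- nested-observation uncertainty shrinkage, with the largest drop at the
  dominant covariate's reveal, and the influence ranking placing that
  covariate first;
- split R-hat < 1.1 for all regression coefficients, σ and α on
  2 chains × 4000 iterations (observed ≈ 1.01).

## Numerical choices

- All mixture-weight computations in log space with log-sum-exp;
  allocation sampling by Gumbel-max.
- Cholesky factorisations throughout; conditional covariances are
  symmetrised before factorisation; a singular observed-dim block raises
  a degeneracy error naming the component rather than silently
  regularising.
- Stick fractions are clipped to (1e-12, 1−1e-12) so log(1−V) and the α
  conditional stay finite.
- Posterior quantiles use the empirical (linear-interpolation) estimator.
- The model store is a single HDF5 file with embedded JSON metadata
  (schema, spline knots, standardisation constants, design column order,
  config, chain seeds), so a model file alone suffices for prediction.

## Known limitations

- Label-swap moves restore label/α mixing but do not merge co-located
  clusters; heavily overlapping subgroup structures can hold a few
  percent of mass in extra clusters for long stretches (split–merge
  moves would be the next step).
- DPMMs extrapolate poorly: conditional imputations are only trustworthy
  in covariate regions with observed support.
- MAR is assumed, not tested; MNAR mechanisms are out of scope.
- The regression block assumes a Gaussian outcome; other outcome families
  would need their own likelihood and σ-step.
- Training-time imputation stores draws only for masked cells of the
  training data; per-individual acceptance rates are aggregated, not
  exposed per cell.
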