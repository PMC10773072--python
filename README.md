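# dpmselect

Bayesian treatment-selection modelling with Dirichlet process mixture
imputation of missing predictors.

## The problem

Treatment selection models predict a patient's outcome under each of two
competing therapies; the predicted difference — the conditional average
treatment effect (CATE) — guides which therapy to start. In routine care
many predictors (biomarkers, test results) are missing, both in the
development data and, crucially, for the new patient sitting in clinic.
`dpmselect` fits a joint Bayesian model that handles both: incomplete
records contribute to model fitting, and predictions with honest
uncertainty can be made for patients with any subset of predictors
observed. The motivating application is second-line type 2 diabetes
therapy (SGLT2i vs DPP4i arms, 6-month HbA1c outcome), but the model is
generic for one binary treatment and one continuous outcome.

## The model

The outcome follows a linear treatment-selection regression with
restricted cubic splines `S(·)` on the continuous predictors and full
treatment interactions,

```
Y_i = β₀ + β₁ X^T_i + β₂ X^D_i + β₃ S(X^C_i) + β₄ X^T_i X^D_i + β₅ X^T_i S(X^C_i) + ε_i,
ε_i ~ N(0, σ²),
```

while the joint distribution of the mixed continuous/categorical
predictors `X_i = (X^C_i, X^D_i)` is a truncated (K-component)
Dirichlet process mixture model (DPMM):

```
f(X_i | Θ) = Σ_{k=1..K} p_k · N(X^C_i; μ_k, Σ_k) · Π_j Cat(X^D_{ij}; φ_kj),
p_k = V_k Π_{l<k} (1 − V_l),   V_k ~ Beta(1, α).
```

With ψ = (β₀, β, σ), the joint posterior over parameters and the missing
covariate cells X^m is

```
f(ψ, Θ, X^m | X^o, Y) ∝ f(Y | X^o, X^m, ψ) · f(X^o, X^m | Θ) · f(ψ, Θ),
```

sampled by Metropolis-within-Gibbs: conjugate blocked-Gibbs updates for
the DPMM (allocations, sticks, Normal–inverse-Wishart and Dirichlet
component parameters, concentration α, plus label-swap moves), an exact
Gaussian/conjugate block for the regression, and per-patient updates of
missing cells — a joint Metropolis proposal from the component's
conditional Gaussian for continuous dims (the DPMM factor cancels, so
acceptance depends only on the outcome likelihood) and exact enumeration
for categorical cells. Missingness is assumed MCAR or MAR.

For a new patient, missing predictors are integrated out using the DPMM
conditional given whatever is observed (no outcome factor exists at
prediction time), yielding per-arm posterior predictive distributions of
the *expected* outcome, CATE distributions and `P(arm 1 better)`,
threshold-based therapy choice, and a ranking of which unmeasured
variable would be most informative to collect.

## Worked example

```python
import numpy as np
import dpmselect as dps
from dpmselect.inference import MCMCConfig, run_mcmc, rhat, occupancy_summary
from dpmselect.predict import PatientQuery, cate_distribution, variable_influence

cfg = dps.default_scenario(n=1000, seed=42)          # packaged T2D-like cohort
data = dps.apply_missingness(dps.generate_population(cfg), cfg)
fit = run_mcmc(data, MCMCConfig(n_chains=2, n_iterations=4000, n_burnin=2000,
                                seed=11, K=20))

patient = PatientQuery(
    observed={"past_drugs": "2", "current_drugs": "0", "hba1c_base": 73.0},
    missing=["egfr", "alt_log", "bmi"],
)
summ = cate_distribution(fit, patient, rng=np.random.default_rng(0))
```

Printing the fit diagnostics and the summaries of `summ` and a
variable-influence run for a sparser version of the same patient gives:

```
cohort: 1000 patients, 423 masked covariate cells
max split R-hat: 1.003; flagged: none
top-3 cluster occupancy: [516.5 291.  189.2] (99.7% of patients)
expected 6-month HbA1c: arm 1 60.7, arm 0 60.3 mmol/mol
CATE (arm1 - arm0): 0.40 mmol/mol, 95% CI [-4.20, 4.82]
P(arm 1 gives the better response) = 42.8%
most useful variable to collect: hba1c_base
    {'hba1c_base': 22.93, 'egfr': 10.62, 'bmi': 7.59, 'alt_log': 5.11}
```

Reading: the fitted DPMM recovers the cohort's three latent subgroups
(occupancy 517/291/189 against generating sizes 500/300/200); for this
patient the two therapies are predicted nearly equivalent (CATE
0.4 mmol/mol with a wide interval straddling zero, 43% chance arm 1 is
better), and of the unmeasured biomarkers, baseline HbA1c would shift the
prediction by far the most (spread 22.9 mmol/mol across its plausible
range) — it is the variable worth collecting.

The same pipeline is available from the shell:

```
dpmselect simulate --seed 1 --out cohort
dpmselect fit --data cohort.csv --schema cohort.schema.yaml --out model.h5 --seed 2
dpmselect diagnose --model model.h5 --out diag/
dpmselect predict --model model.h5 --patients patients.csv --out report.csv --threshold 60
dpmselect influence --model model.h5 --patients patients.csv --out influence.csv
dpmselect validate --model model.h5 --data cohort.csv --schema cohort.schema.yaml --out val/
```

Patient files are CSVs with one row per query; empty cells declare a
predictor missing. The model file is self-contained — predictions never
need the training data.

## Layout

- `src/dpmselect/synthetic.py` — mixture-cohort generator, MCAR/MAR masking, analytic CATE oracle
- `src/dpmselect/dpmm.py` — truncated DPMM: densities, conjugate Gibbs blocks, conditional Gaussians
- `src/dpmselect/outcome.py` — spline basis, design construction, regression block
- `src/dpmselect/missing.py` — training-time samplers for missing covariate cells
- `src/dpmselect/inference.py` — MCMC orchestration, diagnostics, HDF5 model store
- `src/dpmselect/predict.py` — predictive distributions, CATE, influence, threshold decisions
- `src/dpmselect/cli.py` — command-line surface
- `docs/methods.md` — modelling assumptions, priors, numerical choices, limitations
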