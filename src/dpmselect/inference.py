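"""MCMC orchestration over the joint posterior, diagnostics and the sample store.

The posterior targeted is

    f(psi, Theta, X^m | X^o, Y) propto f(Y | X^o, X^m, psi) f(X | Theta) f(psi, Theta)

with psi the regression parameters, Theta the DPMM parameters and X^m the
missing covariate cells.  Each iteration performs, in fixed order:
allocations -> stick weights -> component parameters -> concentration ->
missing-data sweep -> regression block.  Continuous covariates and the
outcome are standardised internally (training constants stored with the
samples), so predictions made later never need the training data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .data import ColumnSchema, MixedDataset
from .dpmm import (
    DPMMPriors,
    DPMMState,
    label_swap_moves,
    sample_allocations,
    update_component_params,
    update_concentration,
    update_stick_weights,
)
from .missing import ImputationState, TrainingContext, sweep_missing
from .outcome import (
    RegressionPriors,
    RegressionState,
    SplineSpec,
    build_design_matrix,
    design_column_names,
    fit_spline_spec,
    update_regression,
)

__all__ = [
    "MCMCConfig",
    "Standardisation",
    "PosteriorSamples",
    "run_mcmc",
    "split_rhat",
    "rhat",
    "RhatResult",
    "occupancy_summary",
    "posterior_predictive_covariates",
    "standardised_residuals",
]

logger = logging.getLogger("dpmselect")


@dataclass
class MCMCConfig:
    """Chain layout for a fit."""

    n_chains: int = 2
    n_iterations: int = 4000
    n_burnin: int = 2000
    thin: int = 1
    seed: int = 0
    K: int = 20
    fixed_alpha: float | None = None
    n_knots: int = 3

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        if self.n_chains < 1 or self.K < 1:
            raise ValueError("need at least one chain and one component")

    @property
    def n_keep(self) -> int:
        return int(np.ceil((self.n_iterations - self.n_burnin) / self.thin))


@dataclass
class Standardisation:
    """Training-scale constants applied to every later query."""

    cont_mean: np.ndarray
    cont_sd: np.ndarray
    y_mean: float
    y_sd: float

    def to_std(self, x_cont: np.ndarray) -> np.ndarray:
        return (np.asarray(x_cont, dtype=float) - self.cont_mean) / self.cont_sd

    def to_raw(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.cont_sd + self.cont_mean


@dataclass
class PosteriorSamples:
    """Per-chain, per-draw posterior states plus everything needed to predict.

    Arrays are indexed ``(chain, draw, ...)``.  ``beta`` is the full
    regression coefficient vector (intercept first) on the standardised
    scale; ``sigma`` likewise; ``imp_cont``/``imp_cat`` hold imputed values
    for the masked training cells listed in ``miss_cont_cells`` /
    ``miss_cat_cells`` (row, column index pairs).
    """

    schema: ColumnSchema
    spec: SplineSpec
    standardisation: Standardisation
    design_columns: list[str]
    beta: np.ndarray  # (C, D, p)
    sigma: np.ndarray  # (C, D)
    alpha: np.ndarray  # (C, D)
    weights: np.ndarray  # (C, D, K)
    mus: np.ndarray  # (C, D, K, J_C)
    Sigmas: np.ndarray  # (C, D, K, J_C, J_C)
    phis: list[np.ndarray]  # per categorical covariate (C, D, K, K_j)
    counts: np.ndarray  # (C, D, K)
    imp_cont: np.ndarray  # (C, D, M_c)
    imp_cat: np.ndarray  # (C, D, M_d)
    miss_cont_cells: np.ndarray  # (M_c, 2) row, col
    miss_cat_cells: np.ndarray  # (M_d, 2)
    config: dict[str, Any] = field(default_factory=dict)
    chain_seeds: list[int] = field(default_factory=list)
    accept_rate: float = float("nan")

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    @property
    def K(self) -> int:
        return self.weights.shape[2]

    def flat(self, name: str) -> np.ndarray:
        """Array with chain and draw axes merged."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def flat_phis(self) -> list[np.ndarray]:
        return [p.reshape((-1,) + p.shape[2:]) for p in self.phis]

    @property
    def sigma_raw(self) -> np.ndarray:
        """Residual SD draws in original outcome units."""
        return self.sigma * self.standardisation.y_sd

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a self-describing HDF5 model file."""
        with h5py.File(path, "w") as f:
            g = f.create_group("draws")
            for name in ("beta", "sigma", "alpha", "weights", "mus", "Sigmas", "counts",
                         "imp_cont", "imp_cat"):
                g.create_dataset(name, data=getattr(self, name))
            gp = f.create_group("phis")
            for j, col in enumerate(self.schema.cat_names):
                gp.create_dataset(col, data=self.phis[j])
            m = f.create_group("meta")
            m.create_dataset("cont_mean", data=self.standardisation.cont_mean)
            m.create_dataset("cont_sd", data=self.standardisation.cont_sd)
            m.create_dataset("miss_cont_cells", data=self.miss_cont_cells)
            m.create_dataset("miss_cat_cells", data=self.miss_cat_cells)
            m.attrs["y_mean"] = self.standardisation.y_mean
            m.attrs["y_sd"] = self.standardisation.y_sd
            m.attrs["schema"] = json.dumps(self.schema.to_dict())
            m.attrs["spline_spec"] = json.dumps(self.spec.to_dict())
            m.attrs["design_columns"] = json.dumps(self.design_columns)
            m.attrs["config"] = json.dumps(self.config)
            m.attrs["chain_seeds"] = json.dumps([int(s) for s in self.chain_seeds])
            m.attrs["accept_rate"] = self.accept_rate

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorSamples":
        with h5py.File(path, "r") as f:
            m = f["meta"]
            schema = ColumnSchema.from_dict(json.loads(m.attrs["schema"]))
            spec = SplineSpec.from_dict(json.loads(m.attrs["spline_spec"]))
            std = Standardisation(
                cont_mean=m["cont_mean"][()],
                cont_sd=m["cont_sd"][()],
                y_mean=float(m.attrs["y_mean"]),
                y_sd=float(m.attrs["y_sd"]),
            )
            g = f["draws"]
            return cls(
                schema=schema,
                spec=spec,
                standardisation=std,
                design_columns=json.loads(m.attrs["design_columns"]),
                beta=g["beta"][()],
                sigma=g["sigma"][()],
                alpha=g["alpha"][()],
                weights=g["weights"][()],
                mus=g["mus"][()],
                Sigmas=g["Sigmas"][()],
                phis=[f["phis"][col][()] for col in schema.cat_names],
                counts=g["counts"][()],
                imp_cont=g["imp_cont"][()],
                imp_cat=g["imp_cat"][()],
                miss_cont_cells=m["miss_cont_cells"][()],
                miss_cat_cells=m["miss_cat_cells"][()],
                config=json.loads(m.attrs["config"]),
                chain_seeds=json.loads(m.attrs["chain_seeds"]),
                accept_rate=float(m.attrs["accept_rate"]),
            )


def _init_regression(X: np.ndarray, y: np.ndarray, tau: float) -> RegressionState:
    """Deterministic ridge solution (sigma = 1) as the chain start point."""
    p = X.shape[1]
    d = np.full(p, 1.0 / tau**2)
    d[0] = 0.0
    coef = np.linalg.solve(X.T @ X + np.diag(d), X.T @ y)
    return RegressionState(beta0=float(coef[0]), beta=coef[1:], sigma=1.0)


def run_mcmc(
    data: MixedDataset,
    mcmc: MCMCConfig,
    dpmm_priors: DPMMPriors | None = None,
    reg_priors: RegressionPriors | None = None,
    standardisation: Standardisation | None = None,
    spline_spec: SplineSpec | None = None,
) -> PosteriorSamples:
    """Fit the joint model by Metropolis-within-Gibbs MCMC.

    Rows with a missing outcome or treatment are excluded from training.
    ``standardisation`` and ``spline_spec`` may be supplied to reuse the
    constants of a previous fit (e.g. for complete-case comparisons);
    otherwise both are computed from the observed training values and
    frozen.  Deterministic given ``mcmc.seed``.
    """
    s = data.schema
    keep = np.isfinite(data.y) & (data.treatment >= 0)
    if not keep.all():
        logger.info("excluding %d rows with missing outcome/treatment", (~keep).sum())
        data = MixedDataset(
            schema=s,
            x_cont=data.x_cont[keep],
            x_cat=data.x_cat[keep],
            treatment=data.treatment[keep],
            y=data.y[keep],
            miss_cont=data.miss_cont[keep],
            miss_cat=data.miss_cat[keep],
        )
    n, jc, jd = data.n, data.j_cont, data.j_cat
    for j, col in enumerate(s.continuous):
        if not (~data.miss_cont[:, j]).any():
            raise ValueError(f"covariate {col!r} has no observed values")
    if standardisation is None:
        cm = np.array(
            [data.x_cont[~data.miss_cont[:, j], j].mean() for j in range(jc)]
        ) if jc else np.empty(0)
        csd = np.array(
            [max(data.x_cont[~data.miss_cont[:, j], j].std(), 1e-12) for j in range(jc)]
        ) if jc else np.empty(0)
        standardisation = Standardisation(
            cont_mean=cm, cont_sd=csd, y_mean=float(data.y.mean()),
            y_sd=float(max(data.y.std(), 1e-12)),
        )
    std = standardisation
    xc_std = std.to_std(data.x_cont) if jc else np.zeros((n, 0))
    y_std = (data.y - std.y_mean) / std.y_sd
    if spline_spec is None:
        spline_spec = fit_spline_spec(
            {
                col: xc_std[~data.miss_cont[:, j], j]
                for j, col in enumerate(s.continuous)
            },
            n_knots=mcmc.n_knots,
        )
    dpmm_priors = dpmm_priors or DPMMPriors.default(
        jc, fixed_alpha=mcmc.fixed_alpha
    )
    if mcmc.fixed_alpha is not None and dpmm_priors.fixed_alpha is None:
        dpmm_priors.fixed_alpha = mcmc.fixed_alpha
    reg_priors = reg_priors or RegressionPriors()
    ctx = TrainingContext(
        schema=s,
        spec=spline_spec,
        y=y_std,
        treatment=data.treatment,
        miss_cont=data.miss_cont,
        miss_cat=data.miss_cat,
    )
    design_cols = design_column_names(s, spline_spec)
    p = len(design_cols)
    K = mcmc.K
    n_levels = s.n_levels
    cont_cells = np.argwhere(data.miss_cont)
    cat_cells = np.argwhere(data.miss_cat)
    has_missing = bool(cont_cells.size or cat_cells.size)
    C, D = mcmc.n_chains, mcmc.n_keep
    out = PosteriorSamples(
        schema=s,
        spec=spline_spec,
        standardisation=std,
        design_columns=design_cols,
        beta=np.empty((C, D, p)),
        sigma=np.empty((C, D)),
        alpha=np.empty((C, D)),
        weights=np.empty((C, D, K)),
        mus=np.empty((C, D, K, jc)),
        Sigmas=np.empty((C, D, K, jc, jc)),
        phis=[np.empty((C, D, K, kj)) for kj in n_levels],
        counts=np.empty((C, D, K), dtype=np.int32),
        imp_cont=np.empty((C, D, len(cont_cells))),
        imp_cat=np.empty((C, D, len(cat_cells)), dtype=np.int16),
        miss_cont_cells=cont_cells,
        miss_cat_cells=cat_cells,
        config={
            "n_chains": C,
            "n_iterations": mcmc.n_iterations,
            "n_burnin": mcmc.n_burnin,
            "thin": mcmc.thin,
            "seed": mcmc.seed,
            "K": K,
            "n_knots": mcmc.n_knots,
            "fixed_alpha": mcmc.fixed_alpha,
            "tau": reg_priors.tau,
            "sigma_prior": list(reg_priors.sigma_prior),
            "n_rows_fitted": int(n),
        },
    )
    seeds = [int(ss.generate_state(1)[0] % (2**31)) for ss in
             np.random.SeedSequence(mcmc.seed).spawn(C)]
    out.chain_seeds = seeds
    accept_num = accept_den = 0
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        alloc = rng.integers(0, K, size=n)
        alpha = (
            dpmm_priors.fixed_alpha
            if dpmm_priors.fixed_alpha is not None
            else dpmm_priors.alpha_shape / dpmm_priors.alpha_rate
        )
        # component parameters start as prior draws (no rows allocated yet)
        mus, Sigmas, phis = update_component_params(
            np.full(n, -1), xc_std, data.x_cat, dpmm_priors, K, n_levels, rng
        )
        sticks = update_stick_weights(alloc, alpha, K, rng)
        state = DPMMState(
            sticks=sticks, mus=mus, Sigmas=Sigmas, phis=phis, alloc=alloc, alpha=alpha
        )
        xc_work = xc_std.copy()
        xc_work[data.miss_cont] = 0.0  # observed-data mean on the standardised scale
        xcat_work = data.x_cat.copy()
        for j in range(jd):
            obs = data.x_cat[~data.miss_cat[:, j], j]
            mode = int(np.bincount(obs, minlength=n_levels[j]).argmax()) if obs.size else 0
            xcat_work[data.miss_cat[:, j], j] = mode
        imp = ImputationState(x_cont=xc_work, x_cat=xcat_work)
        X = build_design_matrix(imp.x_cont, imp.x_cat, data.treatment, spline_spec, s)
        reg = _init_regression(X, y_std, reg_priors.tau)
        d = 0
        for it in range(mcmc.n_iterations):
            state.alloc = sample_allocations(state, imp.x_cont, imp.x_cat, rng)
            state.sticks = update_stick_weights(state.alloc, state.alpha, K, rng)
            state.mus, state.Sigmas, state.phis = update_component_params(
                state.alloc, imp.x_cont, imp.x_cat, dpmm_priors, K, n_levels, rng
            )
            state = DPMMState(
                sticks=state.sticks, mus=state.mus, Sigmas=state.Sigmas,
                phis=state.phis, alloc=state.alloc, alpha=state.alpha,
            )
            state = label_swap_moves(state, rng)
            state.alpha = update_concentration(state.alpha, state.sticks, dpmm_priors, rng)
            if has_missing:
                sweep_missing(state, reg, imp, ctx, rng)
                X[ctx.incomplete] = build_design_matrix(
                    imp.x_cont[ctx.incomplete],
                    imp.x_cat[ctx.incomplete],
                    data.treatment[ctx.incomplete],
                    spline_spec,
                    s,
                )
            reg = update_regression(X, y_std, reg, reg_priors, rng)
            if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
                out.beta[c, d] = reg.coef
                out.sigma[c, d] = reg.sigma
                out.alpha[c, d] = state.alpha
                out.weights[c, d] = state.weights
                out.mus[c, d] = state.mus
                out.Sigmas[c, d] = state.Sigmas
                for j in range(jd):
                    out.phis[j][c, d] = state.phis[j]
                out.counts[c, d] = np.bincount(state.alloc, minlength=K)
                if len(cont_cells):
                    out.imp_cont[c, d] = imp.x_cont[cont_cells[:, 0], cont_cells[:, 1]]
                if len(cat_cells):
                    out.imp_cat[c, d] = imp.x_cat[cat_cells[:, 0], cat_cells[:, 1]]
                d += 1
            if (it + 1) % max(1, mcmc.n_iterations // 8) == 0:
                logger.info(
                    "chain %d: iteration %d/%d (MH acceptance %.2f)",
                    c, it + 1, mcmc.n_iterations, imp.acceptance_rate,
                )
        accept_num += imp.n_accept.sum()
        accept_den += imp.n_prop.sum()
    out.accept_rate = float(accept_num / accept_den) if accept_den else float("nan")
    return out


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws).  Zero-variance chains are
    defined to have R-hat 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("chains must be a (n_chains, n_draws) array")
    L = x.shape[1] // 2
    if L < 2:
        raise ValueError("need at least 4 draws per chain")
    halves = np.concatenate([x[:, :L], x[:, L : 2 * L]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = L * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))


@dataclass
class RhatResult:
    values: dict[str, float]
    flagged: list[str]

    @property
    def max(self) -> float:
        return max(self.values.values())


def rhat(samples: PosteriorSamples, flag_threshold: float = 1.05) -> RhatResult:
    """Split R-hat for every regression coefficient, sigma and alpha."""
    if samples.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    values: dict[str, float] = {}
    for j, name in enumerate(samples.design_columns):
        values[f"beta[{name}]"] = split_rhat(samples.beta[:, :, j])
    values["sigma"] = split_rhat(samples.sigma)
    values["alpha"] = split_rhat(samples.alpha)
    flagged = [k for k, v in values.items() if v > flag_threshold]
    return RhatResult(values=values, flagged=flagged)


def occupancy_summary(samples: PosteriorSamples, warn_frac: float = 0.01) -> np.ndarray:
    """Posterior mean individuals per component, ranked by occupancy.

    Sorts each retained draw's allocation counts in descending order
    before averaging (rank-based, hence invariant to label switching).
    Warns when the last-ranked occupancy exceeds ``warn_frac`` of n,
    which suggests the truncation level K is too small.
    """
    ranked = np.sort(samples.flat("counts"), axis=1)[:, ::-1].mean(axis=0)
    n = samples.flat("counts")[0].sum()
    if ranked[-1] > warn_frac * n:
        import warnings

        warnings.warn(
            f"last-ranked component holds {ranked[-1]:.1f} individuals on average "
            f"(> {warn_frac:.0%} of n={n}); consider increasing K",
            stacklevel=2,
        )
    return ranked


def posterior_predictive_covariates(
    samples: PosteriorSamples, n_draws: int, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Synthetic covariate profiles from the fitted DPMM, in original units.

    Each draw picks a retained posterior state, samples a component from
    its weights and then the covariates from that component; suitable for
    pairs-plot comparison against held-out data.
    """
    rng = rng or np.random.default_rng(0)
    T = samples.n_total
    idx = rng.integers(T, size=n_draws)
    w = samples.flat("weights")[idx]
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    comp = np.argmax(logw + rng.gumbel(size=logw.shape), axis=1)
    jc = len(samples.schema.continuous)
    out: dict[str, Any] = {}
    if jc:
        mus = samples.flat("mus")[idx, comp]
        Sig = samples.flat("Sigmas")[idx, comp]
        L = np.linalg.cholesky(Sig)
        z = rng.standard_normal((n_draws, jc, 1))
        draws = mus + (L @ z)[..., 0]
        raw = samples.standardisation.to_raw(draws)
        for j, col in enumerate(samples.schema.continuous):
            out[col] = raw[:, j]
    for j, col in enumerate(samples.schema.cat_names):
        phi = samples.flat_phis()[j][idx, comp]
        u = rng.uniform(size=n_draws)
        codes = (u[:, None] > phi.cumsum(axis=1)).sum(axis=1)
        labels = np.array(samples.schema.categorical[col], dtype=object)
        out[col] = labels[np.clip(codes, 0, len(labels) - 1)]
    return pd.DataFrame(out)


def standardised_residuals(
    samples: PosteriorSamples,
    data: MixedDataset,
    rng: np.random.Generator | None = None,
    max_draws: int = 400,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-individual standardised residuals against posterior mean predictions.

    Residual_i = (y_i - posterior mean prediction at i's own arm) divided
    by the posterior mean residual SD.  Missing covariates are integrated
    over via the prediction-path conditional draws (a posterior-draw
    subsample of size ``max_draws`` keeps this fast).  The returned summary
    regresses residuals on fitted values to expose systematic bias.
    """
    from . import predict as _predict

    rng = rng or np.random.default_rng(0)
    std = samples.standardisation
    mean_coef = samples.flat("beta").mean(axis=0)
    mean_sigma = float(samples.sigma_raw.mean())
    fitted = np.empty(data.n)
    complete = data.complete_rows()
    if complete.any():
        X = build_design_matrix(
            std.to_std(data.x_cont[complete]),
            data.x_cat[complete],
            data.treatment[complete],
            samples.spec,
            samples.schema,
        )
        fitted[complete] = std.y_mean + std.y_sd * (X @ mean_coef)
    draw_idx = None
    if samples.n_total > max_draws:
        draw_idx = rng.choice(samples.n_total, size=max_draws, replace=False)
    for i in np.flatnonzero(~complete):
        q = _predict.query_from_row(samples.schema, data, int(i))
        d = _predict.predict_mean_response(
            samples, q, arm=int(data.treatment[i]), rng=rng, draw_indices=draw_idx
        )
        fitted[i] = d.mean()
    resid = (data.y - fitted) / mean_sigma
    slope, intercept = np.polyfit(fitted, resid, 1)
    df = pd.DataFrame({"fitted": fitted, "residual": resid})
    summary = {
        "mean": float(resid.mean()),
        "sd": float(resid.std(ddof=1)),
        "slope_vs_fitted": float(slope),
        "intercept_vs_fitted": float(intercept),
    }
    return df, summary
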