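"""Conditional updates of missing covariate cells during model fitting.

Each incomplete individual's missing continuous dims are proposed jointly
from the conditional Gaussian of their current mixture component given
their observed continuous dims.  Because that conditional is exactly the
DPMM factor of the full conditional, it cancels in the Metropolis-Hastings
ratio and the acceptance probability reduces to min(1, exp(delta outcome
log-likelihood)) — the full conditional is the invariant distribution.
Missing categorical cells are updated by exact enumeration over their
categories (Gibbs; the level counts are small).

The allocation Z_i of each incomplete individual is refreshed from its
full conditional immediately before its missing-value update, so the
proposal always uses the freshest cluster assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ColumnSchema, MixedDataset
from .dpmm import DPMMState, conditional_gaussian, sample_allocations
from .outcome import RegressionState, SplineSpec, build_design_matrix

__all__ = [
    "TrainingContext",
    "ImputationState",
    "sample_missing_continuous",
    "sample_missing_categorical",
    "sweep_missing",
]


@dataclass
class TrainingContext:
    """Frozen per-fit quantities the missing-data samplers need.

    Covariates and outcome are on the standardised training scale; the
    spline spec is likewise frozen in standardised units.
    """

    schema: ColumnSchema
    spec: SplineSpec
    y: np.ndarray  # standardised outcome
    treatment: np.ndarray
    miss_cont: np.ndarray  # (n, J_C) bool
    miss_cat: np.ndarray  # (n, J_D) bool

    def __post_init__(self) -> None:
        self.miss_cont = np.asarray(self.miss_cont, dtype=bool)
        self.miss_cat = np.asarray(self.miss_cat, dtype=bool)
        self.incomplete = np.flatnonzero(
            self.miss_cont.any(axis=1) | self.miss_cat.any(axis=1)
        )
        # group rows by continuous-missingness pattern for vectorised updates
        self.cont_groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        rows_c = np.flatnonzero(self.miss_cont.any(axis=1))
        if rows_c.size:
            keys = [tuple(bool(b) for b in row) for row in self.miss_cont[rows_c]]
            for key in sorted(set(keys)):
                sel = rows_c[np.array([k == key for k in keys], dtype=bool)]
                m_idx = np.flatnonzero(np.array(key))
                o_idx = np.flatnonzero(~np.array(key))
                self.cont_groups.append((m_idx, o_idx, sel))
        self.cat_missing_rows = [
            np.flatnonzero(self.miss_cat[:, j]) for j in range(self.miss_cat.shape[1])
        ]

    def design(self, x_cont: np.ndarray, x_cat: np.ndarray, rows: np.ndarray) -> np.ndarray:
        return build_design_matrix(
            x_cont, x_cat, self.treatment[rows], self.spec, self.schema
        )


@dataclass
class ImputationState:
    """Working covariate matrices (observed values + current imputations).

    Only cells flagged missing in the masks ever change; observed cells
    are bit-identical across any number of sweeps.  Acceptance counters
    for the continuous Metropolis-Hastings step support adaptive-tuning
    diagnostics.
    """

    x_cont: np.ndarray  # (n, J_C) standardised working values
    x_cat: np.ndarray  # (n, J_D) working codes
    n_prop: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_accept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.x_cont = np.atleast_2d(np.asarray(self.x_cont, dtype=float))
        self.x_cat = np.atleast_2d(np.asarray(self.x_cat, dtype=int))
        n = self.x_cont.shape[0]
        if self.n_prop is None:
            self.n_prop = np.zeros(n, dtype=int)
        if self.n_accept is None:
            self.n_accept = np.zeros(n, dtype=int)

    @property
    def acceptance_rate(self) -> float:
        total = self.n_prop.sum()
        return float(self.n_accept.sum() / total) if total else float("nan")


def _loglik_rows(
    X: np.ndarray, y: np.ndarray, reg: RegressionState
) -> np.ndarray:
    """Gaussian log-likelihood kernel per row (constants dropped)."""
    resid = y - X @ reg.coef
    return -0.5 * resid**2 / reg.sigma**2


def sample_missing_continuous(
    i: int,
    state: DPMMState,
    reg: RegressionState,
    imp: ImputationState,
    ctx: TrainingContext,
    rng: np.random.Generator,
) -> np.ndarray:
    """One MH update of individual i's missing continuous dims (joint).

    Proposes from the conditional Gaussian of component Z_i given i's
    observed continuous dims and accepts with probability
    min(1, exp(delta outcome log-likelihood)).  Rejection retains the
    current values.  Returns the (possibly unchanged) working values.
    """
    m_idx = np.flatnonzero(ctx.miss_cont[i])
    if m_idx.size == 0:
        raise ValueError(f"individual {i} has no missing continuous dims")
    o_idx = np.flatnonzero(~ctx.miss_cont[i])
    k = int(state.alloc[i])
    mean, cov = conditional_gaussian(
        state.mus[k], state.Sigmas[k], o_idx, imp.x_cont[i, o_idx]
    )
    L = np.linalg.cholesky(cov)
    prop_vals = mean + L @ rng.standard_normal(m_idx.size)
    xc_cur = imp.x_cont[i].copy()
    xc_prop = xc_cur.copy()
    xc_prop[m_idx] = prop_vals
    rows = np.array([i])
    X = ctx.design(np.stack([xc_cur, xc_prop]), np.stack([imp.x_cat[i]] * 2), np.array([i, i]))
    ll = _loglik_rows(X, np.array([ctx.y[i]] * 2), reg)
    imp.n_prop[i] += 1
    if np.log(rng.uniform()) < ll[1] - ll[0]:
        imp.x_cont[i, m_idx] = prop_vals
        imp.n_accept[i] += 1
    return imp.x_cont[i, m_idx].copy()


def sample_missing_categorical(
    i: int,
    state: DPMMState,
    reg: RegressionState,
    imp: ImputationState,
    ctx: TrainingContext,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact Gibbs update of individual i's missing categorical covariates.

    Each missing cell's full conditional over its levels is proportional
    to phi_{Z_i, j}[l] * exp(outcome log-likelihood with level l); the
    draw is by direct enumeration (no rejection).
    """
    js = np.flatnonzero(ctx.miss_cat[i])
    if js.size == 0:
        raise ValueError(f"individual {i} has no missing categorical covariates")
    k = int(state.alloc[i])
    for j in js:
        kj = state.phis[j].shape[1]
        cand = np.repeat(imp.x_cat[i][None, :], kj, axis=0)
        cand[:, j] = np.arange(kj)
        X = ctx.design(
            np.repeat(imp.x_cont[i][None, :], kj, axis=0), cand, np.full(kj, i)
        )
        with np.errstate(divide="ignore"):
            logw = np.log(state.phis[j][k]) + _loglik_rows(
                X, np.full(kj, ctx.y[i]), reg
            )
        if not np.isfinite(logw).any():
            raise RuntimeError(
                f"all enumerated weights are zero for individual {i}, covariate {j}"
            )
        g = rng.gumbel(size=kj)
        imp.x_cat[i, j] = int(np.argmax(np.where(np.isfinite(logw), logw + g, -np.inf)))
    return imp.x_cat[i, js].copy()


def sweep_missing(
    state: DPMMState,
    reg: RegressionState,
    imp: ImputationState,
    ctx: TrainingContext,
    rng: np.random.Generator,
    resample_alloc: bool = True,
) -> ImputationState:
    """One full missing-data sweep over every incomplete individual.

    Refreshes Z for incomplete rows, then applies the joint continuous MH
    update (vectorised by missingness pattern and component) and the exact
    categorical Gibbs update.  Complete individuals are untouched;
    deterministic given the rng stream.
    """
    inc = ctx.incomplete
    if inc.size == 0:
        return imp
    if resample_alloc:
        state.alloc[inc] = sample_allocations(
            state, imp.x_cont[inc], imp.x_cat[inc], rng
        )
    # joint continuous proposals: conditional params per (pattern, component),
    # design rows and the accept step vectorised per pattern
    for m_idx, o_idx, rows in ctx.cont_groups:
        zrows = state.alloc[rows]
        prop = np.empty((rows.size, m_idx.size))
        for k in np.unique(zrows):
            sel = zrows == k
            r = rows[sel]
            mu, Sig = state.mus[k], state.Sigmas[k]
            Smm = Sig[np.ix_(m_idx, m_idx)]
            if o_idx.size:
                Loo = np.linalg.cholesky(Sig[np.ix_(o_idx, o_idx)])
                A = np.linalg.solve(Loo, Sig[np.ix_(o_idx, m_idx)])  # (o, m)
                w = np.linalg.solve(Loo, (imp.x_cont[np.ix_(r, o_idx)] - mu[o_idx]).T)
                mean = mu[m_idx] + (A.T @ w).T
                cov = Smm - A.T @ A
            else:
                mean = np.repeat(mu[m_idx][None, :], r.size, axis=0)
                cov = Smm
            Lc = np.linalg.cholesky(0.5 * (cov + cov.T))
            prop[sel] = mean + rng.standard_normal((r.size, m_idx.size)) @ Lc.T
        xc_prop = imp.x_cont[rows].copy()
        xc_prop[:, m_idx] = prop
        X_cur = ctx.design(imp.x_cont[rows], imp.x_cat[rows], rows)
        X_prop = ctx.design(xc_prop, imp.x_cat[rows], rows)
        ll_cur = _loglik_rows(X_cur, ctx.y[rows], reg)
        ll_prop = _loglik_rows(X_prop, ctx.y[rows], reg)
        acc = np.log(rng.uniform(size=rows.size)) < ll_prop - ll_cur
        imp.x_cont[np.ix_(rows[acc], m_idx)] = prop[acc]
        imp.n_prop[rows] += 1
        imp.n_accept[rows[acc]] += 1
    # exact categorical updates
    for j, rows in enumerate(ctx.cat_missing_rows):
        for i in rows:
            _update_one_cat(int(i), int(j), state, reg, imp, ctx, rng)
    return imp


def _update_one_cat(
    i: int,
    j: int,
    state: DPMMState,
    reg: RegressionState,
    imp: ImputationState,
    ctx: TrainingContext,
    rng: np.random.Generator,
) -> None:
    k = int(state.alloc[i])
    kj = state.phis[j].shape[1]
    cand = np.repeat(imp.x_cat[i][None, :], kj, axis=0)
    cand[:, j] = np.arange(kj)
    X = ctx.design(np.repeat(imp.x_cont[i][None, :], kj, axis=0), cand, np.full(kj, i))
    with np.errstate(divide="ignore"):
        logw = np.log(state.phis[j][k]) + _loglik_rows(X, np.full(kj, ctx.y[i]), reg)
    if not np.isfinite(logw).any():
        raise RuntimeError(
            f"all enumerated weights are zero for individual {i}, covariate {j}"
        )
    g = rng.gumbel(size=kj)
    imp.x_cat[i, j] = int(np.argmax(np.where(np.isfinite(logw), logw + g, -np.inf)))
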