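"""Truncated Dirichlet process mixture model over mixed covariates.

The covariate distribution is a K-component truncated stick-breaking
mixture.  Each component couples a multivariate Gaussian over the J_C
continuous covariates (parameters mu_k, Sigma_k) with independent
categorical distributions phi_kj over each categorical covariate j,
independence holding conditional on the latent allocation Z_i.  Weights
follow the truncated stick-breaking construction p_k = V_k prod_{l<k}
(1 - V_l) with V_k ~ Beta(1, alpha) a priori, and the concentration alpha
carries a Gamma prior.

Conjugate blocked-Gibbs updates are provided for the allocations, the
stick fractions, the Normal-inverse-Wishart component parameters, the
Dirichlet categorical parameters and the concentration, plus the
conditional-Gaussian machinery needed to update individual missing
dimensions of the multivariate covariate vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ComponentParams",
    "DPMMPriors",
    "DPMMState",
    "component_logdensity",
    "mixture_logdensity",
    "allocation_logweights",
    "sample_allocations",
    "update_stick_weights",
    "update_component_params",
    "update_concentration",
    "conditional_gaussian",
    "stick_weights_from_fractions",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class NumericalDegeneracyError(RuntimeError):
    """Raised when a covariance (sub-)matrix is numerically singular."""


@dataclass
class ComponentParams:
    """Parameters of one mixture component (standardised covariate units)."""

    mu: np.ndarray  # (J_C,)
    Sigma: np.ndarray  # (J_C, J_C), symmetric positive-definite
    phi: list[np.ndarray] = field(default_factory=list)  # per categorical covariate

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.phi = [np.asarray(p, dtype=float) for p in self.phi]
        for p in self.phi:
            if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("each phi_kj must be a probability vector")


@dataclass
class DPMMPriors:
    """Conjugate base measures and the concentration prior.

    Normal-inverse-Wishart over (mu_k, Sigma_k): prior mean ``m0``, scale
    ``kappa0``, degrees of freedom ``nu0 >= J_C`` and scale matrix ``S0``.
    Symmetric Dirichlet concentration per categorical covariate, and a
    Gamma(shape, rate) prior on alpha (or a fixed value).
    """

    m0: np.ndarray
    kappa0: float = 0.1
    nu0: float | None = None  # default J_C + 2
    S0: np.ndarray | None = None  # default identity
    dirichlet_conc: float = 1.0
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    fixed_alpha: float | None = None

    def __post_init__(self) -> None:
        self.m0 = np.asarray(self.m0, dtype=float).reshape(-1)
        p = self.m0.size
        if self.nu0 is None:
            self.nu0 = p + 2.0
        if self.S0 is None:
            self.S0 = np.eye(p)
        self.S0 = np.asarray(self.S0, dtype=float)
        if self.nu0 < p:
            raise ValueError("nu0 must be >= J_C")
        if min(self.kappa0, self.dirichlet_conc, self.alpha_shape, self.alpha_rate) <= 0:
            raise ValueError("all prior concentrations/scales must be positive")

    @classmethod
    def default(cls, j_cont: int, **kw) -> "DPMMPriors":
        return cls(m0=np.zeros(j_cont), **kw)


def stick_weights_from_fractions(v: np.ndarray) -> np.ndarray:
    """Weights p_k = V_k prod_{l<k}(1-V_l), p_K = prod_{l<K}(1-V_l)."""
    v = np.asarray(v, dtype=float)
    log1mv = np.log1p(-v)
    cum = np.concatenate([[0.0], np.cumsum(log1mv)])
    w = np.empty(v.size + 1)
    w[:-1] = v * np.exp(cum[:-1])
    w[-1] = np.exp(cum[-1])
    return w


@dataclass
class DPMMState:
    """Full mixture state: sticks, weights, stacked component params, allocations."""

    sticks: np.ndarray  # (K-1,) in (0,1)
    mus: np.ndarray  # (K, J_C)
    Sigmas: np.ndarray  # (K, J_C, J_C)
    phis: list[np.ndarray]  # per categorical covariate: (K, K_j)
    alloc: np.ndarray  # (n,) in 0..K-1
    alpha: float

    def __post_init__(self) -> None:
        self.sticks = np.asarray(self.sticks, dtype=float)
        self.mus = np.atleast_2d(np.asarray(self.mus, dtype=float))
        self.Sigmas = np.asarray(self.Sigmas, dtype=float)
        self.phis = [np.atleast_2d(np.asarray(p, dtype=float)) for p in self.phis]
        self.alloc = np.asarray(self.alloc, dtype=int)
        self.weights = stick_weights_from_fractions(self.sticks)
        if abs(self.weights.sum() - 1.0) > 1e-9 or self.weights.min() < -1e-12:
            raise ValueError("stick-breaking weights must be a probability vector")
        if self.alloc.size and (self.alloc.min() < 0 or self.alloc.max() >= self.K):
            raise ValueError("allocation out of range")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def K(self) -> int:
        return self.mus.shape[0]

    @property
    def j_cont(self) -> int:
        return self.mus.shape[1]

    def component(self, k: int) -> ComponentParams:
        return ComponentParams(
            mu=self.mus[k], Sigma=self.Sigmas[k], phi=[p[k] for p in self.phis]
        )


def _gauss_marginal_logpdf(x: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Log-density of the Gaussian marginal over the supplied dims."""
    p = x.size
    if p == 0:
        return 0.0
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError(
            "covariance sub-matrix is not positive definite"
        ) from exc
    z = np.linalg.solve(L, x - mu)
    return float(-0.5 * (p * _LOG2PI + z @ z) - np.log(np.diag(L)).sum())


def component_logdensity(
    x_cont: np.ndarray | None,
    x_cat: np.ndarray | None,
    params: ComponentParams,
    cont_obs: np.ndarray | None = None,
    cat_obs: np.ndarray | None = None,
) -> float:
    """Log-density of a partially observed profile under one component.

    Unobserved continuous dims are marginalised by sub-vector/sub-matrix
    extraction; unobserved categorical factors are dropped.  ``cont_obs``
    and ``cat_obs`` are boolean observed-masks (default: all observed).
    """
    total = 0.0
    if x_cont is not None:
        x_cont = np.asarray(x_cont, dtype=float).reshape(-1)
        obs = np.ones(params.mu.size, bool) if cont_obs is None else np.asarray(cont_obs, bool)
        idx = np.flatnonzero(obs)
        if idx.size:
            try:
                total += _gauss_marginal_logpdf(
                    x_cont[idx], params.mu[idx], params.Sigma[np.ix_(idx, idx)]
                )
            except NumericalDegeneracyError as exc:
                raise NumericalDegeneracyError(
                    f"degenerate continuous covariance in component (dims {idx.tolist()})"
                ) from exc
    if x_cat is not None:
        x_cat = np.asarray(x_cat, dtype=int).reshape(-1)
        obs = np.ones(len(params.phi), bool) if cat_obs is None else np.asarray(cat_obs, bool)
        for j in np.flatnonzero(obs):
            total += float(np.log(params.phi[j][x_cat[j]]))
    return total


def mixture_logdensity(
    x_cont: np.ndarray | None,
    x_cat: np.ndarray | None,
    state: DPMMState,
    cont_obs: np.ndarray | None = None,
    cat_obs: np.ndarray | None = None,
) -> float:
    """log sum_k p_k f_k(x), computed with log-sum-exp for stability."""
    logs = np.empty(state.K)
    with np.errstate(divide="ignore"):
        logw = np.log(state.weights)
    for k in range(state.K):
        if np.isneginf(logw[k]):
            logs[k] = -np.inf
            continue
        logs[k] = logw[k] + component_logdensity(
            x_cont, x_cat, state.component(k), cont_obs, cat_obs
        )
    return float(logsumexp(logs))


def _batch_gauss_logpdf(X: np.ndarray, mus: np.ndarray, Sigmas: np.ndarray) -> np.ndarray:
    """(n, K) log-densities of complete rows X under K Gaussians."""
    n, p = X.shape
    K = mus.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        try:
            L = np.linalg.cholesky(Sigmas[k])
        except np.linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                f"degenerate continuous covariance in component {k}"
            ) from exc
        z = np.linalg.solve(L, (X - mus[k]).T)
        out[:, k] = -0.5 * (p * _LOG2PI + (z * z).sum(axis=0)) - np.log(np.diag(L)).sum()
    return out


def allocation_logweights(
    x_cont: np.ndarray, x_cat: np.ndarray, state: DPMMState
) -> np.ndarray:
    """(n, K) unnormalised log full-conditional weights log p_k + log f_k(x_i).

    Rows must be complete working covariate vectors (observed values plus
    current imputations).  Allocations use covariate information only; the
    outcome is conditionally independent of Z given X.
    """
    x_cont = np.atleast_2d(x_cont)
    with np.errstate(divide="ignore"):
        logw = np.log(state.weights)[None, :].repeat(x_cont.shape[0], axis=0)
    if x_cont.shape[1]:
        logw = logw + _batch_gauss_logpdf(x_cont, state.mus, state.Sigmas)
    x_cat = np.atleast_2d(x_cat)
    with np.errstate(divide="ignore"):
        for j, phi in enumerate(state.phis):
            logw = logw + np.log(phi[:, x_cat[:, j]]).T
    return logw


def sample_allocations(
    state: DPMMState,
    x_cont: np.ndarray,
    x_cat: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw Z_i from its categorical full conditional, independently per row."""
    logw = allocation_logweights(x_cont, x_cat, state)
    finite = np.isfinite(logw)
    if not finite.any(axis=1).all():
        raise NumericalDegeneracyError(
            "all component conditional weights underflowed for some row; "
            "consider standardising the continuous covariates"
        )
    g = rng.gumbel(size=logw.shape)
    return np.argmax(np.where(finite, logw + g, -np.inf), axis=1)


def update_stick_weights(
    alloc: np.ndarray, alpha: float, K: int, rng: np.random.Generator
) -> np.ndarray:
    """Truncated stick-breaking posterior: V_k ~ Beta(1 + n_k, alpha + n_{>k})."""
    counts = np.bincount(alloc, minlength=K).astype(float)
    tail = counts[::-1].cumsum()[::-1]
    a = 1.0 + counts[: K - 1]
    b = alpha + tail[1:]
    v = rng.beta(a, b)
    return np.clip(v, 1e-12, 1.0 - 1e-12)


def update_component_params(
    alloc: np.ndarray,
    x_cont: np.ndarray,
    x_cat: np.ndarray,
    priors: DPMMPriors,
    K: int,
    n_levels: list[int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Conjugate posterior draw of every component's (mu, Sigma, phi).

    Gaussian parameters come from the Normal-inverse-Wishart posterior of
    each component's allocated rows; categorical parameters from the
    Dirichlet posterior of allocated category counts.  Empty components
    draw from the prior.
    """
    p = priors.m0.size
    mus = np.empty((K, p))
    Sigmas = np.empty((K, p, p))
    x_cont = np.atleast_2d(x_cont)
    for k in range(K):
        rows = x_cont[alloc == k] if x_cont.shape[1] else np.empty((0, 0))
        nk = rows.shape[0] if p else 0
        if p == 0:
            continue
        kappa_n = priors.kappa0 + nk
        nu_n = priors.nu0 + nk
        if nk:
            xbar = rows.mean(axis=0)
            diff = rows - xbar
            scatter = diff.T @ diff
            dm = xbar - priors.m0
            S_n = priors.S0 + scatter + (priors.kappa0 * nk / kappa_n) * np.outer(dm, dm)
            m_n = (priors.kappa0 * priors.m0 + nk * xbar) / kappa_n
        else:
            S_n = priors.S0
            m_n = priors.m0
        Sigma = stats.invwishart.rvs(df=nu_n, scale=S_n, random_state=rng)
        Sigma = np.atleast_2d(Sigma)
        Sigma = 0.5 * (Sigma + Sigma.T)
        L = np.linalg.cholesky(Sigma)
        mus[k] = m_n + (L @ rng.standard_normal(p)) / np.sqrt(kappa_n)
        Sigmas[k] = Sigma
    phis: list[np.ndarray] = []
    x_cat = np.atleast_2d(x_cat)
    for j, kj in enumerate(n_levels):
        phi = np.empty((K, kj))
        for k in range(K):
            codes = x_cat[alloc == k, j]
            counts = np.bincount(codes, minlength=kj).astype(float)
            phi[k] = rng.dirichlet(priors.dirichlet_conc + counts)
        phis.append(phi)
    return mus, Sigmas, phis


def update_concentration(
    alpha: float, sticks: np.ndarray, priors: DPMMPriors, rng: np.random.Generator
) -> float:
    """Gamma conditional implied by the truncated stick-breaking likelihood.

    alpha | V ~ Gamma(a + K - 1, b - sum_{k<K} log(1 - V_k)).  Returns the
    input unchanged in fixed-alpha mode.
    """
    if priors.fixed_alpha is not None:
        return alpha
    sticks = np.asarray(sticks, dtype=float)
    if np.any(sticks >= 1.0) or np.any(sticks <= 0.0):
        raise ValueError("stick fractions must lie strictly in (0, 1)")
    shape = priors.alpha_shape + sticks.size
    rate = priors.alpha_rate - np.log1p(-sticks).sum()
    return float(rng.gamma(shape, 1.0 / rate))


def label_swap_moves(
    state: DPMMState, rng: np.random.Generator, n_moves: int | None = None
) -> DPMMState:
    """Metropolis label-swap moves between neighbouring components.

    The truncated stick-breaking representation is not exchangeable in the
    component labels: the same clustering carries different stick
    configurations (and hence a different conditional for alpha) depending
    on where the occupied labels sit.  Plain blocked Gibbs never moves
    labels, so chains can freeze in arbitrary arrangements.  These two
    standard moves — swapping the full state of components (k, k+1)
    including their stick fractions, or swapping labels only — let labels
    drift toward the size-biased ordering and restore mixing of the
    weights and the concentration.  Both are exact Metropolis moves on the
    joint posterior.
    """
    K = state.K
    if K < 2:
        return state
    if n_moves is None:
        n_moves = K - 1
    counts = np.bincount(state.alloc, minlength=K)
    with np.errstate(divide="ignore"):
        logw = np.log(state.weights)
    for _ in range(n_moves):
        k = int(rng.integers(K - 1))
        swap_sticks = k + 1 <= K - 2 and rng.uniform() < 0.5
        if swap_sticks:
            # swap (theta, allocations, V_k <-> V_{k+1}); only the two
            # weight-likelihood terms change
            vk, vk1 = state.sticks[k], state.sticks[k + 1]
            log_ratio = counts[k] * np.log1p(-vk1) - counts[k + 1] * np.log1p(-vk)
        elif counts[k] == counts[k + 1]:
            log_ratio = 0.0
        else:
            # swap theta and allocations only, sticks stay put
            log_ratio = (counts[k + 1] - counts[k]) * (logw[k] - logw[k + 1])
        if np.log(rng.uniform()) < log_ratio:
            state.mus[[k, k + 1]] = state.mus[[k + 1, k]]
            state.Sigmas[[k, k + 1]] = state.Sigmas[[k + 1, k]]
            for phi in state.phis:
                phi[[k, k + 1]] = phi[[k + 1, k]]
            sel_k = state.alloc == k
            sel_k1 = state.alloc == k + 1
            state.alloc[sel_k] = k + 1
            state.alloc[sel_k1] = k
            counts[[k, k + 1]] = counts[[k + 1, k]]
            if swap_sticks:
                state.sticks[[k, k + 1]] = state.sticks[[k + 1, k]]
                state.weights = stick_weights_from_fractions(state.sticks)
                with np.errstate(divide="ignore"):
                    logw = np.log(state.weights)
    return state


def conditional_gaussian(
    mu: np.ndarray,
    Sigma: np.ndarray,
    obs_idx: np.ndarray,
    obs_values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional of the missing dims of N(mu, Sigma) given observed dims.

    Returns ``(mu_m + S_mo S_oo^-1 (x_o - mu_o), S_mm - S_mo S_oo^-1 S_om)``;
    with no observed dims, the marginal ``(mu_m, S_mm)``.  The returned
    covariance is symmetrised.
    """
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = mu.size
    obs_idx = np.asarray(obs_idx, dtype=int).reshape(-1)
    miss_idx = np.setdiff1d(np.arange(p), obs_idx)
    if miss_idx.size == 0:
        raise ValueError("no missing dims to condition on")
    if obs_idx.size == 0:
        return mu[miss_idx].copy(), Sigma[np.ix_(miss_idx, miss_idx)].copy()
    Soo = Sigma[np.ix_(obs_idx, obs_idx)]
    Smo = Sigma[np.ix_(miss_idx, obs_idx)]
    Smm = Sigma[np.ix_(miss_idx, miss_idx)]
    try:
        L = np.linalg.cholesky(Soo)
    except np.linalg.LinAlgError as exc:
        raise NumericalDegeneracyError("observed-dim covariance block is singular") from exc
    w = np.linalg.solve(L, (np.asarray(obs_values, dtype=float) - mu[obs_idx]))
    A = np.linalg.solve(L, Smo.T)  # (o, m)
    mean = mu[miss_idx] + A.T @ w
    cov = Smm - A.T @ A
    return mean, 0.5 * (cov + cov.T)
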