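"""Mixture density evaluation and the conjugate Gibbs blocks of the DPMM."""

import numpy as np
import pytest
from scipy import stats

from dpmselect.dpmm import (
    ComponentParams,
    DPMMPriors,
    DPMMState,
    allocation_logweights,
    component_logdensity,
    conditional_gaussian,
    mixture_logdensity,
    NumericalDegeneracyError,
    sample_allocations,
    stick_weights_from_fractions,
    update_component_params,
    update_concentration,
    update_stick_weights,
)


def _sticks_for_weights(w):
    """Invert the stick-breaking map so a state realises given weights."""
    w = np.asarray(w, dtype=float)
    v = np.empty(w.size - 1)
    rem = 1.0
    for k in range(w.size - 1):
        v[k] = min(max(w[k] / rem, 1e-14), 1 - 1e-14)
        rem *= 1 - v[k]
    return v


def _random_state(rng, K=3, jc=2, levels=(3,), n=4):
    mus = rng.normal(size=(K, jc))
    Sigmas = np.empty((K, jc, jc))
    for k in range(K):
        A = rng.normal(size=(jc, jc))
        Sigmas[k] = A @ A.T + jc * np.eye(jc)
    phis = [rng.dirichlet(np.ones(L), size=K) for L in levels]
    w = rng.dirichlet(np.ones(K))
    return DPMMState(
        sticks=_sticks_for_weights(w),
        mus=mus,
        Sigmas=Sigmas,
        phis=phis,
        alloc=rng.integers(0, K, n),
        alpha=1.0,
    )


def test_component_logdensity_standard_normal_at_mode():
    p = ComponentParams(mu=np.zeros(1), Sigma=np.eye(1), phi=[])
    val = component_logdensity(np.zeros(1), None, p)
    assert val == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-10)
    assert val == pytest.approx(-0.91894, abs=1e-5)


def test_component_logdensity_categorical_lookup():
    p = ComponentParams(mu=np.empty(0), Sigma=np.empty((0, 0)), phi=[np.array([0.2, 0.8])])
    assert component_logdensity(None, np.array([1]), p) == pytest.approx(np.log(0.8))


def test_component_logdensity_marginalises_missing_dims():
    rng = np.random.default_rng(1)
    A = rng.normal(size=(3, 3))
    Sigma = A @ A.T + 3 * np.eye(3)
    mu = rng.normal(size=3)
    p = ComponentParams(mu=mu, Sigma=Sigma, phi=[])
    x = rng.normal(size=3)
    obs = np.array([True, False, True])
    got = component_logdensity(x, None, p, cont_obs=obs)
    # brute-force marginal by explicit sub-matrix extraction
    idx = [0, 2]
    ref = stats.multivariate_normal.logpdf(x[idx], mu[idx], Sigma[np.ix_(idx, idx)])
    assert got == pytest.approx(ref, abs=1e-10)


def test_mixture_reduces_to_single_component():
    rng = np.random.default_rng(2)
    state = _random_state(rng, K=1, jc=2, levels=(3,), n=1)
    x, c = rng.normal(size=2), np.array([1])
    assert mixture_logdensity(x, c, state) == pytest.approx(
        component_logdensity(x, c, state.component(0)), abs=1e-10
    )


def test_mixture_with_degenerate_weights_equals_first_component():
    rng = np.random.default_rng(3)
    state = _random_state(rng, K=3, jc=2, levels=(3,))
    state.sticks = _sticks_for_weights([1 - 2e-14, 1e-14, 1e-14])
    state.weights = stick_weights_from_fractions(state.sticks)
    x, c = rng.normal(size=2), np.array([0])
    assert mixture_logdensity(x, c, state) == pytest.approx(
        component_logdensity(x, c, state.component(0)), abs=1e-9
    )


def test_mixture_matches_naive_summation():
    rng = np.random.default_rng(4)
    state = _random_state(rng, K=3, jc=2, levels=(3,))
    x, c = rng.normal(size=2), np.array([2])
    naive = np.log(
        sum(
            state.weights[k] * np.exp(component_logdensity(x, c, state.component(k)))
            for k in range(3)
        )
    )
    got = mixture_logdensity(x, c, state)
    assert got == pytest.approx(naive, rel=1e-10)


def test_mixture_invariant_under_component_permutation():
    rng = np.random.default_rng(5)
    state = _random_state(rng, K=3, jc=2, levels=(3,))
    x, c = rng.normal(size=2), np.array([1])
    base = mixture_logdensity(x, c, state)
    perm = np.array([2, 0, 1])
    permuted = DPMMState(
        sticks=_sticks_for_weights(state.weights[perm]),
        mus=state.mus[perm],
        Sigmas=state.Sigmas[perm],
        phis=[p[perm] for p in state.phis],
        alloc=state.alloc,
        alpha=state.alpha,
    )
    assert mixture_logdensity(x, c, permuted) == pytest.approx(base, abs=1e-9)


def test_logsumexp_stable_for_extreme_logdensities():
    state = DPMMState(
        sticks=np.array([0.5]),
        mus=np.array([[0.0], [600.0]]),
        Sigmas=np.tile(np.eye(1) * 0.25, (2, 1, 1)),
        phis=[],
        alloc=np.zeros(1, dtype=int),
        alpha=1.0,
    )
    val = mixture_logdensity(np.array([0.0]), None, state)
    assert np.isfinite(val)


def test_allocation_excludes_zero_support_component():
    state = DPMMState(
        sticks=np.array([0.5]),
        mus=np.zeros((2, 1)),
        Sigmas=np.tile(np.eye(1), (2, 1, 1)),
        phis=[np.array([[0.5, 0.5], [1.0, 0.0]])],
        alloc=np.zeros(1, dtype=int),
        alpha=1.0,
    )
    rng = np.random.default_rng(6)
    z = sample_allocations(state, np.zeros((200, 1)), np.ones((200, 1), dtype=int), rng)
    assert np.all(z == 0)


def test_allocation_frequencies_match_exact_conditional():
    rng = np.random.default_rng(7)
    state = _random_state(rng, K=3, jc=2, levels=(3,))
    x, c = rng.normal(size=2), np.array([1])
    logw = allocation_logweights(x[None, :], c[None, :], state)[0]
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    n = 100_000
    z = sample_allocations(
        state, np.tile(x, (n, 1)), np.tile(c, (n, 1)), np.random.default_rng(8)
    )
    for k in range(3):
        se = np.sqrt(probs[k] * (1 - probs[k]) / n)
        assert abs((z == k).mean() - probs[k]) < 4 * se


def test_single_component_allocates_everything():
    rng = np.random.default_rng(9)
    state = _random_state(rng, K=1, jc=1, levels=(2,))
    z = sample_allocations(state, rng.normal(size=(50, 1)), np.zeros((50, 1), int), rng)
    assert np.all(z == 0)


def test_stick_posterior_beta_moments():
    alloc = np.array([0] * 3 + [1] * 2)
    rng = np.random.default_rng(10)
    draws = np.array([update_stick_weights(alloc, 1.0, 3, rng) for _ in range(20000)])
    # V1 ~ Beta(4, 3), V2 ~ Beta(3, 1)
    for j, (a, b) in enumerate([(4, 3), (3, 1)]):
        mean = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        se = np.sqrt(var / draws.shape[0])
        assert abs(draws[:, j].mean() - mean) < 4 * se


def test_stick_weights_sum_to_one():
    rng = np.random.default_rng(11)
    v = update_stick_weights(rng.integers(0, 5, 100), 0.7, 5, rng)
    assert abs(stick_weights_from_fractions(v).sum() - 1.0) < 1e-12


def test_concentrated_allocation_with_small_alpha_gives_weight_one():
    alloc = np.zeros(500, dtype=int)
    rng = np.random.default_rng(12)
    v = np.array([update_stick_weights(alloc, 1e-6, 3, rng) for _ in range(200)])
    w1 = np.array([stick_weights_from_fractions(x)[0] for x in v])
    assert w1.mean() > 0.99


def test_empty_component_draws_from_prior():
    priors = DPMMPriors(m0=np.zeros(1), kappa0=0.5, nu0=5.0, S0=np.eye(1))
    rng = np.random.default_rng(13)
    mus = np.array(
        [
            update_component_params(
                np.full(0, -1), np.empty((0, 1)), np.empty((0, 0), int),
                priors, 1, [], rng,
            )[0][0, 0]
            for _ in range(4000)
        ]
    )
    # marginal prior: mu ~ m0 + t-like; mean m0, var E[Sigma]/kappa0 = S0/(nu0-2)/kappa0
    var = 1.0 / (5.0 - 2.0) / 0.5
    assert abs(mus.mean()) < 4 * np.sqrt(var / mus.size)


def test_niw_posterior_mean_closed_form():
    rng = np.random.default_rng(14)
    x = rng.normal(loc=2.0, scale=1.5, size=(300, 1))
    priors = DPMMPriors(m0=np.zeros(1), kappa0=0.1, nu0=3.0, S0=np.eye(1))
    alloc = np.zeros(300, dtype=int)
    draws = np.array(
        [
            update_component_params(alloc, x, np.empty((300, 0), int), priors, 1, [], rng)[0][0, 0]
            for _ in range(3000)
        ]
    )
    m_n = (0.1 * 0.0 + 300 * x.mean()) / (0.1 + 300)
    post_sd = draws.std()
    assert abs(draws.mean() - m_n) < 3 * post_sd / np.sqrt(draws.size) + 1e-3


def test_dirichlet_posterior_mean():
    rng = np.random.default_rng(15)
    codes = np.array([0] * 7 + [1] * 3)[:, None]
    priors = DPMMPriors(m0=np.empty(0), dirichlet_conc=1.0)
    draws = np.array(
        [
            update_component_params(
                np.zeros(10, int), np.empty((10, 0)), codes, priors, 1, [2], rng
            )[2][0][0]
            for _ in range(5000)
        ]
    )
    mean = draws[:, 0].mean()
    se = draws[:, 0].std() / np.sqrt(draws.shape[0])
    assert abs(mean - 8 / 12) < 3 * se + 1e-3


def test_concentration_fixed_mode_is_identity():
    priors = DPMMPriors(m0=np.zeros(1), fixed_alpha=0.7)
    assert update_concentration(0.7, np.array([0.3]), priors, np.random.default_rng(0)) == 0.7


def test_concentration_conditional_gamma_moments():
    priors = DPMMPriors(m0=np.zeros(1), alpha_shape=2.0, alpha_rate=1.0)
    sticks = np.array([0.3, 0.6, 0.1])
    rng = np.random.default_rng(16)
    draws = np.array([update_concentration(1.0, sticks, priors, rng) for _ in range(20000)])
    shape = 2.0 + 3
    rate = 1.0 - np.log1p(-sticks).sum()
    mean = shape / rate
    se = np.sqrt(shape) / rate / np.sqrt(draws.size)
    assert abs(draws.mean() - mean) < 3 * se
    # near-zero sticks: conditional approaches the Gamma(a + K - 1, b) limit
    tiny = np.array([1e-12, 1e-12, 1e-12])
    d2 = np.array([update_concentration(1.0, tiny, priors, rng) for _ in range(20000)])
    assert abs(d2.mean() - 5.0) < 3 * np.sqrt(5.0) / np.sqrt(d2.size)


def test_concentration_invalid_sticks_rejected():
    priors = DPMMPriors(m0=np.zeros(1))
    with pytest.raises(ValueError):
        update_concentration(1.0, np.array([1.0]), priors, np.random.default_rng(0))


def test_conditional_gaussian_diagonal_is_marginal():
    mu = np.array([1.0, -2.0])
    Sigma = np.diag([2.0, 5.0])
    mean, cov = conditional_gaussian(mu, Sigma, np.array([1]), np.array([100.0]))
    assert mean == pytest.approx(np.array([1.0]))
    assert cov == pytest.approx(np.array([[2.0]]))


def test_conditional_gaussian_bivariate_closed_form():
    rho = 0.6
    Sigma = np.array([[1.0, rho], [rho, 1.0]])
    x2 = 1.7
    mean, cov = conditional_gaussian(np.zeros(2), Sigma, np.array([1]), np.array([x2]))
    assert mean[0] == pytest.approx(rho * x2)
    assert cov[0, 0] == pytest.approx(1 - rho**2)


def test_conditional_gaussian_no_observed_dims_returns_marginal():
    mu = np.array([1.0, 2.0, 3.0])
    Sigma = np.diag([1.0, 2.0, 3.0]) + 0.1
    mean, cov = conditional_gaussian(mu, Sigma, np.empty(0, int), np.empty(0))
    assert np.allclose(mean, mu)
    assert np.allclose(cov, Sigma)


def test_conditional_gaussian_singular_block_raises():
    Sigma = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(NumericalDegeneracyError):
        conditional_gaussian(np.zeros(3), Sigma, np.array([0, 1]), np.array([0.0, 0.0]))


def test_phi_rows_always_sum_to_one_after_update():
    rng = np.random.default_rng(18)
    codes = rng.integers(0, 3, size=(50, 1))
    priors = DPMMPriors(m0=np.empty(0))
    _, _, phis = update_component_params(
        rng.integers(0, 4, 50), np.empty((50, 0)), codes, priors, 4, [3], rng
    )
    assert np.allclose(phis[0].sum(axis=1), 1.0, atol=1e-12)
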