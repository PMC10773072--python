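"""Missing-covariate samplers: cancellation identity, conjugate oracle, locality."""

import numpy as np
import pytest
from scipy import stats

from dpmselect.data import ColumnSchema
from dpmselect.dpmm import DPMMState
from dpmselect.missing import (
    ImputationState,
    TrainingContext,
    sample_missing_categorical,
    sample_missing_continuous,
    sweep_missing,
)
from dpmselect.outcome import RegressionState, SplineSpec


def _cont_toy(c=1.0, y0=2.0, sigma=1.0, m=0.0, s2=1.0):
    """One individual, one continuous covariate (missing), K=1, linear basis.

    The full conditional for the missing value is Gaussian in closed form:
    precision 1/s2 + c^2/sigma^2, mean = var * (m/s2 + c*(y0 - b0)/sigma^2).
    """
    schema = ColumnSchema(continuous=["x"], categorical={}, treatment="t", outcome="y")
    ctx = TrainingContext(
        schema=schema,
        spec=SplineSpec({"x": np.empty(0)}),
        y=np.array([y0]),
        treatment=np.array([0]),
        miss_cont=np.array([[True]]),
        miss_cat=np.empty((1, 0), dtype=bool),
    )
    state = DPMMState(
        sticks=np.empty(0),
        mus=np.array([[m]]),
        Sigmas=np.array([[[s2]]]),
        phis=[],
        alloc=np.array([0]),
        alpha=1.0,
    )
    # design columns: intercept, treat, x, treat:x
    reg = RegressionState(beta0=0.0, beta=np.array([0.0, c, 0.0]), sigma=sigma)
    imp = ImputationState(x_cont=np.array([[0.0]]), x_cat=np.empty((1, 0), dtype=int))
    return state, reg, imp, ctx


def test_zero_coefficients_make_acceptance_exactly_one():
    state, reg, imp, ctx = _cont_toy(c=0.0)
    rng = np.random.default_rng(0)
    draws = np.array(
        [sample_missing_continuous(0, state, reg, imp, ctx, rng)[0] for _ in range(4000)]
    )
    assert imp.n_accept[0] == imp.n_prop[0] == 4000
    # exact draws from the DPMM conditional (here the N(0,1) marginal)
    assert stats.kstest(draws, "norm").pvalue > 0.01


def test_mh_chain_matches_conjugate_closed_form():
    c, y0, sigma = 1.0, 2.0, 1.0
    state, reg, imp, ctx = _cont_toy(c=c, y0=y0, sigma=sigma)
    prec = 1.0 + c**2 / sigma**2
    post_var = 1.0 / prec
    post_mean = post_var * (0.0 + c * y0 / sigma**2)
    rng = np.random.default_rng(1)
    draws = []
    for _ in range(40000):
        sample_missing_continuous(0, state, reg, imp, ctx, rng)
        draws.append(imp.x_cont[0, 0])
    draws = np.asarray(draws[2000:])
    # independence-proposal chain: effective size conservatively n/10
    se_mean = draws.std() / np.sqrt(draws.size / 10)
    assert abs(draws.mean() - post_mean) < 4 * se_mean
    assert abs(draws.var() - post_var) < 0.06


def test_informative_outcome_concentrates_near_solution():
    # steep slope, tiny residual SD: imputations solve y = c * x
    c, y0, sigma = 4.0, 2.0, 0.05
    state, reg, imp, ctx = _cont_toy(c=c, y0=y0, sigma=sigma)
    prec = 1.0 + c**2 / sigma**2
    post_var = 1.0 / prec
    post_mean = post_var * (c * y0 / sigma**2)
    # grid-quadrature oracle over the true (unnormalised) conditional
    grid = np.linspace(-3, 3, 20001)
    logp = stats.norm.logpdf(grid) + stats.norm.logpdf(y0, c * grid, sigma)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    grid_mean = float(grid @ w)
    assert grid_mean == pytest.approx(post_mean, abs=1e-6)
    rng = np.random.default_rng(2)
    draws = []
    for _ in range(60000):
        sample_missing_continuous(0, state, reg, imp, ctx, rng)
        draws.append(imp.x_cont[0, 0])
    draws = np.asarray(draws[5000:])
    assert abs(draws.mean() - grid_mean) < 0.02
    assert abs(draws.mean() - c * y0 / (c**2 + sigma**2)) < 0.05  # near y = c*x solution


def _cat_toy(bg=1.0, y0=1.0, sigma=1.0, phi=(0.3, 0.7)):
    schema = ColumnSchema(
        continuous=[], categorical={"g": ["a", "b"]}, treatment="t", outcome="y"
    )
    ctx = TrainingContext(
        schema=schema,
        spec=SplineSpec({}),
        y=np.array([y0]),
        treatment=np.array([0]),
        miss_cont=np.empty((1, 0), dtype=bool),
        miss_cat=np.array([[True]]),
    )
    state = DPMMState(
        sticks=np.empty(0),
        mus=np.empty((1, 0)),
        Sigmas=np.empty((1, 0, 0)),
        phis=[np.array([list(phi)])],
        alloc=np.array([0]),
        alpha=1.0,
    )
    # design columns: intercept, treat, g=b, treat:g=b
    reg = RegressionState(beta0=0.0, beta=np.array([0.0, bg, 0.0]), sigma=sigma)
    imp = ImputationState(x_cont=np.empty((1, 0)), x_cat=np.array([[0]]))
    return state, reg, imp, ctx


def test_categorical_prior_only_case_matches_phi():
    state, reg, imp, ctx = _cat_toy(bg=0.0, phi=(0.3, 0.7))
    rng = np.random.default_rng(3)
    draws = np.array(
        [sample_missing_categorical(0, state, reg, imp, ctx, rng)[0] for _ in range(20000)]
    )
    se = np.sqrt(0.7 * 0.3 / draws.size)
    assert abs(draws.mean() - 0.7) < 4 * se


def test_categorical_two_term_enumeration_oracle():
    bg, y0, sigma, phi = 1.0, 1.0, 1.0, (0.3, 0.7)
    state, reg, imp, ctx = _cat_toy(bg=bg, y0=y0, sigma=sigma, phi=phi)
    # hand-computable two-term normalisation
    w0 = phi[0] * stats.norm.pdf(y0, 0.0, sigma)
    w1 = phi[1] * stats.norm.pdf(y0, bg, sigma)
    p1 = w1 / (w0 + w1)
    rng = np.random.default_rng(4)
    draws = np.array(
        [sample_missing_categorical(0, state, reg, imp, ctx, rng)[0] for _ in range(20000)]
    )
    se = np.sqrt(p1 * (1 - p1) / draws.size)
    assert abs(draws.mean() - p1) < 4 * se


def test_single_category_is_forced():
    state, reg, imp, ctx = _cat_toy(phi=(1.0,))
    state.phis = [np.array([[1.0]])]
    ctx2 = TrainingContext(
        schema=ColumnSchema(
            continuous=[], categorical={"g": ["only"]}, treatment="t", outcome="y"
        ),
        spec=SplineSpec({}),
        y=np.array([1.0]),
        treatment=np.array([0]),
        miss_cont=np.empty((1, 0), dtype=bool),
        miss_cat=np.array([[True]]),
    )
    reg2 = RegressionState(beta0=0.0, beta=np.array([0.0]), sigma=1.0)
    imp2 = ImputationState(x_cont=np.empty((1, 0)), x_cat=np.array([[0]]))
    out = sample_missing_categorical(0, state, reg2, imp2, ctx2, np.random.default_rng(5))
    assert out[0] == 0


def _sweep_setup(miss_pattern):
    rng = np.random.default_rng(6)
    n = 6
    schema = ColumnSchema(
        continuous=["x1", "x2"], categorical={"g": ["a", "b"]}, treatment="t", outcome="y"
    )
    ctx = TrainingContext(
        schema=schema,
        spec=SplineSpec({"x1": np.empty(0), "x2": np.empty(0)}),
        y=rng.normal(size=n),
        treatment=rng.integers(0, 2, n),
        miss_cont=miss_pattern,
        miss_cat=np.zeros((n, 1), dtype=bool),
    )
    state = DPMMState(
        sticks=np.array([0.5]),
        mus=rng.normal(size=(2, 2)),
        Sigmas=np.tile(np.eye(2), (2, 1, 1)),
        phis=[np.array([[0.5, 0.5], [0.2, 0.8]])],
        alloc=rng.integers(0, 2, n),
        alpha=1.0,
    )
    reg = RegressionState(beta0=0.0, beta=rng.normal(size=7), sigma=1.0)
    imp = ImputationState(
        x_cont=rng.normal(size=(n, 2)), x_cat=rng.integers(0, 2, (n, 1))
    )
    return state, reg, imp, ctx


def test_sweep_is_noop_without_missing_cells():
    state, reg, imp, ctx = _sweep_setup(np.zeros((6, 2), dtype=bool))
    before_c, before_d = imp.x_cont.copy(), imp.x_cat.copy()
    sweep_missing(state, reg, imp, ctx, np.random.default_rng(7))
    assert np.array_equal(imp.x_cont, before_c)
    assert np.array_equal(imp.x_cat, before_d)


def test_sweep_only_touches_the_masked_cell():
    mask = np.zeros((6, 2), dtype=bool)
    mask[3, 1] = True
    state, reg, imp, ctx = _sweep_setup(mask)
    before = imp.x_cont.copy()
    for seed in range(5):
        sweep_missing(state, reg, imp, ctx, np.random.default_rng(seed))
    changed = imp.x_cont != before
    assert not changed[~mask].any()


def test_observed_cells_bit_identical_across_many_sweeps():
    mask = np.zeros((6, 2), dtype=bool)
    mask[0, 0] = mask[2, 1] = mask[4, 0] = mask[4, 1] = True
    state, reg, imp, ctx = _sweep_setup(mask)
    before = imp.x_cont.copy()
    rng = np.random.default_rng(8)
    for _ in range(50):
        sweep_missing(state, reg, imp, ctx, rng)
    assert np.array_equal(imp.x_cont[~mask], before[~mask])


def test_independence_mh_acceptance_rule_satisfies_detailed_balance():
    # two-point discretisation: proposal q from the covariate model, target
    # pi propto q * L; transition matrix of the accept rule leaves pi invariant
    q = np.array([0.4, 0.6])
    L = np.array([0.9, 0.1])
    pi = q * L / (q * L).sum()
    P = np.zeros((2, 2))
    for a in range(2):
        for b in range(2):
            if a != b:
                P[a, b] = q[b] * min(1.0, L[b] / L[a])
        P[a, a] = 1.0 - P[a].sum()
    assert np.allclose(pi @ P, pi, atol=1e-12)
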