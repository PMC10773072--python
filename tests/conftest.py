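"""Shared fixtures: small fitted models and the full-size default-scenario fit.

The expensive fixtures are session-scoped so the recovery, calibration,
convergence and decision-support checks all reuse one MCMC run each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import dpmselect as dps
from dpmselect.inference import MCMCConfig, run_mcmc
from dpmselect.synthetic import apply_missingness, default_scenario, generate_population


@pytest.fixture(scope="session")
def default_cfg():
    """The packaged 3-component scenario at its stated size (n=1000, 20% MAR)."""
    return default_scenario()


@pytest.fixture(scope="session")
def default_data(default_cfg):
    return apply_missingness(generate_population(default_cfg), default_cfg)


@pytest.fixture(scope="session")
def default_fit(default_data):
    """Full-size fit: K=20, 2 chains x 4000 iterations (2000 burn-in)."""
    mc = MCMCConfig(
        n_chains=2, n_iterations=4000, n_burnin=2000, thin=1, seed=11, K=20
    )
    return run_mcmc(default_data, mc)


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced copy of the default scenario for fast unit-level fits."""
    cfg = default_scenario(n=250, seed=7)
    return cfg


@pytest.fixture(scope="session")
def small_data(small_cfg):
    return apply_missingness(generate_population(small_cfg), small_cfg)


@pytest.fixture(scope="session")
def small_fit(small_data):
    mc = MCMCConfig(n_chains=2, n_iterations=700, n_burnin=300, seed=5, K=8)
    return run_mcmc(small_data, mc)


@pytest.fixture()
def simple_cfg():
    """Single-component, two-covariate toy generator for targeted unit tests."""
    schema = dps.ColumnSchema(
        continuous=["x1", "x2"],
        categorical={"g": ["a", "b"]},
        treatment="treat",
        outcome="y",
    )
    return dps.GeneratorConfig(
        schema=schema,
        n_individuals=200,
        component_weights=np.array([1.0]),
        component_means=np.array([[0.0, 0.0]]),
        component_covariances=np.array([[[1.0, 0.3], [0.3, 1.0]]]),
        component_category_probs={"g": np.array([[0.6, 0.4]])},
        true_beta=dps.TrueBeta(
            intercept=1.0,
            treatment=-2.0,
            continuous={"x1": 1.5, "x2": -0.5},
            categorical={"g": [0.8]},
            treat_continuous={"x1": 0.7, "x2": 0.0},
            treat_categorical={"g": [-0.4]},
        ),
        true_sigma=1.0,
        treatment_assignment_prob=0.5,
        seed=3,
    )


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
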