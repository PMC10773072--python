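"""Treatment-selection regression: restricted cubic splines and conjugate updates.

The outcome model is a Gaussian linear regression

    Y_i = beta_0 + beta_1 T_i + beta_2 X^D_i + beta_3 S(X^C_i)
          + beta_4 T_i X^D_i + beta_5 T_i S(X^C_i) + eps_i,   eps_i ~ N(0, sigma^2)

where S() places a restricted (natural) cubic spline basis on every
continuous predictor and each block interacts with the binary treatment
indicator T, so that treatment effects vary with patient characteristics.
Coefficients carry a shared zero-mean Gaussian (ridge) prior with scale
``tau`` (intercept unpenalised), and sigma carries a half-Cauchy prior by
default (inverse-gamma conjugate option for exactness tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data import ColumnSchema

__all__ = [
    "SplineSpec",
    "RegressionState",
    "RegressionPriors",
    "fit_spline_spec",
    "rcs_basis",
    "design_row",
    "build_design_matrix",
    "design_column_names",
    "outcome_loglik",
    "update_regression",
]

# Harrell-convention quantile locations per knot count
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass
class SplineSpec:
    """Frozen knot locations per continuous covariate.

    ``knots[col]`` is a strictly increasing array; an *empty* array selects
    the pure-linear fallback (basis = the covariate itself, one column).
    """

    knots: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.knots = {c: np.asarray(k, dtype=float) for c, k in self.knots.items()}
        for col, k in self.knots.items():
            if k.size and not np.all(np.diff(k) > 0):
                raise ValueError(f"knots for {col!r} must be strictly increasing")
            if k.size in (1, 2):
                raise ValueError(f"column {col!r}: need >= 3 knots (or none for linear)")

    def n_basis(self, col: str) -> int:
        k = self.knots[col]
        return 1 if k.size == 0 else k.size - 1

    def to_dict(self) -> dict[str, list[float]]:
        return {c: [float(v) for v in k] for c, k in self.knots.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls({c: np.asarray(k, dtype=float) for c, k in d.items()})


@dataclass
class RegressionState:
    """Intercept + coefficient vector (design order, sans intercept) + residual SD."""

    beta0: float
    beta: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def coef(self) -> np.ndarray:
        """Full coefficient vector including the intercept, aligned to design rows."""
        return np.concatenate([[self.beta0], self.beta])


@dataclass
class RegressionPriors:
    """Weakly informative regularising priors for the regression block.

    tau is the shared ridge scale on standardised response/covariates;
    sigma_prior is ``("half_cauchy", scale)`` or ``("inv_gamma", a, b)``.
    """

    tau: float = 2.5
    sigma_prior: tuple = ("half_cauchy", 5.0)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        kind = self.sigma_prior[0]
        if kind not in ("half_cauchy", "inv_gamma"):
            raise ValueError(f"unknown sigma prior {kind!r}")
        if any(v <= 0 for v in self.sigma_prior[1:]):
            raise ValueError("sigma prior hyperparameters must be positive")


def fit_spline_spec(
    columns: dict[str, np.ndarray], n_knots: int | dict[str, int] = 3
) -> SplineSpec:
    """Place knots at the standard quantiles of the observed training values.

    ``n_knots`` of 0 selects the linear fallback for that column.  Knots are
    computed once from observed (non-missing) values and frozen thereafter.
    """
    knots: dict[str, np.ndarray] = {}
    for col, x in columns.items():
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        nk = n_knots[col] if isinstance(n_knots, dict) else n_knots
        if nk == 0:
            knots[col] = np.empty(0)
            continue
        if nk not in _KNOT_QUANTILES:
            raise ValueError(f"unsupported knot count {nk}; use 0 (linear) or 3/4/5")
        if np.unique(x).size < nk:
            raise ValueError(f"column {col!r} has fewer than {nk} distinct values")
        k = np.quantile(x, _KNOT_QUANTILES[nk])
        if not np.all(np.diff(k) > 0):
            raise ValueError(
                f"tied quantiles for column {col!r}; try fewer knots or the linear fallback"
            )
        knots[col] = k
    return SplineSpec(knots)


def rcs_basis(x: np.ndarray | float, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis, shape ``(..., len(knots)-1)``.

    First column is x itself; the remaining columns are the natural-spline
    cubic terms, normalised by the squared boundary-knot span, linear beyond
    the boundary knots (zero second derivative outside them).  With no
    knots the basis is the single column x.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    if k.size == 0:
        return x[..., None]
    nk = k.size
    cols = [x]
    denom = (k[-1] - k[0]) ** 2
    r = k[-1] - k[-2]

    def cube(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    for j in range(nk - 2):
        term = (
            cube(x - k[j])
            - cube(x - k[-2]) * (k[-1] - k[j]) / r
            + cube(x - k[-1]) * (k[-2] - k[j]) / r
        )
        cols.append(term / denom)
    return np.stack(cols, axis=-1)


def design_column_names(schema: ColumnSchema, spec: SplineSpec) -> list[str]:
    """Stable, documented column order for design rows.

    Order: intercept, treatment, categorical dummies (first level is the
    reference), spline basis columns per continuous covariate, then the
    treatment interactions with the same dummy and spline columns.
    """
    names = ["intercept", "treat"]
    main: list[str] = []
    for col, levels in schema.categorical.items():
        main += [f"{col}={lv}" for lv in levels[1:]]
    for col in schema.continuous:
        main += [f"{col}_s{j}" for j in range(spec.n_basis(col))]
    names += main
    names += [f"treat:{m}" for m in main]
    return names


def build_design_matrix(
    x_cont: np.ndarray,
    x_cat: np.ndarray,
    treatment: np.ndarray,
    spec: SplineSpec,
    schema: ColumnSchema,
) -> np.ndarray:
    """Design matrix for complete covariate rows; shape ``(n, p)``.

    Row layout follows :func:`design_column_names`.
    """
    x_cont = np.atleast_2d(np.asarray(x_cont, dtype=float))
    x_cat = np.atleast_2d(np.asarray(x_cat, dtype=int))
    t = np.asarray(treatment, dtype=float).reshape(-1)
    n = x_cont.shape[0]
    blocks = []
    for j, (col, levels) in enumerate(schema.categorical.items()):
        codes = x_cat[:, j]
        if codes.size and (codes.min() < 0 or codes.max() >= len(levels)):
            bad = int(codes.max() if codes.max() >= len(levels) else codes.min())
            raise ValueError(f"unseen category code {bad} for covariate {col!r}")
        dummies = np.zeros((n, len(levels) - 1))
        for lv in range(1, len(levels)):
            dummies[:, lv - 1] = codes == lv
        blocks.append(dummies)
    for j, col in enumerate(schema.continuous):
        blocks.append(rcs_basis(x_cont[:, j], spec.knots[col]))
    main = np.concatenate(blocks, axis=1) if blocks else np.zeros((n, 0))
    ones = np.ones((n, 1))
    tcol = t[:, None]
    return np.concatenate([ones, tcol, main, tcol * main], axis=1)


def design_row(
    x_cont: Sequence[float],
    x_cat: Sequence[int],
    treatment: int,
    spec: SplineSpec,
    schema: ColumnSchema,
) -> np.ndarray:
    """Design row for a single complete profile (treatment in {0, 1})."""
    if treatment not in (0, 1):
        raise ValueError("treatment must be 0 or 1")
    return build_design_matrix(
        np.asarray(x_cont, dtype=float)[None, :],
        np.asarray(x_cat, dtype=int)[None, :],
        np.array([treatment]),
        spec,
        schema,
    )[0]


def outcome_loglik(y: float | np.ndarray, row: np.ndarray, state: RegressionState) -> float | np.ndarray:
    """Gaussian log-density of y at mean = row . (beta0, beta), SD sigma."""
    mu = np.asarray(row) @ state.coef
    return stats.norm.logpdf(y, loc=mu, scale=state.sigma)


def _draw_coefficients(
    X: np.ndarray, y: np.ndarray, sigma: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw (beta0, beta) from the Gaussian conditional of the ridge model.

    Prior precision is 1/tau^2 on every coefficient except the (flat)
    intercept; the conditional mean is the ridge estimator
    (X'X + sigma^2 D)^{-1} X'y.
    """
    p = X.shape[1]
    d = np.full(p, 1.0 / tau**2)
    d[0] = 0.0  # intercept unpenalised
    prec = X.T @ X / sigma**2 + np.diag(d)
    L = np.linalg.cholesky(prec)
    rhs = X.T @ y / sigma**2
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(p)
    return mean + np.linalg.solve(L.T, z)


def update_regression(
    X: np.ndarray,
    y: np.ndarray,
    state: RegressionState,
    priors: RegressionPriors,
    rng: np.random.Generator,
    mh_scale: float = 0.2,
) -> RegressionState:
    """One block update of the regression: coefficients given sigma, then sigma.

    Coefficients are a conjugate Gaussian draw.  sigma is an inverse-gamma
    conjugate draw when configured, otherwise a Metropolis step on
    log(sigma) under the half-Cauchy prior.
    """
    n = len(y)
    coef = _draw_coefficients(X, y, state.sigma, priors.tau, rng)
    resid = y - X @ coef
    ssr = float(resid @ resid)
    kind = priors.sigma_prior[0]
    if kind == "inv_gamma":
        a0, b0 = priors.sigma_prior[1], priors.sigma_prior[2]
        sigma2 = 1.0 / rng.gamma(a0 + n / 2.0, 1.0 / (b0 + ssr / 2.0))
        sigma = float(np.sqrt(sigma2))
    else:
        scale = priors.sigma_prior[1]

        def logpost(log_s: float) -> float:
            s = np.exp(log_s)
            # likelihood + half-Cauchy prior + log-Jacobian of the log transform
            return (
                -n * log_s
                - ssr / (2.0 * s**2)
                - np.log1p((s / scale) ** 2)
                + log_s
            )

        cur = float(np.log(state.sigma))
        prop = cur + mh_scale * rng.standard_normal()
        if np.log(rng.uniform()) < logpost(prop) - logpost(cur):
            cur = prop
        sigma = float(np.exp(cur))
    return RegressionState(beta0=float(coef[0]), beta=coef[1:], sigma=sigma)
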