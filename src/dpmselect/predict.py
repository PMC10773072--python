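"""Decision support from a fitted model: counterfactual predictions, CATE,
variable influence and threshold-based therapy choice.

All quantities are posterior predictive distributions of the *expected*
outcome for a patient profile (the conditional average treatment response;
no residual noise is added).  For a patient with missing covariates the
missing values are integrated out using, per posterior draw, the DPMM
conditional given the observed covariates: a component is sampled from the
weights reweighted by the observed-dimension likelihoods, then the missing
continuous dims come from the conditional Gaussian and missing categorical
dims from that component's category probabilities.  No outcome factor
enters — the outcome is unknown at prediction time.

The CATE sign convention is arm 1 minus arm 0: for an outcome where lower
is better (e.g. HbA1c), a negative CATE means the treatment coded 1 is the
better therapy, and ``P(CATE < 0)`` estimates the probability that arm 1
gives the better average response.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .data import ColumnSchema, MixedDataset
from .inference import PosteriorSamples
from .outcome import build_design_matrix

__all__ = [
    "PatientQuery",
    "PredictiveSummary",
    "InfluenceResult",
    "ThresholdDecision",
    "predict_mean_response",
    "cate_distribution",
    "variable_influence",
    "threshold_probability",
    "query_from_row",
]


@dataclass
class PatientQuery:
    """A partially observed covariate profile (original units / labels).

    ``observed`` maps covariate names to values; ``missing`` lists the
    declared-missing covariates.  Together they must cover every model
    covariate exactly once.
    """

    observed: dict[str, Any]
    missing: list[str] = field(default_factory=list)

    def validate(self, schema: ColumnSchema) -> None:
        obs = set(self.observed)
        mis = set(self.missing)
        cov = set(schema.covariates)
        if obs & mis:
            raise ValueError(f"covariates both observed and missing: {sorted(obs & mis)}")
        unknown = (obs | mis) - cov
        if unknown:
            raise ValueError(f"unknown covariate name(s): {sorted(unknown)}")
        if (obs | mis) != cov:
            raise ValueError(f"covariates unaccounted for: {sorted(cov - obs - mis)}")
        for col, levels in schema.categorical.items():
            if col in self.observed and str(self.observed[col]) not in levels:
                raise ValueError(
                    f"value {self.observed[col]!r} not in category dictionary of {col!r}"
                )

    def with_observed(self, name: str, value: Any) -> "PatientQuery":
        obs = dict(self.observed)
        obs[name] = value
        return PatientQuery(observed=obs, missing=[m for m in self.missing if m != name])

    @property
    def is_complete(self) -> bool:
        return not self.missing


def query_from_row(schema: ColumnSchema, data: MixedDataset, i: int) -> PatientQuery:
    """Build a query from row i of a dataset, honouring its missingness mask."""
    observed: dict[str, Any] = {}
    missing: list[str] = []
    for j, col in enumerate(schema.continuous):
        if data.miss_cont[i, j]:
            missing.append(col)
        else:
            observed[col] = float(data.x_cont[i, j])
    for j, col in enumerate(schema.cat_names):
        if data.miss_cat[i, j]:
            missing.append(col)
        else:
            observed[col] = schema.categorical[col][int(data.x_cat[i, j])]
    return PatientQuery(observed=observed, missing=missing)


def _parse_query(samples: PosteriorSamples, query: PatientQuery):
    """Split a query into standardised observed values and missing index sets."""
    s = samples.schema
    query.validate(s)
    std = samples.standardisation
    cont_obs_idx, cont_obs_vals, cont_mis_idx = [], [], []
    for j, col in enumerate(s.continuous):
        if col in query.observed:
            cont_obs_idx.append(j)
            cont_obs_vals.append(
                (float(query.observed[col]) - std.cont_mean[j]) / std.cont_sd[j]
            )
        else:
            cont_mis_idx.append(j)
    cat_obs, cat_mis_idx = {}, []
    for j, col in enumerate(s.cat_names):
        if col in query.observed:
            cat_obs[j] = s.categorical[col].index(str(query.observed[col]))
        else:
            cat_mis_idx.append(j)
    return (
        np.array(cont_obs_idx, dtype=int),
        np.array(cont_obs_vals, dtype=float),
        np.array(cont_mis_idx, dtype=int),
        cat_obs,
        np.array(cat_mis_idx, dtype=int),
    )


def _batch_marginal_loglik(
    x: np.ndarray, mus: np.ndarray, Sigmas: np.ndarray
) -> np.ndarray:
    """(D, K) Gaussian log-density of one observed sub-vector x under all draws."""
    o = x.size
    L = np.linalg.cholesky(Sigmas)
    diff = (x - mus)[..., None]
    z = np.linalg.solve(L, diff)[..., 0]
    logdet = np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
    return -0.5 * (o * np.log(2 * np.pi) + (z**2).sum(axis=-1)) - logdet


def _conditional_component_draws(
    samples: PosteriorSamples,
    parsed,
    rng: np.random.Generator,
    draw_indices: np.ndarray | None = None,
):
    """Sample, per posterior draw, a component and the missing covariates.

    Components come from the exact conditional mixture: prior weights
    multiplied by each component's likelihood of the observed dims.
    Returns (component index, missing-continuous draws (D, m) on the
    standardised scale, dict j -> categorical code draws (D,)).
    """
    o_idx, o_vals, m_idx, cat_obs, cat_mis = parsed
    weights = samples.flat("weights")
    mus = samples.flat("mus")
    Sigmas = samples.flat("Sigmas")
    phis = samples.flat_phis()
    if draw_indices is not None:
        weights, mus, Sigmas = weights[draw_indices], mus[draw_indices], Sigmas[draw_indices]
        phis = [p[draw_indices] for p in phis]
    D = weights.shape[0]
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    if o_idx.size:
        sub_mu = mus[:, :, o_idx]
        sub_S = Sigmas[:, :, o_idx[:, None], o_idx[None, :]]
        logw = logw + _batch_marginal_loglik(o_vals, sub_mu, sub_S)
    with np.errstate(divide="ignore"):
        for j, code in cat_obs.items():
            logw = logw + np.log(phis[j][:, :, code])
    comp = np.argmax(logw + rng.gumbel(size=logw.shape), axis=1)
    ar = np.arange(D)
    cont_draws = np.empty((D, m_idx.size))
    if m_idx.size:
        mu_sel = mus[ar, comp]
        S_sel = Sigmas[ar, comp]
        mu_m = mu_sel[:, m_idx]
        Smm = S_sel[:, m_idx[:, None], m_idx[None, :]]
        if o_idx.size:
            Soo = S_sel[:, o_idx[:, None], o_idx[None, :]]
            Som = S_sel[:, o_idx[:, None], m_idx[None, :]]
            L = np.linalg.cholesky(Soo)
            A = np.linalg.solve(L, Som)  # (D, o, m)
            w = np.linalg.solve(L, (o_vals - mu_sel[:, o_idx])[..., None])  # (D, o, 1)
            mean = mu_m + (A.transpose(0, 2, 1) @ w)[..., 0]
            cov = Smm - A.transpose(0, 2, 1) @ A
        else:
            mean = mu_m
            cov = Smm
        cov = 0.5 * (cov + cov.transpose(0, 2, 1))
        Lc = np.linalg.cholesky(cov)
        eps = rng.standard_normal((D, m_idx.size, 1))
        cont_draws = mean + (Lc @ eps)[..., 0]
    cat_draws: dict[int, np.ndarray] = {}
    for j in cat_mis:
        p = phis[j][ar, comp]
        u = rng.uniform(size=D)
        cat_draws[j] = np.minimum(
            (u[:, None] > p.cumsum(axis=1)).sum(axis=1), p.shape[1] - 1
        )
    return comp, cont_draws, cat_draws


def _expected_outcome_draws(
    samples: PosteriorSamples,
    query: PatientQuery,
    arms: tuple[int, ...],
    rng: np.random.Generator | None = None,
    draw_indices: np.ndarray | None = None,
    return_imputations: bool = False,
):
    """Per-draw expected outcome for each requested arm (original units).

    Within each posterior draw the *same* imputed covariates are used for
    every arm, so arm contrasts are pure treatment contrasts.
    """
    rng = rng or np.random.default_rng(0)
    parsed = _parse_query(samples, query)
    o_idx, o_vals, m_idx, cat_obs, cat_mis = parsed
    beta = samples.flat("beta")
    if draw_indices is not None:
        beta = beta[draw_indices]
    D = beta.shape[0]
    jc = len(samples.schema.continuous)
    jd = len(samples.schema.cat_names)
    xc = np.zeros((D, jc))
    if o_idx.size:
        xc[:, o_idx] = o_vals
    xcat = np.zeros((D, jd), dtype=int)
    for j, code in cat_obs.items():
        xcat[:, j] = code
    imput = None
    if m_idx.size or cat_mis.size:
        comp, cont_draws, cat_draws = _conditional_component_draws(
            samples, parsed, rng, draw_indices
        )
        if m_idx.size:
            xc[:, m_idx] = cont_draws
        for j, codes in cat_draws.items():
            xcat[:, j] = codes
        imput = (comp, cont_draws, cat_draws)
    std = samples.standardisation
    out: dict[int, np.ndarray] = {}
    for arm in arms:
        X = build_design_matrix(
            xc, xcat, np.full(D, arm), samples.spec, samples.schema
        )
        out[arm] = std.y_mean + std.y_sd * np.einsum("ij,ij->i", X, beta)
    if return_imputations:
        return out, imput
    return out


def predict_mean_response(
    samples: PosteriorSamples,
    query: PatientQuery,
    arm: int,
    rng: np.random.Generator | None = None,
    draw_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior predictive draws of the expected outcome under one arm.

    For a complete query the draws are the deterministic linear predictor
    per posterior draw (parameter uncertainty only); for an incomplete
    query the missing covariates are integrated out via the DPMM
    conditional, one imputation per draw.
    """
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    return _expected_outcome_draws(samples, query, (arm,), rng, draw_indices)[arm]


@dataclass
class PredictiveSummary:
    """Per-arm expected-outcome draws and the CATE distribution (arm1 - arm0)."""

    arm0: np.ndarray
    arm1: np.ndarray
    cate: np.ndarray
    p_arm1_better: float  # P(CATE < 0): arm 1 lowers the outcome more
    p_arm0_better: float  # P(CATE > 0)

    @property
    def mean_cate(self) -> float:
        return float(self.cate.mean())

    def interval(self, which: str = "cate", level: float = 0.95) -> tuple[float, float]:
        draws = getattr(self, which)
        lo = (1 - level) / 2
        return tuple(np.quantile(draws, [lo, 1 - lo]))


def cate_distribution(
    samples: PosteriorSamples,
    query: PatientQuery,
    rng: np.random.Generator | None = None,
    draw_indices: np.ndarray | None = None,
) -> PredictiveSummary:
    """Posterior distribution of the conditional average treatment effect.

    CATE draw = (arm-1 expected outcome) - (arm-0 expected outcome) within
    each posterior draw, using identical imputed covariates in both arms.
    """
    out = _expected_outcome_draws(samples, query, (0, 1), rng, draw_indices)
    cate = out[1] - out[0]
    return PredictiveSummary(
        arm0=out[0],
        arm1=out[1],
        cate=cate,
        p_arm1_better=float((cate < 0).mean()),
        p_arm0_better=float((cate > 0).mean()),
    )


@dataclass
class InfluenceResult:
    """Variable-influence analysis output.

    ``values[v]`` maps a quantile label (e.g. "q05") or category label to
    the clamped value; ``responses[v][label][arm]`` holds the expected-
    outcome draws with v clamped there (other missing variables still
    integrated out).  ``ranking`` orders the missing variables by the
    spread of the posterior-mean response across the clamped values —
    the first entry is the most useful additional variable to collect.
    """

    values: dict[str, dict[str, Any]]
    responses: dict[str, dict[str, dict[int, np.ndarray]]]
    spread: dict[str, float]
    ranking: list[str]


def variable_influence(
    samples: PosteriorSamples,
    query: PatientQuery,
    quantile_levels: tuple[float, ...] = (0.05, 0.5, 0.95),
    rng: np.random.Generator | None = None,
    min_category_prob: float = 0.05,
    draw_indices: np.ndarray | None = None,
) -> InfluenceResult:
    """How the response prediction would shift if a missing variable were known.

    For each missing continuous variable the requested quantiles of its
    conditional posterior predictive distribution (pooled across posterior
    draws, given the observed covariates) are computed; the prediction is
    then re-run with the variable clamped at each quantile.  Missing
    categorical variables are clamped at every category whose conditional
    probability is at least ``min_category_prob``.
    """
    if not query.missing:
        raise ValueError(
            "variable influence is undefined for a complete query: no missing variables"
        )
    if any(not 0 < q < 1 for q in quantile_levels):
        raise ValueError("quantile levels must lie in (0, 1)")
    rng = rng or np.random.default_rng(0)
    s = samples.schema
    parsed = _parse_query(samples, query)
    o_idx, o_vals, m_idx, cat_obs, cat_mis = parsed
    comp, cont_draws, cat_draws = _conditional_component_draws(
        samples, parsed, rng, draw_indices
    )
    std = samples.standardisation
    phis = samples.flat_phis()
    if draw_indices is not None:
        phis = [p[draw_indices] for p in phis]
    ar = np.arange(comp.size)
    values: dict[str, dict[str, Any]] = {}
    responses: dict[str, dict[str, dict[int, np.ndarray]]] = {}
    spread: dict[str, float] = {}
    for v in query.missing:
        values[v] = {}
        responses[v] = {}
        if v in s.continuous:
            jm = s.continuous.index(v)
            pos = int(np.flatnonzero(m_idx == jm)[0])
            pooled_raw = cont_draws[:, pos] * std.cont_sd[jm] + std.cont_mean[jm]
            for q in quantile_levels:
                label = f"q{int(round(q * 100)):02d}"
                values[v][label] = float(np.quantile(pooled_raw, q))
        else:
            j = s.cat_names.index(v)
            cond_prob = phis[j][ar, comp].mean(axis=0)
            for code, p in enumerate(cond_prob):
                if p >= min_category_prob:
                    label = s.categorical[v][code]
                    values[v][label] = label
        for label, val in values[v].items():
            q2 = query.with_observed(v, val)
            # common random numbers across clamped values of the same variable:
            # the other missing covariates are integrated with identical draws,
            # so the between-value spread isolates the effect of v itself
            sub_rng = np.random.default_rng(
                np.random.SeedSequence([zlib.crc32(v.encode()) % 2**31])
            )
            out = _expected_outcome_draws(samples, q2, (0, 1), sub_rng, draw_indices)
            responses[v][label] = out
        per_arm_spread = []
        for a in (0, 1):
            mm = [float(responses[v][lab][a].mean()) for lab in responses[v]]
            per_arm_spread.append(max(mm) - min(mm) if len(mm) > 1 else 0.0)
        spread[v] = max(per_arm_spread)
    ranking = sorted(spread, key=lambda v: -spread[v])
    return InfluenceResult(values=values, responses=responses, spread=spread, ranking=ranking)


@dataclass
class ThresholdDecision:
    """Probabilities of meeting an outcome target per arm, plus recommendations.

    ``recommended_arm_threshold`` maximises the probability of meeting the
    target; ``recommended_arm_mean`` is the conventional choice (best mean
    expected outcome).  ``disagreement`` flags when the two rules differ.
    """

    threshold: float
    direction: str
    p_arm0: float
    p_arm1: float
    recommended_arm_threshold: int
    recommended_arm_mean: int
    disagreement: bool
    summary: PredictiveSummary


def threshold_probability(
    samples: PosteriorSamples,
    query: PatientQuery,
    threshold: float,
    direction: str = "below",
    rng: np.random.Generator | None = None,
    draw_indices: np.ndarray | None = None,
) -> ThresholdDecision:
    """Per-arm probability that the expected outcome meets a target threshold.

    ``direction="below"`` treats outcomes under the threshold as meeting
    the target (the high-risk glycaemic-control use case); ``"above"``
    flips the inequality.
    """
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    summ = cate_distribution(samples, query, rng, draw_indices)
    if direction == "below":
        p0 = float((summ.arm0 < threshold).mean())
        p1 = float((summ.arm1 < threshold).mean())
        mean_rec = 1 if summ.arm1.mean() < summ.arm0.mean() else 0
    else:
        p0 = float((summ.arm0 > threshold).mean())
        p1 = float((summ.arm1 > threshold).mean())
        mean_rec = 1 if summ.arm1.mean() > summ.arm0.mean() else 0
    thr_rec = 1 if p1 > p0 else 0 if p0 > p1 else mean_rec
    return ThresholdDecision(
        threshold=float(threshold),
        direction=direction,
        p_arm0=p0,
        p_arm1=p1,
        recommended_arm_threshold=thr_rec,
        recommended_arm_mean=mean_rec,
        disagreement=thr_rec != mean_rec,
        summary=summ,
    )
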