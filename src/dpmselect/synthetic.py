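"""Synthetic cohorts with the statistical structure the model assumes.

Covariates come from a finite Gaussian/categorical mixture (the structure
the DPMM is built to recover), the outcome from a linear treatment-
selection model with treatment-by-covariate interactions, and missingness
from an MCAR or MAR mechanism.  The generator doubles as the ground-truth
oracle for recovery tests: true component labels, pre-masking covariate
values and the analytic conditional average treatment effect (CATE) are
all retained.

The default scenario (``default_scenario()``, shipped as a YAML config)
emulates a second-line type 2 diabetes cohort: four continuous biomarkers
on the scales of baseline HbA1c (mmol/mol), eGFR, logged ALT and BMI, two
ordinal drug-count covariates, a binary therapy indicator, and an HbA1c
outcome whose treatment effect is driven predominantly by baseline HbA1c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .data import ColumnSchema, MixedDataset
from .outcome import SplineSpec, build_design_matrix

__all__ = [
    "TrueBeta",
    "MissingnessConfig",
    "GeneratorConfig",
    "generate_population",
    "apply_missingness",
    "true_cate",
    "default_scenario",
    "load_generator_config",
]


@dataclass
class TrueBeta:
    """Generating coefficients, keyed by schema column (linear basis).

    ``categorical[col]`` lists effects for levels 1.. (level 0 is the
    reference); ``treat_*`` are the treatment-by-covariate interactions.
    """

    intercept: float
    treatment: float
    continuous: dict[str, float]
    categorical: dict[str, list[float]]
    treat_continuous: dict[str, float]
    treat_categorical: dict[str, list[float]]

    def design_vector(self, schema: ColumnSchema) -> np.ndarray:
        """Coefficients in design-row order (linear spline basis)."""
        main: list[float] = []
        inter: list[float] = []
        for col, levels in schema.categorical.items():
            eff = list(self.categorical.get(col, [0.0] * (len(levels) - 1)))
            ieff = list(self.treat_categorical.get(col, [0.0] * (len(levels) - 1)))
            if len(eff) != len(levels) - 1 or len(ieff) != len(levels) - 1:
                raise ValueError(f"wrong number of effects for categorical {col!r}")
            main += eff
            inter += ieff
        for col in schema.continuous:
            main.append(self.continuous.get(col, 0.0))
            inter.append(self.treat_continuous.get(col, 0.0))
        return np.array([self.intercept, self.treatment] + main + inter)

    def standardised_design_vector(
        self,
        schema: ColumnSchema,
        cont_mean: np.ndarray,
        cont_sd: np.ndarray,
        y_mean: float,
        y_sd: float,
    ) -> np.ndarray:
        """Exact coefficients after covariate and outcome standardisation.

        For the linear (identity) basis the standardising map is affine, so
        the generating coefficients transform exactly: continuous effects
        scale by s_j/s_y, categorical effects by 1/s_y, and the covariate
        centres fold into the intercept and the treatment main effect.
        """
        cont_mean = np.asarray(cont_mean, dtype=float)
        cont_sd = np.asarray(cont_sd, dtype=float)
        b_cont = np.array([self.continuous.get(c, 0.0) for c in schema.continuous])
        c_cont = np.array([self.treat_continuous.get(c, 0.0) for c in schema.continuous])
        main: list[float] = []
        inter: list[float] = []
        for col, levels in schema.categorical.items():
            main += [b / y_sd for b in self.categorical.get(col, [0.0] * (len(levels) - 1))]
            inter += [
                b / y_sd for b in self.treat_categorical.get(col, [0.0] * (len(levels) - 1))
            ]
        main += list(b_cont * cont_sd / y_sd)
        inter += list(c_cont * cont_sd / y_sd)
        b0 = (self.intercept + float(b_cont @ cont_mean) - y_mean) / y_sd
        bt = (self.treatment + float(c_cont @ cont_mean)) / y_sd
        return np.array([b0, bt] + main + inter)


@dataclass
class MissingnessConfig:
    """MCAR or MAR masking of covariate cells.

    ``rates`` gives the per-column marginal masking probability.  Under
    MAR the cell-level probability is a logistic function of the driver
    columns (``drivers[col] = {driver: slope}``); the intercept is solved
    so the realised marginal rate matches ``rates[col]``.  Driver columns
    must not themselves be subject to missingness (this guarantees MAR
    rather than MNAR) and treatment/outcome are never masked.
    """

    mechanism: str = "mcar"
    rates: dict[str, float] = field(default_factory=dict)
    drivers: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError("mechanism must be 'mcar' or 'mar'")
        for col, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {col!r} outside [0, 1]")
        if self.mechanism == "mar":
            masked = {c for c, r in self.rates.items() if r > 0}
            for col in masked:
                for drv in self.drivers.get(col, {}):
                    if drv in masked:
                        raise ValueError(
                            f"MAR driver {drv!r} for column {col!r} is itself subject "
                            "to missingness; that would make the mechanism MNAR"
                        )


@dataclass
class GeneratorConfig:
    """Complete specification of a synthetic cohort."""

    schema: ColumnSchema
    n_individuals: int
    component_weights: np.ndarray
    component_means: np.ndarray  # (K, J_C)
    component_covariances: np.ndarray  # (K, J_C, J_C)
    component_category_probs: dict[str, np.ndarray]  # col -> (K, K_j)
    true_beta: TrueBeta
    true_sigma: float
    treatment_assignment_prob: float | Callable[[np.ndarray], np.ndarray] = 0.5
    missingness: MissingnessConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.component_weights = np.asarray(self.component_weights, dtype=float)
        self.component_means = np.atleast_2d(np.asarray(self.component_means, dtype=float))
        self.component_covariances = np.asarray(self.component_covariances, dtype=float)
        self.component_category_probs = {
            c: np.atleast_2d(np.asarray(p, dtype=float))
            for c, p in self.component_category_probs.items()
        }
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if abs(self.component_weights.sum() - 1.0) > 1e-8 or self.component_weights.min() < 0:
            raise ValueError("component_weights must be a probability vector")
        for k, S in enumerate(self.component_covariances):
            S = np.atleast_2d(S)
            if S.size and (
                not np.allclose(S, S.T) or np.linalg.eigvalsh(S).min() <= 0
            ):
                raise ValueError(f"covariance of component {k} is not symmetric positive-definite")
        for col, probs in self.component_category_probs.items():
            if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
                raise ValueError(f"category probabilities for {col!r} must sum to 1")
        if self.true_sigma <= 0:
            raise ValueError("true_sigma must be positive")

    @property
    def n_components(self) -> int:
        return self.component_weights.size

    def linear_spec(self) -> SplineSpec:
        """Identity (linear) basis spec matching this schema."""
        return SplineSpec({c: np.empty(0) for c in self.schema.continuous})


def generate_population(config: GeneratorConfig) -> MixedDataset:
    """Draw a complete cohort (no missingness) from the generating mixture.

    The outcome applies ``true_beta`` through the same design construction
    as the outcome model's design rows, with the identity basis in place
    of splines.  Deterministic given ``config.seed``; the true component
    labels are stored in ``attrs["component"]``.
    """
    rng = np.random.default_rng(config.seed)
    s = config.schema
    n, K = config.n_individuals, config.n_components
    jc, jd = len(s.continuous), len(s.categorical)
    comp = rng.choice(K, size=n, p=config.component_weights)
    x_cont = np.zeros((n, jc))
    for k in range(K):
        rows = comp == k
        if not rows.any() or jc == 0:
            continue
        L = np.linalg.cholesky(config.component_covariances[k])
        x_cont[rows] = config.component_means[k] + rng.standard_normal((rows.sum(), jc)) @ L.T
    x_cat = np.zeros((n, jd), dtype=int)
    for j, col in enumerate(s.cat_names):
        probs = config.component_category_probs[col]
        u = rng.uniform(size=n)
        x_cat[:, j] = (u[:, None] > probs[comp].cumsum(axis=1)).sum(axis=1)
    if callable(config.treatment_assignment_prob):
        pt = np.asarray(config.treatment_assignment_prob(x_cont), dtype=float)
    else:
        pt = np.full(n, float(config.treatment_assignment_prob))
    treatment = (rng.uniform(size=n) < pt).astype(int)
    X = build_design_matrix(x_cont, x_cat, treatment, config.linear_spec(), s)
    lin = X @ config.true_beta.design_vector(s)
    y = lin + config.true_sigma * rng.standard_normal(n)
    return MixedDataset(
        schema=s,
        x_cont=x_cont,
        x_cat=x_cat,
        treatment=treatment,
        y=y,
        miss_cont=np.zeros((n, jc), dtype=bool),
        miss_cat=np.zeros((n, jd), dtype=bool),
        attrs={"component": comp, "seed": config.seed},
    )


def _mar_probs(rate: float, logits: np.ndarray) -> np.ndarray:
    """Cell probabilities expit(a + logits) with a solved so the mean is rate."""
    if rate <= 0:
        return np.zeros_like(logits)
    if rate >= 1:
        return np.ones_like(logits)

    def mean_minus_rate(a: float) -> float:
        return float(expit(a + logits).mean() - rate)

    a = brentq(mean_minus_rate, -40.0, 40.0)
    return expit(a + logits)


def apply_missingness(data: MixedDataset, config: GeneratorConfig) -> MixedDataset:
    """Mask covariate cells per the configured MCAR/MAR mechanism.

    Returns a copy; treatment and outcome are never masked, and the true
    pre-masking values are retained in ``attrs`` for oracle comparison.
    Deterministic given ``config.seed``.
    """
    out = data.copy()
    mc = config.missingness
    if mc is None or not mc.rates:
        return out
    if data.n_missing_cells:
        raise ValueError("apply_missingness expects complete input data")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    s = data.schema
    out.attrs["x_cont_true"] = data.x_cont.copy()
    out.attrs["x_cat_true"] = data.x_cat.copy()
    all_cols = {c: ("cont", j) for j, c in enumerate(s.continuous)}
    all_cols.update({c: ("cat", j) for j, c in enumerate(s.cat_names)})
    for col in sorted(mc.rates):
        rate = mc.rates[col]
        if rate == 0 or col not in all_cols:
            continue
        if mc.mechanism == "mcar":
            probs = np.full(data.n, rate)
        else:
            logits = np.zeros(data.n)
            for drv, slope in mc.drivers.get(col, {}).items():
                kind, j = all_cols[drv]
                vals = data.x_cont[:, j] if kind == "cont" else data.x_cat[:, j].astype(float)
                logits += slope * vals
            probs = _mar_probs(rate, logits)
        mask = rng.uniform(size=data.n) < probs
        kind, j = all_cols[col]
        if kind == "cont":
            out.miss_cont[:, j] = mask
        else:
            out.miss_cat[:, j] = mask
    return out


def true_cate(config: GeneratorConfig, profile: dict[str, Any]) -> float:
    """Exact generating mean-outcome difference (arm 1 minus arm 0).

    ``profile`` must give a value for every covariate (categoricals as
    labels or integer codes); the oracle is undefined for incomplete
    profiles.
    """
    s = config.schema
    missing = [c for c in s.covariates if c not in profile]
    if missing:
        raise ValueError(f"true_cate requires a complete profile; missing {missing}")
    tb = config.true_beta
    cate = tb.treatment
    for col in s.continuous:
        cate += tb.treat_continuous.get(col, 0.0) * float(profile[col])
    for col, levels in s.categorical.items():
        v = profile[col]
        code = levels.index(str(v)) if not isinstance(v, (int, np.integer)) else int(v)
        if code > 0:
            cate += tb.treat_categorical.get(col, [0.0] * (len(levels) - 1))[code - 1]
    return float(cate)


def _config_from_dict(d: dict[str, Any]) -> GeneratorConfig:
    schema = ColumnSchema.from_dict(d["columns"])
    comp = d["components"]
    mis = d.get("missingness")
    tb = d["true_beta"]
    return GeneratorConfig(
        schema=schema,
        n_individuals=int(d["n_individuals"]),
        component_weights=np.asarray(comp["weights"], dtype=float),
        component_means=np.asarray(comp["means"], dtype=float),
        component_covariances=np.asarray(comp["covariances"], dtype=float),
        component_category_probs={
            c: np.asarray(p, dtype=float) for c, p in comp["category_probs"].items()
        },
        true_beta=TrueBeta(
            intercept=float(tb["intercept"]),
            treatment=float(tb["treatment"]),
            continuous={k: float(v) for k, v in tb.get("continuous", {}).items()},
            categorical={k: [float(x) for x in v] for k, v in tb.get("categorical", {}).items()},
            treat_continuous={k: float(v) for k, v in tb.get("treat_continuous", {}).items()},
            treat_categorical={
                k: [float(x) for x in v] for k, v in tb.get("treat_categorical", {}).items()
            },
        ),
        true_sigma=float(d["true_sigma"]),
        treatment_assignment_prob=float(d.get("treatment_assignment_prob", 0.5)),
        missingness=None
        if mis is None
        else MissingnessConfig(
            mechanism=mis.get("mechanism", "mcar"),
            rates={k: float(v) for k, v in mis.get("rates", {}).items()},
            drivers={
                k: {d2: float(v2) for d2, v2 in v.items()}
                for k, v in mis.get("drivers", {}).items()
            },
        ),
        seed=int(d.get("seed", 0)),
    )


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Load a generator configuration from a YAML (or JSON) file."""
    return _config_from_dict(yaml.safe_load(Path(path).read_text()))


def default_scenario(n: int | None = None, seed: int | None = None) -> GeneratorConfig:
    """The packaged 3-component, 4-continuous + 2-categorical scenario.

    n = 1000 with 20% MAR missingness on two continuous biomarkers by
    default; ``n`` and ``seed`` may be overridden.
    """
    with resources.files("dpmselect.configs").joinpath("default_scenario.yaml").open() as fh:
        d = yaml.safe_load(fh)
    if n is not None:
        d["n_individuals"] = int(n)
    if seed is not None:
        d["seed"] = int(seed)
    return _config_from_dict(d)
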