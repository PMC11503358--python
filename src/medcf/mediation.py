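"""Counterfactual mediation estimator for a binary mediator and outcome.

The algorithm follows the mediation formula with quasi-Bayesian uncertainty
propagation:

1. fit logistic mediator and outcome models by maximum likelihood;
2. draw model parameters from the asymptotic normal distribution of the MLEs;
3. per parameter draw, simulate each participant's two counterfactual
   mediator values M(0), M(1) from the mediator model and evaluate the four
   counterfactual outcome quantities Y(t, M(t')) from the outcome model;
4. average the per-participant contrasts into the indirect effects IE(1),
   IE(0), the direct effects DE(1), DE(0) and the total effect TTE (risk
   differences in percentage points), and take percentile intervals over the
   draws.

The proportion mediated is PM = 100 * IE(1)/TTE; its interval comes from the
per-draw ratio and is flagged unstable whenever the TTE draws straddle zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .glm_core import FittedModel, ModelSpec, design_matrix, fit_logistic
from .trialgen import TrialDataset

__all__ = [
    "MediationConfig",
    "CounterfactualProbabilities",
    "EffectVector",
    "EffectEstimate",
    "MediationResult",
    "EstimationError",
    "draw_parameters",
    "simulate_counterfactuals",
    "compute_effects",
    "estimate",
    "proportion_mediated",
]

EFFECT_NAMES = ("ie1", "ie0", "de1", "de0", "tte")


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MediationConfig:
    n_param_draws: int = 1000
    mediator_draws_per_param: int = 1
    ci_level: float = 0.95
    interaction: bool = False
    seed: int = 0
    outcome_aggregation: str = "expected_probability"  # or "binary_draw"
    couple_mediator_draws: bool = False  # shared uniform for M(0), M(1)

    def __post_init__(self) -> None:
        if self.n_param_draws < 2:
            raise ValueError("n_param_draws must be >= 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.outcome_aggregation not in ("expected_probability", "binary_draw"):
            raise ValueError(f"unknown outcome_aggregation {self.outcome_aggregation!r}")


@dataclass
class CounterfactualProbabilities:
    """Per-participant counterfactual quantities for one parameter draw.

    ``y_tt'`` holds Y(t, M(t')) — an expected probability by default, or a
    binary draw under the ``binary_draw`` aggregation.
    """

    p_m0: np.ndarray
    p_m1: np.ndarray
    m0: np.ndarray
    m1: np.ndarray
    y00: np.ndarray
    y01: np.ndarray
    y10: np.ndarray
    y11: np.ndarray


@dataclass(frozen=True)
class EffectVector:
    """One draw's averaged effects, in percentage points."""

    ie1: float
    ie0: float
    de1: float
    de0: float
    tte: float


@dataclass(frozen=True)
class EffectEstimate:
    point: float
    lo: float
    hi: float


@dataclass
class MediationResult:
    outcome: str
    n_obs: int
    config: MediationConfig
    effects: dict[str, EffectEstimate]
    pm: EffectEstimate
    pm_unstable: bool
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "outcome": self.outcome,
            "n_obs": self.n_obs,
            "seed": self.config.seed,
            "config": {
                "n_param_draws": self.config.n_param_draws,
                "mediator_draws_per_param": self.config.mediator_draws_per_param,
                "ci_level": self.config.ci_level,
                "interaction": self.config.interaction,
                "outcome_aggregation": self.config.outcome_aggregation,
                "couple_mediator_draws": self.config.couple_mediator_draws,
            },
            "effects": {
                name: {"point": e.point, "lo": e.lo, "hi": e.hi}
                for name, e in self.effects.items()
            },
            "pm": {
                "point": self.pm.point,
                "lo": self.pm.lo,
                "hi": self.pm.hi,
                "unstable": self.pm_unstable,
            },
        }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def proportion_mediated(ie: float, tte: float) -> float:
    """Proportion mediated, in percent: 100 * ie / tte (effects in the same
    units, e.g. percentage-point risk differences)."""
    if tte == 0:
        raise EstimationError("proportion mediated is undefined when TTE = 0")
    return 100.0 * ie / tte


def draw_parameters(
    mediator_model: FittedModel,
    outcome_model: FittedModel,
    j: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``j`` independent quasi-Bayesian draws: each model's coefficients are
    sampled from N(beta_hat, vcov_hat), independently across the two models."""
    bm = _mvn_draws(mediator_model.beta, mediator_model.vcov, j, rng)
    by = _mvn_draws(outcome_model.beta, outcome_model.vcov, j, rng)
    return [(bm[i], by[i]) for i in range(j)]


def _mvn_draws(beta: np.ndarray, vcov: np.ndarray, j: int, rng: np.random.Generator) -> np.ndarray:
    vcov = np.asarray(vcov, dtype=float)
    if not np.all(np.isfinite(vcov)):
        raise EstimationError("non-finite vcov; refit the model with ridge=True")
    sym = (vcov + vcov.T) / 2.0
    evals, evecs = np.linalg.eigh(sym)
    scale = max(1.0, float(evals.max(initial=0.0)))
    if evals.min(initial=0.0) < -1e-8 * scale:
        raise EstimationError(
            "vcov is not positive semidefinite; refit the model with ridge=True"
        )
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((j, len(beta)))
    return beta + z @ root.T


class _DesignCache:
    """Counterfactual design matrices for a dataset: X_m(t') for t' in {0,1}
    and X_y(t, m) for the four (t, m) cells."""

    def __init__(self, data: TrialDataset, mediator_model: FittedModel, outcome_model: FittedModel):
        df = data.data
        self.n = len(df)
        self.xm = {}
        for tp in (0, 1):
            mod = df.assign(t=tp)
            self.xm[tp], _ = design_matrix(mediator_model.spec, mod, centers=mediator_model.centers)
        self.xy = {}
        for t in (0, 1):
            for m in (0, 1):
                mod = df.assign(t=t, m=m)
                self.xy[(t, m)], _ = design_matrix(
                    outcome_model.spec, mod, centers=outcome_model.centers
                )


def _simulate(
    beta_m: np.ndarray,
    beta_y: np.ndarray,
    cache: _DesignCache,
    config: MediationConfig,
    rng: np.random.Generator,
) -> CounterfactualProbabilities:
    p_m0 = expit(cache.xm[0] @ beta_m)
    p_m1 = expit(cache.xm[1] @ beta_m)
    if config.couple_mediator_draws:
        # shared uniform: a variance-reduction option that also makes the
        # two counterfactual mediator values comonotone
        u = rng.random(cache.n)
        m0 = (u < p_m0).astype(float)
        m1 = (u < p_m1).astype(float)
    else:
        # default: independent uniforms for the two counterfactual values
        m0 = (rng.random(cache.n) < p_m0).astype(float)
        m1 = (rng.random(cache.n) < p_m1).astype(float)
    py = {cell: expit(x @ beta_y) for cell, x in cache.xy.items()}
    if config.outcome_aggregation == "binary_draw":
        # one uniform per participant per (t, m) cell keeps Y(t, M(0)) and
        # Y(t, M(1)) consistent whenever M(0) = M(1)
        py = {cell: (rng.random(cache.n) < p).astype(float) for cell, p in py.items()}
    y10 = np.where(m0 == 1.0, py[(1, 1)], py[(1, 0)])
    y11 = np.where(m1 == 1.0, py[(1, 1)], py[(1, 0)])
    y00 = np.where(m0 == 1.0, py[(0, 1)], py[(0, 0)])
    y01 = np.where(m1 == 1.0, py[(0, 1)], py[(0, 0)])
    return CounterfactualProbabilities(p_m0, p_m1, m0, m1, y00, y01, y10, y11)


def simulate_counterfactuals(
    param_draw: tuple[np.ndarray, np.ndarray],
    data: TrialDataset,
    config: MediationConfig,
    rng: np.random.Generator,
    mediator_model: FittedModel | None = None,
    outcome_model: FittedModel | None = None,
    _cache: _DesignCache | None = None,
) -> CounterfactualProbabilities:
    """Simulate every participant's counterfactuals for one parameter draw.

    ``mediator_model``/``outcome_model`` supply the model structure (specs and
    squared-term centers); their coefficients are replaced by ``param_draw``.
    """
    if _cache is None:
        if mediator_model is None or outcome_model is None:
            raise EstimationError("fitted models are required to build the design")
        _cache = _DesignCache(data, mediator_model, outcome_model)
    beta_m, beta_y = param_draw
    return _simulate(np.asarray(beta_m, float), np.asarray(beta_y, float), _cache, config, rng)


def compute_effects(cf: CounterfactualProbabilities) -> EffectVector:
    """Average the counterfactual contrasts over participants, in percentage
    points. ``ie1 + de0 == ie0 + de1 == tte`` holds algebraically."""
    ie1 = float(np.mean(cf.y11 - cf.y10)) * 100.0
    ie0 = float(np.mean(cf.y01 - cf.y00)) * 100.0
    de1 = float(np.mean(cf.y11 - cf.y01)) * 100.0
    de0 = float(np.mean(cf.y10 - cf.y00)) * 100.0
    tte = float(np.mean(cf.y11 - cf.y00)) * 100.0
    return EffectVector(ie1, ie0, de1, de0, tte)


def estimate(
    data: TrialDataset,
    mediator_spec: ModelSpec,
    outcome_spec: ModelSpec,
    config: MediationConfig = MediationConfig(),
    ridge: bool = False,
) -> MediationResult:
    """Full mediation analysis for one outcome.

    Fits both models once, runs ``n_param_draws * mediator_draws_per_param``
    Monte Carlo draws, and reports means and percentile intervals.  The PM
    point estimate is the ratio of the averaged IE(1) and TTE; its interval
    is the percentile interval of the per-draw ratios.
    """
    if config.interaction and "T:M" not in outcome_spec.terms:
        outcome_spec = outcome_spec.with_term("T:M")
    mediator_model = fit_logistic(data, mediator_spec, ridge=ridge)
    outcome_model = fit_logistic(data, outcome_spec, ridge=ridge)

    rng = np.random.default_rng(config.seed)
    pairs = draw_parameters(mediator_model, outcome_model, config.n_param_draws, rng)
    cache = _DesignCache(data, mediator_model, outcome_model)

    total = config.n_param_draws * config.mediator_draws_per_param
    draws = {name: np.empty(total) for name in EFFECT_NAMES}
    i = 0
    for beta_m, beta_y in pairs:
        for _ in range(config.mediator_draws_per_param):
            cf = _simulate(beta_m, beta_y, cache, config, rng)
            vec = compute_effects(cf)
            for name in EFFECT_NAMES:
                draws[name][i] = getattr(vec, name)
            i += 1

    alpha = (1.0 - config.ci_level) / 2.0
    effects = {}
    for name in EFFECT_NAMES:
        d = draws[name]
        effects[name] = EffectEstimate(
            point=float(d.mean()),
            lo=float(np.quantile(d, alpha)),
            hi=float(np.quantile(d, 1.0 - alpha)),
        )

    tte_draws = draws["tte"]
    pm_unstable = bool(tte_draws.min() <= 0.0 <= tte_draws.max())
    with np.errstate(divide="ignore", invalid="ignore"):
        pm_draws = np.where(tte_draws != 0.0, 100.0 * draws["ie1"] / tte_draws, np.nan)
    if effects["tte"].point == 0.0:
        raise EstimationError("proportion mediated is undefined when TTE = 0")
    pm = EffectEstimate(
        point=proportion_mediated(effects["ie1"].point, effects["tte"].point),
        lo=float(np.nanquantile(pm_draws, alpha)),
        hi=float(np.nanquantile(pm_draws, 1.0 - alpha)),
    )
    return MediationResult(
        outcome=outcome_spec.response,
        n_obs=data.n,
        config=config,
        effects=effects,
        pm=pm,
        pm_unstable=pm_unstable,
        draws=draws,
    )
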