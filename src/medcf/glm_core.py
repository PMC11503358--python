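"""Logistic model fitting and the two model checks used by the pipeline.

Models are specified by a small formula grammar, e.g.::

    vf_i ~ 1 + T + M + age + T:age + age^2

``T`` and ``M`` map to the trial columns ``t`` and ``m``; ``:`` builds a
product term and ``^2`` a squared term (continuous covariates only, centered
at their sample mean before squaring).  Fitting is maximum likelihood via
iteratively reweighted least squares (statsmodels GLM under the hood, plus a
Newton polish until the score vanishes to < 1e-9), with the covariance taken
as the inverse observed information at the MLE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats
from scipy.special import expit

from .trialgen import TrialDataset

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelError",
    "SeparationError",
    "parse_formula",
    "fit_logistic",
    "predict_prob",
    "predict_matrix",
    "hosmer_lemeshow",
    "lr_interaction_test",
]

_FACTOR_MAP = {"T": "t", "M": "m"}


class ModelError(ValueError):
    """Invalid model specification or design."""


class SeparationError(ModelError):
    """The likelihood is maximized at infinity (perfect separation)."""


@dataclass(frozen=True)
class ModelSpec:
    """Response name plus an ordered tuple of term descriptors."""

    response: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.terms.count("1") != 1:
            raise ModelError("the intercept term '1' must appear exactly once")
        if len(set(self.terms)) != len(self.terms):
            dupes = sorted({t for t in self.terms if self.terms.count(t) > 1})
            raise ModelError(f"duplicate terms: {', '.join(dupes)}")
        if self.response in ("m", "M") and self.uses_mediator:
            raise ModelError("M cannot appear as a term in the mediator model")

    @property
    def uses_mediator(self) -> bool:
        return any("M" in term.split(":") or term == "M^2" for term in self.terms)

    def with_term(self, term: str) -> "ModelSpec":
        return ModelSpec(self.response, self.terms + (term,))

    def formula(self) -> str:
        return f"{self.response} ~ {' + '.join(self.terms)}"


def parse_formula(formula: str) -> ModelSpec:
    """Parse ``response ~ term + term + ...`` into a :class:`ModelSpec`."""
    if "~" not in formula:
        raise ModelError(f"formula {formula!r} lacks '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    terms = tuple(t.strip() for t in rhs.split("+") if t.strip())
    if not response or not terms:
        raise ModelError(f"empty response or term list in {formula!r}")
    return ModelSpec(response, terms)


@dataclass
class FittedModel:
    """Maximum-likelihood logistic fit.

    ``centers`` stores the sample means used for squared terms so that
    predictions on new records reuse the fit-time centering.
    """

    spec: ModelSpec
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_obs: int
    term_names: tuple[str, ...]
    centers: dict[str, float] = field(default_factory=dict)


def _as_frame(data: TrialDataset | pd.DataFrame) -> pd.DataFrame:
    return data.data if isinstance(data, TrialDataset) else data


def _factor_column(factor: str, df: pd.DataFrame, centers: dict, fit: bool) -> np.ndarray:
    if factor == "1":
        return np.ones(len(df))
    if factor.endswith("^2"):
        base = factor[:-2]
        col = _factor_column(base, df, centers, fit)
        if set(np.unique(col)) <= {0.0, 1.0}:
            raise ModelError(f"squared term on binary variable {base!r}")
        if fit:
            centers[base] = float(col.mean())
        if base not in centers:
            raise ModelError(f"no stored center for squared term {factor!r}")
        return (col - centers[base]) ** 2
    name = _FACTOR_MAP.get(factor, factor)
    if name not in df.columns:
        raise ModelError(f"variable {factor!r} (column {name!r}) not found in data")
    return df[name].to_numpy(dtype=float)


def design_matrix(
    spec: ModelSpec,
    data: TrialDataset | pd.DataFrame,
    centers: dict | None = None,
    fit: bool = False,
) -> tuple[np.ndarray, dict]:
    """Build the n x p design matrix for ``spec.terms``."""
    df = _as_frame(data)
    centers = {} if centers is None else dict(centers)
    cols = []
    for term in spec.terms:
        col = np.ones(len(df))
        for factor in term.split(":"):
            col = col * _factor_column(factor, df, centers, fit)
        cols.append(col)
    return np.column_stack(cols), centers


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        collinear = sorted(names[i] for i in piv[rank:])
        raise ModelError(f"singular design; collinear terms: {', '.join(collinear)}")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood sum(y*eta - log1p(exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    data: TrialDataset | pd.DataFrame,
    spec: ModelSpec,
    ridge: bool = False,
) -> FittedModel:
    """Fit ``spec`` by maximum likelihood.

    Perfect separation raises :class:`SeparationError` unless ``ridge`` is
    set, in which case a lightly penalized fit (1e-6 * ||beta||^2) is returned
    with a warning — the mediation engine needs a finite covariance matrix.
    """
    df = _as_frame(data)
    resp_col = _FACTOR_MAP.get(spec.response, spec.response)
    if resp_col not in df.columns:
        raise ModelError(f"response column {resp_col!r} not found")
    y = df[resp_col].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ModelError(f"response {spec.response!r} is not binary 0/1")
    X, centers = design_matrix(spec, df, fit=True)
    _check_rank(X, spec.terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
    beta = np.asarray(start.params, dtype=float)

    lam = 1e-6 if ridge else 0.0
    separated = False
    # Newton polish: convergence when max |delta beta| < 1e-8, cap 100 steps
    for _ in range(100):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - p) - 2.0 * lam * beta
        w = p * (1.0 - p)
        H = (X.T * w) @ X + 2.0 * lam * np.eye(X.shape[1])
        try:
            delta = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            separated = True
            break
        if not np.all(np.isfinite(delta)):
            separated = True
            break
        beta = beta + delta
        if np.max(np.abs(beta)) > 25.0:
            separated = True  # logit drifting to infinity: stop early
            break
        if np.max(np.abs(delta)) < 1e-8:
            break
    if separated or np.max(np.abs(beta)) > 25.0:
        if not ridge:
            raise SeparationError(
                f"perfect or quasi-perfect separation fitting {spec.formula()!r}; "
                "retry with ridge=True for a penalized fit"
            )
        warnings.warn(f"separation in {spec.formula()!r}; ridge-penalized fit returned")
        beta = _ridge_fit(X, y, lam=1e-6)

    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X.T * w) @ X + 2.0 * lam * np.eye(X.shape[1])
    vcov = linalg.inv(info)
    vcov = (vcov + vcov.T) / 2.0
    return FittedModel(
        spec=spec,
        beta=beta,
        vcov=vcov,
        loglik=_loglik(y, eta),
        n_obs=len(y),
        term_names=spec.terms,
        centers=centers,
    )


def _ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        p = expit(X @ beta)
        grad = X.T @ (y - p) - 2.0 * lam * beta
        H = (X.T * (p * (1.0 - p) + 1e-10)) @ X + 2.0 * lam * np.eye(X.shape[1])
        delta = linalg.solve(H, grad, assume_a="pos")
        beta = beta + np.clip(delta, -5.0, 5.0)
        if np.max(np.abs(delta)) < 1e-8:
            break
    return beta


def predict_prob(
    model: FittedModel,
    t: int,
    m: int | None = None,
    covariates: dict | None = None,
) -> float:
    """Success probability for one participant profile."""
    if model.spec.uses_mediator and m is None:
        raise ModelError("this model requires a mediator value m")
    if m is not None and not model.spec.uses_mediator:
        m = None
    row = dict(covariates or {})
    row["t"] = t
    if m is not None:
        row["m"] = m
    df = pd.DataFrame([row])
    X, _ = design_matrix(model.spec, df, centers=model.centers)
    return float(expit(X @ model.beta)[0])


def predict_matrix(model: FittedModel, data: TrialDataset | pd.DataFrame) -> np.ndarray:
    """Vectorized success probabilities for every row of ``data``."""
    X, _ = design_matrix(model.spec, data, centers=model.centers)
    return expit(X @ model.beta)


def hosmer_lemeshow(
    model: FittedModel,
    data: TrialDataset | pd.DataFrame,
    groups: int = 10,
) -> tuple[float, int, float]:
    """Deciles-of-risk goodness-of-fit test.

    Participants are sorted by predicted probability and cut into
    ``groups`` (near) equal-count groups; predicted-probability ties at a
    boundary stay in the lower group, and groups with expected count < 1 are
    merged into their neighbor with a warning.  Returns (statistic, df,
    p-value) with df = final group count - 2.
    """
    df = _as_frame(data)
    if groups < 2:
        raise ModelError("groups must be >= 2")
    if len(df) < groups:
        raise ModelError("fewer observations than groups")
    resp_col = _FACTOR_MAP.get(model.spec.response, model.spec.response)
    y = df[resp_col].to_numpy(dtype=float)
    p = predict_matrix(model, df)
    order = np.argsort(p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    n = len(p_sorted)

    bounds = [0]
    for k in range(1, groups):
        b = int(round(n * k / groups))
        b = max(b, bounds[-1])
        while 0 < b < n and p_sorted[b] == p_sorted[b - 1]:
            b += 1  # ties stay in the lower group
        if b > bounds[-1]:
            bounds.append(b)
    bounds.append(n)

    obs = [float(y_sorted[a:b].sum()) for a, b in zip(bounds[:-1], bounds[1:])]
    exp = [float(p_sorted[a:b].sum()) for a, b in zip(bounds[:-1], bounds[1:])]
    cnt = [b - a for a, b in zip(bounds[:-1], bounds[1:])]

    i = 0
    while i < len(exp):
        if exp[i] < 1.0 and len(exp) > 1:
            warnings.warn("merging a risk group with expected count < 1")
            j = i - 1 if i > 0 else i + 1
            obs[j] += obs[i]
            exp[j] += exp[i]
            cnt[j] += cnt[i]
            del obs[i], exp[i], cnt[i]
        else:
            i += 1

    stat = 0.0
    for o, e, ng in zip(obs, exp, cnt):
        denom = e * (1.0 - e / ng)
        if denom <= 0:
            continue  # perfectly homogeneous group contributes nothing
        stat += (o - e) ** 2 / denom
    dfree = max(len(obs) - 2, 1)
    return stat, dfree, float(stats.chi2.sf(stat, dfree))


def lr_interaction_test(
    data: TrialDataset | pd.DataFrame,
    outcome_spec: ModelSpec,
    ridge: bool = False,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for a treatment-by-mediator interaction.

    Fits ``outcome_spec`` and ``outcome_spec + T:M``; the statistic is twice
    the log-likelihood gain on 1 df.  With ``ridge`` the fits fall back to a
    lightly penalized likelihood under separation (a sparse treatment-by-
    mediator cell can separate the augmented model at trial-sized n), making
    the statistic and p-value approximate in that case.
    """
    if "T" not in outcome_spec.terms or "M" not in outcome_spec.terms:
        raise ModelError("outcome spec must contain both T and M main effects")
    if "T:M" in outcome_spec.terms or "M:T" in outcome_spec.terms:
        raise ModelError("outcome spec already contains the T:M interaction")
    reduced = fit_logistic(data, outcome_spec, ridge=ridge)
    full = fit_logistic(data, outcome_spec.with_term("T:M"), ridge=ridge)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, 1, float(stats.chi2.sf(stat, 1))
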