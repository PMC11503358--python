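"""Synthetic two-arm randomized trial generator.

Emulates the structure of a sham-controlled ophthalmology trial: a binary
treatment assignment, a binary post-treatment anatomic mediator (adhesion
resolution at day 28), one or more binary long-term vision outcomes, baseline
covariates, and an optional rescue-vitrectomy rule under which any rescued
participant counts as an outcome failure (composite-endpoint estimand).

The generator is mechanistic: mediator, outcomes and rescue are Bernoulli
draws from logistic models whose true coefficients are part of the
data-generating process (:class:`DGP`), so exact population effects can be
computed by :mod:`medcf.oracle`.  Full latent counterfactuals — M(0), M(1) and
Y(t, m) for all four (t, m) cells — are retained for validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

__all__ = [
    "Covariate",
    "DGP",
    "TrialDataset",
    "ConfigError",
    "FormatError",
    "generate_trial",
    "oasis_like_dgp",
    "stress_dgps",
    "write_trial",
    "read_trial",
    "load_dgp",
    "save_dgp",
    "dgp_from_dict",
    "dgp_to_dict",
]

RESERVED_COLUMNS = ("id", "t", "m", "vitrectomy")

# latent counterfactual outcome cells, fixed draw order
_CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))


class ConfigError(ValueError):
    """Invalid data-generating-process configuration."""


class FormatError(ValueError):
    """Malformed trial CSV."""


@dataclass(frozen=True)
class Covariate:
    """Baseline covariate distribution.

    kind 'binary' uses ``p``; 'continuous' uses ``mean``/``sd`` (values are
    generated on the raw scale but enter all logits standardized, i.e. as
    (x - mean)/sd); 'discrete' uses ``support``/``probs`` and enters logits
    on its raw scale.
    """

    name: str
    kind: str
    p: float | None = None
    mean: float | None = None
    sd: float | None = None
    support: tuple[float, ...] | None = None
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.name in ("1", "T", "M") or self.name in RESERVED_COLUMNS:
            raise ConfigError(f"covariate name {self.name!r} is reserved")
        if self.kind == "binary":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ConfigError(f"binary covariate {self.name!r} needs p in [0, 1]")
        elif self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ConfigError(f"continuous covariate {self.name!r} needs mean and sd > 0")
        elif self.kind == "discrete":
            if not self.support or not self.probs or len(self.support) != len(self.probs):
                raise ConfigError(f"discrete covariate {self.name!r} needs matching support/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
                raise ConfigError(f"discrete covariate {self.name!r} probs must sum to 1")
        else:
            raise ConfigError(f"unknown covariate kind {self.kind!r} for {self.name!r}")


@dataclass
class DGP:
    """True data-generating process of a synthetic trial.

    Term grammar for the logistic linear predictors: ``"1"`` (intercept),
    ``"T"`` (treatment), ``"M"`` (mediator, outcome models only), a covariate
    name, or a product like ``"T:age"`` / ``"T:M"``.  Continuous covariates
    enter every logit standardized by their true mean/sd.
    """

    n: int
    alloc_ratio: float
    covariates: list[Covariate]
    mediator_terms: list[tuple[str, float]]
    outcome_terms: dict[str, list[tuple[str, float]]]
    vitrectomy_terms: list[tuple[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be positive")
        if not 0.0 < self.alloc_ratio < 1.0:
            raise ConfigError("alloc_ratio must lie strictly inside (0, 1)")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        if not self.outcome_terms:
            raise ConfigError("at least one outcome is required")
        for term, _ in self.mediator_terms:
            _check_term(term, names, allow_m=False)
        for out, terms in self.outcome_terms.items():
            if out in RESERVED_COLUMNS or out in names:
                raise ConfigError(f"outcome name {out!r} clashes with another column")
            for term, _ in terms:
                _check_term(term, names, allow_m=True)
        for term, _ in self.vitrectomy_terms or []:
            _check_term(term, names, allow_m=False)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.outcome_terms)

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


def _check_term(term: str, cov_names: Sequence[str], allow_m: bool) -> None:
    for factor in term.split(":"):
        if factor == "1" or factor == "T":
            continue
        if factor == "M":
            if not allow_m:
                raise ConfigError(f"term {term!r}: M is only allowed in outcome models")
            continue
        if factor not in cov_names:
            raise ConfigError(f"term {term!r} references unknown variable {factor!r}")


def eval_logit(
    terms: Sequence[tuple[str, float]],
    t: np.ndarray | float,
    m: np.ndarray | float | None,
    cov: Mapping[str, np.ndarray | float],
) -> np.ndarray:
    """Evaluate a DGP linear predictor. ``cov`` holds logit-scale covariate
    values (standardized for continuous covariates)."""
    total = 0.0
    for term, coef in terms:
        value = 1.0
        for factor in term.split(":"):
            if factor == "1":
                continue
            if factor == "T":
                value = value * t
            elif factor == "M":
                if m is None:
                    raise ConfigError(f"term {term!r} needs a mediator value")
                value = value * m
            else:
                value = value * cov[factor]
        total = total + coef * value
    return np.asarray(total, dtype=float)


@dataclass
class TrialDataset:
    """Per-participant trial records backed by a DataFrame.

    ``data`` columns are ``id, t, m, vitrectomy, <outcomes>, <covariates>``.
    ``latent`` (present for generated data) holds the counterfactual mediator
    values ``m0, m1`` and, per outcome, the four cells ``<out>_y_t{t}_m{m}``.
    Latent counterfactual outcomes exclude the rescue rule; observed outcomes
    are zeroed for rescued participants.
    """

    data: pd.DataFrame
    outcomes: list[str]
    covariates: list[str]
    latent: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        if df["id"].duplicated().any():
            raise FormatError("duplicate participant ids")
        binary_cols = ["t", "m", "vitrectomy", *self.outcomes]
        for col in binary_cols:
            bad = ~df[col].isin((0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"column {col!r} row {row} has non-binary value {df[col].iloc[row]!r}"
                )
        rescued = df["vitrectomy"] == 1
        for out in self.outcomes:
            if (df.loc[rescued, out] != 0).any():
                raise FormatError(f"rescued participants must have {out} = 0")
        if self.latent is not None:
            self._validate_latent()

    def _validate_latent(self) -> None:
        df, lat = self.data, self.latent
        t = df["t"].to_numpy()
        m_assigned = np.where(t == 1, lat["m1"].to_numpy(), lat["m0"].to_numpy())
        if not np.array_equal(df["m"].to_numpy(), m_assigned):
            raise FormatError("observed mediator disagrees with latent counterfactual")
        ok = df["vitrectomy"].to_numpy() == 0
        for out in self.outcomes:
            cells = {
                (tt, mm): lat[f"{out}_y_t{tt}_m{mm}"].to_numpy() for tt, mm in _CELLS
            }
            y_assigned = np.select(
                [(t == tt) & (df["m"].to_numpy() == mm) for tt, mm in _CELLS],
                [cells[c] for c in _CELLS],
            )
            if not np.array_equal(df[out].to_numpy()[ok], y_assigned[ok]):
                raise FormatError(f"observed {out} disagrees with latent counterfactual")

    def subset(self, query: str) -> "TrialDataset":
        """Row subset by a pandas query expression (latent rows follow)."""
        sub = self.data.query(query)
        lat = None
        if self.latent is not None:
            lat = self.latent.loc[self.latent["id"].isin(sub["id"])].reset_index(drop=True)
        return TrialDataset(sub.reset_index(drop=True), list(self.outcomes), list(self.covariates), lat)


def _draw_covariates(dgp: DGP, rng: np.random.Generator) -> tuple[dict, dict]:
    """Return (raw values, logit-scale values) per covariate name."""
    raw: dict[str, np.ndarray] = {}
    z: dict[str, np.ndarray] = {}
    for cov in dgp.covariates:
        if cov.kind == "binary":
            x = (rng.random(dgp.n) < cov.p).astype(float)
            raw[cov.name] = x
            z[cov.name] = x
        elif cov.kind == "continuous":
            x = rng.normal(cov.mean, cov.sd, dgp.n)
            raw[cov.name] = x
            z[cov.name] = (x - cov.mean) / cov.sd
        else:
            x = rng.choice(np.asarray(cov.support, dtype=float), size=dgp.n, p=cov.probs)
            raw[cov.name] = x
            z[cov.name] = x
    return raw, z


def generate_trial(dgp: DGP, seed: int | None = None) -> TrialDataset:
    """Simulate one trial from ``dgp`` (seed defaults to ``dgp.seed``).

    Counterfactual consistency holds by construction: one uniform per
    participant per (t, m) outcome cell decides the latent outcome, and the
    observed outcome is the latent value at the assigned (t, M(t)) — zeroed
    if the participant is rescued.
    """
    rng = np.random.default_rng(dgp.seed if seed is None else seed)
    n = dgp.n
    t = (rng.random(n) < dgp.alloc_ratio).astype(int)
    raw, z = _draw_covariates(dgp, rng)

    p_m0 = expit(eval_logit(dgp.mediator_terms, 0.0, None, z))
    p_m1 = expit(eval_logit(dgp.mediator_terms, 1.0, None, z))
    # one shared uniform per participant couples the two latent mediator
    # counterfactuals (comonotone), so a null treatment effect gives m0 == m1
    u_m = rng.random(n)
    m0 = (u_m < p_m0).astype(int)
    m1 = (u_m < p_m1).astype(int)
    m = np.where(t == 1, m1, m0)

    latent: dict[str, np.ndarray] = {"id": np.arange(n), "m0": m0, "m1": m1}
    observed_y: dict[str, np.ndarray] = {}
    for out, terms in dgp.outcome_terms.items():
        cells = {}
        for tt, mm in _CELLS:
            p = expit(eval_logit(terms, float(tt), float(mm), z))
            cells[(tt, mm)] = (rng.random(n) < p).astype(int)
            latent[f"{out}_y_t{tt}_m{mm}"] = cells[(tt, mm)]
        observed_y[out] = np.select(
            [(t == tt) & (m == mm) for tt, mm in _CELLS], [cells[c] for c in _CELLS]
        )

    if dgp.vitrectomy_terms:
        p_vit = expit(eval_logit(dgp.vitrectomy_terms, t.astype(float), None, z))
        vit = (rng.random(n) < p_vit).astype(int)
    else:
        vit = np.zeros(n, dtype=int)
    for out in observed_y:
        observed_y[out] = np.where(vit == 1, 0, observed_y[out])

    data = pd.DataFrame({"id": np.arange(n), "t": t, "m": m, "vitrectomy": vit})
    for out in dgp.outcome_names:
        data[out] = observed_y[out]
    for name in dgp.covariate_names:
        data[name] = raw[name]
    ds = TrialDataset(data, dgp.outcome_names, dgp.covariate_names, pd.DataFrame(latent))
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Shipped data-generating processes
# ---------------------------------------------------------------------------

# Outcome-model (intercept, T, M) coefficients calibrated by root-finding
# against the exact oracle so that the population TTE per outcome matches the
# published risk differences (13.9 / 23.9 / 29.3 percentage points) with the
# indirect/direct split 5.7+8.3 / 11.8+12.1 / 5.2+24.1 and plausible sham-arm
# response rates.  See docs/methods.md and analysis/00_calibrate_dgp.py.
_OASIS_OUTCOME_COEFS = {
    "vfq_i": {"1": -0.1188, "T": 0.2563, "M": 0.8637},
    "va_i": {"1": -0.8388, "T": 0.5248, "M": 1.8822},
    "vf_i": {"1": -0.0405, "T": 1.0141, "M": 1.1138},
}


def oasis_like_dgp() -> DGP:
    """Default data-generating process emulating a 218-participant, 2:1
    sham-controlled trial with a day-28 anatomic mediator and three binary
    month-24 vision outcomes (``vfq_i``, ``va_i``, ``vf_i``).

    The mediator (adhesion resolution) is strongly increased by treatment and
    modulated by age, adhesion width and epiretinal-membrane status, with a
    treatment-by-age interaction.  Rescue vitrectomy is more frequent in the
    sham arm and forces failure of every outcome.  Deterministic: repeated
    calls return identical objects.
    """
    covariates = [
        Covariate("age", "continuous", mean=66.0, sd=8.5),
        Covariate("sex", "binary", p=0.62),
        Covariate("adhesion_width", "continuous", mean=480.0, sd=160.0),
        Covariate("phakic", "binary", p=0.64),
        Covariate("erm", "binary", p=0.20),
        Covariate("ftmh", "binary", p=0.33),
        Covariate("va_base", "continuous", mean=63.0, sd=12.0),
        Covariate("vfq_base", "continuous", mean=76.0, sd=14.0),
    ]
    mediator = [
        ("1", -2.35),
        ("T", 2.05),
        ("age", -0.30),
        ("adhesion_width", -0.50),
        ("erm", -0.90),
        ("T:age", -0.30),
    ]
    common = [
        ("ftmh", -0.40),
        ("erm", -0.25),
        ("va_base", -0.30),
        ("vfq_base", -0.35),
        ("age", -0.15),
    ]
    outcomes = {}
    for out, coefs in _OASIS_OUTCOME_COEFS.items():
        outcomes[out] = [("1", coefs["1"]), ("T", coefs["T"]), ("M", coefs["M"])] + list(common)
    vitrectomy = [("1", -2.30), ("T", -0.90), ("ftmh", 0.50)]
    return DGP(
        n=218,
        alloc_ratio=2.0 / 3.0,
        covariates=covariates,
        mediator_terms=mediator,
        outcome_terms=outcomes,
        vitrectomy_terms=vitrectomy,
        seed=20240930,
    )


def stress_dgps(n: int = 500) -> dict[str, DGP]:
    """Five single-outcome stress scenarios over one Bernoulli(0.5) covariate:
    no mediation pathway, mediation-only, direct-only, mixed pathways, and
    mixed with a treatment-by-mediator interaction."""

    def make(med_t: float, out_t: float, out_m: float, out_tm: float | None = None) -> DGP:
        outcome = [("1", -1.0), ("T", out_t), ("M", out_m), ("c", 0.5)]
        if out_tm is not None:
            outcome.insert(3, ("T:M", out_tm))
        return DGP(
            n=n,
            alloc_ratio=0.5,
            covariates=[Covariate("c", "binary", p=0.5)],
            mediator_terms=[("1", -1.0), ("T", med_t), ("c", 0.5)],
            outcome_terms={"y": outcome},
            seed=0,
        )

    return {
        "null": make(0.0, 0.5, 1.5),
        "mediation_only": make(2.0, 0.0, 1.5),
        "direct_only": make(2.0, 0.5, 0.0),
        "mixed": make(2.0, 0.5, 1.5),
        "interaction": make(2.0, 0.3, 1.2, 0.8),
    }


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_trial(dataset: TrialDataset, path, latent_path=None) -> None:
    """Write observed records to ``path`` (header ``id,t,m,vitrectomy,
    <outcomes>,<covariates>``).  Latent counterfactuals, if present and
    ``latent_path`` is given, go to a sidecar CSV and are never required for
    analysis."""
    dataset.validate()
    cols = ["id", "t", "m", "vitrectomy", *dataset.outcomes, *dataset.covariates]
    dataset.data[cols].to_csv(path, index=False)
    if latent_path is not None and dataset.latent is not None:
        dataset.latent.to_csv(latent_path, index=False)


def read_trial(path, outcomes: Sequence[str], latent_path=None) -> TrialDataset:
    """Read a trial CSV. ``outcomes`` names the binary endpoint columns; any
    extra column beyond id/t/m/vitrectomy/outcomes is kept as a covariate."""
    df = pd.read_csv(path)
    required = ["id", "t", "m", "vitrectomy", *outcomes]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {', '.join(missing)}")
    covariates = [c for c in df.columns if c not in required]
    latent = pd.read_csv(latent_path) if latent_path is not None else None
    ds = TrialDataset(df, list(outcomes), covariates, latent)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def dgp_to_dict(dgp: DGP) -> dict:
    covs = []
    for c in dgp.covariates:
        d = {k: v for k, v in dataclasses.asdict(c).items() if v is not None}
        if "support" in d:
            d["support"] = list(d["support"])
            d["probs"] = list(d["probs"])
        covs.append(d)
    out = {
        "n": dgp.n,
        "alloc_ratio": dgp.alloc_ratio,
        "seed": dgp.seed,
        "covariates": covs,
        "mediator": {term: coef for term, coef in dgp.mediator_terms},
        "outcomes": {
            name: {term: coef for term, coef in terms}
            for name, terms in dgp.outcome_terms.items()
        },
    }
    if dgp.vitrectomy_terms:
        out["vitrectomy"] = {term: coef for term, coef in dgp.vitrectomy_terms}
    return out


def dgp_from_dict(cfg: Mapping) -> DGP:
    try:
        covs = [
            Covariate(
                name=c["name"],
                kind=c["kind"],
                p=c.get("p"),
                mean=c.get("mean"),
                sd=c.get("sd"),
                support=tuple(c["support"]) if "support" in c else None,
                probs=tuple(c["probs"]) if "probs" in c else None,
            )
            for c in cfg.get("covariates", [])
        ]
        return DGP(
            n=int(cfg["n"]),
            alloc_ratio=float(cfg["alloc_ratio"]),
            covariates=covs,
            mediator_terms=[(k, float(v)) for k, v in cfg["mediator"].items()],
            outcome_terms={
                name: [(k, float(v)) for k, v in terms.items()]
                for name, terms in cfg["outcomes"].items()
            },
            vitrectomy_terms=(
                [(k, float(v)) for k, v in cfg["vitrectomy"].items()]
                if "vitrectomy" in cfg
                else None
            ),
            seed=int(cfg.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing DGP config key: {exc}") from exc


def load_dgp(path) -> DGP:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("DGP config must be a mapping")
    return dgp_from_dict(cfg)


def save_dgp(dgp: DGP, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dgp_to_dict(dgp), fh, sort_keys=False)
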