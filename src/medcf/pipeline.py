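"""End-to-end analysis runner and simulation validation harness.

``run_analysis`` reproduces the shape of a trial mediation report: for each
outcome, for the total population and an anatomic subgroup, and for a primary
and an extended covariate adjustment, it runs the model checks
(Hosmer-Lemeshow per model, likelihood-ratio test for a treatment-by-mediator
interaction) and the mediation estimator, then tabulates Average IE(1),
Average DE(0), Average TTE and the Proportion Mediated with percentile
confidence intervals.

``simulate_and_recover`` validates the estimator against the exact oracle:
repeated datasets from a known DGP, with bias, empirical SD, RMSE and CI
coverage per effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .glm_core import (
    ModelSpec,
    SeparationError,
    fit_logistic,
    hosmer_lemeshow,
    lr_interaction_test,
    parse_formula,
)
from .mediation import EFFECT_NAMES, EstimationError, MediationConfig, estimate
from .oracle import true_effects
from .trialgen import DGP, ConfigError, TrialDataset, generate_trial, read_trial

__all__ = ["AnalysisPlan", "run_analysis", "simulate_and_recover", "specs_from_dgp"]

log = logging.getLogger("medcf")

_TABLE_ROWS = (("ie1", "Average IE(1)"), ("de0", "Average DE(0)"), ("tte", "Average TTE"))


@dataclass
class AnalysisPlan:
    """What to estimate, on which data, and how to report it.

    ``outcome_formulas`` maps outcome name -> {variant: formula}; the usual
    variants are ``primary`` and ``extended`` (a richer covariate adjustment).
    ``subgroup`` is a pandas query over the trial columns (e.g. ``ftmh == 0``).
    """

    dataset: TrialDataset | str
    mediator_formula: str
    outcome_formulas: dict[str, dict[str, str]]
    config: MediationConfig
    subgroup: str | None = None
    subgroup_label: str = "subgroup"
    # optional re-specified models for the subgroup (e.g. dropping a covariate
    # that the filter makes constant); default: reuse the main formulas
    subgroup_mediator_formula: str | None = None
    subgroup_outcome_formulas: dict[str, dict[str, str]] | None = None
    decimals: int = 1

    def formulas_for(self, scope_is_subgroup: bool) -> tuple[str, dict[str, dict[str, str]]]:
        if scope_is_subgroup:
            return (
                self.subgroup_mediator_formula or self.mediator_formula,
                self.subgroup_outcome_formulas or self.outcome_formulas,
            )
        return self.mediator_formula, self.outcome_formulas

    def load(self) -> TrialDataset:
        if isinstance(self.dataset, TrialDataset):
            return self.dataset
        return read_trial(self.dataset, outcomes=list(self.outcome_formulas))

    def validate(self, data: TrialDataset) -> None:
        cols = set(data.data.columns)
        for med_formula, formulas in (self.formulas_for(False), self.formulas_for(True)):
            parse_formula(med_formula)
            for out, variants in formulas.items():
                if out not in cols:
                    raise ConfigError(f"outcome column {out!r} missing from the dataset")
                for formula in variants.values():
                    parse_formula(formula)


def _scopes(plan: AnalysisPlan, data: TrialDataset) -> dict[str, TrialDataset]:
    scopes = {"total": data}
    if plan.subgroup is not None:
        sub = data.subset(plan.subgroup)
        if sub.n == 0:
            raise ConfigError(f"subgroup filter {plan.subgroup!r} matches no records")
        if sub.n < 30:
            warnings.warn(
                f"subgroup {plan.subgroup!r} has only {sub.n} records; estimates may be unstable"
            )
        scopes[plan.subgroup_label] = sub
    return scopes


def run_analysis(plan: AnalysisPlan, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis menu and return (and optionally write) the report.

    Per-cell estimation failures are recorded in the report and the run
    continues.  Identical plan + seed produce a byte-identical JSON report.
    """
    data = plan.load()
    plan.validate(data)
    scopes = _scopes(plan, data)

    cells = []
    for scope in scopes:
        _, formulas = plan.formulas_for(scope != "total")
        cells += [
            (scope, out, variant) for out in formulas for variant in formulas[out]
        ]
    children = np.random.SeedSequence(plan.config.seed).spawn(len(cells))
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]

    report: dict = {
        "plan": {
            "mediator_formula": plan.mediator_formula,
            "outcome_formulas": plan.outcome_formulas,
            "subgroup_mediator_formula": plan.subgroup_mediator_formula,
            "subgroup_outcome_formulas": plan.subgroup_outcome_formulas,
            "subgroup": plan.subgroup,
            "subgroup_label": plan.subgroup_label,
            "seed": plan.config.seed,
            "n_param_draws": plan.config.n_param_draws,
            "mediator_draws_per_param": plan.config.mediator_draws_per_param,
            "ci_level": plan.config.ci_level,
            "interaction": plan.config.interaction,
            "outcome_aggregation": plan.config.outcome_aggregation,
            "decimals": plan.decimals,
        },
        "cells": {},
    }
    rows = []
    for (scope, out, variant), cell_seed in zip(cells, seeds):
        key = f"{scope}/{out}/{variant}"
        log.info("cell %s (seed %d)", key, cell_seed)
        sub = scopes[scope]
        med_formula, formulas = plan.formulas_for(scope != "total")
        mediator_spec = parse_formula(med_formula)
        outcome_spec = parse_formula(formulas[out][variant])
        cell: dict = {"seed": cell_seed, "n": sub.n}
        try:
            ridge = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    med_fit = fit_logistic(sub, mediator_spec)
                    out_fit = fit_logistic(sub, outcome_spec)
                    lr = lr_interaction_test(sub, outcome_spec)
                except SeparationError:
                    # sparse cells can separate a fit at trial-sized n;
                    # fall back to lightly penalized likelihoods and say so
                    ridge = True
                    med_fit = fit_logistic(sub, mediator_spec, ridge=True)
                    out_fit = fit_logistic(sub, outcome_spec, ridge=True)
                    lr = lr_interaction_test(sub, outcome_spec, ridge=True)
                hl_m = hosmer_lemeshow(med_fit, sub)
                hl_y = hosmer_lemeshow(out_fit, sub)
            cell["ridge_fallback"] = ridge
            cell["hosmer_lemeshow"] = {
                "mediator": {"statistic": hl_m[0], "df": hl_m[1], "p": hl_m[2]},
                "outcome": {"statistic": hl_y[0], "df": hl_y[1], "p": hl_y[2]},
            }
            cell["lr_interaction"] = {"statistic": lr[0], "df": lr[1], "p": lr[2]}
            cfg = dataclasses.replace(plan.config, seed=cell_seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    result = estimate(sub, mediator_spec, outcome_spec, cfg, ridge=ridge)
                except SeparationError:
                    # config.interaction adds T:M inside estimate, which can
                    # separate even when the diagnostic fits did not
                    cell["ridge_fallback"] = ridge = True
                    result = estimate(sub, mediator_spec, outcome_spec, cfg, ridge=True)
            cell["effects"] = result.to_dict()["effects"]
            cell["pm"] = result.to_dict()["pm"]
            for name, label in _TABLE_ROWS:
                e = result.effects[name]
                rows.append(_table_row(scope, variant, out, label, e.point, e.lo, e.hi, plan.decimals))
            rows.append(
                _table_row(
                    scope, variant, out, "Proportion Mediated",
                    result.pm.point, result.pm.lo, result.pm.hi, plan.decimals,
                )
            )
        except (EstimationError, ConfigError, ValueError) as exc:
            log.error("cell %s failed: %s", key, exc)
            cell["error"] = str(exc)
        report["cells"][key] = cell

    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        table.to_csv(out_dir / "table.csv", index=False)
    report["table"] = rows
    return report


def _table_row(scope, variant, outcome, metric, point, lo, hi, decimals) -> dict:
    return {
        "scope": scope,
        "variant": variant,
        "outcome": outcome,
        "metric": metric,
        "estimate": round(point, decimals),
        "ci_lo": round(lo, decimals),
        "ci_hi": round(hi, decimals),
    }


def specs_from_dgp(dgp: DGP, outcome: str | None = None) -> tuple[ModelSpec, ModelSpec]:
    """Correctly specified mediator/outcome model specs for a DGP (fitting on
    the raw covariate scale, which the logistic fit absorbs)."""
    if outcome is None:
        outcome = dgp.outcome_names[0]
    med_terms = tuple(term for term, _ in dgp.mediator_terms)
    out_terms = tuple(term for term, _ in dgp.outcome_terms[outcome])
    return ModelSpec("m", med_terms), ModelSpec(outcome, out_terms)


def simulate_and_recover(
    dgp: DGP,
    n_replicates: int,
    config: MediationConfig,
    outcome: str | None = None,
) -> dict:
    """Repeatedly simulate from ``dgp`` and re-estimate, summarizing recovery
    of the oracle truth: bias, empirical SD, RMSE and CI coverage per effect,
    plus the proportion mediated."""
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    outcome = outcome or dgp.outcome_names[0]
    truth = true_effects(dgp, outcome)
    mediator_spec, outcome_spec = specs_from_dgp(dgp, outcome)

    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    points = {name: [] for name in EFFECT_NAMES}
    covered = {name: [] for name in EFFECT_NAMES}
    pm_points = []
    for child in children:
        s_data, s_est = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        data = generate_trial(dgp, seed=s_data)
        result = estimate(data, mediator_spec, outcome_spec, dataclasses.replace(config, seed=s_est))
        for name in EFFECT_NAMES:
            e = result.effects[name]
            points[name].append(e.point)
            covered[name].append(e.lo <= getattr(truth, name) <= e.hi)
        pm_points.append(result.pm.point)

    summary: dict = {"n_replicates": n_replicates, "n": dgp.n, "outcome": outcome, "effects": {}}
    for name in EFFECT_NAMES:
        p = np.asarray(points[name])
        tval = getattr(truth, name)
        summary["effects"][name] = {
            "truth": tval,
            "mean": float(p.mean()),
            "bias": float(p.mean() - tval),
            "empirical_sd": float(p.std(ddof=1)) if n_replicates > 1 else 0.0,
            "rmse": float(np.sqrt(np.mean((p - tval) ** 2))),
            "coverage_pct": 100.0 * float(np.mean(covered[name])),
        }
    pm_arr = np.asarray(pm_points)
    summary["effects"]["pm"] = {
        "truth": truth.pm,
        "mean": float(pm_arr.mean()),
        "bias": float(pm_arr.mean() - truth.pm) if truth.pm is not None else None,
        "empirical_sd": float(pm_arr.std(ddof=1)) if n_replicates > 1 else 0.0,
        "rmse": (
            float(np.sqrt(np.mean((pm_arr - truth.pm) ** 2))) if truth.pm is not None else None
        ),
        "coverage_pct": None,
    }
    return summary
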