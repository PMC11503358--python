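# medcf — counterfactual mediation analysis for randomized trials

`medcf` estimates how much of a randomized treatment's effect on a binary
endpoint is transmitted through a binary post-treatment mediator, using the
counterfactual (natural effects) framework. It was built around a concrete
clinical question — in a sham-controlled trial of enzymatic vitreolysis for
vitreomacular traction, how much of the treatment effect on month-24 vision
outcomes runs through resolution of the vitreomacular adhesion at day 28? —
but the machinery is generic: any two-arm trial with a binary mediator,
binary outcomes and baseline confounders of the mediator–outcome relation.

Because individual-participant trial data of this kind are access-restricted,
the package ships a synthetic trial generator whose logistic mechanisms are
calibrated to published effect sizes, together with an exact analytic oracle
that computes the population values of every estimand for any generator
configuration. Estimator and oracle are developed independently, so the
oracle doubles as the validation standard for the estimator.

## The estimands

For participant *i*, let M<sub>i</sub>(t) be the mediator status under
treatment t ∈ {0, 1} and Y<sub>i</sub>(t, m) the outcome under treatment t
with mediator fixed at m. The four counterfactual outcomes
Y<sub>i</sub>(t, M<sub>i</sub>(t′)) define, as risk differences:

- **indirect (mediated) effects** IE(1) = E[Y(1, M(1)) − Y(1, M(0))] and
  IE(0) = E[Y(0, M(1)) − Y(0, M(0))] — the outcome shift caused by moving the
  mediator as far as treatment moves it, at fixed treatment;
- **direct effects** DE(1) = E[Y(1, M(1)) − Y(0, M(1))] and
  DE(0) = E[Y(1, M(0)) − Y(0, M(0))] — the outcome shift caused by treatment
  with the mediator held at one of its counterfactual values;
- **total treatment effect** TTE = E[Y(1, M(1)) − Y(0, M(0))], which
  decomposes exactly as TTE = IE(1) + DE(0) = IE(0) + DE(1);
- **proportion mediated** PM = IE(1)/TTE (unstable when TTE ≈ 0).

Estimation follows the mediation formula with two logistic regressions — a
mediator model given treatment and baseline covariates, and an outcome model
given treatment, mediator and covariates — and a quasi-Bayesian Monte Carlo
loop: model coefficients are drawn from the asymptotic normal distribution of
the maximum-likelihood estimates; per draw, each participant's two
counterfactual mediator values are simulated and the four counterfactual
outcome probabilities evaluated; effects are averaged over participants, and
percentile intervals are taken over draws. Valid causal interpretation needs
sequential ignorability: given treatment and the adjusted baseline
covariates, the mediator is as-if randomized.

## Worked example

```python
from medcf import MediationConfig, estimate, generate_trial, oasis_like_dgp, parse_formula

trial = generate_trial(oasis_like_dgp(), seed=11)   # 218 participants, 2:1
result = estimate(
    trial,
    mediator_spec=parse_formula("m ~ 1 + T + age + adhesion_width + erm + T:age"),
    outcome_spec=parse_formula("vf_i ~ 1 + T + M + ftmh + va_base + vfq_base"),
    config=MediationConfig(n_param_draws=1000, seed=1),
)
for name in ("ie1", "de0", "tte"):
    e = result.effects[name]
    print(f"{name}: {e.point:5.1f}  [{e.lo:5.1f}, {e.hi:5.1f}]")
print(f"pm : {result.pm.point:5.1f}  [{result.pm.lo:5.1f}, {result.pm.hi:5.1f}]")
```

prints

```
ie1:   6.9  [  2.5,  12.4]
de0:  24.6  [ 10.2,  37.5]
tte:  31.5  [ 18.3,  43.7]
pm :  21.8  [  7.7,  48.4]
```

Read: treatment raises the probability of a composite vision improvement by
31.5 percentage points in this simulated trial; 6.9 points of that operate
through adhesion resolution (about 22% mediated), the remaining 24.6 points
through other pathways. The intervals are 95% percentile intervals over 1000
quasi-Bayesian draws. For this generator configuration the exact population
values are IE(1) = 5.2, DE(0) = 24.1, TTE = 29.3 — the single-trial estimates
scatter around them with the sampling noise a 218-participant trial implies.

## Analysis scripts

The `analysis/` directory holds the narrative pipeline, each step writing its
tables under `results/`:

| script | what it does |
|---|---|
| `00_calibrate_dgp.py` | re-derives the generator's outcome coefficients by root-finding against the oracle |
| `01_generate_trial.py` | simulates the trial CSV (+ latent counterfactual sidecar) |
| `02_model_checks.py` | Hosmer–Lemeshow fit checks; LR tests for treatment×mediator interaction |
| `03_mediation_analysis.py` | full effect tables: total population, VMT-only subgroup, extended adjustment, interaction sensitivity |
| `04_recovery.py` | bias/SD/RMSE/coverage of the estimator against the oracle on five stress scenarios |

The same pipeline is scriptable via the `medcf` command
(`generate` / `truth` / `run` / `recover`); see `medcf --help`.

## Documentation

`docs/methods.md` describes the statistical model, the generator's
calibration and its limitations, numerical choices and known caveats.
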