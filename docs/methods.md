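# Methods

## Scope and estimands

`medcf` targets a two-arm randomized trial with a binary post-treatment
mediator M (an anatomic surrogate measured shortly after treatment), one or
more binary long-term outcomes Y, and baseline covariates C that confound the
mediator–outcome relation. Treatment T is randomized; the mediator is not.
The estimands are the natural-effects decomposition of the total treatment
effect on the risk-difference scale, in percentage points:

    IE(1) = E[Y(1, M(1)) − Y(1, M(0))]     IE(0) = E[Y(0, M(1)) − Y(0, M(0))]
    DE(1) = E[Y(1, M(1)) − Y(0, M(1))]     DE(0) = E[Y(1, M(0)) − Y(0, M(0))]
    TTE   = E[Y(1, M(1)) − Y(0, M(0))] = IE(1) + DE(0) = IE(0) + DE(1)
    PM    = IE(1) / TTE

Identification rests on sequential ignorability: randomization handles
treatment–mediator and treatment–outcome confounding; conditional on T and C,
the mediator must be as-if randomized (no unmeasured mediator–outcome
confounders and no post-treatment confounders). This is an assumption, not a
testable property; the package provides no diagnostic for it.

## Estimation algorithm

1. **Model fitting.** Two logistic regressions by maximum likelihood: the
   mediator model P(M = 1 | T, C) and the outcome model P(Y = 1 | T, M, C)
   (optionally with a T×M interaction). The covariance of the estimates is
   the inverse observed information.
2. **Parameter uncertainty.** J quasi-Bayesian draws (default 1000) from
   N(β̂, V̂), independently for the two models. This propagates estimation
   uncertainty at a fraction of the cost of a bootstrap; a bootstrap is not
   implemented.
3. **Counterfactual simulation.** Per draw and participant, the mediator
   model is evaluated at t′ = 0 and t′ = 1 with the participant's own
   covariates, and M(0), M(1) are Bernoulli draws from those probabilities
   (independent uniforms by default; `couple_mediator_draws` shares one
   uniform as a variance-reduction option). The outcome model is then
   evaluated at the four (t, M(t′)) configurations.
4. **Aggregation.** By default the counterfactual outcomes enter as expected
   probabilities (`expected_probability`), which is identical in expectation
   to drawing binary outcomes but strictly less noisy; the literal
   `binary_draw` variant is retained and tested for the variance ordering.
   Effects are participant means per draw; point estimates are means over
   draws; intervals are symmetric percentile intervals at `ci_level`
   (default 0.95), with no bias correction.
5. **Proportion mediated.** The point estimate is the ratio of the averaged
   IE(1) and TTE (this reproduces the conventional printed arithmetic, e.g.
   5.2/29.3 → 17.7%); the interval is the percentile interval of per-draw
   ratios, which legitimately explodes when TTE draws approach zero — the
   result carries an `unstable` flag whenever the TTE draws straddle zero.
   PM is undefined at TTE = 0 and raises.

Without a T×M interaction the two decompositions coincide up to Monte Carlo
noise and reports tabulate the (IE(1), DE(0)) pair; with an interaction all
five effects remain available and the draws retain both decompositions
exactly (the identity IE(1)+DE(0) = IE(0)+DE(1) = TTE holds algebraically per
draw and is property-tested to 1e-10).

## Model fitting details

- Optimization starts from a statsmodels IRLS fit and finishes with Newton
  steps until max |Δβ| < 1e-8 (cap 100), so the score at the returned
  estimate vanishes below 1e-6 — an invariant the tests assert.
- **Separation** (a logit drifting beyond ±25) raises a hard error by
  default. With `ridge=True` the fit falls back to a lightly penalized
  likelihood (1e-6·‖β‖²) with a warning: the Monte Carlo engine needs a
  finite covariance matrix, and at trial-sized n a sparse treatment×mediator
  cell can genuinely separate the interaction-augmented outcome model. The
  analysis runner applies this fallback per cell automatically and records
  `ridge_fallback` in the report.
- Singular designs are rejected with the collinear terms named (QR with
  column pivoting).
- The formula grammar is `y ~ 1 + T + M + age + T:age + age^2`. Squared
  terms apply to continuous covariates only and are centered at the sample
  mean before squaring (the center is stored with the fit and reused for
  prediction).
- **Hosmer–Lemeshow**: deciles of risk on the sorted predicted
  probabilities; ties at a group boundary stay in the lower group, making
  the partition deterministic; groups with expected count < 1 are merged
  into a neighbor with a warning; df = final group count − 2. Under a
  correctly specified model the simulated rejection rate at α = 0.05 sits
  near nominal (asserted in [2%, 9%] over 500 fits).
- **Interaction LR test**: the outcome model with and without T×M, statistic
  2·Δloglik on 1 df. Type-I error is simulation-tested at n = 1000.

## The synthetic trial generator

The generator emulates the structure of a sham-controlled vitreolysis trial:
n = 218 participants, 2:1 treatment allocation (independent Bernoulli per
participant, not blocked), a day-28 binary mediator (adhesion resolution)
strongly increased by treatment and modulated by age, adhesion width and
epiretinal-membrane status with a treatment-by-age interaction, three binary
month-24 outcomes (questionnaire response `vfq_i`, acuity response `va_i`,
composite response `vf_i`) depending on treatment, mediator and prognostic
baseline covariates, and a rescue-vitrectomy indicator — more frequent under
sham — that forces all outcomes to failure (composite-endpoint estimand).
Latent counterfactuals (M(0), M(1), and Y(t, m) for all four cells) are
retained; one uniform per participant per (t, m) cell makes the observed data
consistent with the latent values by construction, and a shared uniform
couples M(0)/M(1) comonotonically.

**Calibration.** The outcome models' (intercept, T, M) coefficients were
solved by root-finding against the exact oracle (`analysis/00_calibrate_dgp.py`)
so that the population IE(1)/DE(0) per outcome equal 5.7/8.3, 11.8/12.1 and
5.2/24.1 percentage points — published values for this trial design — giving
TTEs of 14.0, 23.9 and 29.3. Quantities the public record does not pin down
are design choices made once: sham-arm response rates (0.40/0.28/0.42),
covariate distributions (age ~ N(66, 8.5) years, adhesion width
~ N(480, 160) µm, baseline acuity ~ N(63, 12) letters, baseline questionnaire
score ~ N(76, 14), sex 62% / phakic 64% / ERM 20% / FTMH 33%), the mediator
model's logits (sham resolution ≈ 10%, treated ≈ 42%), the vitrectomy logits
(sham ≈ 11%, treated ≈ 5%) and the 2:1 allocation. Continuous covariates
enter every logit standardized by their true mean/sd; raw values are stored
in the CSV.

**What passing tests do and do not show.** The generator draws all mechanisms
from correctly specified logistic models with complete data: no missingness,
no longitudinal visit structure, no blocked randomization, no measurement
error in the mediator, and a rescue process that depends only on treatment
and baseline FTMH. Estimator validation against this generator therefore
demonstrates correctness of the algorithm under its own assumptions — not
robustness to the model misspecification, attrition or unmeasured
confounding a real trial may harbor. One deliberate misspecification does
remain: the rescue rule makes the observed-outcome law a vitrectomy-survival
factor times a logistic term, which a single logistic outcome model only
approximates; the calibrated oracle targets the observed (composite)
estimand, and at n = 218 the approximation error is far below sampling noise.

## The oracle

For any generator configuration the population counterfactual mean is

    E[Y(t, M(t′))] = E_C[(1 − p_vit(t, C)) · Σ_m P(M = m | t′, C) · P(Y = 1 | t, m, C)]

Binary and discrete covariates are enumerated exactly; up to two continuous
covariates are integrated by 32-node Gauss–Hermite quadrature on the
standardized scale; beyond two (the shipped trial DGP has four) a fixed-seed
Monte Carlo integral is used, chunked at 10⁶ draws (default 10⁷ total,
standard error ≈ 0.002 percentage points on an effect). The four means share
integration points, so the decomposition identities hold to machine
precision. A companion mode integrates over an empirical covariate table for
sample-average estimands.

## Validation summary (computed by the tests and `scripts/acceptance.py`)

- Exact decomposition per Monte Carlo draw (≤ 1e-10 over ≥ 1000 draws).
- Oracle recovery at n = 50 000 / 500 draws on the mixed stress scenario;
  the estimator is unbiased and the residual error is the information bound
  of a 50 000-participant trial (per-effect SD ≈ 0.45 points).
- Null-pathway calibration (IE(1) near zero, interval covering zero ≥ 90%
  of 200 replicates at n = 500) and interval coverage in [90%, 98%] for
  IE(1) and DE(0) on the mixed scenario.
- LR interaction test type-I error near nominal over 500 replicates.
- Generator TTEs within 3 points of their calibration targets.
- Byte-identical reports for identical plan and seed.

Problem sizes in the routine runs (200–500 replicates at n = 500–1000, one
50 000-participant recovery run, 4·10⁶ oracle draws) were chosen to keep each
simulation's Monte Carlo error well below the tolerance it checks.

## Known limitations

- Single binary mediator; no continuous-mediator or multiple-mediator
  support, and no treatment-policy estimand for continuous outcomes.
- No sensitivity analysis for unmeasured mediator–outcome confounding.
- Percentile intervals without bias correction; PM intervals are honest but
  can be uninformative when TTE ≈ 0 (flagged, not suppressed).
- The quasi-Bayesian approximation relies on asymptotic normality of the
  MLEs; in very small subgroups (< 30 records the runner warns) or under
  separation handled by the ridge fallback, intervals are approximate.
- Automatic model building is intentionally absent: model specs are explicit
  inputs, keeping the estimator auditable.
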