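"""Mediation analysis: how much of the treatment effect runs through the
anatomic mediator?

Runs the full counterfactual mediation pipeline on the generated trial for
the three vision outcomes: total population and the VMT-only subgroup (no
full-thickness macular hole), each under the primary and an extended
covariate adjustment, plus a sensitivity analysis that adds a
treatment-by-mediator interaction.  Writes report.json and table.csv under
results/mediation/ and prints the headline rows (Average IE(1), Average
DE(0), Average TTE, Proportion Mediated, with 95% percentile intervals),
then compares against the exact oracle values implied by the generator.
"""

from pathlib import Path

import pandas as pd

from medcf import MediationConfig, read_trial, run_analysis, true_effects_all, oasis_like_dgp
from medcf.pipeline import AnalysisPlan

RESULTS = Path(__file__).resolve().parents[1] / "results"
OUTCOMES = ("vfq_i", "va_i", "vf_i")
SEED = 7

MEDIATOR_FORMULA = "m ~ 1 + T + age + adhesion_width + erm + T:age"
PRIMARY = "{out} ~ 1 + T + M + ftmh + va_base + vfq_base"
EXTENDED = "{out} ~ 1 + T + M + ftmh + erm + va_base + vfq_base + age + sex + phakic"
# ftmh is constant in the VMT-only subgroup, so the refitted models drop it
SUB_PRIMARY = "{out} ~ 1 + T + M + va_base + vfq_base"
SUB_EXTENDED = "{out} ~ 1 + T + M + erm + va_base + vfq_base + age + sex + phakic"


def build_plan(data, interaction: bool) -> AnalysisPlan:
    return AnalysisPlan(
        dataset=data,
        mediator_formula=MEDIATOR_FORMULA,
        outcome_formulas={
            out: {"primary": PRIMARY.format(out=out), "extended": EXTENDED.format(out=out)}
            for out in OUTCOMES
        },
        subgroup="ftmh == 0",
        subgroup_label="vmt_only",
        subgroup_outcome_formulas={
            out: {"primary": SUB_PRIMARY.format(out=out), "extended": SUB_EXTENDED.format(out=out)}
            for out in OUTCOMES
        },
        config=MediationConfig(n_param_draws=1000, seed=SEED, interaction=interaction),
    )


def main() -> None:
    data = read_trial(RESULTS / "trial.csv", outcomes=list(OUTCOMES))

    report = run_analysis(build_plan(data, interaction=False), out_dir=RESULTS / "mediation")
    table = pd.DataFrame(report["table"])
    print("primary analysis (no treatment-by-mediator interaction):")
    for scope in ("total", "vmt_only"):
        sub = table[(table["scope"] == scope) & (table["variant"] == "primary")]
        print(f"\n  {scope}:")
        print(
            sub.pivot(index="metric", columns="outcome", values="estimate")
            .loc[["Average IE(1)", "Average DE(0)", "Average TTE", "Proportion Mediated"]]
            .to_string()
        )

    # sensitivity: allow the direct effect to differ by mediator status
    sens = run_analysis(build_plan(data, interaction=True), out_dir=RESULTS / "mediation_interaction")
    print("\nsensitivity analysis with T:M interaction (total population, primary):")
    max_shift = 0.0
    for out in OUTCOMES:
        cell = sens["cells"][f"total/{out}/primary"]["effects"]
        main_cell = report["cells"][f"total/{out}/primary"]["effects"]
        shift = max(
            abs(cell["ie1"]["point"] - main_cell["ie1"]["point"]),
            abs(cell["de0"]["point"] - main_cell["de0"]["point"]),
        )
        max_shift = max(max_shift, shift)
        print(
            f"  {out}: IE(1) {main_cell['ie1']['point']:5.1f} -> {cell['ie1']['point']:5.1f}, "
            f"DE(0) {main_cell['de0']['point']:5.1f} -> {cell['de0']['point']:5.1f}"
        )
    if max_shift < 3.0:
        print("  -> estimates remain similar; the no-interaction assumption is retained")
    else:
        print(
            f"  -> allowing the interaction shifts an effect by up to {max_shift:.1f} points; "
            "report both analyses"
        )

    print("\noracle truth of the generator (population estimands, percentage points):")
    for out, t in true_effects_all(oasis_like_dgp(), n_mc=1_000_000).items():
        print(f"  {out}: IE(1) {t.ie1:4.1f}, DE(0) {t.de0:4.1f}, TTE {t.tte:4.1f}, PM {t.pm:4.1f}%")
    print(f"\nwrote {RESULTS / 'mediation'} and {RESULTS / 'mediation_interaction'}")


if __name__ == "__main__":
    main()
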