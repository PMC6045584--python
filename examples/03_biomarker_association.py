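"""Test a genotype marker for association with drug sensitivity.

Simulates a 20-line panel in which 30% of lines carry a marker that
makes them 30-fold more sensitive (lower ED50) to one drug, runs the
full fit-and-score chain, and applies the two-sided Mann-Whitney U test
(uncorrected) of robust Z scores between carriers and non-carriers —
the same analysis used to link, e.g., FGFR1 amplification to FGFR
inhibitor response or Rb loss to CDK4/6 inhibitor resistance.
"""

from chemoscreen import (
    GenotypeEffect,
    ScreenSimConfig,
    mann_whitney_association,
    sensitivity_ranks,
    simulate_screen,
)
from chemoscreen.pipeline import fit_and_score

cfg = ScreenSimConfig(
    n_cell_lines=20,
    n_drugs=1,
    noise_sigma=0.1,
    genotype_effects={
        "MARKER_amp": GenotypeEffect(fraction=0.3, ed50_fold=30.0, drugs=("DRUG001",))
    },
    seed=11,
)
datasets, annotations, _ = simulate_screen(cfg)
_, _, _, auc_z = fit_and_score(datasets)
flags = {a.cell_line_id: a.genotype_flags["MARKER_amp"] for a in annotations}

res = mann_whitney_association(
    auc_z["DRUG001"].to_numpy(),
    [flags[line] for line in auc_z.index],
    drug_id="DRUG001",
    marker="MARKER_amp",
)
print(
    f"DRUG001 vs MARKER_amp: U = {res.u_statistic:.1f}, "
    f"p = {res.p_value:.4g} (uncorrected), groups = {res.group_sizes}"
)
ranks = sensitivity_ranks(auc_z["DRUG001"])
carriers = [line for line, f in flags.items() if f == "positive"]
print(f"carrier sensitivity ranks (1 = most sensitive): "
      f"{sorted(int(ranks[c]) for c in carriers)} of {len(ranks)}")
print(
    "\nA small p with carriers clustered at the top ranks reproduces the\n"
    "expected genotype-linked sensitivity; p values are reported raw, so\n"
    "screening many markers requires multiplicity correction downstream."
)
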