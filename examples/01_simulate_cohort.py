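"""Generate a synthetic two-release pharmacogenomic cohort and inspect it.

The cohort mimics two consecutive GDSC-style data releases: release 1
provides the training panel, release 2 contributes only newly tested cell
lines.  Ground truth (which drugs are monogenic/polygenic/null, and which
genes are causal) is recorded so downstream recovery can be checked.
"""

import pharmbench as pb

config = pb.GeneratorConfig(
    n_genes=500,
    n_cells_release1=120,
    n_cells_new_release2=60,
    drug_specs=pb.default_drug_panel(n_monogenic=2, n_polygenic=2, n_null=2),
    seed=1,
)
cohort = pb.generate_cohort(config)

n_cells, n_genes = cohort.expression.shape
print(f"expression matrix: {n_cells} cell lines x {n_genes} genes")
print(f"release 1 measurements: {cohort.response_r1.n_pairs} (drug, cell) pairs")
print(f"release 2 measurements: {cohort.response_r2.n_pairs} (new cells only)")
print(f"mutated fraction overall: {cohort.mutations.status.to_numpy().mean():.3f}")
print("\nground truth per drug:")
print(cohort.truth.rows.to_string(index=False))
# Each monogenic drug has one causal gene whose mutation shifts logIC50 by
# `effect` (negative = sensitising); polygenic drugs sum 20 weighted
# expression effects; null drugs carry no signal at all.
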