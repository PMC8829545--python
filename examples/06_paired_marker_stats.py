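"""Paired blood-vs-LN and between-group statistics on per-donor summaries.

Tests operate on one value per donor (a subset frequency or an MSI),
never on cells, to avoid pseudoreplication. Paired t tests compare the
two compartments within donors; BH correction runs across the family
of subsets. The replica cohort plants more Tfh-like (CD69+ memory)
CD4 T cells and CD56-bright NK cells in the lymph node.
"""

from cytopheno import differential_scan, evaluate_gate_tree, generate_cohort, subset_frequencies
from cytopheno.presets import replica_cohort_spec, replica_gate_tree

table = generate_cohort(replica_cohort_spec(cells_per_subject=800, seed=2))
assign = evaluate_gate_tree(table, replica_gate_tree())

frames = {
    name: subset_frequencies(assign, table, num, den)
    for name, (num, den) in {
        "CD4_Trm_of_CD4_T": ("CD4_Trm", "CD4_T"),
        "CD4_Tfh_of_CD4_T": ("CD4_Tfh", "CD4_T"),
        "CD8_Tem_of_CD8_T": ("CD8_Tem", "CD8_T"),
        "NK_bright_of_NK": ("NK_CD56bright", "NK"),
        "NK_dim_of_NK": ("NK_CD56dim", "NK"),
    }.items()
}
result = differential_scan(frames, "percentage", mode="paired", arms=("blood", "LN"))
print(result.round(4).to_string(index=False))
# Negative t: the LN arm is larger. The planted LN shifts (Tfh/Trm up,
# activated effector CD8 and CD56-dim NK down) should be significant
# after BH; subsets without planted shifts should not.
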