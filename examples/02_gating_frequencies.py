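"""Hierarchical gating: canonical subset frequencies and MSI.

Evaluates the shipped T/NK gate tree (T cells = CD19-CD14-CD33-CD3+,
naive vs memory by CD45RA/CD45RO, NK strata by CD56 level, ...) on a
synthetic cohort and summarizes per-donor subset frequencies and mean
signal intensities, the quantities the downstream paired/unpaired
statistics consume.
"""

from cytopheno import evaluate_gate_tree, generate_cohort, mean_signal_intensity, subset_frequencies
from cytopheno.presets import replica_cohort_spec, replica_gate_tree

table = generate_cohort(replica_cohort_spec(cells_per_subject=1000, seed=1))
tree = replica_gate_tree()

assign = evaluate_gate_tree(table, tree)
assign.check_hierarchy()   # child membership implies parent membership
assign.check_partitions()  # quadrant/stratum partitions are exclusive+exhaustive

freq = subset_frequencies(assign, table, "CD4_Tn", "CD4_T")
print("naive CD4 T cells as % of CD4 T, per donor and compartment (head):")
print(freq.head(6).to_string(index=False))

msi = mean_signal_intensity(table, assign, "CD8_T", "CD38")
print("\nCD38 MSI on CD8 T cells (head):")
print(msi.head(6).to_string(index=False))
# Frequencies are percentages of the parent gate; MSI is the arithmetic
# mean of the arcsinh-transformed marker over the donor's gated cells.
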