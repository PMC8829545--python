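"""SNN/Jaccard graph clustering of a cohort with known populations.

Builds the exact k-nearest-neighbor graph on the clustering channels,
re-weights edges by the Jaccard similarity of neighbor sets, runs
Leiden community detection, filters communities below 50 cells, and
compares the result with the planted populations.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from cytopheno import cluster_graph, filter_clusters, generate_cohort, knn_neighbors, snn_jaccard
from cytopheno.io import PanelConfig
from cytopheno.presets import well_separated_spec

table = generate_cohort(well_separated_spec(cells_per_subject=1000, seed=3))
panel = PanelConfig(markers=list(table.markers))

knn = knn_neighbors(table, panel, k=20)
graph = snn_jaccard(knn, prune_threshold=1 / 15)
print(f"SNN graph: {graph.n_cells} cells, {len(graph.weights)} edges, "
      f"median Jaccard weight {np.median(graph.weights):.3f}")

labels = filter_clusters(cluster_graph(graph, resolution=0.05, seed=0), min_cells=50)
mask = labels.labels != -1
ari = adjusted_rand_score(table.truth_population[mask], labels.labels[mask])
print(f"clusters: {labels.n_clusters}, sizes {labels.sizes()}")
print(f"adjusted Rand index vs planted populations: {ari:.3f}")
# ARI of 1.0 means the communities reproduce the planted populations
# exactly (up to labeling); the 5 populations are ~8 SDs apart, so any
# resolution in the scan range recovers them.
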