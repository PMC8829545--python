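"""Shipped configurations and fixture builders.

The replica panel (42 markers, 39 clustering channels), gate hierarchy
and default synthetic cohort live as YAML under
``cytopheno/configs``; this module loads them and provides small
programmatic cohort builders used throughout the tests and examples.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .gating import GateTree, load_gate_tree
from .io import PanelConfig, load_panel
from .synthetic import CohortSpec, PopulationArchetype

__all__ = [
    "replica_panel",
    "replica_gate_tree",
    "replica_cohort_spec",
    "archetype_expected_gates",
    "well_separated_spec",
]


def _config_path(name: str):
    return resources.files("cytopheno") / "configs" / name


def replica_panel() -> PanelConfig:
    with resources.as_file(_config_path("panel_replica.yaml")) as p:
        return load_panel(p)


def replica_gate_tree() -> GateTree:
    with resources.as_file(_config_path("gates_replica.yaml")) as p:
        return load_gate_tree(p)


def replica_cohort_spec(**overrides) -> CohortSpec:
    """The default 19-subject, two-compartment synthetic cohort.

    Keyword overrides replace spec fields (e.g. ``cells_per_subject=500``
    for a quick run).
    """
    from dataclasses import replace

    from .io import load_cohort_spec

    with resources.as_file(_config_path("cohort_replica.yaml")) as p:
        spec = load_cohort_spec(p)
    return replace(spec, **overrides) if overrides else spec


# Gate memberships each archetype's noise-free cells must have under the
# replica tree (used to verify gating recovers the ground truth exactly).
archetype_expected_gates: dict[str, frozenset[str]] = {
    "CD4_Tn": frozenset({"T", "CD4_T", "CD4_Tn"}),
    "CD4_Tcm": frozenset({"T", "CD4_T", "CD4_Tm", "CD4_Tcm"}),
    "CD4_Tfh": frozenset({"T", "CD4_T", "CD4_Tm", "CD4_Tfh", "CD4_Trm"}),
    "CD4_Treg": frozenset({"T", "CD4_T", "CD4_Tm", "CD4_Treg"}),
    "CD8_Tn": frozenset({"T", "CD8_T", "CD8_Tn"}),
    "CD8_Tem_act": frozenset({"T", "CD8_T", "CD8_Tm", "CD8_Tem", "CD8_activated"}),
    "NK_bright": frozenset({"NK", "NK_CD56bright", "NK_bright_TCF1pos"}),
    "NK_dim": frozenset({"NK", "NK_CD56dim", "NK_dim_TCF1neg"}),
}


def well_separated_spec(
    n_populations: int = 5,
    n_markers: int = 10,
    n_subjects: int = 8,
    cells_per_subject: int = 2000,
    sd: float = 0.4,
    separation_sds: float = 6.0,
    seed: int = 0,
) -> CohortSpec:
    """Cohort of well-separated spherical populations for clustering tests.

    Population means sit on distinct coordinate axes at a distance
    giving pairwise separation of at least ``separation_sds`` pooled
    SDs (Euclidean distance between means >= separation_sds * sd).
    """
    if n_populations > n_markers:
        raise ValueError("need at least one marker axis per population")
    offset = separation_sds * sd  # axis offset; pairwise distance = offset * sqrt(2)
    markers = [f"M{i + 1}" for i in range(n_markers)]
    pops = []
    for j in range(n_populations):
        mean = np.zeros(n_markers)
        mean[j] = offset
        pops.append(
            PopulationArchetype(
                name=f"pop{j + 1}",
                mean_vector=mean,
                sd_vector=np.full(n_markers, sd),
                base_logit=0.0,
            )
        )
    half = max(2, n_subjects // 2)
    return CohortSpec(
        populations=pops,
        markers=markers,
        groups=("controller", "acute"),
        subjects_per_group={"controller": half, "acute": n_subjects - half},
        cells_per_subject=cells_per_subject,
        subject_sd=0.0,
        seed=seed,
    )
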