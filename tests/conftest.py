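import dataclasses

import numpy as np
import pytest

from cytopheno.io import PanelConfig
from cytopheno.presets import replica_cohort_spec, replica_gate_tree, well_separated_spec
from cytopheno.synthetic import generate_cohort


@pytest.fixture(scope="session")
def replica_tree():
    return replica_gate_tree()


@pytest.fixture(scope="session")
def small_cohort():
    """Replica cohort at reduced size: 19 subjects x 2 compartments x 200 cells."""
    return generate_cohort(replica_cohort_spec(cells_per_subject=200, seed=11))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Replica cohort with all marker SDs zero: cells sit exactly on archetype means."""
    spec = replica_cohort_spec(cells_per_subject=100, seed=5)
    pops = [dataclasses.replace(p, sd_vector=np.zeros_like(p.sd_vector))
            for p in spec.populations]
    return generate_cohort(dataclasses.replace(spec, populations=pops))


@pytest.fixture(scope="session")
def separated_table():
    """5 well-separated populations, 8 subjects x 500 cells, 10 markers."""
    table = generate_cohort(well_separated_spec(cells_per_subject=500, seed=2))
    panel = PanelConfig(markers=list(table.markers))
    return table, panel
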