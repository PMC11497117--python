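import numpy as np
import pandas as pd
import pytest

from spatialniche import synthetic_data as sd
from spatialniche.phenotyping import phenotype_cells


@pytest.fixture(scope="session")
def small_config():
    """A reduced-field sample configuration for fast unit tests."""
    return sd.SimulationConfig(
        seed=11,
        archetype="inflamed_margin",
        field_size_um=(1400.0, 1400.0),
        tumor_center_um=(700.0, 700.0),
        tumor_radius_um=400.0,
        stroma_margin_um=200.0,
        satellite_clusters=(6, 40.0, 30.0),
        aggregate_offset_um=(300.0, 500.0),
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    cells, truth = sd.simulate_sample(small_config, sample_id="s0")
    return cells, truth


@pytest.fixture(scope="session")
def phenotyped_sample(small_sample):
    cells, truth = small_sample
    return phenotype_cells(cells, sd.canonical_rule()), truth


def random_cells(rng, n, size_um=1000.0, sample_id="s"):
    """Uniform random phenotyped point pattern (test helper)."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "sample_id": sample_id,
            "x_um": rng.uniform(0, size_um, n),
            "y_um": rng.uniform(0, size_um, n),
            "phenotype": rng.integers(0, 8, n),
        }
    )
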