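import warnings

import numpy as np
import pytest

from asokd import (CellTypeSpec, SimConfig, aggregate_counts, simulate_experiment)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_type_config():
    """A small cerebellum-like experiment: three cell types with unequal
    proportions, basal expression and knockdown depth."""
    return SimConfig(
        cell_types=[
            CellTypeSpec("granule", 0.6, 250.0),
            CellTypeSpec("MLI", 0.2, 400.0),
            CellTypeSpec("astrocyte", 0.2, 150.0),
        ],
        residual={"granule": 0.6, "MLI": 0.25, "astrocyte": 0.45},
        mechanism="scale",
        n_animals_per_arm=3,
        n_cells_per_animal=800,
        seed=42,
    )


@pytest.fixture(scope="session")
def three_type_experiment(three_type_config):
    return simulate_experiment(three_type_config)


@pytest.fixture(scope="session")
def three_type_aggregate(three_type_experiment):
    counts, meta = three_type_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate_counts(counts, meta)
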