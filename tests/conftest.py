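import numpy as np
import pytest

import rarestrat as rs


@pytest.fixture(scope="session")
def small_cohort() -> rs.GenotypeDataset:
    """European-like 3-subpopulation cohort, small enough for unit tests."""
    model = rs.european_like(n_per_subpop=60, n_genes=40, seed=101)
    ds = rs.simulate_genotype_dataset(model)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def two_pop_cohort() -> rs.GenotypeDataset:
    """Two well-separated subpopulations (F = 0.1) for structure tests."""
    model = rs.PopulationModel(
        subpop_sizes=(200, 200), fst=0.1, n_genes=120, seed=202, subpop_names=("A", "B")
    )
    return rs.simulate_genotype_dataset(model)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
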