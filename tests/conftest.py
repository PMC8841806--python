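import numpy as np
import pandas as pd
import pytest

from metabalance.io_formats import GeneSet
from metabalance.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient cohort with 300 genes (15 planted per program)."""
    params = SimulationParams(n_patients=60, n_genes=300, n_glucose=15,
                              n_lipid=15, seed=7)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    from metabalance.simulate import write_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(small_cohort, outdir, seed=7)
    return paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_counts(rng):
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{i}" for i in range(10)]
    vals = rng.integers(0, 1000, size=(50, 10))
    return pd.DataFrame(vals, index=genes, columns=samples)


@pytest.fixture
def toy_gene_set():
    return GeneSet("TOY", "toy set", ("A", "B", "C"))
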