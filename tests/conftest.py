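import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import trnapool as tp

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def make_count_matrix(counts, feature_ids, sample_ids, genotypes, tissue="cerebrum"):
    """Assemble a CountMatrix from raw arrays."""
    df = pd.DataFrame(np.asarray(counts, dtype=np.int64), index=feature_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"genotype": genotypes, "tissue": tissue},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return tp.CountMatrix(df, samples)


@pytest.fixture
def small_registry():
    """Six nuclear genes in four families, two mito tRNAs and the spike-in."""
    names = [
        "tRNA-Ser-AGA-1-1", "tRNA-Ser-AGA-2-1", "tRNA-Ser-CGA-1-1",
        "tRNA-Val-AAC-1-1", "tRNA-Met-CAT-1-1", "tRNA-iMet-CAT-1-1",
        "mt-Tf", "mt-Tv", "Ecoli-Gln-spike",
    ]
    return tp.registry_from_names(names)


@pytest.fixture(scope="session")
def default_sim():
    """One study-default simulated dataset, shared across read-only tests."""
    return tp.simulate_counts(tp.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A lighter simulated dataset for pipeline smoke tests."""
    cfg = tp.SimulationConfig(
        seed=5, n_nuclear_genes=60, n_families=20, n_mito=5,
        baseline_log10_range=(1.0, 4.0),
    )
    return tp.simulate_counts(cfg)
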