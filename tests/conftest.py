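import numpy as np
import pytest

import riboflow as rf
from riboflow.flowmodel import FitConfig, transform_counts


@pytest.fixture(scope="session")
def small_world():
    """60 genes x ~200 codons at moderate depth: shared by fit-level tests."""
    genes = rf.synthdata.simulate_genome(60, mean_length=200, seed=21)
    truth = rf.synthdata.simulate_dwells(genes, seed=22)
    profiles = rf.synthdata.simulate_footprints(truth, depth=30.0)
    return genes, truth, profiles


@pytest.fixture(scope="session")
def small_fit(small_world):
    genes, truth, profiles = small_world
    fit = rf.fit_model(genes, profiles, FitConfig(seed=1))
    tc = transform_counts(profiles, genes=genes)
    return fit, tc


@pytest.fixture()
def toy_genes():
    """Three tiny hand-made genes (sense codons only, stop appended)."""
    return {
        "gA": rf.GeneRecord("gA", "ATG" + "AAA" * 4 + "CCC" * 3 + "TAA"),
        "gB": rf.GeneRecord("gB", "ATG" + "AAA" * 5 + "GGG" * 2 + "TAA"),
        "gC": rf.GeneRecord("gC", "ATG" + "CCC" * 6 + "GGG" * 1 + "TAA"),
    }
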