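import numpy as np
import pandas as pd
import pytest

from kcne1_dms.sim_assay import (
    SimConfig,
    simulate_depletion,
    simulate_library,
    simulate_sortseq,
)
from kcne1_dms.variants import ReferenceModel

#: 6-codon toy reference used by the subassembly tests (protein MKLDFG)
TOY_CDS = "ATGAAACTGGATTTTGGT"


@pytest.fixture(scope="session")
def toy_reference() -> ReferenceModel:
    return ReferenceModel.from_cds(TOY_CDS)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        protein_length=25,
        reads_per_sample=60_000,
        cells_per_replicate=150_000,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """Small but fully realistic simulated experiment, shared read-only."""
    barcode_map, truth = simulate_library(small_cfg)
    sort_counts = simulate_sortseq(barcode_map, truth, small_cfg)
    depl_counts = simulate_depletion(barcode_map, truth, small_cfg)
    return barcode_map, truth, sort_counts, depl_counts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
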