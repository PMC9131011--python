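import numpy as np
import pandas as pd
import pytest

from pdbiome import SimulationConfig, generate_cohort
from pdbiome.tables import FeatureTable, TaxonomyMap


@pytest.fixture
def toy_table() -> FeatureTable:
    """5 features x 4 samples with hand-chosen counts."""
    data = pd.DataFrame(
        {
            "s1": [5, 0, 1, 3, 0],
            "s2": [2, 1, 0, 4, 0],
            "s3": [0, 2, 0, 5, 1],
            "s4": [1, 0, 0, 6, 0],
        },
        index=[f"ASV_{i}" for i in range(1, 6)],
    )
    return FeatureTable(data, rank="asv")


@pytest.fixture
def toy_taxonomy(toy_table) -> TaxonomyMap:
    rows = {
        "ASV_1": ("P1", "C1", "O1", "F1", "G1"),
        "ASV_2": ("P1", "C1", "O1", "F1", "G1"),
        "ASV_3": ("P1", "C1", "O1", "F2", "G2"),
        "ASV_4": ("P2", "C2", "O2", "F3", "G3"),
        "ASV_5": ("P2", "C2", "O2", "F3", ""),
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["phylum", "class", "order", "family", "genus"]
    )
    return TaxonomyMap(df)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30+30-sample cohort with a clear planted signal, reused across
    tests that only need realistic structure."""
    cfg = SimulationConfig(
        n_group_a=30, n_group_b=30, n_asv=80, n_differential=5,
        effect_log2=2.0, sequencing_depth_mean=20_000, seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
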