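import numpy as np
import pandas as pd
import pytest

from phyllocore import AsvTable, SampleMetadata, Taxonomy
from phyllocore.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def toy_table() -> AsvTable:
    """3 samples × 4 ASVs with hand-checkable counts."""
    return AsvTable(
        pd.DataFrame(
            [[6, 0, 2, 2], [2, 2, 0, 6], [5, 5, 0, 0]],
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "a3", "a4"],
        )
    )


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "sample_type": ["plant"] * 3,
                "crop": ["tomato"] * 3,
                "greenhouse": ["C"] * 3,
                "department": ["D1", "D1", "D2"],
                "week": [1, 2, 1],
                "run": ["run1"] * 3,
                "batch": [None] * 3,
                "replicate_group": [None] * 3,
            }
        )
    )


@pytest.fixture
def mixed_taxonomy() -> Taxonomy:
    return Taxonomy(
        pd.DataFrame(
            {
                "asv_id": ["a1", "a2", "a3", "a4"],
                "domain": ["Bacteria"] * 4,
                "phylum": ["Proteobacteria", "Cyanobacteria", "Firmicutes", "Proteobacteria"],
                "class": ["Gamma", "Chloroplast", "Bacilli", "Alpha"],
                "order": ["", "", "", "Rickettsiales"],
                "family": ["", "", "", "Mitochondria"],
                "genus": ["Pseudomonas", "", "Staphylococcus", ""],
            }
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at generator defaults, shared across tests."""
    return generate_dataset(SimulationConfig(seed=7))


def random_table(rng: np.random.Generator, n_samples: int, n_asvs: int, max_count: int = 50) -> AsvTable:
    counts = rng.integers(0, max_count + 1, size=(n_samples, n_asvs))
    return AsvTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"a{j}" for j in range(n_asvs)],
        )
    )
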