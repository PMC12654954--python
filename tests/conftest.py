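import numpy as np
import pandas as pd
import pytest

from codoninfo import Dataset, SpeciesRecord, standard_code
from codoninfo.genetic_code import CODONS


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture
def uniform_rcf():
    return np.full(64, 1.0 / 64.0)


@pytest.fixture
def random_rcf():
    """Factory for reproducible random RCF vectors (Dirichlet draws)."""
    rng = np.random.default_rng(20250923)

    def make(alpha: float = 1.0) -> np.ndarray:
        return rng.dirichlet(np.full(64, alpha))

    return make


@pytest.fixture
def toy_dataset():
    """Four hand-made species in two groups; frequencies are counts."""
    rng = np.random.default_rng(7)
    records = []
    for i, group in enumerate(["An", "An", "Ar", "Ar"]):
        counts = rng.integers(1, 500, size=64).astype(float)
        records.append(
            SpeciesRecord(
                label=f"{group}{i + 1}",
                freqs=counts,
                group=group,
                scientific_name=f"Toy species {i + 1}",
            )
        )
    return Dataset(records=records)


@pytest.fixture
def toy_csv(tmp_path, toy_dataset):
    path = tmp_path / "toy.csv"
    toy_dataset.to_frame().to_csv(path, index=False)
    return path


def uniform_dataset(n: int = 4, group: str = "An") -> Dataset:
    recs = [
        SpeciesRecord(
            label=f"{group}{i + 1}", freqs=np.full(64, 10.0), group=group
        )
        for i in range(n)
    ]
    return Dataset(records=recs)
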