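import numpy as np
import pandas as pd
import pytest

from correctkin.datatypes import (
    GenotypeDataset,
    MarkerTable,
    SampleTable,
)


def dataset_from_matrix(calls, mode="diploid", alleles=None, sample_ids=None):
    """Wrap a raw state matrix in a GenotypeDataset with generic metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if alleles is None:
        alleles = [("C", "T")] * m
    markers = MarkerTable.from_arrays(
        marker_id=[f"m{j + 1}" for j in range(m)],
        chromosome=["1"] * m,
        position=np.arange(1, m + 1) * 10,
        allele_major=[a for a, _ in alleles],
        allele_minor=[b for _, b in alleles],
    )
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    samples = SampleTable.from_ids(sample_ids)
    return GenotypeDataset(markers, samples, calls, mode)


def random_dataset(n, m, seed=0, missing_rate=0.2, mode="diploid"):
    """Random dataset exercising all four genotype states."""
    rng = np.random.default_rng(seed)
    if mode == "diploid":
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    else:
        calls = (rng.integers(0, 2, size=(n, m)) * 2).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = 3
    return dataset_from_matrix(calls, mode=mode)


@pytest.fixture
def tiny_diploid():
    return random_dataset(5, 7, seed=42, missing_rate=0.25)
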