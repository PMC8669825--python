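import numpy as np
import pandas as pd
import pytest

from ptgut.diversity import rarefy, relative_abundance
from ptgut.synthetic_cohort import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 15-infant synthetic cohort shared across read-only tests."""
    config = SynthConfig(n_infants=15)
    return generate_cohort(config, seed=42)


@pytest.fixture(scope="session")
def small_relab(small_cohort):
    table, _, _, _ = small_cohort
    return relative_abundance(rarefy(table, 2000, seed=7))


@pytest.fixture()
def toy_counts():
    from ptgut.io_tables import TaxaCountTable

    return TaxaCountTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C"],
        np.array([[10, 0, 10], [3, 7, 0], [5, 5, 10]]),
    )


def two_blob_distances(n_per=5, gap=10.0):
    """1-D two-blob Euclidean distance matrix: points 0..n-1 and gap..gap+n-1."""
    coords = np.concatenate([np.arange(n_per) * 0.1,
                             gap + np.arange(n_per) * 0.1])
    d = np.abs(coords[:, None] - coords[None, :])
    labels = np.array([0] * n_per + [1] * n_per)
    return d, labels, coords
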