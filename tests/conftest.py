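import numpy as np
import pandas as pd
import pytest

from zfamkit.io import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20220315)


def make_matrix(calls, gene_ids=None, samples=None):
    """Small GenotypeMatrix from a 2-D array of 0/1/-1 calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    samples = samples or [f"S{i+1}" for i in range(n_samples)]
    gene_ids = gene_ids or ["g1"] * n_sites
    sites = pd.DataFrame(
        {
            "chromosome": ["chr1H"] * n_sites,
            "position": np.arange(1, n_sites + 1) * 100,
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
            "gene_id": gene_ids,
        }
    )
    return GenotypeMatrix(samples, sites, calls)


@pytest.fixture
def small_matrix():
    return make_matrix(
        [
            [0, 0, 1, 0],
            [0, 1, 1, MISSING],
            [1, 0, 1, 0],
            [1, 1, 0, 0],
        ],
        gene_ids=["g1", "g1", "g2", "g2"],
    )
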