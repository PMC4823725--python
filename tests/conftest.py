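import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from marspace.intervals import GeneModel, Peak, PeakSet


@pytest.fixture
def two_blob_points():
    """Two well-separated Gaussian blobs (sigma 15 nm, 500 nm apart)."""
    rng = np.random.default_rng(2024)
    a = rng.normal(0.0, 15.0, size=(50, 2))
    b = rng.normal(0.0, 15.0, size=(50, 2)) + np.array([500.0, 0.0])
    return np.vstack([a, b]), np.array([0] * 50 + [1] * 50)


@pytest.fixture
def simple_gene():
    """One +-strand gene on chr1: 10000-20000, exons [10000,12000) and [18000,20000)."""
    return GeneModel(
        chrom="chr1", strand="+", tx_start=10_000, tx_end=20_000,
        exons=((10_000, 12_000), (18_000, 20_000)), gene_name="geneX",
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        chrom="chr1", strand="-", tx_start=50_000, tx_end=60_000,
        exons=((50_000, 52_000), (58_000, 60_000)), gene_name="geneY",
    )


def make_peaks(coords, label="test"):
    return PeakSet([Peak(c, s, e) for c, s, e in coords], label=label)
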