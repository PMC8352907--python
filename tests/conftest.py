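import numpy as np
import pytest

from hicks import core, contact


@pytest.fixture
def two_chrom_sizes():
    return core.ChromSizes([("chr1", 1_000_000), ("chr2", 500_000)])


@pytest.fixture
def two_chrom_bins(two_chrom_sizes):
    return core.make_bins(two_chrom_sizes, 400_000)


def symmetric_matrix(bins, values):
    """Build a ContactMatrix from a raw (possibly upper) array, symmetrised."""
    v = np.asarray(values, dtype=float)
    v = np.triu(v) + np.triu(v, 1).T
    return contact.ContactMatrix(bins, v)


@pytest.fixture
def single_chrom_bins():
    return core.make_bins(core.ChromSizes([("chr1", 100)]), 1)
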