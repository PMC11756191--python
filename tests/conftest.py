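import numpy as np
import pytest

from tadfuse import GenomeSpec, GenomicBinTable, ContactMatrix


@pytest.fixture
def tiny_spec():
    """One 30-bin chromosome at 100 kb."""
    return GenomeSpec(("chr1",), (3_000_000,), 100_000)


@pytest.fixture
def two_chrom_spec():
    """Two 250-bin chromosomes at 100 kb."""
    return GenomeSpec(("chr1", "chr2"), (25_000_000, 25_000_000), 100_000)


def dense_matrix(values: np.ndarray, bin_size: int = 100_000,
                 chrom: str = "chr1", **kw) -> ContactMatrix:
    """Wrap one symmetric array as a single-chromosome ContactMatrix."""
    n = values.shape[0]
    spec = GenomeSpec((chrom,), (n * bin_size,), bin_size)
    return ContactMatrix(spec.bins(), {chrom: np.asarray(values, dtype=float)}, **kw)


@pytest.fixture
def dense():
    return dense_matrix
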