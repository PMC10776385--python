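import numpy as np
import pytest
import scipy.sparse as sp

from scatac_counts.core import CellTable, CountKind, CountMatrix, PeakSet


def make_matrix(dense, kind="fragments", batches=None, cell_types=None):
    """Wrap a dense array into a CountMatrix with generated metadata."""
    dense = np.asarray(dense)
    n, p = dense.shape
    barcodes = np.array([f"BC{i:04d}" for i in range(n)], dtype=object)
    batch = np.array(batches if batches is not None else ["b0"] * n, dtype=object)
    ct = None if cell_types is None else np.array(cell_types, dtype=object)
    cells = CellTable(barcodes, batch, ct)
    starts = np.arange(p, dtype=np.int64) * 1000
    peaks = PeakSet(np.array(["chr1"] * p, dtype=object), starts, starts + 500)
    return CountMatrix(sp.csr_matrix(dense.astype(np.int64)), CountKind(kind),
                       cells, peaks).with_totals()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_fragment_matrix(rng):
    return make_matrix(rng.poisson(1.0, size=(30, 12)))
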