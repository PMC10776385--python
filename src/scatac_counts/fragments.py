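"""Fragment-count computation and count-distribution diagnostics.

The 10x CellRanger ATAC pipeline counts *reads* (deduplicated fragment ends)
per peak. Because fragments are sequenced paired-end, read counts come
predominantly in even numbers — odd counts arise only when one end of a pair
falls outside the peak — and their per-peak variance across cells is about
twice the mean, which a Poisson model cannot express. Fragment counts, by
contrast, behave approximately Poisson. This module converts read matrices
to approximate fragment matrices, counts fragments in peaks directly from
fragment files, and computes the diagnostics (count histogram, parity ratio,
mean-variance profile) that expose the read-count artifact.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .core import CellTable, CountKind, CountMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "reads_to_fragments", "count_fragments_in_peaks", "filter_peaks",
    "mean_variance_profile", "count_distribution", "downsample",
    "MeanVarianceProfile", "CountDistributionSummary",
]


def reads_to_fragments(read_matrix: CountMatrix) -> CountMatrix:
    """Approximate fragment counts from a read-count matrix.

    Every uneven read count is rounded up to the next even number and the
    result halved: r -> ceil(r / 2). The sparsity pattern is unchanged
    (ceil(r/2) = 0 iff r = 0).
    """
    if read_matrix.kind is not CountKind.reads:
        raise TypeError(
            f"expected a reads-kind matrix, got {read_matrix.kind.value}"
        )
    frag = read_matrix.values.copy()
    frag.data = (frag.data + 1) // 2
    out = CountMatrix(frag, CountKind.fragments, read_matrix.cells, read_matrix.peaks)
    return out.with_totals()


def count_fragments_in_peaks(
    fragment_stream,
    peaks: PeakSet,
    barcodes: list[str],
) -> tuple[CountMatrix, int]:
    """Count fragments per (cell, peak) from a stream of fragment records.

    A fragment increments every peak it overlaps by at least 1 bp, so a
    fragment spanning two peaks counts once in each. Fragments on
    chromosomes absent from the peak set are ignored; their number is
    returned alongside the matrix.
    """
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("barcodes are not unique")
    bc_index = {b: i for i, b in enumerate(barcodes)}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p, (chrom, s, e) in enumerate(zip(peaks.chrom, peaks.start, peaks.end)):
        trees[chrom][s:e] = p

    counts: dict[tuple[int, int], int] = defaultdict(int)
    ignored_chrom = 0
    for chrom, start, end, barcode in fragment_stream:
        c = bc_index.get(barcode)
        if c is None:
            continue
        tree = trees.get(chrom)
        if tree is None:
            ignored_chrom += 1
            continue
        for iv in tree.overlap(start, end):
            counts[(c, iv.data)] += 1
    if ignored_chrom:
        logger.info("%d fragments on chromosomes without peaks ignored", ignored_chrom)

    if counts:
        rows, cols = zip(*counts.keys())
        mat = sp.coo_matrix(
            (list(counts.values()), (rows, cols)),
            shape=(len(barcodes), len(peaks)), dtype=np.int64,
        ).tocsr()
    else:
        mat = sp.csr_matrix((len(barcodes), len(peaks)), dtype=np.int64)
    cells = CellTable(np.array(barcodes, dtype=object),
                      np.array(["batch0"] * len(barcodes), dtype=object))
    return CountMatrix(mat, CountKind.fragments, cells, peaks).with_totals(), ignored_chrom


def filter_peaks(
    matrix: CountMatrix, min_cell_fraction: float = 0.01
) -> tuple[CountMatrix, np.ndarray]:
    """Keep peaks detected in at least ``min_cell_fraction`` of cells.

    The boundary is inclusive: a peak nonzero in exactly 1% of cells is
    kept. Returns the filtered matrix and the integer index of kept peaks.
    """
    if not 0 < min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in (0, 1]")
    n = matrix.n_cells
    nonzero_cells = matrix.values.getnnz(axis=0)
    keep = np.flatnonzero(nonzero_cells / n >= min_cell_fraction)
    if keep.size == 0:
        raise ValueError(
            "all peaks removed; lower min_cell_fraction "
            f"(max detection fraction is {nonzero_cells.max() / n:.4g})"
        )
    return matrix.subset_peaks(keep), keep


@dataclass
class MeanVarianceProfile:
    """Per-peak sample mean and unbiased variance across cells."""

    mean: np.ndarray
    variance: np.ndarray

    def var_mean_ratio(self, min_mean: float = 0.0) -> np.ndarray:
        """Variance/mean per peak, restricted to peaks with mean > min_mean."""
        keep = self.mean > max(min_mean, 0.0)
        return self.variance[keep] / self.mean[keep]


def mean_variance_profile(matrix: CountMatrix) -> MeanVarianceProfile:
    """Per-peak mean and (n-1)-denominator variance, without densifying.

    A Poisson-distributed column has variance ~= mean; doubled paired-end
    read counts have variance ~= 2x mean (Var(2X) = 4 mu against E(2X) = 2 mu).
    """
    n = matrix.n_cells
    if n < 2:
        raise ValueError("variance undefined for a single cell")
    x = matrix.values
    s1 = np.asarray(x.sum(axis=0)).ravel().astype(float)
    s2 = np.asarray(x.multiply(x).sum(axis=0)).ravel().astype(float)
    mean = s1 / n
    var = (s2 - n * mean**2) / (n - 1)
    return MeanVarianceProfile(mean, np.maximum(var, 0.0))


@dataclass
class CountDistributionSummary:
    """Histogram and parity diagnostics of the matrix entries.

    ``even_odd_ratio`` is (# entries with even count >= 2) / (# odd entries);
    a strong even excess is the signature of paired-end read counting.
    """

    histogram: dict[int, int]
    fraction_nonzero_gt1: float
    even_odd_ratio: float
    degenerate: bool = False


def count_distribution(matrix: CountMatrix, max_count: int = 10) -> CountDistributionSummary:
    """Exact entry-count histogram with counts > max_count pooled.

    An all-zero matrix yields zeroed fractions with ``degenerate=True``
    rather than an error, since downsampling can produce such inputs.
    """
    if max_count < 2:
        raise ValueError("max_count must be >= 2")
    n_entries = matrix.n_cells * matrix.n_peaks
    data = matrix.values.data
    data = data[data > 0]
    if data.size == 0:
        return CountDistributionSummary({0: n_entries}, 0.0, 0.0, degenerate=True)
    clipped = np.minimum(data, max_count)
    binc = np.bincount(clipped, minlength=max_count + 1)
    hist = {0: n_entries - data.size}
    for k in range(1, max_count + 1):
        if binc[k]:
            hist[k] = int(binc[k])
    n_gt1 = int((data > 1).sum())
    n_odd = int((data % 2 == 1).sum())
    n_even = data.size - n_odd  # all even entries are >= 2
    ratio = n_even / n_odd if n_odd else float("inf")
    return CountDistributionSummary(hist, n_gt1 / data.size, ratio)


def downsample(matrix: CountMatrix, fraction: float, seed: int) -> CountMatrix:
    """Binomially thin every entry: count -> Binomial(count, fraction)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return matrix
    rng = np.random.default_rng(seed)
    out = matrix.values.copy()
    out.data = rng.binomial(out.data.astype(np.int64), fraction)
    out.eliminate_zeros()
    return CountMatrix(out, matrix.kind, matrix.cells, matrix.peaks).with_totals()
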