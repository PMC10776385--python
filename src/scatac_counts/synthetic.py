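"""Synthetic scATAC-seq fragment-count data with known ground truth.

The generator realizes the same generative structure the Poisson model
assumes: each cell type t has an accessibility profile w*_t over peaks
(rows sum to 1, drawn from a Dirichlet), each cell c has a lognormal depth
d_c, and fragment counts are x_cp ~ Poisson(d_c * w*_{t(c),p}) after a
multiplicative batch effect on a peak subset. A companion routine produces
"read" matrices carrying the paired-end artifact (each fragment yields two
reads unless one end misses the peak), and another plants rank correlation
between promoter-peak counts and a synthetic expression matrix via a
Gaussian copula, for testing the association analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .core import CellTable, CountKind, CountMatrix, PeakSet

__all__ = ["SyntheticTruth", "generate", "fragments_to_reads", "plant_expression"]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    cell_type: np.ndarray            # per-cell type label
    batch: np.ndarray                # per-cell batch label
    profiles: np.ndarray             # n_types x n_peaks, rows sum to 1
    depth: np.ndarray                # per-cell expected total fragments d_c
    batch_affected_peaks: np.ndarray  # indices of peaks carrying batch effect
    batch_multiplier: np.ndarray     # per-batch fold change on those peaks
    expression_genes: np.ndarray | None = None  # genes with planted correlation
    promoter_peak_map: dict | None = None       # gene index -> peak index


def _dummy_peaks(n_peaks: int) -> PeakSet:
    width = 500
    starts = np.arange(n_peaks, dtype=np.int64) * 1000
    return PeakSet(np.array(["chr1"] * n_peaks, dtype=object), starts, starts + width)


def generate(
    n_cells: int = 2000,
    n_peaks: int = 1000,
    n_types: int = 4,
    n_batches: int = 2,
    depth_log_mean: float = float(np.log(3000.0)),
    depth_log_sigma: float = 0.5,
    type_sharpness: float = 3.0,
    batch_effect_size: float = 1.0,
    batch_peak_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate a fragment CountMatrix plus its SyntheticTruth.

    Parameters
    ----------
    type_sharpness
        Controls how distinct type profiles are: profiles are drawn from
        Dirichlet(alpha) with alpha = 1 / type_sharpness, so larger values
        give spikier, better-separated profiles.
    batch_effect_size
        log2 fold change applied to a random ``batch_peak_fraction`` subset
        of peaks in every batch beyond the first, after which profiles are
        renormalized.
    depth_log_mean, depth_log_sigma
        Lognormal depth parameters; the defaults put the median cell at
        ~3000 fragments, a 10x-like regime, with the spread real datasets
        show. Lowering depth reproduces the sparse regime (median per-peak
        fragment counts of a few hundredths).
    """
    rng = np.random.default_rng(seed)
    alpha = 1.0 / max(type_sharpness, 1e-6)
    profiles = rng.dirichlet(np.full(n_peaks, alpha), size=n_types)

    cell_type_idx = rng.integers(n_types, size=n_cells)
    batch_idx = rng.integers(n_batches, size=n_cells)
    depth = rng.lognormal(depth_log_mean, depth_log_sigma, size=n_cells)

    n_affected = max(1, int(round(batch_peak_fraction * n_peaks)))
    affected = rng.choice(n_peaks, size=n_affected, replace=False)
    multiplier = np.ones(n_batches)
    for b in range(1, n_batches):
        multiplier[b] = 2.0 ** (batch_effect_size * (1 if b % 2 else -1))

    # Per (type, batch) adjusted profile, renormalized to sum to 1.
    w = np.empty((n_types, n_batches, n_peaks))
    for t in range(n_types):
        for b in range(n_batches):
            prof = profiles[t].copy()
            prof[affected] *= multiplier[b]
            w[t, b] = prof / prof.sum()

    lam = depth[:, None] * w[cell_type_idx, batch_idx]
    counts = rng.poisson(lam)
    mat = sp.csr_matrix(counts, dtype=np.int64)

    barcodes = np.array([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    batch_labels = np.array([f"batch{b}" for b in batch_idx], dtype=object)
    type_labels = np.array([f"type{t}" for t in cell_type_idx], dtype=object)
    cells = CellTable(barcodes, batch_labels, type_labels)
    cm = CountMatrix(mat, CountKind.fragments, cells, _dummy_peaks(n_peaks)).with_totals()
    truth = SyntheticTruth(type_labels, batch_labels, profiles, depth,
                           affected, multiplier)
    return cm, truth


def fragments_to_reads(
    fragment_matrix: CountMatrix, end_loss_prob: float = 0.0, seed: int = 0
) -> CountMatrix:
    """Turn fragment counts into paired-end read counts.

    Each fragment contributes two reads unless one end falls outside the
    peak (probability ``end_loss_prob``), in which case it contributes one.
    With q = 0 this is exactly reads = 2 x fragments, producing the even-only
    count histogram and the variance ~= 2 x mean signature.
    """
    if not 0 <= end_loss_prob < 0.5:
        raise ValueError("end_loss_prob must be in [0, 0.5)")
    out = fragment_matrix.values.copy()
    if end_loss_prob == 0.0:
        out.data = out.data * 2
    else:
        rng = np.random.default_rng(seed)
        lost = rng.binomial(out.data.astype(np.int64), end_loss_prob)
        out.data = out.data * 2 - lost
    cm = CountMatrix(out, CountKind.reads, fragment_matrix.cells,
                     fragment_matrix.peaks)
    return cm.with_totals()


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Gaussian correlation giving Spearman rho_s for a bivariate normal."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def plant_expression(
    fragment_matrix: CountMatrix,
    n_genes: int,
    frac_correlated: float,
    target_rho: float,
    mean_expression: float = 2.0,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Synthesize a gene-expression count matrix tied to promoter peaks.

    Gene g is mapped to peak g (the first ``n_genes`` peaks serve as
    promoters). For a random ``frac_correlated`` subset of genes the
    expression counts are generated with rank correlation ~= ``target_rho``
    to the promoter fragment counts through a Gaussian copula: the fragment
    counts are converted to jittered normal scores u, a latent
    v = r*u + sqrt(1-r^2)*eps is drawn with r chosen so the latent Spearman
    correlation is ``target_rho``, and v is mapped to counts by the Poisson
    quantile function. Remaining genes are independent Poisson.
    """
    if not 0 <= frac_correlated <= 1:
        raise ValueError("frac_correlated must be in [0, 1]")
    if n_genes > fragment_matrix.n_peaks:
        raise ValueError("n_genes exceeds the number of peaks")
    rng = np.random.default_rng(seed)
    n_cells = fragment_matrix.n_cells
    n_corr = int(round(frac_correlated * n_genes))
    corr_genes = rng.choice(n_genes, size=n_corr, replace=False)
    corr_set = set(corr_genes.tolist())
    r = _spearman_to_pearson(np.clip(target_rho, -0.99, 0.99))

    frag = np.asarray(fragment_matrix.values[:, :n_genes].todense())
    expr = np.empty((n_cells, n_genes), dtype=np.int64)
    for g in range(n_genes):
        if g in corr_set and abs(r) > 0:
            # jittered ranks break count ties so the copula is well defined
            jitter = rng.uniform(-0.25, 0.25, size=n_cells)
            ranks = stats.rankdata(frag[:, g] + jitter)
            u = stats.norm.ppf(ranks / (n_cells + 1))
            v = r * u + np.sqrt(1 - r**2) * rng.standard_normal(n_cells)
            q = stats.norm.cdf(v)
            expr[:, g] = stats.poisson.ppf(q, mean_expression).astype(np.int64)
        else:
            expr[:, g] = rng.poisson(mean_expression, size=n_cells)

    gene_peaks = PeakSet(
        np.array(["chr1"] * n_genes, dtype=object),
        fragment_matrix.peaks.start[:n_genes],
        fragment_matrix.peaks.end[:n_genes],
    )
    cm = CountMatrix(sp.csr_matrix(expr), CountKind.fragments,
                     fragment_matrix.cells, gene_peaks)
    truth = SyntheticTruth(
        cell_type=fragment_matrix.cells.cell_type,
        batch=fragment_matrix.cells.batch,
        profiles=np.empty((0, 0)),
        depth=np.asarray(fragment_matrix.values.sum(axis=1)).ravel(),
        batch_affected_peaks=np.empty(0, dtype=int),
        batch_multiplier=np.empty(0),
        expression_genes=np.sort(corr_genes),
        promoter_peak_map={g: g for g in range(n_genes)},
    )
    return cm, truth
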