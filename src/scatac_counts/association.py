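"""Downstream biological-signal analyses on quantitative accessibility.

Two analyses that only make sense when counts are kept quantitative:

* Peaks are scored by the fraction of cells whose count exceeds the usual
  binarization threshold, grouped by score quantiles, and each group is
  tested for enrichment against annotation interval sets (enhancers,
  super-enhancers, promoter classes) with a one-sided Fisher exact test and
  Benjamini-Hochberg correction.
* Promoter-peak fragment counts are correlated (Spearman) with gene
  expression, restricted to cells of intermediate total depth (0.25-0.75
  quantile band) so the correlation is not driven by sequencing depth, and
  to cells with signal in the promoter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "PeakQuantileGroups", "peak_quantile_groups", "EnrichmentResult",
    "fisher_enrichment", "benjamini_hochberg", "PromoterCorrelation",
    "CorrelationSummary", "promoter_expression_correlation",
]


@dataclass
class PeakQuantileGroups:
    """Per-peak detection score and quantile-group assignment."""

    score: np.ndarray       # fraction of cells with count > threshold
    group: np.ndarray       # quantile-bin index per peak
    edges: np.ndarray       # score values at the quantile edges
    n_groups: int


def peak_quantile_groups(matrix: CountMatrix, threshold: int = 1,
                         quantile_edges=(0.25, 0.5, 0.75)) -> PeakQuantileGroups:
    """Group peaks by the fraction of cells above the binarization threshold.

    The score of peak p is (# cells with count > threshold) / N. Groups are
    the quantile bins of the score distribution; a score exactly on an edge
    goes to the lower bin.
    """
    edges = np.asarray(quantile_edges, dtype=float)
    if edges.size and (np.any(np.diff(edges) <= 0) or edges.min() <= 0 or edges.max() >= 1):
        raise ValueError("quantile edges must be strictly increasing within (0, 1)")
    score = np.asarray((matrix.values > threshold).sum(axis=0)).ravel() / matrix.n_cells
    cutpoints = np.quantile(score, edges) if edges.size else np.empty(0)
    if np.all(score == score[0]):
        warnings.warn("all peak scores identical; all peaks in one group")
        group = np.zeros(matrix.n_peaks, dtype=int)
    else:
        # side='left': score == cutpoint stays in the lower bin
        group = np.searchsorted(cutpoints, score, side="left")
    return PeakQuantileGroups(score, group, cutpoints, len(edges) + 1)


@dataclass
class EnrichmentResult:
    annotation_name: str
    group_id: int
    odds_ratio: float     # inf/0 reported as-is when a table cell is zero
    p_value: float
    q_value: float | None = None
    table: tuple | None = None


def _interval_trees(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c, s, e in zip(peaks.chrom, peaks.start, peaks.end):
        trees.setdefault(c, IntervalTree())[s:e] = True
    return trees


def _overlaps_annotation(peaks: PeakSet, annotation: PeakSet) -> np.ndarray:
    trees = _interval_trees(annotation)
    out = np.zeros(len(peaks), dtype=bool)
    for i, (c, s, e) in enumerate(zip(peaks.chrom, peaks.start, peaks.end)):
        tree = trees.get(c)
        out[i] = bool(tree is not None and tree.overlap(s, e))
    return out


def fisher_enrichment(group_peaks: PeakSet, all_peaks: PeakSet,
                      annotation: PeakSet, annotation_name: str = "",
                      group_id: int = 0) -> EnrichmentResult:
    """One-sided (enrichment) Fisher exact test of group vs annotation.

    The 2x2 table crosses group membership with any-overlap (>= 1 bp) of the
    annotation intervals. The odds ratio is (a*d)/(b*c); a zero b or c cell
    gives inf (and a zero a or d cell gives 0) with no continuity
    correction applied.
    """
    if len(group_peaks) == 0:
        raise ValueError("empty peak group")
    group_ids = set(group_peaks.peak_ids)
    in_group = np.array([pid in group_ids for pid in all_peaks.peak_ids])
    if not in_group.any():
        raise ValueError("group peaks not found in the full peak set")
    overlaps = _overlaps_annotation(all_peaks, annotation)
    a = int(np.sum(in_group & overlaps))
    b = int(np.sum(in_group & ~overlaps))
    c = int(np.sum(~in_group & overlaps))
    d = int(np.sum(~in_group & ~overlaps))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        oddsr = 0.0 if a * d == 0 else float("inf")
    else:
        oddsr = (a * d) / (b * c)
    return EnrichmentResult(annotation_name, group_id, oddsr, float(p),
                            table=(a, b, c, d))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class PromoterCorrelation:
    gene_id: str
    spearman_rho: float
    p_value: float
    q_value: float | None
    n_cells_used: int


@dataclass
class CorrelationSummary:
    n_genes_tested: int
    n_genes_skipped: int
    n_significant_positive: int
    significant_fraction: float
    nominal_rate: float
    binomial_p: float


def promoter_expression_correlation(
    fragment_matrix: CountMatrix,
    expression_matrix: CountMatrix,
    promoter_peak_map: dict,
    min_promoter_count: int = 1,
    depth_quantile_band: tuple[float, float] = (0.25, 0.75),
    alpha: float = 0.05,
) -> tuple[list[PromoterCorrelation], CorrelationSummary]:
    """Spearman correlation of promoter fragment counts with expression.

    Per gene, cells are filtered to (i) total fragment count inside the
    depth quantile band (inclusive on both ends) and (ii) promoter fragment
    count >= ``min_promoter_count`` (default 1; pass 2 for the stricter >1
    reading). Two-sided Spearman rho is computed per gene and BH-adjusted
    across genes; the summary counts genes with a positive correlation at
    raw p < alpha and tests that fraction against the nominal alpha with a
    one-sided binomial test.
    """
    if fragment_matrix.n_cells != expression_matrix.n_cells:
        raise ValueError("matrices must share cells")
    totals = fragment_matrix.row_totals()
    lo, hi = np.quantile(totals, depth_quantile_band)
    in_band = (totals >= lo) & (totals <= hi)

    results: list[PromoterCorrelation] = []
    skipped = 0
    for gene, peak in promoter_peak_map.items():
        frag = np.asarray(fragment_matrix.values[:, peak].todense()).ravel()
        eligible = in_band & (frag >= min_promoter_count)
        n = int(eligible.sum())
        if n < 3:
            logger.info("gene %s skipped: only %d eligible cells", gene, n)
            skipped += 1
            continue
        expr = np.asarray(
            expression_matrix.values[:, _gene_column(expression_matrix, gene)]
            .todense()).ravel()
        x, yv = frag[eligible], expr[eligible]
        if np.all(x == x[0]) or np.all(yv == yv[0]):
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.spearmanr(x, yv)
        results.append(PromoterCorrelation(str(gene), float(rho), float(p), None, n))

    if results:
        q = benjamini_hochberg([r.p_value for r in results])
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    n_sig = sum(1 for r in results if r.p_value < alpha and r.spearman_rho > 0)
    n_tested = len(results)
    frac = n_sig / n_tested if n_tested else 0.0
    binom_p = (stats.binomtest(n_sig, n_tested, alpha, alternative="greater").pvalue
               if n_tested else 1.0)
    summary = CorrelationSummary(n_tested, skipped, n_sig, frac, alpha,
                                 float(binom_p))
    return results, summary


def _gene_column(expression_matrix: CountMatrix, gene) -> int:
    """Column of a gene in the expression matrix.

    Integer gene ids index columns directly (the synthetic generator's
    convention); string ids are looked up in the peak-id manifest.
    """
    if isinstance(gene, (int, np.integer)):
        return int(gene)
    ids = expression_matrix.peaks.peak_ids
    return ids.index(gene)
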