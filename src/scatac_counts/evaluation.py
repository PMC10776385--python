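"""Scoring of reconstructions and latent embeddings.

Reconstruction is scored as average precision of predicted accessibility
probabilities against the binarized held-out matrix — the right scale for a
task where only a few percent of entries are positive. Embeddings are scored
with the standard single-cell integration metrics, split into
bioconservation (NMI, ARI, label silhouette, isolated-label F1/silhouette)
and batch correction (batch silhouette, principal-component regression,
graph connectivity). All reported scores live in [0, 1]; higher is better.
"""

from __future__ import annotations

import logging
import random as _pyrandom
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph
from sklearn import metrics as skm
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "average_precision", "knn_graph", "louvain_sweep", "nmi", "ari",
    "label_silhouette", "isolated_label_scores", "graph_connectivity",
    "batch_silhouette", "principal_component_regression",
    "celltype_separation", "SeparationScore", "IntegrationReport",
    "integration_report",
]

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))


def average_precision(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise estimator).

    Flattened inputs; ties are handled by grouping tied score blocks, which
    is equivalent to averaging over tied orderings.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y_true).ravel()
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary")
    if y.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(skm.average_precision_score(y, scores))


def knn_graph(embedding: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Symmetrized (union) k-nearest-neighbor adjacency, Euclidean."""
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    adj = nn.kneighbors_graph(embedding, mode="connectivity")
    adj = adj.tolil()
    adj.setdiag(0)
    adj = adj.tocsr()
    adj.eliminate_zeros()
    adj = adj.maximum(adj.T)
    return adj


def _cluster_graph(adj: sp.csr_matrix, resolution: float, seed: int,
                   backend: str) -> np.ndarray:
    src, dst = adj.nonzero()
    mask = src < dst
    g = igraph.Graph(n=adj.shape[0],
                     edges=list(zip(src[mask].tolist(), dst[mask].tolist())))
    if backend == "leiden":
        import leidenalg
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed)
    else:
        _pyrandom.seed(seed)  # igraph draws from Python's random module
        part = g.community_multilevel(resolution=resolution)
    return np.array(part.membership)


def louvain_sweep(embedding: np.ndarray, labels: np.ndarray,
                  resolutions=DEFAULT_RESOLUTIONS, k_neighbors: int = 15,
                  seed: int = 0, backend: str = "louvain"):
    """Cluster a kNN graph over a resolution grid; keep the best-NMI result.

    Returns (best_clustering, best_nmi, all_clusterings). A degenerate
    embedding (all rows equal) yields a single cluster and NMI 0.
    """
    labels = np.asarray(labels)
    embedding = np.asarray(embedding, dtype=float)
    if np.allclose(embedding, embedding[0]):
        warnings.warn("degenerate embedding: all rows equal; single cluster")
        single = np.zeros(len(embedding), dtype=int)
        return single, 0.0, [single]
    adj = knn_graph(embedding, k_neighbors)
    best_c, best_score, all_c = None, -1.0, []
    for res in resolutions:
        clustering = _cluster_graph(adj, float(res), seed, backend)
        all_c.append(clustering)
        score = nmi(clustering, labels)
        if score > best_score:
            best_c, best_score = clustering, score
    return best_c, best_score, all_c


def nmi(clustering: np.ndarray, labels: np.ndarray) -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    Degenerate single-cluster comparisons score 0.
    """
    clustering, labels = np.asarray(clustering), np.asarray(labels)
    if len(set(clustering.tolist())) < 2 or len(set(labels.tolist())) < 2:
        return 0.0
    return float(skm.normalized_mutual_info_score(labels, clustering,
                                                  average_method="arithmetic"))


def ari(clustering: np.ndarray, labels: np.ndarray) -> float:
    """Adjusted Rand index (raw scale; can be negative)."""
    clustering, labels = np.asarray(clustering), np.asarray(labels)
    if len(set(clustering.tolist())) < 2 or len(set(labels.tolist())) < 2:
        return 0.0
    return float(skm.adjusted_rand_score(labels, clustering))


def label_silhouette(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width over cells, rescaled from [-1, 1] to [0, 1]."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("label silhouette needs >= 2 labels")
    if counts.min() < 2:
        raise ValueError("every label needs >= 2 cells")
    s = skm.silhouette_score(np.asarray(embedding, dtype=float), labels)
    return float((s + 1.0) / 2.0)


def isolated_label_scores(embedding: np.ndarray, labels: np.ndarray,
                          batches: np.ndarray,
                          clusterings: list[np.ndarray]) -> tuple[float, float]:
    """F1 and silhouette for the label(s) present in the fewest batches.

    F1 is the max over the supplied clusterings and over clusters of the F1
    of "cluster == c" against "label == isolated". The silhouette is the
    rescaled mean silhouette width of isolated vs non-isolated cells,
    computed over the isolated cells. Ties for isolation are averaged.
    """
    labels, batches = np.asarray(labels), np.asarray(batches)
    uniq = np.unique(labels)
    n_batches = {lab: len(set(batches[labels == lab].tolist())) for lab in uniq}
    fewest = min(n_batches.values())
    isolated = [lab for lab in uniq if n_batches[lab] == fewest]

    f1s, sils = [], []
    emb = np.asarray(embedding, dtype=float)
    for lab in isolated:
        truth = labels == lab
        best_f1 = 0.0
        for clustering in clusterings:
            for c in np.unique(clustering):
                pred = clustering == c
                best_f1 = max(best_f1, skm.f1_score(truth, pred))
        f1s.append(best_f1)
        samples = skm.silhouette_samples(emb, truth.astype(int))
        sils.append((samples[truth].mean() + 1.0) / 2.0)
    return float(np.mean(f1s)), float(np.mean(sils))


def graph_connectivity(embedding: np.ndarray, labels: np.ndarray,
                       k_neighbors: int = 15) -> float:
    """Mean over labels of the largest-connected-component fraction of the
    label-restricted kNN subgraph. Batch effects that split a cell type into
    disconnected islands push this below 1."""
    labels = np.asarray(labels)
    adj = knn_graph(embedding, k_neighbors)
    fracs = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        sub = adj[idx][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        fracs.append(largest / idx.size)
    return float(np.mean(fracs))


def batch_silhouette(embedding: np.ndarray, labels: np.ndarray,
                     batches: np.ndarray) -> float:
    """Batch-mixing ASW: per cell-type group, mean of 1 - |silhouette| of the
    batch labels; averaged over groups. 1 means batches are indistinguishable
    within every cell type."""
    labels, batches = np.asarray(labels), np.asarray(batches)
    emb = np.asarray(embedding, dtype=float)
    if len(set(batches.tolist())) < 2:
        raise ValueError("batch silhouette needs >= 2 batches")
    per_group = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        grp_batches = batches[idx]
        uniq, counts = np.unique(grp_batches, return_counts=True)
        if len(uniq) < 2 or counts.min() < 2:
            warnings.warn(f"group {lab!r} lacks two batches; skipped")
            continue
        samples = skm.silhouette_samples(emb[idx], grp_batches)
        per_group.append(float(np.mean(1.0 - np.abs(samples))))
    if not per_group:
        raise ValueError("no cell-type group had >= 2 batches")
    return float(np.mean(per_group))


def _batch_variance_explained(embedding: np.ndarray, batches: np.ndarray) -> float:
    """Variance-weighted R^2 of principal components regressed on batch."""
    emb = np.asarray(embedding, dtype=float)
    n_comp = min(emb.shape[0] - 1, emb.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pcs = pca.fit_transform(emb)
    var = pca.explained_variance_
    cats = np.unique(batches)
    onehot = (np.asarray(batches)[:, None] == cats[None, :]).astype(float)
    # least-squares fit of each PC on the batch design (with intercept)
    X = np.column_stack([np.ones(len(emb)), onehot[:, :-1]])
    beta, *_ = np.linalg.lstsq(X, pcs, rcond=None)
    resid = pcs - X @ beta
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((pcs - pcs.mean(axis=0))**2).sum(axis=0)
    safe = ss_tot > 0
    r2 = np.zeros_like(ss_tot)
    r2[safe] = 1.0 - ss_res[safe] / ss_tot[safe]
    return float((var * r2).sum() / var.sum())


def principal_component_regression(embedding_before: np.ndarray,
                                   embedding_after: np.ndarray,
                                   batches: np.ndarray) -> float:
    """Batch-variance reduction score (Var_before - Var_after)/Var_before.

    Clipped to [0, 1]; 1 means the integrated embedding retains none of the
    batch-explainable variance the unintegrated one had.
    """
    if len(embedding_before) != len(embedding_after):
        raise ValueError("embeddings must cover the same cells")
    before = _batch_variance_explained(embedding_before, batches)
    after = _batch_variance_explained(embedding_after, batches)
    if before <= 0:
        raise ValueError("no batch-explained variance before integration")
    return float(np.clip((before - after) / before, 0.0, 1.0))


@dataclass
class SeparationScore:
    """1-D separation of a target cell type by an accessibility value."""

    silhouette: float
    roc_auc: float
    target_label: object


def celltype_separation(values: np.ndarray, labels: np.ndarray,
                        target_label) -> SeparationScore:
    """Silhouette width and ROC AUC of target-vs-rest on a 1-D score."""
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    is_target = labels == target_label
    if not is_target.any():
        raise ValueError(f"target label {target_label!r} absent")
    if is_target.all():
        raise ValueError("target label covers all cells")
    sil = float(skm.silhouette_score(values.reshape(-1, 1), is_target.astype(int)))
    auc = float(skm.roc_auc_score(is_target.astype(int), values))
    return SeparationScore(sil, auc, target_label)


@dataclass
class IntegrationReport:
    """Bioconservation and batch-correction scores, all in [0, 1]."""

    bioconservation: dict[str, float] = field(default_factory=dict)
    batch: dict[str, float] = field(default_factory=dict)
    raw: dict[str, float] = field(default_factory=dict)

    def aggregate(self, bio_weight: float = 0.6) -> float:
        """Weighted mean of the two category means (scib convention)."""
        bio = float(np.mean(list(self.bioconservation.values())))
        bat = float(np.mean(list(self.batch.values())))
        return bio_weight * bio + (1.0 - bio_weight) * bat

    def as_dict(self) -> dict:
        return {"bioconservation": self.bioconservation, "batch": self.batch,
                "raw": self.raw}


def integration_report(embedding: np.ndarray, labels: np.ndarray,
                       batches: np.ndarray,
                       embedding_before: np.ndarray | None = None,
                       k_neighbors: int = 15, seed: int = 0) -> IntegrationReport:
    """Compute the full metric panel for one embedding.

    ARI is rescaled to [0, 1] as (ari + 1)/2 for aggregation only; the raw
    value is kept in ``raw``. Graph connectivity is stored under batch
    correction. PCR requires an unintegrated reference embedding and is
    omitted when none is given.
    """
    clustering, best_nmi, all_c = louvain_sweep(
        embedding, labels, k_neighbors=k_neighbors, seed=seed)
    raw_ari = ari(clustering, labels)
    f1, iso_sil = isolated_label_scores(embedding, labels, batches, all_c)
    rep = IntegrationReport()
    rep.bioconservation = {
        "nmi": best_nmi,
        "ari": (raw_ari + 1.0) / 2.0,
        "label_silhouette": label_silhouette(embedding, labels),
        "isolated_label_f1": f1,
        "isolated_label_silhouette": iso_sil,
    }
    rep.batch = {
        "batch_silhouette": batch_silhouette(embedding, labels, batches),
        "graph_connectivity": graph_connectivity(embedding, labels, k_neighbors),
    }
    if embedding_before is not None:
        rep.batch["pcr"] = principal_component_regression(
            embedding_before, embedding, batches)
    rep.raw = {"ari": raw_ari}
    return rep
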