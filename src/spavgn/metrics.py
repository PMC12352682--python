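"""Imputation and clustering quality metrics.

* gene-wise Pearson correlation between predicted and true expression
  vectors across evaluated spots (median as the summary statistic; genes
  with zero variance in either vector are undefined and excluded),
* Silhouette Coefficient and Davies–Bouldin index over an embedding of the
  (imputed) expression, the standard internal measures of spatial-domain
  clustering quality.  Distances are Euclidean.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = ["EvaluationReport", "ClusterMetrics", "genewise_pcc", "silhouette",
           "davies_bouldin", "cluster_metrics", "expression_pca"]


@dataclasses.dataclass
class EvaluationReport:
    per_gene_pcc: np.ndarray      # (G,), NaN where undefined
    median_pcc: float             # over defined genes
    n_spots_evaluated: int
    n_undefined: int
    method: str = ""

    def defined(self) -> np.ndarray:
        return self.per_gene_pcc[np.isfinite(self.per_gene_pcc)]


@dataclasses.dataclass
class ClusterMetrics:
    silhouette: float
    davies_bouldin: float
    n_clusters: int


def genewise_pcc(truth: np.ndarray, pred: np.ndarray,
                 method: str = "") -> EvaluationReport:
    """Pearson correlation per gene over spots (rows = spots, cols = genes)."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {pred.shape}")
    n = truth.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to correlate")
    tc = truth - truth.mean(axis=0)
    pc = pred - pred.mean(axis=0)
    st = np.sqrt((tc ** 2).sum(axis=0))
    sp = np.sqrt((pc ** 2).sum(axis=0))
    defined = (st > 0) & (sp > 0)
    pcc = np.full(truth.shape[1], np.nan)
    pcc[defined] = (tc[:, defined] * pc[:, defined]).sum(axis=0) / (
        st[defined] * sp[defined])
    if not defined.any():
        raise ValueError("every gene has zero variance; PCC undefined")
    return EvaluationReport(
        per_gene_pcc=pcc,
        median_pcc=float(np.median(pcc[defined])),
        n_spots_evaluated=n,
        n_undefined=int((~defined).sum()),
        method=method,
    )


def silhouette(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b) with Euclidean distances.

    Singleton clusters score 0.  Requires at least 2 clusters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(embeddings, dtype=np.float64),
                                  labels, metric="euclidean"))


def davies_bouldin(embeddings: np.ndarray, labels: np.ndarray) -> float:
    """DB = (1/K) sum_i max_{j != i} (S_i + S_j) / D_ij.

    S_i is the mean Euclidean distance of cluster-i points to their
    centroid; D_ij is the distance between centroids.  Coincident centroids
    make the ratio undefined and raise.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin requires at least 2 clusters")
    centroids = np.stack([x[labels == u].mean(axis=0) for u in uniq])
    scatter = np.array([
        np.linalg.norm(x[labels == u] - centroids[i], axis=1).mean()
        for i, u in enumerate(uniq)])
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    off = ~np.eye(k, dtype=bool)
    if np.any(d[off] == 0):
        raise ZeroDivisionError("coincident cluster centroids")
    ratio = (scatter[:, None] + scatter[None, :]) / np.where(off, d, np.inf)
    return float(np.mean(ratio.max(axis=1)))


def cluster_metrics(embeddings: np.ndarray, labels: np.ndarray) -> ClusterMetrics:
    return ClusterMetrics(
        silhouette=silhouette(embeddings, labels),
        davies_bouldin=davies_bouldin(embeddings, labels),
        n_clusters=len(np.unique(labels)),
    )


def expression_pca(expr_spots_by_genes: np.ndarray, n_comps: int = 20,
                   seed: int = 0) -> np.ndarray:
    """PCA embedding of a spots x genes matrix (the default space fed to the
    cluster metrics when evaluating imputed expression)."""
    x = np.asarray(expr_spots_by_genes, dtype=np.float64)
    n_comps = min(n_comps, min(x.shape) - 1)
    return PCA(n_components=n_comps, random_state=seed).fit_transform(x)
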