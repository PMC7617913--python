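"""Gene co-expression structure: Pearson correlation, PCA, PAM/CLARA k-medoids.

Each gene is a point in assay space (its vector of log2 fold-changes across
the filtered assays). Co-expression is summarised three ways:

* a gene-gene Pearson correlation matrix (the heatmap object),
* PCA coordinates of genes (assay variables centered, not scaled),
* k-medoids cluster assignments computed with CLARA — PAM (greedy BUILD
  plus best-improvement SWAP) run on random subsamples, with all genes
  assigned to the nearest subsample medoid and the best-scoring solution
  retained.

Clustering operates on Euclidean distance between per-gene z-scored
profiles. For standardized rows the squared distance is an affine function
of the Pearson correlation, d^2 = 2(n-1)(1-r), so the cluster structure is
consistent with the correlation heatmaps it accompanies. The number of
clusters is chosen by maximizing mean silhouette width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from chemocoex._util import substream
from chemocoex.filtering import ExpressionMatrix

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class PcaResult:
    """Per-gene principal-component coordinates with explained-variance fractions."""

    scores: pd.DataFrame  # genes x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x assay-variables


@dataclass(frozen=True)
class ClusterAssignment:
    """k-medoids output: labels in 1..k, medoid items, total dissimilarity."""

    items: tuple[str, ...]
    labels: np.ndarray  # int, 1..k
    medoids: tuple[str, ...]
    total_dissimilarity: float

    def members(self, cluster: int) -> tuple[str, ...]:
        return tuple(it for it, lab in zip(self.items, self.labels) if lab == cluster)


def pearson_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation across assays of a complete matrix.

    Zero-variance genes are dropped with a warning before computing; the
    result has unit diagonal and is exactly symmetric.
    """
    v = matrix.values
    if matrix.n_missing:
        raise ValueError("correlation requires a complete (post-filtration) matrix")
    if v.shape[1] < 3:
        raise ClusteringError(f"need >=3 assays for correlation, have {v.shape[1]}")
    sd = v.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        logger.warning("dropping %d zero-variance genes before correlation: %s", len(flat), flat)
        v = v.drop(index=flat)
    if v.shape[0] < 2:
        raise ClusteringError("fewer than 2 genes with variance; correlation undefined")
    r = np.corrcoef(v.to_numpy())
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=v.index, columns=v.index)


def pca_scores(matrix: ExpressionMatrix, m: int = 2) -> PcaResult:
    """PCA with genes as observations and assays as (centered) variables.

    Sign convention: the largest-magnitude entry of each loading vector is
    made positive, so the orientation is deterministic.
    """
    v = matrix.values
    if matrix.n_missing:
        raise ValueError("PCA requires a complete matrix")
    n, p = v.shape
    if n < 2 or p < 2:
        raise ClusteringError("PCA needs at least 2 genes and 2 assays")
    if m > min(n, p):
        raise ClusteringError(f"m={m} exceeds min(genes, assays)={min(n, p)}")
    x = v.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # orient each component so its largest-|.| loading is positive
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    var = s**2 / (n - 1)
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        (u * s)[:, :m], index=v.index, columns=[f"PC{i + 1}" for i in range(m)]
    )
    return PcaResult(scores=scores, explained_variance_ratio=ratio[:m], loadings=vt[:m])


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """z-score each gene row to mean 0, sample-sd 1 across assays."""
    v = matrix.values
    sd = v.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ClusteringError(f"zero-variance genes cannot be standardized: {flat}")
    z = v.sub(v.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(values=z, assay_meta=matrix.assay_meta)


def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ClusteringError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T):
        raise ClusteringError("dissimilarity must be symmetric")
    if (d < 0).any():
        raise ClusteringError("dissimilarity must be non-negative")
    if not np.allclose(np.diag(d), 0):
        raise ClusteringError("dissimilarity diagonal must be zero")
    return d


def pam(
    dissimilarity: np.ndarray | pd.DataFrame,
    k: int,
    items: tuple[str, ...] | None = None,
) -> ClusterAssignment:
    """Partitioning Around Medoids: greedy BUILD then best-improvement SWAP.

    BUILD adds, k times, the candidate medoid that minimizes total
    dissimilarity of all items to their nearest medoid. SWAP repeatedly
    applies the single (medoid, non-medoid) exchange with the largest cost
    decrease until none improves. All ties break toward the lowest item
    index, making the procedure fully deterministic.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        if items is None:
            items = tuple(dissimilarity.index)
        dissimilarity = dissimilarity.to_numpy()
    d = _validate_dissimilarity(dissimilarity)
    n = d.shape[0]
    if items is None:
        items = tuple(str(i) for i in range(n))
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} out of range [1, {n}]")

    medoids: list[int] = []
    nearest = np.full(n, np.inf)
    for _ in range(k):
        best_c, best_cost = -1, np.inf
        for c in range(n):
            if c in medoids:
                continue
            cost = float(np.minimum(nearest, d[c]).sum())
            if cost < best_cost - 1e-12:
                best_c, best_cost = c, cost
        medoids.append(best_c)
        nearest = np.minimum(nearest, d[best_c])

    def total_cost(meds: list[int]) -> float:
        return float(d[np.ix_(meds, range(n))].min(axis=0).sum())

    current = total_cost(medoids)
    while True:
        best_delta, best_swap = -1e-12, None
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = current - total_cost(trial)
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        current = total_cost(medoids)

    med_order = sorted(medoids)
    labels = np.argmin(d[np.ix_(med_order, range(n))], axis=0) + 1
    total = float(d[np.array(med_order)[labels - 1], np.arange(n)].sum())
    return ClusterAssignment(
        items=tuple(items),
        labels=labels,
        medoids=tuple(items[m] for m in med_order),
        total_dissimilarity=total,
    )


def clara(
    matrix: ExpressionMatrix,
    k: int,
    n_samples: int = 5,
    sample_size: int | None = None,
    seed: int = 0,
) -> ClusterAssignment:
    """Clustering Large Applications: PAM on random subsamples of genes.

    For each of ``n_samples`` seeded subsamples of ``sample_size`` genes, PAM
    is run on the subsample's Euclidean distances; every gene is then
    assigned to its nearest medoid and the solution is scored by total
    dissimilarity over all genes. The best-scoring assignment wins (ties to
    the earlier sample). With ``sample_size >= n`` the procedure is exactly
    PAM on the full set. Defaults (5 samples of min(n, 40+2k)) follow the
    algorithm's classical published values.
    """
    x = matrix.values.to_numpy(dtype=float)
    items = tuple(matrix.values.index)
    n = x.shape[0]
    if sample_size is None:
        sample_size = min(n, 40 + 2 * k)
    if sample_size < k:
        raise ClusteringError(f"sample_size={sample_size} < k={k}")
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} out of range [1, {n}]")
    sample_size = min(sample_size, n)
    d_full = squareform(pdist(x, metric="euclidean"))
    rng = substream(seed, "clara")

    best: ClusterAssignment | None = None
    for s in range(n_samples):
        if sample_size >= n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=sample_size, replace=False))
        logger.debug("clara sample %d: indices %s", s, idx.tolist())
        sub = pam(d_full[np.ix_(idx, idx)], k, items=tuple(items[i] for i in idx))
        med_idx = np.array([items.index(m) for m in sub.medoids])
        labels = np.argmin(d_full[np.ix_(med_idx, range(n))], axis=0) + 1
        total = float(d_full[med_idx[labels - 1], np.arange(n)].sum())
        cand = ClusterAssignment(
            items=items,
            labels=labels,
            medoids=tuple(items[m] for m in med_idx),
            total_dissimilarity=total,
        )
        if best is None or cand.total_dissimilarity < best.total_dissimilarity - 1e-12:
            best = cand
    assert best is not None
    return best


def silhouette_width(
    assignment: ClusterAssignment, dissimilarity: np.ndarray | pd.DataFrame
) -> float:
    """Mean silhouette width s(i) = (b-a)/max(a,b); singleton clusters get s=0."""
    if isinstance(dissimilarity, pd.DataFrame):
        dissimilarity = dissimilarity.to_numpy()
    d = _validate_dissimilarity(dissimilarity)
    labels = assignment.labels
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ClusteringError("silhouette requires at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        if not same.any():
            s[i] = 0.0  # singleton
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == other].mean() for other in ks if other != own)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def select_k(
    matrix: ExpressionMatrix,
    k_range: range | tuple[int, ...] = range(2, 7),
    n_samples: int = 5,
    sample_size: int | None = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose k by maximizing mean silhouette over CLARA runs; ties -> smallest k."""
    ks = list(k_range)
    n = matrix.values.shape[0]
    if not ks:
        raise ClusteringError("empty k range")
    if min(ks) < 2 or max(ks) > n - 1:
        raise ClusteringError(f"k range {ks} outside [2, {n - 1}]")
    d = squareform(pdist(matrix.values.to_numpy(dtype=float), metric="euclidean"))
    rows = []
    for k in ks:
        assignment = clara(matrix, k, n_samples=n_samples, sample_size=sample_size, seed=seed)
        rows.append((k, silhouette_width(assignment, d)))
    table = pd.DataFrame(rows, columns=["k", "mean_silhouette"])
    best_k = int(table.loc[table["mean_silhouette"].idxmax(), "k"])  # idxmax: first max, ks ascending
    return best_k, table


def hclust_order(corr: pd.DataFrame) -> list[str]:
    """Display ordering of genes for the correlation heatmap.

    Complete-linkage agglomerative clustering on distance 1 - r; returns the
    dendrogram leaf order. Deterministic given the input.
    """
    genes = list(corr.index)
    if len(genes) < 3:
        return genes
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="complete")
    return [genes[i] for i in leaves_list(z)]
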