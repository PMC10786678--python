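"""Quasi-rigid cluster decomposition by spectral clustering.

Distance fluctuations are turned into edge similarities with a Gaussian
kernel S_ij = exp(−σ_ij²/(2σ̄²)) whose bandwidth is the mean σ² over the
stored pairs (so the construction is invariant to the global fluctuation
scale).  Rows of the k lowest eigenvectors of the symmetric-normalized
graph Laplacian embed the residues; the embedding is partitioned either
by iterative rotation to the nearest cluster-indicator matrix
("discretize", the default) or by seeded k-means.

Each candidate cluster count k receives a quality score.  The selection
score is the *fluctuation contrast*: the mean σ² over residue pairs that
cross cluster boundaries divided by the mean σ² over pairs inside
clusters.  It directly measures what a quasi-rigid decomposition is for
— internal distance fluctuations small, boundary fluctuations large —
and, unlike purely embedding-geometric scores, it is not inflated when
several rigid blocks collapse onto coincident positions in a low-
dimensional embedding.  σ² is recovered from the kernel weights as
−log S (exact up to the global bandwidth, which cancels in the ratio).

A secondary embedding-geometry diagnostic, :func:`quality_score`
(mean_i d_i^(2)/d_i^(1), distances to cluster centroids in the
embedding), is also provided.  The k maximizing the selection score
wins; ties break to smaller k, and all local maxima are reported so
alternative decompositions can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .fluctuations import PairFluctuations

__all__ = [
    "SimilarityGraph",
    "ClusteringResult",
    "similarity_graph",
    "spectral_embedding",
    "cluster_embedding",
    "quality_score",
    "fluctuation_contrast",
    "scan_clusters",
]


@dataclass
class SimilarityGraph:
    """Sparse symmetric similarity graph with Gaussian-kernel weights in (0, 1]."""

    pairs: np.ndarray
    weights: np.ndarray
    n_nodes: int

    def adjacency(self) -> sp.csr_array:
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        return sp.coo_array(
            (np.r_[self.weights, self.weights], (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_nodes, self.n_nodes),
        ).tocsr()


@dataclass
class ClusteringResult:
    """Labels, quality profile and selection over a scanned range of k."""

    k_values: np.ndarray
    labels_by_k: dict[int, np.ndarray]
    quality_by_k: np.ndarray
    selected_k: int
    local_maxima: list[int]

    @property
    def selected_labels(self) -> np.ndarray:
        return self.labels_by_k[self.selected_k]


def similarity_graph(
    fluct: PairFluctuations, bandwidth_factor: float = 1.0
) -> SimilarityGraph:
    """Gaussian kernel S_ij = exp(−σ_ij² / (2·b·σ̄²)) with σ̄² the mean σ²."""
    if fluct.pairs.shape[0] == 0:
        raise ValueError("empty pair set")
    mean_s2 = float(fluct.sigma2.mean())
    if mean_s2 <= 0:
        raise ValueError(
            "all distance fluctuations are zero: the structure behaves as a "
            "single rigid body and cannot be decomposed"
        )
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth factor must be positive")
    w = np.exp(-fluct.sigma2 / (2.0 * bandwidth_factor * mean_s2))
    return SimilarityGraph(pairs=fluct.pairs, weights=w, n_nodes=fluct.n_nodes)


def _embedding_vectors(graph: SimilarityGraph, k: int) -> np.ndarray:
    """Columns: k lowest eigenvectors of L = I − D^(−1/2) S D^(−1/2), sign-fixed."""
    n = graph.n_nodes
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_nodes, got k={k}, n={n}")
    s = graph.adjacency()
    n_comp, _ = connected_components(s, directed=False)
    if n_comp > 1:
        raise ValueError(f"similarity graph is disconnected ({n_comp} components)")
    deg = np.asarray(s.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    m = sp.csr_array(s.multiply(np.outer(dinv, dinv)))
    if k >= n - 1 or n < 50:
        w, v = np.linalg.eigh(m.toarray())
        w, v = w[::-1][:k], v[:, ::-1][:, :k]
    else:
        v0 = np.random.default_rng(0).uniform(-1.0, 1.0, n)
        w, v = spla.eigsh(m, k=k, which="LA", v0=v0)
        order = np.argsort(w)[::-1]  # ascending Laplacian eigenvalue
        w, v = w[order], v[:, order]
    for c in range(v.shape[1]):
        nz = np.nonzero(np.abs(v[:, c]) > 1e-12)[0]
        if nz.size and v[nz[0], c] < 0:
            v[:, c] = -v[:, c]
    return v


def _row_normalize(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def spectral_embedding(graph: SimilarityGraph, k: int) -> np.ndarray:
    """N×k spectral embedding: lowest normalized-Laplacian eigenvectors,
    rows normalized to unit length."""
    return _row_normalize(_embedding_vectors(graph, k))


def _discretize(x: np.ndarray, seed: int, max_iter: int = 500) -> np.ndarray:
    """Rotate the embedding to the nearest cluster-indicator matrix.

    Alternates row-argmax assignment with an orthogonal-Procrustes update
    of the rotation until the assignment reaches a fixed point.
    """
    n, k = x.shape
    rng = np.random.default_rng(seed)
    # greedy init: pick rows that are mutually as orthogonal as possible
    r = np.zeros((k, k))
    idx = int(rng.integers(n))
    r[:, 0] = x[idx]
    c = np.zeros(n)
    for col in range(1, k):
        c += np.abs(x @ r[:, col - 1])
        r[:, col] = x[int(np.argmin(c))]
    labels = np.argmax(x @ r, axis=1)
    for _ in range(max_iter):
        onehot = sp.csr_array(
            (np.ones(n), (np.arange(n), labels)), shape=(n, k)
        )
        a = (onehot.T @ x)  # (k, k)
        u, _, vt = np.linalg.svd(a)
        r = vt.T @ u.T
        new_labels = np.argmax(x @ r, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def _relabel_compact(labels: np.ndarray) -> np.ndarray:
    """Map labels to 0..k−1 in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for idx, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[idx] = mapping[lab]
    return out


def cluster_embedding(
    embedding: np.ndarray, k: int, method: str = "discretize", seed: int = 0
) -> np.ndarray:
    """Partition embedding rows into exactly k nonempty clusters.

    ``discretize`` rotates the embedding to the nearest indicator matrix;
    ``kmeans`` uses seeded k-means with greedy (k-means++) centers.  An
    empty cluster triggers up to 10 reseeded retries.
    """
    x = np.asarray(embedding, float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"cannot form {k} clusters from {n} points")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"embedding has fewer than {k} distinct rows")
    for attempt in range(10):
        s = seed + 1000 * attempt
        if method == "discretize":
            labels = _discretize(x, seed=s)
        elif method == "kmeans":
            km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=s % (2**32))
            labels = km.fit_predict(x)
        else:
            raise ValueError(f"unknown clustering method {method!r}")
        if len(np.unique(labels)) == k:
            return _relabel_compact(labels)
    raise RuntimeError(f"clustering produced an empty cluster after 10 retries (k={k})")


def quality_score(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Partition sharpness: mean over points of d^(2)/d^(1).

    d^(1) is the distance to the point's own cluster centroid in the
    embedding, d^(2) the distance to the nearest other centroid.  Larger
    is better; a degenerate point (coincident with both centroids)
    contributes 1.
    """
    x = np.asarray(embedding, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("quality score requires at least 2 clusters")
    centroids = np.stack([x[labels == u].mean(axis=0) for u in uniq])
    lab_idx = np.searchsorted(uniq, labels)
    dists = np.linalg.norm(x[:, None, :] - centroids[None], axis=2)  # (n, k)
    d_own = dists[np.arange(len(x)), lab_idx]
    dists_other = dists.copy()
    dists_other[np.arange(len(x)), lab_idx] = np.inf
    d_other = dists_other.min(axis=1)
    tiny = 1e-12
    ratios = np.where(
        (d_own < tiny) & (d_other < tiny), 1.0, d_other / np.maximum(d_own, tiny)
    )
    return float(ratios.mean())


def fluctuation_contrast(graph: SimilarityGraph, labels: np.ndarray) -> float:
    """Mean cross-cluster σ² over the largest within-cluster σ².

    σ_ij² is recovered from the kernel weights as −log S_ij, exact up to
    the (positive) kernel bandwidth which cancels in the ratio, so the
    score is scale invariant.  Larger is better: a good quasi-rigid
    partition keeps every strongly fluctuating pair on a cluster
    boundary, so swallowing a floppy interface into a cluster collapses
    the score through the max in the denominator, while oversplitting a
    rigid cluster dilutes the cross-boundary mean.  Degenerate
    partitions with no within-cluster or no cross-cluster pairs score 0.
    """
    labels = np.asarray(labels)
    i, j = graph.pairs[:, 0], graph.pairs[:, 1]
    s2 = -np.log(np.maximum(graph.weights, 1e-300))
    within = labels[i] == labels[j]
    if not within.any() or within.all():
        return 0.0
    within_max = s2[within].max()
    cross_mean = s2[~within].mean()
    if within_max <= 0.0:
        return float(np.inf) if cross_mean > 0 else 0.0
    return float(cross_mean / within_max)


def _local_maxima(k_values: np.ndarray, q: np.ndarray) -> list[int]:
    out = []
    for idx, k in enumerate(k_values):
        left_ok = idx == 0 or q[idx] >= q[idx - 1]
        right_ok = idx == len(q) - 1 or q[idx] >= q[idx + 1]
        if left_ok and right_ok:
            out.append(int(k))
    return out


def scan_clusters(
    graph: SimilarityGraph,
    k_min: int = 4,
    k_max: int = 100,
    method: str = "discretize",
    seed: int = 0,
) -> ClusteringResult:
    """Embed, cluster and score every k in [k_min, k_max]; select argmax Q.

    One eigendecomposition of size k_max is reused: the embedding for
    each k takes its first k columns (re-normalizing rows).  Q is the
    fluctuation contrast of the partition.
    """
    if k_max < k_min:
        raise ValueError(f"k_max={k_max} < k_min={k_min}")
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    full = _embedding_vectors(graph, k_max)
    k_values = np.arange(k_min, k_max + 1)
    labels_by_k: dict[int, np.ndarray] = {}
    q = np.empty(len(k_values))
    for idx, k in enumerate(k_values):
        emb = _row_normalize(full[:, :k])
        labels = cluster_embedding(emb, int(k), method=method, seed=seed)
        labels_by_k[int(k)] = labels
        q[idx] = fluctuation_contrast(graph, labels)
    best = int(k_values[int(np.argmax(q))])  # argmax returns first => smallest k on ties
    return ClusteringResult(
        k_values=k_values,
        labels_by_k=labels_by_k,
        quality_by_k=q,
        selected_k=best,
        local_maxima=_local_maxima(k_values, q),
    )
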