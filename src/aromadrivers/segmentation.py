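"""PCA and k-means segmentation of consumers by hedonic pattern.

Consumers are clustered on their raw liking rows with Lloyd's k-means
(Euclidean distance, many random restarts, best inertia kept); PCA is
computed by SVD with a deterministic sign convention and is used for the 2-D
map of the segmentation, not for the clustering itself (clustering on PCA
scores is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consumer_panel import ConsumerPanel, liking_summary

__all__ = [
    "PCAResult",
    "pca",
    "ClusterAssignment",
    "segment_consumers",
    "cluster_profiles",
    "ClusterProfiles",
    "adjusted_rand_index",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame          # observations x components
    loadings: pd.DataFrame        # variables x components
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None

    def reconstruct(self) -> pd.DataFrame:
        """Reconstruct the centered/scaled data from all retained components."""
        x = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(x, index=self.scores.index, columns=self.loadings.index)


def pca(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Principal component analysis via singular value decomposition.

    The input is centered (and optionally scaled to unit column variance),
    decomposed as ``X = U S V^T``; scores are ``U S``, loadings the columns of
    ``V``.  Sign is fixed by making the largest-magnitude entry of every
    loading column positive, so results are fully deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if matrix.isna().any().any():
        raise ValueError("PCA input contains missing cells; impute first")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=0) if center else np.zeros(x.shape[1])
    x = x - mean
    scale_vec = None
    if scale:
        scale_vec = x.std(axis=0, ddof=1)
        zero = np.flatnonzero(scale_vec == 0)
        if zero.size:
            names = [str(matrix.columns[i]) for i in zero]
            raise ValueError(f"zero-variance column(s) under scaling: {names}")
        x = x / scale_vec

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest |loading| entry positive per component
    v = vt.T
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip

    var = s**2 / (x.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    k = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (u[:, :k] * s[:k]), index=matrix.index, columns=comp_names
    )
    loadings = pd.DataFrame(v[:, :k], index=matrix.columns, columns=comp_names)
    return PCAResult(scores, loadings, ratio[:k], mean, scale_vec)


@dataclass
class ClusterAssignment:
    labels: pd.Series             # consumer_id -> cluster label 1..k
    centroids: pd.DataFrame       # cluster x product
    inertia: float
    seed: int
    inertia_history: list[np.ndarray] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _lloyd(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One Lloyd's k-means run from a random (k-means++-free) init; returns
    (labels, centroids, inertia, per-iteration inertia history)."""
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.zeros(n, dtype=int)
    history = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(n), new_labels].sum())
        history.append(inertia)
        for j in range(k):
            members = x[new_labels == j]
            if len(members) == 0:
                # re-seed an empty cluster at the point farthest from its centroid
                far = int(d2[np.arange(n), new_labels].argmax())
                centroids[j] = x[far]
                new_labels[far] = j
            else:
                centroids[j] = members.mean(axis=0)
        if np.array_equal(new_labels, labels) and len(history) > 1:
            labels = new_labels
            break
        labels = new_labels
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2[np.arange(n), labels].sum())
    history.append(inertia)
    return labels, centroids, inertia, np.asarray(history)


def segment_consumers(
    liking: pd.DataFrame,
    k: int = 3,
    n_init: int = 50,
    seed: int = 0,
    on_scores: bool = False,
) -> ClusterAssignment:
    """k-means segmentation of consumers on their liking rows.

    Lloyd's algorithm with ``n_init`` random restarts; the restart with the
    lowest within-cluster sum of squares wins.  Labels are canonicalized to
    1..k by decreasing cluster size, ties broken by first-consumer position,
    so reports are stable across runs with the same seed.
    """
    if liking.isna().any().any():
        raise ValueError("segment only completers (missing liking scores found)")
    if k > len(liking):
        raise ValueError(f"k={k} exceeds number of consumers {len(liking)}")
    x = liking.to_numpy(dtype=float)
    if on_scores:
        x = pca(liking, center=True, scale=False).scores.to_numpy()
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float, np.ndarray] | None = None
    for _ in range(n_init):
        labels, centroids, inertia, history = _lloyd(x, k, rng)
        if len(np.unique(labels)) < k:
            continue
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia, history)
    if best is None:
        raise RuntimeError("all k-means restarts produced degenerate clusterings")
    labels, centroids, inertia, history = best

    # canonical labels: decreasing size, then first occurrence in panel order
    order = sorted(
        range(k),
        key=lambda j: (-int((labels == j).sum()), int(np.flatnonzero(labels == j)[0])),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    canon = np.array([relabel[j] for j in labels])
    centroids = centroids[order]
    return ClusterAssignment(
        labels=pd.Series(canon, index=liking.index, name="cluster"),
        centroids=pd.DataFrame(
            centroids, index=range(1, k + 1), columns=liking.columns
        ),
        inertia=inertia,
        seed=seed,
        inertia_history=[history],
    )


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two clusterings (ARI).

    Computed from the contingency table; 1 for identical partitions, ~0 for
    independent ones.  Used to score recovery of planted clusters.
    """
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    n = len(a)
    table = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class ClusterProfiles:
    sizes: pd.Series              # cluster -> n consumers
    liking_means: pd.DataFrame    # cluster x product
    attitude_means: pd.DataFrame | None


def cluster_profiles(
    panel: ConsumerPanel, assignment: ClusterAssignment
) -> ClusterProfiles:
    """Per-cluster sizes, mean liking per product, and attitude-item means."""
    missing = panel.liking.index.difference(assignment.labels.index)
    if len(missing):
        raise ValueError(f"assignment does not cover consumers: {list(missing)}")
    labels = assignment.labels.loc[panel.liking.index]
    sizes = labels.value_counts().sort_index()
    liking_means = panel.liking.groupby(labels).mean()
    att = panel.attitude_items()
    attitude_means = att.groupby(labels).mean() if att.shape[1] else None
    return ClusterProfiles(sizes, liking_means, attitude_means)
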