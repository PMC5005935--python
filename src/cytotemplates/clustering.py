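"""Cell population identification: k-means partitioning, consensus
selection of the number of populations via five cluster-validity indices,
and reduction of populations to Gaussian (mean, covariance, size) summaries.

The five indices are average silhouette width, Calinski-Harabasz, Dunn,
S_Dbw and Davies-Bouldin. The first three are maximized, the last two
minimized; each casts a vote for its optimal k and the consensus k is the
majority vote (ties toward smaller k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .model import ClusteredSample, ClusterSummary, EventMatrix

log = logging.getLogger(__name__)

__all__ = [
    "fit_kmeans",
    "validation_indices",
    "select_k",
    "summarize_clusters",
    "ValidationReport",
    "MAXIMIZED_INDICES",
    "MINIMIZED_INDICES",
]

N_RESTARTS = 10
SUBSAMPLE_CAP = 5000
COV_REG_REL = 1e-6
COV_REG_FLOOR = 1e-12

MAXIMIZED_INDICES = ("silhouette", "calinski_harabasz", "dunn")
MINIMIZED_INDICES = ("s_dbw", "davies_bouldin")
ALL_INDICES = MAXIMIZED_INDICES + MINIMIZED_INDICES


def _regularize(cov: np.ndarray) -> np.ndarray:
    p = cov.shape[0]
    eps = max(COV_REG_REL * float(np.trace(cov)) / p, COV_REG_FLOOR)
    return cov + eps * np.eye(p)


def summarize_clusters(
    events: EventMatrix, assignments: np.ndarray, sample_id: str | None = None
) -> ClusteredSample:
    """Reduce a partitioned sample to Gaussian cluster summaries.

    Covariances are maximum-likelihood (divide by n) with a small ridge
    (1e-6 * trace/p, floored) so that pooled covariances stay invertible
    even for tiny clusters.
    """
    assignments = np.asarray(assignments, dtype=int)
    labels = np.unique(assignments)
    clusters = []
    for lab in labels:
        pts = events.values[assignments == lab]
        mu = pts.mean(axis=0)
        if pts.shape[0] > 1:
            cov = np.cov(pts, rowvar=False, ddof=0)
            cov = np.atleast_2d(cov)
        else:
            cov = np.zeros((events.n_channels, events.n_channels))
        clusters.append(
            ClusterSummary(mean=mu, covariance=_regularize(cov), size=pts.shape[0])
        )
    # Relabel assignments densely in label order
    remap = {int(lab): i for i, lab in enumerate(labels)}
    dense = np.array([remap[int(a)] for a in assignments])
    return ClusteredSample(
        sample_id=sample_id if sample_id is not None else events.sample_id,
        clusters=clusters,
        assignments=dense,
    )


def fit_kmeans(events: EventMatrix, k: int, seed: int = 0) -> ClusteredSample:
    """Standard k-means with multiple restarts; deterministic given seed."""
    if k > events.n_cells:
        raise ValueError(f"k={k} exceeds the {events.n_cells} cells available")
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
    labels = km.fit_predict(events.values)
    # k-means++ with restarts essentially never leaves a cluster empty, but
    # guard anyway: refit with fresh seeds until all k clusters are filled.
    attempts = 0
    while len(np.unique(labels)) < k and attempts < 5:
        attempts += 1
        log.warning("empty cluster after k-means; re-initializing (attempt %d)", attempts)
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed + 1000 * attempts)
        labels = km.fit_predict(events.values)
    return summarize_clusters(events, labels)


def _subsample(X: np.ndarray, labels: np.ndarray, cap: int, seed: int):
    if X.shape[0] <= cap:
        return X, labels
    rng = np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=cap, replace=False)
    Xs, ls = X[idx], labels[idx]
    if len(np.unique(ls)) < 2:
        return X, labels  # degenerate subsample; fall back to full data
    return Xs, ls


def _dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Dunn's index: min between-cluster point distance over max diameter."""
    uniq = np.unique(labels)
    groups = [X[labels == u] for u in uniq]
    max_diam = 0.0
    for g in groups:
        if g.shape[0] > 1:
            max_diam = max(max_diam, float(cdist(g, g).max()))
    if max_diam == 0.0:
        return np.inf
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_sep = min(min_sep, float(cdist(groups[i], groups[j]).min()))
    return min_sep / max_diam


def _s_dbw_index(X: np.ndarray, labels: np.ndarray) -> float:
    """S_Dbw: average cluster scatter plus inter-cluster density (minimized)."""
    uniq = np.unique(labels)
    k = len(uniq)
    groups = [X[labels == u] for u in uniq]
    centroids = np.array([g.mean(axis=0) for g in groups])
    sigma_tot = np.var(X, axis=0)
    sigma = [np.var(g, axis=0) for g in groups]
    norm_tot = np.linalg.norm(sigma_tot)
    scat = float(np.mean([np.linalg.norm(s) for s in sigma]) / norm_tot) if norm_tot > 0 else 0.0

    stdev = np.sqrt(sum(np.linalg.norm(s) for s in sigma)) / k

    def density(point: np.ndarray, pts: np.ndarray) -> int:
        return int(np.sum(np.linalg.norm(pts - point, axis=1) <= stdev))

    dens = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            union = np.vstack([groups[i], groups[j]])
            d_i = density(centroids[i], union)
            d_j = density(centroids[j], union)
            d_mid = density((centroids[i] + centroids[j]) / 2.0, union)
            denom = max(d_i, d_j)
            if denom > 0:
                dens += d_mid / denom
    dens /= k * (k - 1)
    return scat + dens


def _silhouette_with_singletons(X: np.ndarray, labels: np.ndarray) -> float:
    # Convention: points in singleton clusters contribute silhouette 0.
    from sklearn.metrics import silhouette_samples

    counts = np.bincount(labels)
    if np.all(counts[np.unique(labels)] > 1):
        return float(silhouette_score(X, labels))
    vals = silhouette_samples(X, labels)
    single = counts[labels] == 1
    vals[single] = 0.0
    return float(vals.mean())


def validation_indices(
    events: EventMatrix | np.ndarray,
    assignments: np.ndarray,
    seed: int = 0,
    subsample_cap: int = SUBSAMPLE_CAP,
) -> dict[str, float]:
    """Compute the five validity indices for one partition.

    The O(n^2) indices (silhouette, Dunn, S_Dbw) are computed on a seeded
    subsample of at most ``subsample_cap`` cells.
    """
    X = events.values if isinstance(events, EventMatrix) else np.asarray(events)
    labels = np.asarray(assignments, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("validity indices need at least 2 non-empty clusters")
    Xs, ls = _subsample(X, labels, subsample_cap, seed)
    return {
        "silhouette": _silhouette_with_singletons(Xs, ls),
        "calinski_harabasz": float(calinski_harabasz_score(X, labels)),
        "dunn": _dunn_index(Xs, ls),
        "s_dbw": _s_dbw_index(Xs, ls),
        "davies_bouldin": float(davies_bouldin_score(X, labels)),
    }


@dataclass
class ValidationReport:
    """Index scores across a k range, per-index votes, and the consensus k."""

    k_values: list[int]
    scores: dict[str, list[float]] = field(default_factory=dict)
    votes: dict[str, int] = field(default_factory=dict)
    consensus_k: int = 0


def consensus_from_votes(votes: list[int]) -> int:
    """Majority vote over per-index optimal k; ties break toward smaller k."""
    ks, counts = np.unique(votes, return_counts=True)
    best = counts.max()
    return int(ks[counts == best].min())


def select_k(
    events: EventMatrix,
    k_range,
    seed: int = 0,
    subsample_cap: int = SUBSAMPLE_CAP,
) -> ValidationReport:
    """Choose the number of cell populations by consensus of five indices."""
    k_values = sorted(int(k) for k in k_range)
    if min(k_values) < 2:
        raise ValueError("k range must start at 2 or above")
    scores: dict[str, list[float]] = {name: [] for name in ALL_INDICES}
    for k in k_values:
        cs = fit_kmeans(events, k, seed=seed)
        idx = validation_indices(events, cs.assignments, seed=seed, subsample_cap=subsample_cap)
        for name in ALL_INDICES:
            scores[name].append(idx[name])
    votes: dict[str, int] = {}
    for name in MAXIMIZED_INDICES:
        votes[name] = k_values[int(np.argmax(scores[name]))]
    for name in MINIMIZED_INDICES:
        votes[name] = k_values[int(np.argmin(scores[name]))]
    consensus = consensus_from_votes(list(votes.values()))
    return ValidationReport(
        k_values=k_values, scores=scores, votes=votes, consensus_k=consensus
    )
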