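"""Cluster dissimilarities and mixed-edge-cover (MEC) registration.

Two Gaussian-summarized cell populations are compared by the Mahalanobis
distance with pooled covariance (default), the symmetrized Kullback-Leibler
divergence, or the Euclidean distance between centers. Populations of two
samples are then registered by a minimum-cost mixed edge cover: every
cluster is matched to zero, one, or more clusters on the other side, with
an unmatched cluster paying a fixed penalty lambda. The minimum cover cost
is the sample dissimilarity D(A, B).

The optimal cover decomposes into stars: a cluster is matched once inside
an ordinary matching, left unmatched (cost lambda), or attached to its
cheapest partner (which is thereby multi-covered). The problem therefore
reduces exactly to a square linear assignment problem with per-vertex slack
priced at min(lambda, cheapest incident edge), solved by the Hungarian
algorithm in O(k^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import ClusteredSample, ClusterSummary, TemplateNode

__all__ = [
    "MatchConfig",
    "MECResult",
    "cluster_dissimilarity",
    "dissimilarity_matrix",
    "mixed_edge_cover",
    "mec_from_distance_matrix",
    "sample_dissimilarity",
]

Method = Literal["mahalanobis", "symmetrized_kl", "euclidean_center"]


@dataclass
class MatchConfig:
    """Dissimilarity method and unmatched penalty.

    ``lam`` defaults to the dimensionality p, so that (in the squared
    Mahalanobis reading) two clusters are matched only when the average
    squared deviation per dimension is below one. ``squared=True`` switches
    the Mahalanobis form from sqrt(0.5 * d2) to 0.5 * d2.
    """

    method: Method = "mahalanobis"
    lam: float | None = None
    squared: bool = False

    def resolve_lambda(self, p: int) -> float:
        lam = float(p) if self.lam is None else float(self.lam)
        if lam <= 0:
            raise ValueError("lambda must be positive")
        return lam


def _pooled_covariance(c1: ClusterSummary, c2: ClusterSummary) -> np.ndarray:
    n1, n2 = c1.size, c2.size
    if n1 + n2 < 3:
        raise ValueError("pooled covariance needs n1 + n2 >= 3 cells")
    return ((n1 - 1) * c1.covariance + (n2 - 1) * c2.covariance) / (n1 + n2 - 2)


def _gaussian_kl(c1: ClusterSummary, c2: ClusterSummary) -> float:
    p = c1.dim
    delta = c2.mean - c1.mean
    s2_inv = np.linalg.inv(c2.covariance)
    _, ld1 = np.linalg.slogdet(c1.covariance)
    _, ld2 = np.linalg.slogdet(c2.covariance)
    return 0.5 * (
        float(np.trace(s2_inv @ c1.covariance))
        + float(delta @ s2_inv @ delta)
        - p
        + (ld2 - ld1)
    )


def cluster_dissimilarity(
    c1: ClusterSummary, c2: ClusterSummary, cfg: MatchConfig | None = None
) -> float:
    """Dissimilarity between two Gaussian population summaries (>= 0)."""
    cfg = cfg or MatchConfig()
    if c1.dim != c2.dim:
        raise ValueError("clusters live in different dimensions")
    if cfg.method == "euclidean_center":
        return float(np.linalg.norm(c1.mean - c2.mean))
    if cfg.method == "symmetrized_kl":
        return 0.5 * (_gaussian_kl(c1, c2) + _gaussian_kl(c2, c1))
    if cfg.method != "mahalanobis":
        raise ValueError(f"unknown dissimilarity method {cfg.method!r}")
    pooled = _pooled_covariance(c1, c2)
    delta = c1.mean - c2.mean
    try:
        solved = np.linalg.solve(pooled, delta)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled covariance is singular even after regularization"
        ) from None
    d2 = 0.5 * float(delta @ solved)
    d2 = max(d2, 0.0)
    return d2 if cfg.squared else float(np.sqrt(d2))


def dissimilarity_matrix(
    A: Sequence[ClusterSummary],
    B: Sequence[ClusterSummary],
    cfg: MatchConfig | None = None,
) -> np.ndarray:
    cfg = cfg or MatchConfig()
    out = np.empty((len(A), len(B)))
    for i, a in enumerate(A):
        for j, b in enumerate(B):
            out[i, j] = cluster_dissimilarity(a, b, cfg)
    return out


@dataclass
class MECResult:
    """A minimum-cost mixed edge cover between cluster lists A and B."""

    edges: set[tuple[int, int]]
    unmatched_A: set[int]
    unmatched_B: set[int]
    cost: float
    lam: float
    distances: np.ndarray = field(repr=False, default=None)

    def matched_B(self, i: int) -> list[int]:
        """Indices of B-side partners of A-cluster i (mec(a_i))."""
        return sorted(j for a, j in self.edges if a == i)

    def matched_A(self, j: int) -> list[int]:
        return sorted(i for i, b in self.edges if b == j)

    def average_distance_A(self, i: int) -> float:
        """Mean distance from A-cluster i to its matched set (<= 2 lambda)."""
        partners = self.matched_B(i)
        if not partners:
            raise ValueError(f"A-cluster {i} is unmatched")
        return float(np.mean([self.distances[i, j] for j in partners]))

    def average_distance_B(self, j: int) -> float:
        partners = self.matched_A(j)
        if not partners:
            raise ValueError(f"B-cluster {j} is unmatched")
        return float(np.mean([self.distances[i, j] for i in partners]))


def mec_from_distance_matrix(d: np.ndarray, lam: float) -> MECResult:
    """Exact minimum-cost mixed edge cover for a given distance matrix."""
    d = np.asarray(d, dtype=float)
    ka, kb = d.shape
    if ka == 0 or kb == 0:
        return MECResult(
            edges=set(),
            unmatched_A=set(range(ka)),
            unmatched_B=set(range(kb)),
            cost=lam * (ka + kb),
            lam=lam,
            distances=d,
        )

    r_a = np.minimum(lam, d.min(axis=1))
    r_b = np.minimum(lam, d.min(axis=0))
    big = float(d.sum() + lam * (ka + kb) + 1.0)

    n = ka + kb
    C = np.full((n, n), big)
    C[:ka, :kb] = d
    C[:ka, kb:] = big
    C[np.arange(ka), kb + np.arange(ka)] = r_a
    C[ka + np.arange(kb), np.arange(kb)] = r_b
    C[ka:, kb:] = 0.0

    rows, cols = linear_sum_assignment(C)

    edges: set[tuple[int, int]] = set()
    unmatched_A: set[int] = set()
    unmatched_B: set[int] = set()
    for r, c in zip(rows, cols):
        if r < ka and c < kb:
            edges.add((int(r), int(c)))
        elif r < ka:  # a_r resolved through its slack
            i = int(r)
            j = int(np.argmin(d[i]))
            if d[i, j] < lam:
                edges.add((i, j))
            else:
                unmatched_A.add(i)
        elif c < kb:  # b_c resolved through its slack
            j = int(c)
            i = int(np.argmin(d[:, j]))
            if d[i, j] < lam:
                edges.add((i, j))
            else:
                unmatched_B.add(j)

    cost = float(
        sum(d[i, j] for i, j in edges)
        + lam * (len(unmatched_A) + len(unmatched_B))
    )
    return MECResult(
        edges=edges,
        unmatched_A=unmatched_A,
        unmatched_B=unmatched_B,
        cost=cost,
        lam=lam,
        distances=d,
    )


def _contents(x) -> list[ClusterSummary]:
    if isinstance(x, ClusteredSample):
        return x.clusters
    if isinstance(x, TemplateNode):
        return x.contents
    return list(x)


def mixed_edge_cover(A, B, cfg: MatchConfig | None = None) -> MECResult:
    """Register the populations of A against those of B (Gaussian summaries,
    ClusteredSample, or TemplateNode) by a minimum-cost mixed edge cover."""
    cfg = cfg or MatchConfig()
    ca, cb = _contents(A), _contents(B)
    p = ca[0].dim if ca else (cb[0].dim if cb else 1)
    lam = cfg.resolve_lambda(p)
    d = dissimilarity_matrix(ca, cb, cfg)
    return mec_from_distance_matrix(d, lam)


def sample_dissimilarity(A, B, cfg: MatchConfig | None = None) -> float:
    """D(A, B): the minimum mixed-edge-cover cost between two samples or
    templates. Symmetric and zero for identical cluster lists."""
    return mixed_edge_cover(A, B, cfg).cost
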