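"""Core domain types shared by every stage of the pipeline.

A flow cytometry *sample* enters as an :class:`EventMatrix` (cells x
channels), is partitioned into cell populations summarized as Gaussians
(:class:`ClusterSummary`), and cohorts of samples are condensed into
*templates*: collections of :class:`MetaCluster` objects living at internal
nodes of a binary :class:`TemplateTree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EventMatrix",
    "SpilloverMatrix",
    "CohortMetadata",
    "ClusterSummary",
    "ClusteredSample",
    "MetaCluster",
    "TemplateNode",
    "TemplateTree",
    "ConfusionCounts",
]


@dataclass
class EventMatrix:
    """A single sample: an ``n_cells x n_channels`` matrix of signal values.

    Values may be raw fluorescence/scatter intensities or transformed
    (compensated, asinh-scaled) quantities; the type does not track which.
    """

    values: np.ndarray
    channel_names: list[str]
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (cells x channels) array")
        if self.values.shape[0] < 1:
            raise ValueError("an EventMatrix needs at least one cell")
        if len(self.channel_names) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.values.shape[1]} columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            rows = sorted({int(r) for r, _ in bad[:20]})
            raise ValueError(f"non-finite values in rows {rows}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_index(name)]


@dataclass
class SpilloverMatrix:
    """Column-stochastic spillover matrix M of the unmixing system o = M s.

    ``M[i, j]`` is the fractional contribution of fluorochrome *j* to the
    detector of fluorochrome *i*; each column sums to one.
    """

    M: np.ndarray
    channel_names: list[str]

    COLUMN_SUM_TOL = 1e-6
    MAX_CONDITION = 1e8

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        p = len(self.channel_names)
        if self.M.shape != (p, p):
            raise ValueError("spillover matrix must be square, one row per channel")
        colsums = self.M.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=self.COLUMN_SUM_TOL):
            raise ValueError(
                f"spillover columns must sum to 1 (got {colsums.tolist()})"
            )
        if np.linalg.cond(self.M) > self.MAX_CONDITION:
            raise ValueError(
                "spillover matrix is ill-conditioned; repair it (e.g. re-run "
                "single-stain controls) before unmixing"
            )


@dataclass
class SampleMeta:
    class_label: str
    subject: Optional[str] = None
    day: Optional[str] = None
    replicate: Optional[str] = None


@dataclass
class CohortMetadata:
    """Maps sample_id to class / subject / day / replicate labels."""

    samples: dict[str, SampleMeta] = field(default_factory=dict)

    def add(self, sample_id: str, class_label: str, subject: str | None = None,
            day: str | None = None, replicate: str | None = None) -> None:
        self.samples[sample_id] = SampleMeta(class_label, subject, day, replicate)

    def class_of(self, sample_id: str) -> str:
        return self.samples[sample_id].class_label

    def subject_of(self, sample_id: str) -> Optional[str]:
        return self.samples[sample_id].subject

    @property
    def class_labels(self) -> list[str]:
        return sorted({m.class_label for m in self.samples.values()})

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ClusterSummary:
    """Gaussian summary (mean, covariance, cell count) of one cell population."""

    mean: np.ndarray
    covariance: np.ndarray
    size: int
    label: str = ""

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        p = self.mean.shape[0]
        if self.covariance.shape != (p, p):
            raise ValueError("covariance shape must match mean length")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("cluster mean must be finite")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


@dataclass
class ClusteredSample:
    """A sample reduced to its k cell populations plus per-cell assignments."""

    sample_id: str
    clusters: list[ClusterSummary]
    assignments: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.clusters) < 1:
            raise ValueError("a clustered sample needs at least one cluster")
        if self.assignments is not None:
            self.assignments = np.asarray(self.assignments, dtype=int)
            counts = np.bincount(self.assignments, minlength=len(self.clusters))
            sizes = np.array([c.size for c in self.clusters])
            if not np.array_equal(counts[: len(sizes)], sizes):
                raise ValueError("cluster sizes must equal assignment counts")

    @property
    def k(self) -> int:
        return len(self.clusters)

    @property
    def n_cells(self) -> int:
        return int(sum(c.size for c in self.clusters))


@dataclass
class MetaCluster(ClusterSummary):
    """A merged group of matched clusters, with provenance records.

    ``members`` lists ``(sample_id, cluster_index)`` pairs identifying every
    per-sample cluster pooled into this meta-cluster.
    """

    members: list[tuple[str, int]] = field(default_factory=list)
    member_sizes: list[int] = field(default_factory=list)

    def distinct_samples(self) -> set[str]:
        return {sid for sid, _ in self.members}


@dataclass
class TemplateNode:
    """One node of the binary template tree.

    Leaves carry a sample's clusters at height 0; internal nodes carry the
    meta-clusters formed by merging their two children, at height equal to
    the children's dissimilarity at merge time.
    """

    node_id: int
    contents: list[ClusterSummary]
    height: float = 0.0
    children: tuple[int, int] | None = None
    sample_ids: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def k(self) -> int:
        return len(self.contents)


@dataclass
class TemplateTree:
    """Binary dendrogram over samples; nodes indexed by id, last node = root."""

    nodes: dict[int, TemplateNode]
    root_id: int

    @property
    def root(self) -> TemplateNode:
        return self.nodes[self.root_id]

    def leaves(self, node_id: int | None = None) -> list[TemplateNode]:
        start = self.root_id if node_id is None else node_id
        out: list[TemplateNode] = []
        stack = [start]
        while stack:
            node = self.nodes[stack.pop()]
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_sample_ids(self, node_id: int | None = None) -> list[str]:
        return [leaf.sample_ids[0] for leaf in self.leaves(node_id)]


@dataclass
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary classifier."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def pooled_total_cells(samples: Sequence[ClusteredSample]) -> int:
    return int(sum(s.n_cells for s in samples))
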