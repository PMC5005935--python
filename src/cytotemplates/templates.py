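"""Hierarchical matching-and-merging (HM&M) template trees.

A cohort of clustered samples is organized into a binary tree: starting
from one orphan node per sample, the two least-dissimilar orphans (under
the mixed-edge-cover dissimilarity D) are repeatedly matched and merged
until one orphan remains. Matched clusters pool into *meta-clusters* whose
Gaussian parameters are the maximum-likelihood fit to the union of member
cells, computed in closed form from the members' moments. Internal nodes
store their meta-cluster lists; the roots of well-separated branches are
the class *templates*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matching import MatchConfig, MECResult, mixed_edge_cover, sample_dissimilarity
from .model import (
    ClusteredSample,
    ClusterSummary,
    CohortMetadata,
    MetaCluster,
    TemplateNode,
    TemplateTree,
)

log = logging.getLogger(__name__)

__all__ = [
    "sample_to_node",
    "merge_matched",
    "build_template_tree",
    "cut_templates",
    "insert_sample",
    "metacluster_participation",
]


def sample_to_node(sample: ClusteredSample, node_id: int = 0) -> TemplateNode:
    """Wrap a clustered sample as a height-0 leaf node."""
    return TemplateNode(
        node_id=node_id,
        contents=list(sample.clusters),
        height=0.0,
        children=None,
        sample_ids=[sample.sample_id],
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _ml_moment_merge(members: list[ClusterSummary]) -> tuple[np.ndarray, np.ndarray, int]:
    """Closed-form ML Gaussian fit to the pooled cells of the members.

    mu = sum n_i mu_i / n;  Sigma = sum n_i (Sigma_i + mu_i mu_i^T)/n - mu mu^T.
    Exact whenever member covariances are themselves ML (divide-by-n) fits.
    """
    sizes = np.array([m.size for m in members], dtype=float)
    n = sizes.sum()
    mu = sum(m.size * m.mean for m in members) / n
    second = sum(
        m.size * (m.covariance + np.outer(m.mean, m.mean)) for m in members
    ) / n
    cov = second - np.outer(mu, mu)
    cov = 0.5 * (cov + cov.T)
    return mu, cov, int(n)


def _provenance(node: TemplateNode, idx: int) -> tuple[list[tuple[str, int]], list[int]]:
    c = node.contents[idx]
    if isinstance(c, MetaCluster):
        return list(c.members), list(c.member_sizes)
    sid = node.sample_ids[0] if node.sample_ids else f"node{node.node_id}"
    return [(sid, idx)], [c.size]


def merge_matched(
    left: TemplateNode, right: TemplateNode, mec: MECResult
) -> list[MetaCluster]:
    """Form meta-clusters from the connected components of the MEC edges.

    Each component of the bipartite edge set (including unmatched singleton
    clusters, which form self-contained meta-clusters) becomes one
    meta-cluster whose parameters are the ML moment merge of its members.
    """
    ka, kb = left.k, right.k
    uf = _UnionFind(ka + kb)
    for i, j in mec.edges:
        uf.union(i, ka + j)
    components: dict[int, list[tuple[TemplateNode, int]]] = {}
    for i in range(ka):
        components.setdefault(uf.find(i), []).append((left, i))
    for j in range(kb):
        components.setdefault(uf.find(ka + j), []).append((right, j))

    metas: list[MetaCluster] = []
    for root in sorted(components):
        group = components[root]
        summaries = [node.contents[idx] for node, idx in group]
        mu, cov, n = _ml_moment_merge(summaries)
        members: list[tuple[str, int]] = []
        member_sizes: list[int] = []
        for node, idx in group:
            mem, msz = _provenance(node, idx)
            members.extend(mem)
            member_sizes.extend(msz)
        metas.append(
            MetaCluster(
                mean=mu,
                covariance=cov,
                size=n,
                members=members,
                member_sizes=member_sizes,
            )
        )
    return metas


def build_template_tree(
    samples: list[ClusteredSample], cfg: MatchConfig | None = None
) -> TemplateTree:
    """Build the HM&M binary template tree over a cohort.

    All pairwise dissimilarities among orphans are cached; after each merge
    only the new node's dissimilarities are computed, for O(N^2) D
    evaluations total. Argmin ties break toward the lexicographically
    smallest (node_id, node_id) pair, making rebuilds deterministic.
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    cfg = cfg or MatchConfig()
    nodes: dict[int, TemplateNode] = {}
    for i, s in enumerate(samples):
        nodes[i] = sample_to_node(s, node_id=i)
    orphans = sorted(nodes)
    if len(orphans) == 1:
        return TemplateTree(nodes=nodes, root_id=orphans[0])

    cache: dict[tuple[int, int], float] = {}
    for ai, a in enumerate(orphans):
        for b in orphans[ai + 1 :]:
            cache[(a, b)] = sample_dissimilarity(nodes[a], nodes[b], cfg)

    next_id = len(samples)
    while len(orphans) > 1:
        best = min(
            ((cache[(a, b)], a, b) for i, a in enumerate(orphans)
             for b in orphans[i + 1 :]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        height, a, b = best
        mec = mixed_edge_cover(nodes[a], nodes[b], cfg)
        metas = merge_matched(nodes[a], nodes[b], mec)
        new = TemplateNode(
            node_id=next_id,
            contents=metas,
            height=float(height),
            children=(a, b),
            sample_ids=nodes[a].sample_ids + nodes[b].sample_ids,
        )
        if height < max(nodes[a].height, nodes[b].height):
            log.warning(
                "height inversion: node %d at %.4g below child height %.4g",
                next_id, height, max(nodes[a].height, nodes[b].height),
            )
        nodes[next_id] = new
        orphans = [o for o in orphans if o not in (a, b)]
        for o in orphans:
            cache[(min(o, next_id), max(o, next_id))] = sample_dissimilarity(
                nodes[o], new, cfg
            )
        orphans.append(next_id)
        next_id += 1

    return TemplateTree(nodes=nodes, root_id=orphans[0])


def _gap_threshold(heights: np.ndarray) -> float:
    """Cut level at the largest relative gap between sorted merge heights."""
    hs = np.sort(heights)
    if hs.size == 1:
        return float(hs[0]) / 2.0
    tiny = max(hs.max(), 1.0) * 1e-12
    ratios = (hs[1:] + tiny) / (hs[:-1] + tiny)
    gi = int(np.argmax(ratios))
    return float(np.sqrt((hs[gi] + tiny) * (hs[gi + 1] + tiny)))


def cut_templates(
    tree: TemplateTree,
    mode: str = "by_gap",
    height: float | None = None,
    metadata: CohortMetadata | None = None,
    label: str = "class_label",
) -> list[TemplateNode]:
    """Extract class templates as subtree roots of well-separated branches.

    ``by_gap`` cuts at the largest relative gap between successive merge
    heights (the standard dendrogram heuristic); ``by_height`` cuts below a
    given height; ``by_labels`` returns the lowest nodes covering exactly
    one class per the cohort metadata.
    """
    if mode == "by_height":
        if height is None:
            raise ValueError("by_height requires a height")
        threshold = height
    elif mode == "by_gap":
        internal = [n for n in tree.nodes.values() if not n.is_leaf]
        if not internal:
            return [tree.root]
        threshold = _gap_threshold(np.array([n.height for n in internal]))
    elif mode == "by_labels":
        if metadata is None:
            raise ValueError("by_labels requires cohort metadata")
        return _cut_by_labels(tree, metadata, label)
    else:
        raise ValueError(f"unknown cut mode {mode!r}")

    out: list[TemplateNode] = []
    stack = [tree.root_id]
    while stack:
        node = tree.nodes[stack.pop()]
        if node.height <= threshold:
            out.append(node)
        else:
            stack.extend(reversed(node.children))
    return out


def _node_labels(tree: TemplateTree, node_id: int, meta: CohortMetadata, field: str) -> set[str]:
    out = set()
    for sid in tree.nodes[node_id].sample_ids:
        rec = meta.samples[sid]
        out.add(getattr(rec, field) if field != "class_label" else rec.class_label)
    return out


def _cut_by_labels(
    tree: TemplateTree, metadata: CohortMetadata, field: str
) -> list[TemplateNode]:
    out: list[TemplateNode] = []
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        node = tree.nodes[nid]
        labels = _node_labels(tree, nid, metadata, field)
        if len(labels) == 1:
            out.append(node)
        else:
            stack.extend(reversed(node.children))
    seen: dict[str, int] = {}
    for node in out:
        lab = next(iter(_node_labels(tree, node.node_id, metadata, field)))
        seen[lab] = seen.get(lab, 0) + 1
    split = {lab: n for lab, n in seen.items() if n > 1}
    if split:
        log.warning(
            "classes %s are non-contiguous in the tree; returning per-class forests",
            sorted(split),
        )
    return out


def insert_sample(
    templates: list[TemplateNode] | TemplateTree,
    sample: ClusteredSample,
    threshold: float | None = None,
    cfg: MatchConfig | None = None,
) -> tuple[list[TemplateNode], int | None]:
    """Dynamically classify-and-insert a new sample into existing templates.

    Computes D(sample, T_i) for every template; if the minimum is within
    the threshold, the sample is merged into that template (meta-cluster
    parameters updated by matching and ML merging) and its index returned.
    Otherwise a new singleton template is appended and ``None`` is returned
    as the matched index (a "new class").

    A TemplateTree may be passed, in which case its root is the single
    template and the default threshold is the root height.
    """
    cfg = cfg or MatchConfig()
    if isinstance(templates, TemplateTree):
        if threshold is None:
            threshold = templates.root.height
        templates = [templates.root]
    else:
        templates = list(templates)
    if threshold is None:
        raise ValueError("a threshold is required when passing a template list")

    next_id = max((t.node_id for t in templates), default=-1) + 1
    if templates:
        dissims = [sample_dissimilarity(t, sample, cfg) for t in templates]
        best = int(np.argmin(dissims))
        if dissims[best] <= threshold:
            target = templates[best]
            leaf = sample_to_node(sample, node_id=next_id)
            mec = mixed_edge_cover(target, leaf, cfg)
            merged = TemplateNode(
                node_id=next_id + 1,
                contents=merge_matched(target, leaf, mec),
                height=max(target.height, float(dissims[best])),
                children=None,
                sample_ids=target.sample_ids + [sample.sample_id],
            )
            templates[best] = merged
            return templates, best

    templates.append(
        TemplateNode(
            node_id=next_id,
            contents=[
                MetaCluster(
                    mean=c.mean,
                    covariance=c.covariance,
                    size=c.size,
                    members=[(sample.sample_id, i)],
                    member_sizes=[c.size],
                )
                for i, c in enumerate(sample.clusters)
            ],
            height=0.0,
            children=None,
            sample_ids=[sample.sample_id],
        )
    )
    return templates, None


def metacluster_participation(template: TemplateNode) -> np.ndarray:
    """Fraction of the template's samples contributing to each meta-cluster."""
    n_samples = len(template.sample_ids)
    out = np.empty(len(template.contents))
    for i, mc in enumerate(template.contents):
        if not isinstance(mc, MetaCluster):
            raise ValueError("participation requires meta-clusters with provenance")
        out[i] = len(mc.distinct_samples()) / n_samples
    return out
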