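"""Readers and writers: CSV/FCS samples, spillover matrices, cohort
metadata, Newick trees, and JSON serialization of clusters and templates."""

from __future__ import annotations

import json
import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .fcs import read_fcs
from .model import (
    ClusteredSample,
    ClusterSummary,
    CohortMetadata,
    EventMatrix,
    MetaCluster,
    SpilloverMatrix,
    TemplateNode,
    TemplateTree,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_sample",
    "write_sample",
    "read_spillover",
    "read_metadata",
    "write_tree_newick",
    "clustered_sample_to_dict",
    "clustered_sample_from_dict",
    "save_clustered_sample",
    "load_clustered_sample",
]


def read_sample(path: str, format: str | None = None) -> EventMatrix:
    """Read one sample from a headered CSV or an FCS 3.0/3.1 file.

    The format is inferred from the extension when not given. CSV files must
    have a single header row of channel names and numeric cells only.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "fcs" if ext == ".fcs" else "csv"
    if format == "fcs":
        return read_fcs(path)
    if format != "csv":
        raise ValueError(f"unknown sample format {format!r} (need csv or fcs)")

    df = pd.read_csv(path)
    bad = df.columns[df.dtypes == object]
    if len(bad) > 0:
        for col in bad:
            coerced = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[coerced.isna() & df[col].notna()].tolist()
            if rows:
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, "
                    f"row(s) {rows[:10]} (0-based, after header)"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing values in rows {rows[:10]}")
    sample_id = os.path.splitext(os.path.basename(path))[0]
    return EventMatrix(
        values=df.to_numpy(dtype=float),
        channel_names=[str(c) for c in df.columns],
        sample_id=sample_id,
    )


def write_sample(events: EventMatrix, path: str) -> None:
    """Write an EventMatrix as a headered CSV (the package's interchange form)."""
    pd.DataFrame(events.values, columns=events.channel_names).to_csv(
        path, index=False
    )


def read_spillover(path: str) -> SpilloverMatrix:
    """Read a spillover matrix from CSV: header row of channel names, one
    row per detector channel in the same order."""
    df = pd.read_csv(path)
    return SpilloverMatrix(
        M=df.to_numpy(dtype=float), channel_names=[str(c) for c in df.columns]
    )


def read_metadata(path: str) -> CohortMetadata:
    """Read cohort metadata from CSV (columns sample_id, class_label and
    optional subject/day/replicate) or an equivalent JSON mapping."""
    meta = CohortMetadata()
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        for sid, rec in data.items():
            meta.add(
                sid,
                rec["class_label"],
                rec.get("subject"),
                rec.get("day"),
                rec.get("replicate"),
            )
        return meta
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns or "class_label" not in df.columns:
        raise ValueError(f"{path}: metadata needs sample_id and class_label columns")
    for _, row in df.iterrows():
        meta.add(
            row["sample_id"],
            row["class_label"],
            row.get("subject"),
            row.get("day"),
            row.get("replicate"),
        )
    return meta


def _newick_node(tree: TemplateTree, node_id: int, parent_height: float | None) -> str:
    node = tree.nodes[node_id]
    if node.is_leaf:
        label = node.sample_ids[0] if node.sample_ids else f"node{node_id}"
    else:
        left = _newick_node(tree, node.children[0], node.height)
        right = _newick_node(tree, node.children[1], node.height)
        label = f"({left},{right})"
    if parent_height is None:
        return label
    branch = parent_height - node.height
    if branch < 0:
        log.warning(
            "height inversion at node %d (child %.4g above parent %.4g); "
            "emitting zero-length branch",
            node_id,
            node.height,
            parent_height,
        )
        branch = 0.0
    return f"{label}:{branch:g}"


def write_tree_newick(tree: TemplateTree, path: str | None = None) -> str:
    """Serialize a template tree to Newick; leaf names are sample ids and
    branch lengths are parent height minus child height."""
    newick = _newick_node(tree, tree.root_id, None) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(newick + "\n")
    return newick


# --- JSON round-trips for cluster/template objects -------------------------


def _summary_to_dict(c: ClusterSummary) -> dict:
    d = {
        "mean": c.mean.tolist(),
        "covariance": c.covariance.tolist(),
        "size": int(c.size),
        "label": c.label,
    }
    if isinstance(c, MetaCluster):
        d["members"] = [[sid, int(idx)] for sid, idx in c.members]
        d["member_sizes"] = [int(s) for s in c.member_sizes]
    return d


def _summary_from_dict(d: dict) -> ClusterSummary:
    if "members" in d:
        return MetaCluster(
            mean=np.array(d["mean"]),
            covariance=np.array(d["covariance"]),
            size=d["size"],
            label=d.get("label", ""),
            members=[(sid, idx) for sid, idx in d["members"]],
            member_sizes=list(d.get("member_sizes", [])),
        )
    return ClusterSummary(
        mean=np.array(d["mean"]),
        covariance=np.array(d["covariance"]),
        size=d["size"],
        label=d.get("label", ""),
    )


def clustered_sample_to_dict(sample: ClusteredSample) -> dict:
    return {
        "sample_id": sample.sample_id,
        "clusters": [_summary_to_dict(c) for c in sample.clusters],
    }


def clustered_sample_from_dict(d: dict) -> ClusteredSample:
    return ClusteredSample(
        sample_id=d["sample_id"],
        clusters=[_summary_from_dict(c) for c in d["clusters"]],
    )


def save_clustered_sample(sample: ClusteredSample, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(clustered_sample_to_dict(sample), fh)


def load_clustered_sample(path: str) -> ClusteredSample:
    with open(path) as fh:
        return clustered_sample_from_dict(json.load(fh))


def save_template(node: TemplateNode, path: str) -> None:
    """Serialize one template (a tree node's meta-cluster list) to JSON."""
    with open(path, "w") as fh:
        json.dump(
            {
                "node_id": node.node_id,
                "height": node.height,
                "sample_ids": node.sample_ids,
                "contents": [_summary_to_dict(c) for c in node.contents],
            },
            fh,
        )


def load_template(path: str) -> TemplateNode:
    with open(path) as fh:
        d = json.load(fh)
    return TemplateNode(
        node_id=d["node_id"],
        contents=[_summary_from_dict(c) for c in d["contents"]],
        height=d["height"],
        sample_ids=list(d["sample_ids"]),
    )
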