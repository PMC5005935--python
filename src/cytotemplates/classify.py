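"""Template-based classification and the piecewise disease score.

Nearest-template classification assigns a sample to the class whose
template it is least dissimilar to. For diseases like AML that perturb
only a subset of cell populations, a dedicated score compares a sample X
against both the disease template T+ and the healthy template T-:
meta-clusters of T+ with no counterpart in T- form the disease-specific
set M+, and each cluster of X earns a large positive score when it matches
an M+ meta-cluster, a small negative score when it matches healthy-like
populations, and a positive penalty lambda when it matches nothing in T-.
The asymmetry makes false negatives (missed disease) less likely than
false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .matching import MatchConfig, mixed_edge_cover, sample_dissimilarity
from .model import ClusteredSample, ConfusionCounts, TemplateNode

__all__ = [
    "nearest_template",
    "disease_specific_metaclusters",
    "score_sample",
    "combine_panel_scores",
    "classification_metrics",
    "empirical_pvalue",
    "ScoreReport",
    "ClusterScore",
]


def nearest_template(
    sample: ClusteredSample,
    templates: Sequence[TemplateNode],
    cfg: MatchConfig | None = None,
    reject_threshold: float | None = None,
) -> tuple[int | None, np.ndarray]:
    """Assign a sample to its least-dissimilar template.

    Returns ``(index, dissimilarities)``; index is ``None`` ("unassigned",
    i.e. a potential new class) when a reject threshold is given and even
    the closest template exceeds it. Exact ties resolve to the smallest
    template index.
    """
    if len(templates) == 0:
        raise ValueError("need at least one template")
    cfg = cfg or MatchConfig()
    d = np.array([sample_dissimilarity(sample, t, cfg) for t in templates])
    best = int(np.argmin(d))
    if reject_threshold is not None and d[best] > reject_threshold:
        return None, d
    return best, d


def disease_specific_metaclusters(
    t_pos: TemplateNode, t_neg: TemplateNode, cfg: MatchConfig | None = None
) -> set[int]:
    """Indices of T+ meta-clusters with no match in T- (the set M+).

    A minimum-cost mixed edge cover is computed on the complete bipartite
    graph between the two templates' meta-cluster lists; M+ is the set of
    T+ meta-clusters left unmatched (disease-specific immunophenotypes).
    """
    if t_pos.k == 0 or t_neg.k == 0:
        raise ValueError("both templates must contain meta-clusters")
    mec = mixed_edge_cover(t_pos, t_neg, cfg)
    return set(mec.unmatched_A)


@dataclass
class ClusterScore:
    """Per-cluster scoring record: matched sets, similarities, f+ and f-."""

    index: int
    size: int
    mec_pos: list[int]
    mec_neg: list[int]
    s_pos: Optional[float]
    s_neg: Optional[float]
    f_pos: float
    f_neg: float


@dataclass
class ScoreReport:
    """Sample-level disease score with its per-cluster breakdown."""

    sample_id: str
    clusters: list[ClusterScore]
    score: float
    predicted_positive: bool
    lam: float
    m_plus: set[int] = field(default_factory=set)


def score_sample(
    sample: ClusteredSample,
    t_pos: TemplateNode,
    t_neg: TemplateNode,
    cfg: MatchConfig | None = None,
    m_plus: set[int] | None = None,
) -> ScoreReport:
    """Score a sample against the disease (T+) and healthy (T-) templates.

    Two independent mixed edge covers register the sample's clusters
    against each template. With s = 2*lambda - d (d the average distance
    to the matched set, bounded by 2*lambda):

    f+(c) =  s        if c matches an M+ meta-cluster of T+,
            -s / k    if c matches only non-specific T+ meta-clusters,
             0        if c is unmatched in T+;
    f-(c) = -s / k    if c matches some T- meta-cluster,
             lambda   if c is unmatched in T-.

    The sample score is the abundance-weighted mean of (f+ + f-)/2; a
    positive score predicts the disease class (exact zero is negative).
    """
    cfg = cfg or MatchConfig()
    if sample.k == 0:
        raise ValueError("sample has no clusters to score")
    if m_plus is None:
        m_plus = disease_specific_metaclusters(t_pos, t_neg, cfg)
    k = sample.k
    lam = cfg.resolve_lambda(sample.clusters[0].dim)
    mec_pos = mixed_edge_cover(sample, t_pos, cfg)
    mec_neg = mixed_edge_cover(sample, t_neg, cfg)

    records: list[ClusterScore] = []
    total_cells = sample.n_cells
    score = 0.0
    for i, c in enumerate(sample.clusters):
        pos_set = mec_pos.matched_B(i)
        neg_set = mec_neg.matched_B(i)
        if pos_set:
            s_pos = 2.0 * lam - mec_pos.average_distance_A(i)
            if set(pos_set) & m_plus:
                f_pos = s_pos
            else:
                f_pos = -s_pos / k
        else:
            s_pos, f_pos = None, 0.0
        if neg_set:
            s_neg = 2.0 * lam - mec_neg.average_distance_A(i)
            f_neg = -s_neg / k
        else:
            s_neg, f_neg = None, lam
        weight = c.size / total_cells
        score += weight * 0.5 * (f_pos + f_neg)
        records.append(
            ClusterScore(
                index=i,
                size=c.size,
                mec_pos=pos_set,
                mec_neg=neg_set,
                s_pos=s_pos,
                s_neg=s_neg,
                f_pos=f_pos,
                f_neg=f_neg,
            )
        )
    return ScoreReport(
        sample_id=sample.sample_id,
        clusters=records,
        score=float(score),
        predicted_positive=score > 0,
        lam=lam,
        m_plus=set(m_plus),
    )


def combine_panel_scores(scores: Sequence[float]) -> float:
    """Average the classification scores of several marker panels."""
    if len(scores) == 0:
        raise ValueError("need at least one panel score")
    return float(np.mean(scores))


def classification_metrics(cc: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall (sensitivity), specificity and F-value.

    A metric whose denominator is zero is reported as ``None``
    (undefined), never as 0.
    """
    precision = cc.TP / (cc.TP + cc.FP) if (cc.TP + cc.FP) > 0 else None
    recall = cc.TP / (cc.TP + cc.FN) if (cc.TP + cc.FN) > 0 else None
    specificity = cc.TN / (cc.FP + cc.TN) if (cc.FP + cc.TN) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f_value = 2.0 * precision * recall / (precision + recall)
    else:
        f_value = None
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f_value": f_value,
    }


def empirical_pvalue(score: float, null_scores: Sequence[float]) -> float:
    """Empirical p-value of a score against a null distribution.

    Add-one rule: p = (1 + #{null >= score}) / (1 + #null), so p is never
    exactly zero. The null scores typically come from a control panel
    carrying no disease-relevant markers.
    """
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("need at least one null score")
    return float((1 + int(np.sum(null >= score))) / (1 + null.size))
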