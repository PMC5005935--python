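"""End-to-end convenience pipelines over synthetic cohorts.

These wire the stages together the way a cohort study would run them:
cluster every sample (consensus k), build class templates from training
samples, detect disease-specific meta-clusters, and score held-out
samples. They are used by the command-line workflow and by the
reproducibility script.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import (
    classification_metrics,
    disease_specific_metaclusters,
    score_sample,
)
from .clustering import fit_kmeans, select_k
from .matching import MatchConfig
from .model import ClusteredSample, ConfusionCounts, EventMatrix, TemplateNode
from .synth import DiseaseCohort, simulate_disease_cohort
from .templates import build_template_tree

__all__ = ["cluster_cohort", "DiseaseExperimentResult", "disease_classification_experiment"]


def cluster_cohort(
    samples: list[EventMatrix],
    k_range=range(2, 7),
    seed: int = 0,
    subsample_cap: int = 2000,
) -> list[ClusteredSample]:
    """Cluster every sample with its own consensus k."""
    out = []
    for em in samples:
        report = select_k(em, k_range, seed=seed, subsample_cap=subsample_cap)
        out.append(fit_kmeans(em, report.consensus_k, seed=seed))
    return out


@dataclass
class DiseaseExperimentResult:
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    m_plus: set[int]
    t_pos: TemplateNode
    t_neg: TemplateNode
    scores: dict[str, float]
    blast_in_m_plus: bool
    cohort: DiseaseCohort


def disease_classification_experiment(
    seed: int = 0,
    n_negative: int = 200,
    n_positive: int = 30,
    n_cells: int = 1000,
    k_range=range(2, 7),
    cfg: MatchConfig | None = None,
) -> DiseaseExperimentResult:
    """Train/test template classification on a synthetic disease cohort.

    Clusters all samples, builds the healthy template T- and disease
    template T+ from the training split (template-tree roots), finds the
    disease-specific meta-cluster set M+, scores every held-out sample,
    and tabulates the confusion counts of the sign rule (score > 0 =>
    disease).
    """
    cfg = cfg or MatchConfig()
    cohort = simulate_disease_cohort(
        seed=seed, n_negative=n_negative, n_positive=n_positive, n_cells=n_cells
    )
    clustered = {
        em.sample_id: cs
        for em, cs in zip(
            cohort.samples, cluster_cohort(cohort.samples, k_range, seed=seed)
        )
    }

    train_neg = [clustered[s] for s in cohort.train_ids
                 if cohort.metadata.class_of(s) == "negative"]
    train_pos = [clustered[s] for s in cohort.train_ids
                 if cohort.metadata.class_of(s) == "positive"]
    t_neg = build_template_tree(train_neg, cfg).root
    t_pos = build_template_tree(train_pos, cfg).root
    m_plus = disease_specific_metaclusters(t_pos, t_neg, cfg)

    # Which meta-clusters of T+ are built from true blast clusters? A
    # meta-cluster counts as blast-like when most of its member clusters
    # are dominated by cells whose ground-truth population is the blast.
    blast_idx = len(cohort.truths[0]) and max(
        int(t.max()) for t in cohort.truths
    )
    truth_by_sid = {em.sample_id: t for em, t in zip(cohort.samples, cohort.truths)}
    blast_metas = set()
    for mi, meta in enumerate(t_pos.contents):
        votes = 0
        for sid, ci in meta.members:
            truth = truth_by_sid[sid]
            mask = clustered[sid].assignments == ci
            if mask.any() and (truth[mask] == blast_idx).mean() > 0.5:
                votes += 1
        if votes > len(meta.members) / 2:
            blast_metas.add(mi)
    blast_in_m_plus = bool(blast_metas) and blast_metas <= m_plus

    tp = tn = fp = fn = 0
    scores: dict[str, float] = {}
    for sid in cohort.test_ids:
        rep = score_sample(clustered[sid], t_pos, t_neg, cfg, m_plus=m_plus)
        scores[sid] = rep.score
        truth_pos = cohort.metadata.class_of(sid) == "positive"
        if rep.predicted_positive and truth_pos:
            tp += 1
        elif rep.predicted_positive:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    return DiseaseExperimentResult(
        counts=counts,
        metrics=classification_metrics(counts),
        m_plus=m_plus,
        t_pos=t_pos,
        t_neg=t_neg,
        scores=scores,
        blast_in_m_plus=blast_in_m_plus,
        cohort=cohort,
    )
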