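import numpy as np
import pytest

from cytotemplates.classify import (
    classification_metrics,
    combine_panel_scores,
    disease_specific_metaclusters,
    empirical_pvalue,
    nearest_template,
    score_sample,
)
from cytotemplates.matching import MatchConfig
from cytotemplates.model import ClusteredSample, ClusterSummary, ConfusionCounts, TemplateNode

from conftest import random_cluster


def _gauss(mu, var=1.0, n=100, p=2):
    return ClusterSummary(np.full(p, float(mu)), var * np.eye(p), n)


def _template(nid, clusters, sample_ids=("t",)):
    return TemplateNode(
        node_id=nid, contents=list(clusters), height=0.0,
        sample_ids=list(sample_ids),
    )


P = 2  # feature dimensionality used throughout; lambda defaults to p


class TestNearestTemplate:
    def test_exact_match_is_assigned_at_zero(self, rng):
        clusters = [random_cluster(rng) for _ in range(2)]
        t1 = _template(0, clusters)
        t2 = _template(1, [random_cluster(rng)])
        s = ClusteredSample(sample_id="x", clusters=clusters)
        idx, d = nearest_template(s, [t1, t2])
        assert idx == 0
        assert d[0] == pytest.approx(0.0, abs=1e-8)

    def test_single_template_always_wins(self, rng):
        t = _template(0, [random_cluster(rng)])
        s = ClusteredSample(sample_id="x", clusters=[random_cluster(rng)])
        idx, _ = nearest_template(s, [t])
        assert idx == 0

    def test_reject_threshold_gives_unassigned(self):
        t = _template(0, [_gauss(0.0)])
        s = ClusteredSample(sample_id="x", clusters=[_gauss(500.0)])
        idx, _ = nearest_template(s, [t], reject_threshold=0.5)
        assert idx is None

    def test_separated_two_class_holdout_fully_correct(self, rng):
        def make(center, sid):
            cs = [
                _gauss(center + rng.normal(0, 0.05), n=100),
                _gauss(center + 6 + rng.normal(0, 0.05), n=100),
            ]
            return ClusteredSample(sample_id=sid, clusters=cs)

        neg_t = _template(0, make(0.0, "t-").clusters)
        pos_t = _template(1, make(60.0, "t+").clusters)
        for i in range(10):
            center = 0.0 if i % 2 == 0 else 60.0
            idx, _ = nearest_template(make(center, f"h{i}"), [neg_t, pos_t])
            assert idx == (0 if center == 0.0 else 1)


class TestDiseaseSpecificMetaclusters:
    def test_identical_templates_have_empty_m_plus(self, rng):
        clusters = [random_cluster(rng) for _ in range(3)]
        assert disease_specific_metaclusters(
            _template(0, clusters), _template(1, clusters)
        ) == set()

    def test_one_extra_far_metacluster_detected(self, rng):
        shared = [_gauss(0.0), _gauss(8.0)]
        extra = _gauss(1000.0)
        m_plus = disease_specific_metaclusters(
            _template(0, shared + [extra]), _template(1, shared)
        )
        assert m_plus == {2}

    def test_disjoint_templates_are_all_specific(self):
        t_pos = _template(0, [_gauss(0.0), _gauss(8.0)])
        t_neg = _template(1, [_gauss(1000.0)])
        assert disease_specific_metaclusters(t_pos, t_neg) == {0, 1}


class TestScoreSample:
    def test_healthy_like_cluster_scores_minus_lambda(self):
        # One cluster matching T- at d=0 and unmatched in T+:
        # f+ = 0, f- = -2*lam/k = -2*lam, f(X) = 0.5*(0 - 2*lam) = -lam.
        lam = float(P)
        healthy = _gauss(0.0)
        t_neg = _template(0, [healthy])
        t_pos = _template(1, [_gauss(1000.0)])
        s = ClusteredSample(sample_id="x", clusters=[healthy])
        rep = score_sample(s, t_pos, t_neg)
        assert rep.score == pytest.approx(-lam, abs=1e-8)
        assert not rep.predicted_positive
        assert rep.clusters[0].f_pos == 0.0
        assert rep.clusters[0].f_neg == pytest.approx(-2 * lam, abs=1e-8)

    def test_disease_like_cluster_scores_1p5_lambda(self):
        # One cluster matching an M+ meta-cluster at d=0, unmatched in T-:
        # f+ = 2*lam, f- = lam, f(X) = 1.5*lam.
        lam = float(P)
        blast = _gauss(0.0)
        t_pos = _template(1, [blast])
        t_neg = _template(0, [_gauss(1000.0)])
        s = ClusteredSample(sample_id="x", clusters=[blast])
        rep = score_sample(s, t_pos, t_neg)
        assert rep.score == pytest.approx(1.5 * lam, abs=1e-8)
        assert rep.predicted_positive

    def test_two_cluster_mixture_hand_evaluation(self):
        # 90% of cells healthy-like (d=0 to T-, unmatched in T+), 10%
        # blast-like (d=0 to M+, unmatched in T-):
        # f(X) = 0.9 * 0.5 * (0 - 2 lam / k) + 0.1 * 0.5 * (2 lam + lam)
        # with k = 2 -> 0.9 * (-lam/2) + 0.1 * 1.5 lam = -0.3 lam.
        lam = float(P)
        healthy, blast = _gauss(0.0), _gauss(500.0)
        t_neg = _template(0, [healthy])
        t_pos = _template(1, [blast])
        s = ClusteredSample(
            sample_id="x",
            clusters=[
                ClusterSummary(healthy.mean, healthy.covariance, 900),
                ClusterSummary(blast.mean, blast.covariance, 100),
            ],
        )
        rep = score_sample(s, t_pos, t_neg)
        assert rep.score == pytest.approx(-0.3 * lam, abs=1e-8)
        assert not rep.predicted_positive

    def test_score_invariant_to_proportional_cell_scaling(self, rng):
        # The abundance weights |c_i| / |X| renormalize exactly, so scaling
        # every cluster's cell count by the same factor leaves f(X)
        # unchanged. Checked under the center-distance method, whose d does
        # not itself depend on cluster sizes (the Mahalanobis pooled
        # covariance does, through its (n-1) weights).
        cfg = MatchConfig(method="euclidean_center", lam=2.0)
        clusters = [random_cluster(rng, n=100), random_cluster(rng, n=300)]
        t_pos = _template(1, [random_cluster(rng)])
        t_neg = _template(0, [random_cluster(rng)])
        s1 = ClusteredSample(sample_id="a", clusters=clusters)
        s2 = ClusteredSample(
            sample_id="b",
            clusters=[
                ClusterSummary(c.mean, c.covariance, 5 * c.size) for c in clusters
            ],
        )
        r1 = score_sample(s1, t_pos, t_neg, cfg)
        r2 = score_sample(s2, t_pos, t_neg, cfg)
        assert r1.score == pytest.approx(r2.score, abs=1e-10)

    def test_similarities_within_mec_bound(self, rng):
        lam = 3.0
        cfg = MatchConfig(lam=lam)
        for _ in range(20):
            s = ClusteredSample(
                sample_id="x",
                clusters=[random_cluster(rng, p=3) for _ in range(3)],
            )
            t_pos = _template(1, [random_cluster(rng, p=3) for _ in range(2)])
            t_neg = _template(0, [random_cluster(rng, p=3) for _ in range(2)])
            rep = score_sample(s, t_pos, t_neg, cfg)
            for c in rep.clusters:
                for s_val in (c.s_pos, c.s_neg):
                    if s_val is not None:
                        assert 0.0 - 1e-9 <= s_val <= 2 * lam + 1e-9


class TestPanelAndMetrics:
    def test_combine_is_plain_mean(self, rng):
        assert combine_panel_scores([-1.0, 1.0]) == 0.0
        assert combine_panel_scores([0.7, 0.7, 0.7]) == pytest.approx(0.7)
        v = rng.normal(size=6)
        assert combine_panel_scores(v) == pytest.approx(np.mean(v))

    def test_training_cohort_worked_example(self):
        # 23 disease and 156 healthy training samples with a single false
        # negative and no false positives.
        m = classification_metrics(ConfusionCounts(TP=22, FN=1, FP=0, TN=156))
        assert m["precision"] == pytest.approx(1.00, abs=0.005)
        assert round(m["recall"], 2) == 0.96
        assert m["specificity"] == pytest.approx(1.00, abs=0.005)
        assert round(m["f_value"], 2) == 0.98

    def test_perfect_counts(self):
        m = classification_metrics(ConfusionCounts(TP=20, FN=0, FP=0, TN=157))
        assert m["precision"] == m["recall"] == m["specificity"] == 1.0
        assert m["f_value"] == 1.0

    def test_undefined_metrics_reported_as_none(self):
        m = classification_metrics(ConfusionCounts(TP=0, FN=0, FP=0, TN=10))
        assert m["recall"] is None
        assert m["precision"] is None
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)


class TestEmpiricalPvalue:
    def test_score_above_all_nulls(self):
        nulls = [i / 100.0 for i in range(99)]  # all below the score
        assert empirical_pvalue(10.0, nulls) == pytest.approx(0.01)

    def test_score_below_all_nulls(self):
        assert empirical_pvalue(-10.0, [0.0, 1.0, 2.0]) == 1.0

    def test_score_equal_to_single_null(self):
        assert empirical_pvalue(1.0, [1.0]) == 1.0

    def test_never_zero(self, rng):
        assert empirical_pvalue(1e9, rng.normal(size=1000).tolist()) > 0.0
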