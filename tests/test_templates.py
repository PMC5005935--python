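import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cytotemplates.clustering import summarize_clusters
from cytotemplates.matching import MatchConfig, mixed_edge_cover
from cytotemplates.model import ClusteredSample, ClusterSummary, EventMatrix
from cytotemplates.synth import simulate_hd_cohort
from cytotemplates.templates import (
    build_template_tree,
    cut_templates,
    insert_sample,
    merge_matched,
    metacluster_participation,
    sample_to_node,
)

from conftest import random_cluster


def _sample(sample_id, clusters):
    return ClusteredSample(sample_id=sample_id, clusters=clusters)


def _gauss(mu, var=1.0, n=100, p=1):
    mu = np.full(p, float(mu))
    return ClusterSummary(mu, var * np.eye(p), n)


def _ml_summary(points):
    """Independent single-Gaussian ML fit on raw cells (the merge oracle)."""
    mu = points.mean(axis=0)
    cov = np.atleast_2d(np.cov(points, rowvar=False, ddof=0))
    return mu, cov


class TestMergeMatched:
    def test_identical_clusters_merge_to_same_parameters(self, rng):
        c = random_cluster(rng)
        a = sample_to_node(_sample("A", [c]), 0)
        b = sample_to_node(_sample("B", [c]), 1)
        mec = mixed_edge_cover(a, b)
        metas = merge_matched(a, b, mec)
        assert len(metas) == 1
        np.testing.assert_allclose(metas[0].mean, c.mean, atol=1e-10)
        np.testing.assert_allclose(metas[0].covariance, c.covariance, atol=1e-8)
        assert metas[0].size == 2 * c.size

    def test_moment_merge_agrees_with_ml_fit_on_pooled_cells(self, rng):
        # Draw raw cells, summarize each half with ML moments, merge, and
        # compare against the ML fit on the pooled raw cells.
        x1 = rng.normal(0.0, 1.0, size=(10, 1))
        x2 = rng.normal(2.0, 1.0, size=(10, 1))
        cs = [
            ClusterSummary(x.mean(axis=0), np.atleast_2d(np.cov(x.T, ddof=0)), 10)
            for x in (x1, x2)
        ]
        a = sample_to_node(_sample("A", [cs[0]]), 0)
        b = sample_to_node(_sample("B", [cs[1]]), 1)
        mec = mixed_edge_cover(a, b, MatchConfig(lam=100.0))  # force the match
        assert mec.edges == {(0, 0)}
        meta = merge_matched(a, b, mec)[0]
        mu_ml, cov_ml = _ml_summary(np.vstack([x1, x2]))
        np.testing.assert_allclose(meta.mean, mu_ml, atol=1e-10)
        np.testing.assert_allclose(meta.covariance, cov_ml, atol=1e-10)
        assert meta.size == 20

    def test_exact_one_dim_means_and_variances(self):
        # clusters (mu=0, s2=1, n=10) and (mu=2, s2=1, n=10): pooled ML
        # Gaussian has mu=1, s2 = 1 + 1 = 2 (within + between variance).
        a = sample_to_node(_sample("A", [_gauss(0.0, 1.0, 10)]), 0)
        b = sample_to_node(_sample("B", [_gauss(2.0, 1.0, 10)]), 1)
        mec = mixed_edge_cover(a, b, MatchConfig(lam=100.0))
        meta = merge_matched(a, b, mec)[0]
        assert meta.mean[0] == pytest.approx(1.0)
        assert meta.covariance[0, 0] == pytest.approx(2.0)
        assert meta.size == 20

    def test_unmatched_cluster_becomes_singleton_metacluster(self, rng):
        near = _gauss(0.0)
        far = _gauss(1000.0)
        a = sample_to_node(_sample("A", [near, far]), 0)
        b = sample_to_node(_sample("B", [near]), 1)
        mec = mixed_edge_cover(a, b)
        metas = merge_matched(a, b, mec)
        assert len(metas) == 2
        singleton = [m for m in metas if m.members == [("A", 1)]][0]
        np.testing.assert_allclose(singleton.mean, far.mean)
        np.testing.assert_allclose(singleton.covariance, far.covariance, atol=1e-10)

    def test_chain_components_collapse(self):
        # a1-b1 and a2-b1 share b1: one meta-cluster of three members.
        a = sample_to_node(_sample("A", [_gauss(0.0), _gauss(0.5)]), 0)
        b = sample_to_node(_sample("B", [_gauss(0.25)]), 1)
        mec = mixed_edge_cover(a, b, MatchConfig(lam=100.0))
        if len(mec.edges) == 2:  # both a-clusters attached to b1
            metas = merge_matched(a, b, mec)
            assert len(metas) == 1
            assert len(metas[0].members) == 3


class TestBuildTemplateTree:
    def test_single_sample_tree(self, rng):
        tree = build_template_tree([_sample("S1", [random_cluster(rng)])])
        assert tree.root.is_leaf
        assert tree.leaf_sample_ids() == ["S1"]

    def test_two_identical_samples(self, rng):
        clusters = [random_cluster(rng) for _ in range(3)]
        tree = build_template_tree([_sample("A", clusters), _sample("B", clusters)])
        assert tree.root.height == pytest.approx(0.0, abs=1e-8)
        assert tree.root.k == 3
        for meta in tree.root.contents:
            assert meta.size == 2 * meta.member_sizes[0]

    def test_two_class_cohort_pairs_within_class_first(self, rng):
        lo = [_gauss(0.0, n=50, p=2), _gauss(5.0, n=50, p=2)]
        hi = [_gauss(100.0, n=50, p=2), _gauss(105.0, n=50, p=2)]
        jitter = lambda cs: [
            ClusterSummary(c.mean + rng.normal(0, 0.05, 2), c.covariance, c.size)
            for c in cs
        ]
        samples = [
            _sample("lo1", jitter(lo)), _sample("hi1", jitter(hi)),
            _sample("lo2", jitter(lo)), _sample("hi2", jitter(hi)),
        ]
        tree = build_template_tree(samples)
        root = tree.root
        left = set(tree.leaf_sample_ids(root.children[0]))
        assert left in ({"lo1", "lo2"}, {"hi1", "hi2"})
        for child in root.children:
            assert tree.nodes[child].height < root.height

    def test_total_cell_count_conserved_to_root(self, rng):
        samples = [
            _sample(f"S{i}", [random_cluster(rng, n=int(rng.integers(10, 100)))
                              for _ in range(int(rng.integers(1, 4)))])
            for i in range(5)
        ]
        tree = build_template_tree(samples)
        total = sum(s.n_cells for s in samples)
        assert sum(m.size for m in tree.root.contents) == total

    def test_rebuild_is_deterministic(self, rng):
        samples = [
            _sample(f"S{i}", [random_cluster(rng) for _ in range(2)])
            for i in range(6)
        ]
        t1 = build_template_tree(samples)
        t2 = build_template_tree(samples)
        assert t1.leaf_sample_ids() == t2.leaf_sample_ids()
        assert t1.root.height == t2.root.height


@pytest.fixture(scope="module")
def hd_small():
    cohort = simulate_hd_cohort(
        seed=11, days_per_subject=1, n_replicates=3, n_cells=400
    )
    samples = [
        summarize_clusters(em, truth)
        for em, truth in zip(cohort.samples, cohort.truths)
    ]
    return cohort, build_template_tree(samples)


class TestCutTemplates:
    def test_by_height_above_root_returns_root(self, hd_small):
        _, tree = hd_small
        cut = cut_templates(tree, "by_height", height=tree.root.height + 1)
        assert len(cut) == 1 and cut[0].node_id == tree.root_id

    def test_by_gap_recovers_subjects(self, hd_small):
        cohort, tree = hd_small
        cut = cut_templates(tree, "by_gap")
        assert len(cut) == 5
        pred = {}
        for ti, node in enumerate(cut):
            for sid in node.sample_ids:
                pred[sid] = ti
        sids = [em.sample_id for em in cohort.samples]
        truth = [cohort.metadata.subject_of(s) for s in sids]
        assert adjusted_rand_score(truth, [pred[s] for s in sids]) == 1.0

    def test_by_labels_on_subject(self, hd_small):
        cohort, tree = hd_small
        cut = cut_templates(
            tree, "by_labels", metadata=cohort.metadata, label="subject"
        )
        assert len(cut) == 5
        for node in cut:
            subjects = {cohort.metadata.subject_of(s) for s in node.sample_ids}
            assert len(subjects) == 1

    def test_single_class_by_labels_gives_root(self, rng):
        from cytotemplates.model import CohortMetadata

        samples = [_sample(f"S{i}", [random_cluster(rng)]) for i in range(3)]
        meta = CohortMetadata()
        for i in range(3):
            meta.add(f"S{i}", class_label="healthy")
        tree = build_template_tree(samples)
        cut = cut_templates(tree, "by_labels", metadata=meta)
        assert len(cut) == 1 and cut[0].node_id == tree.root_id


class TestInsertSample:
    def test_identical_sample_merges_at_zero(self, rng):
        clusters = [random_cluster(rng) for _ in range(2)]
        tree = build_template_tree([_sample("A", clusters), _sample("B", clusters)])
        before = [m.size for m in tree.root.contents]
        updated, idx = insert_sample(tree, _sample("C", clusters), threshold=1.0)
        assert idx == 0
        after = sorted(m.size for m in updated[0].contents)
        assert after == sorted(int(1.5 * s) for s in before)
        assert "C" in updated[0].sample_ids

    def test_distant_sample_starts_new_class(self, rng):
        base = [_gauss(0.0, p=2)]
        far = [_gauss(1000.0, p=2)]
        tree = build_template_tree([_sample("A", base), _sample("B", base)])
        updated, idx = insert_sample(tree, _sample("X", far), threshold=0.5)
        assert idx is None
        assert len(updated) == 2
        assert updated[1].sample_ids == ["X"]

    def test_incremental_matches_batch_on_separated_classes(self, rng):
        def cls_samples(center, prefix):
            out = []
            for i in range(4):
                cs = [
                    _gauss(center + rng.normal(0, 0.05), n=100, p=2),
                    _gauss(center + 5 + rng.normal(0, 0.05), n=100, p=2),
                ]
                out.append(_sample(f"{prefix}{i}", cs))
            return out

        samples = cls_samples(0.0, "neg") + cls_samples(100.0, "pos")
        tree = build_template_tree(samples)
        batch = cut_templates(tree, "by_gap")
        assert len(batch) == 2

        templates: list = []
        for s in samples:
            templates, _ = insert_sample(templates, s, threshold=5.0)
        assert len(templates) == 2
        batch_counts = sorted(t.k for t in batch)
        incr_counts = sorted(t.k for t in templates)
        assert batch_counts == incr_counts


class TestParticipation:
    def test_full_participation_is_one(self, rng):
        clusters = [random_cluster(rng)]
        tree = build_template_tree(
            [_sample(f"S{i}", clusters) for i in range(4)]
        )
        np.testing.assert_allclose(metacluster_participation(tree.root), 1.0)

    def test_planted_partial_population(self, rng):
        # A population present in ~60% of samples should show up with
        # participation near 0.6 in the cohort template.
        common = _gauss(0.0, p=2)
        sometimes = _gauss(50.0, p=2)
        n = 50
        present = rng.random(n) < 0.6
        samples = [
            _sample(f"S{i}", [common, sometimes] if present[i] else [common])
            for i in range(n)
        ]
        tree = build_template_tree(samples)
        part = sorted(metacluster_participation(tree.root))
        assert len(part) == 2
        assert part[1] == pytest.approx(1.0)
        assert abs(part[0] - present.mean()) < 1e-9
        assert abs(part[0] - 0.6) < 0.1
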