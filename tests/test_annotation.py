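"""Embedding clusters, per-node prediction and label stabilization."""

import numpy as np
import pytest

import census as cs
from census.annotation import StabilizationResult
from tests.conftest import dummy_embedding


def _blobs(n_per=250, dist=12.0, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], sigma, size=(n_per, 2))
    b = rng.normal([dist, dist], sigma, size=(n_per, 2))
    coords = np.vstack([a, b])
    labels = np.array(["A"] * n_per + ["B"] * n_per, dtype=object)
    return coords, labels


class TestClusterEmbedding:
    def test_identical_seed_identical_clusters(self):
        coords, _ = _blobs(n_per=100)
        cfg = cs.RunConfig(seed=3)
        c1 = cs.cluster_embedding(coords, cfg, n_types_hint=2)
        c2 = cs.cluster_embedding(coords, cfg, n_types_hint=2)
        assert np.array_equal(c1, c2)

    def test_separated_blobs_do_not_mix(self):
        coords, labels = _blobs(n_per=150)
        clusters = cs.cluster_embedding(coords, cs.RunConfig(seed=3), n_types_hint=2)
        assert len(np.unique(clusters)) >= 2
        for c in np.unique(clusters):
            frac = np.bincount(labels[clusters == c] == "B", minlength=2)
            contamination = frac.min() / frac.sum()
            assert contamination <= 0.05

    def test_fine_granularity_targets_ten_per_type(self, split, model):
        _, test = split
        ec = cs.embed_and_cluster(
            test.matrix, cs.RunConfig(seed=11), n_types_hint=model.hierarchy.n_leaves
        )
        assert len(np.unique(ec.fine_cluster)) >= model.hierarchy.n_leaves


class TestStabilizeLabels:
    def test_uniform_labels_are_a_fixed_point(self):
        coords, _ = _blobs(n_per=50)
        ec = cs.EmbeddingClusters(coords, np.repeat(np.arange(10), 10))
        labels = np.array(["A"] * 100, dtype=object)
        res = cs.stabilize_labels(ec, labels)
        assert res.converged and res.n_iter == 1
        assert np.array_equal(res.labels, labels)

    def test_single_mislabeled_cell_in_cluster_corrected(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(0, 1, size=(50, 2))
        ec = cs.EmbeddingClusters(coords, np.zeros(50, dtype=int))
        labels = np.array(["A"] * 50, dtype=object)
        labels[7] = "B"
        res = cs.stabilize_labels(ec, labels)
        assert (res.labels == "A").all()

    def test_never_invents_labels(self):
        coords, labels = _blobs(n_per=80)
        clusters = cs.cluster_embedding(coords, cs.RunConfig(seed=0), n_types_hint=2)
        ec = cs.EmbeddingClusters(coords, clusters)
        res = cs.stabilize_labels(ec, labels)
        assert set(res.labels) <= set(labels)

    def test_noisy_blobs_recovered_exactly_and_idempotent(self):
        coords, truth = _blobs(n_per=250, seed=4)
        clusters = cs.cluster_embedding(coords, cs.RunConfig(seed=4), n_types_hint=2)
        ec = cs.EmbeddingClusters(coords, clusters)
        rng = np.random.default_rng(5)
        noisy = truth.copy()
        flip = rng.random(len(noisy)) < 0.05
        noisy[flip] = np.where(truth[flip] == "A", "B", "A")
        res = cs.stabilize_labels(ec, noisy)
        assert np.array_equal(res.labels, truth)
        again = cs.stabilize_labels(ec, res.labels)
        assert np.array_equal(again.labels, res.labels)

    def test_length_mismatch_rejected(self):
        ec = cs.EmbeddingClusters(np.zeros((3, 2)), np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match="one label"):
            cs.stabilize_labels(ec, ["A"])


class TestPredictNode:
    def test_training_cells_recovered_on_separable_fixture(self, tiny_ref, tiny_model):
        ref, _, _ = tiny_ref
        h = tiny_model.hierarchy
        nm = tiny_model.node_models[h.root]
        child, prob, _ = nm.predict(ref.matrix)
        sides = {c: set(h.leaves_under(c)) for c in nm.child_labels}
        truth = np.array(
            [nm.child_labels[1] if lab in sides[nm.child_labels[1]] else nm.child_labels[0]
             for lab in ref.labels]
        )
        assert (child == truth).mean() >= 0.99
        assert ((prob >= 0.5) & (prob <= 1.0)).all()

    def test_probability_tie_breaks_to_first_child(self):
        class HalfBooster:
            def predict_proba(self, X):
                return np.full((len(X), 2), 0.5)

        nm = cs.NodeModel(
            node_id=1, child_labels=(2, 3), marker_genes=["g"],
            booster=HalfBooster(), training_auc=1.0,
        )
        cm = cs.CountMatrix(np.array([[1.0]]), ["g"], ["c0"])
        child, prob, _ = nm.predict(cm)
        assert child[0] == 2 and prob[0] == 0.5

    def test_all_missing_cell_gets_booster_base_response(self, tiny_model):
        nm = tiny_model.node_models[tiny_model.hierarchy.root]
        k = len(nm.marker_genes)
        zero_cell = cs.CountMatrix(np.zeros((1, k)), nm.marker_genes, ["c0"])
        _, _, p2 = nm.predict(zero_cell)
        base = nm.booster.predict_proba(np.full((1, k), np.nan))[0, 1]
        assert p2[0] == pytest.approx(base)

    def test_missing_query_genes_treated_as_missing(self, tiny_model):
        nm = tiny_model.node_models[tiny_model.hierarchy.root]
        # a query containing none of the marker genes behaves as all-missing
        cm = cs.CountMatrix(np.ones((1, 2)), ["absent1", "absent2"], ["c0"])
        _, _, p2 = nm.predict(cm)
        base = nm.booster.predict_proba(
            np.full((1, len(nm.marker_genes)), np.nan)
        )[0, 1]
        assert p2[0] == pytest.approx(base)


class TestAnnotate:
    def test_history_paths_are_valid_lineages(self, model, holdout_result):
        h = model.hierarchy
        for label, hist in zip(
            holdout_result.terminal_labels, holdout_result.history
        ):
            nodes = [n for n, _, _ in hist] + [hist[-1][1]]
            assert nodes == h.lineage(label)
            assert all(0 <= p <= 1 for _, _, p in hist)

    def test_children_partition_parents_at_every_depth(self, model, holdout_result):
        h = model.hierarchy
        asg = holdout_result.node_assignments
        for node in h.internal_nodes:
            if node not in asg:
                continue
            parent_set = set(asg[node])
            kids = [set(asg.get(c, set())) for c in h.children[node]]
            assert kids[0] | kids[1] == parent_set
            assert not (kids[0] & kids[1])

    def test_resubstitution_recovers_training_labels(self, model, split):
        train, _ = split
        res = cs.annotate(model, train.matrix, cs.RunConfig(seed=11))
        assert cs.macro_f1(train.labels, res.terminal_labels) >= 0.99

    def test_empty_gene_intersection_rejected(self, model):
        query = cs.CountMatrix(np.ones((3, 2)), ["foo", "bar"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="gene intersection"):
            cs.annotate(model, query)

    def test_stabilization_disabled_still_produces_valid_paths(self, tiny_model, tiny_ref):
        ref, _, _ = tiny_ref
        cfg = cs.RunConfig(seed=0, stabilize=False)
        res = cs.annotate(
            tiny_model, ref.matrix, cfg,
            embedding=dummy_embedding(ref.matrix.n_cells),
        )
        h = tiny_model.hierarchy
        assert set(res.terminal_labels) <= set(h.labels)
        assert cs.accuracy(ref.labels, res.terminal_labels) >= 0.95
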