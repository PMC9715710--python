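import numpy as np
import pytest
from scipy.special import comb

from otvae.metrics import (
    batch_entropy,
    compute_report,
    foscttm,
    knn_transfer_scores,
    silhouette_scaled,
)


def ari_pair_counting(true, pred):
    """Closed-form pair-counting ARI evaluated from the contingency table."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    cats_t, cats_p = np.unique(true), np.unique(pred)
    n = len(true)
    table = np.array([[(np.logical_and(true == t, pred == p)).sum()
                       for p in cats_p] for t in cats_t])
    sum_comb = sum(comb(x, 2) for x in table.ravel())
    a = sum(comb(x, 2) for x in table.sum(1))
    b = sum(comb(x, 2) for x in table.sum(0))
    expected = a * b / comb(n, 2)
    max_index = (a + b) / 2
    return (sum_comb - expected) / (max_index - expected)


def embed_for_confusion():
    """Embeddings forcing a 1-NN classifier into confusion [[3,1],[1,3]]."""
    ref = np.array([[0.0], [10.0]])
    ref_labels = np.array(["A", "B"])
    pred_wanted = ["A", "A", "A", "B", "A", "B", "B", "B"]
    true = np.array(["A", "A", "A", "A", "B", "B", "B", "B"])
    query = np.array([[0.0] if p == "A" else [10.0] for p in pred_wanted])
    return ref, ref_labels, query, true, np.array(pred_wanted)


class TestKnnTransfer:
    def test_perfect_prediction(self):
        emb = np.array([[0.0], [5.0], [10.0], [0.1], [5.1], [10.1]])
        labels = np.array(["a", "b", "c", "a", "b", "c"])
        ari, nmi, f1 = knn_transfer_scores(emb[:3], labels[:3], emb[3:], labels[3:],
                                           k_neighbors=1)
        assert ari == nmi == f1 == 1.0

    def test_single_class_nmi_is_zero(self):
        emb = np.zeros((4, 2))
        labels = np.array(["a"] * 4)
        _, nmi, _ = knn_transfer_scores(emb, labels, emb, labels, k_neighbors=1)
        assert nmi == 0.0

    def test_confusion_toy_matches_pair_counting_and_macro_f1(self):
        ref, ref_labels, query, true, pred = embed_for_confusion()
        ari, nmi, f1 = knn_transfer_scores(ref, ref_labels, query, true,
                                           k_neighbors=1)
        # per-class P = R = 3/4, so per-class and macro F1 are 0.75
        np.testing.assert_allclose(f1, 0.75)
        np.testing.assert_allclose(ari, ari_pair_counting(true, pred), atol=1e-12)

    def test_disjoint_label_sets_warn(self):
        emb = np.array([[0.0], [1.0]])
        with pytest.warns(UserWarning, match="disjoint"):
            knn_transfer_scores(emb, np.array(["a", "a"]), emb,
                                np.array(["b", "b"]), k_neighbors=1)

    def test_shared_permutation_invariance(self, rng):
        ref = rng.normal(size=(30, 3))
        query = rng.normal(size=(20, 3))
        rl = rng.choice(["a", "b", "c"], 30)
        ql = rng.choice(["a", "b", "c"], 20)
        base = knn_transfer_scores(ref, rl, query, ql)
        perm = rng.permutation(20)
        again = knn_transfer_scores(ref, rl, query[perm], ql[perm])
        np.testing.assert_allclose(base, again, atol=1e-12)


class TestSilhouette:
    def test_well_separated_limit(self, rng):
        a = rng.normal(scale=0.01, size=(10, 2))
        b = rng.normal(scale=0.01, size=(10, 2)) + 1000.0
        emb = np.vstack([a, b])
        labels = ["a"] * 10 + ["b"] * 10
        assert silhouette_scaled(emb, labels) > 0.99

    def test_identical_points_convention(self):
        emb = np.zeros((6, 2))
        labels = ["a", "a", "a", "b", "b", "b"]
        assert silhouette_scaled(emb, labels) == 0.5

    def test_six_point_hand_oracle(self):
        emb = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = np.array(["u", "u", "u", "v", "v", "v"])
        sil = []
        for i in range(6):
            d = np.abs(emb[:, 0] - emb[i, 0])
            a = d[labels == labels[i]].sum() / 2  # mean over the 2 others
            b = d[labels != labels[i]].mean()
            sil.append((b - a) / max(a, b))
        expect = (np.mean(sil) + 1) / 2
        np.testing.assert_allclose(silhouette_scaled(emb, labels), expect, atol=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_scaled(np.zeros((4, 2)), ["a"] * 4)

    def test_rotation_invariance(self, rng):
        emb = rng.normal(size=(30, 3))
        labels = rng.choice(["a", "b"], 30)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        np.testing.assert_allclose(silhouette_scaled(emb, labels),
                                   silhouette_scaled(emb @ Q, labels), atol=1e-9)


class TestBatchEntropy:
    def test_perfect_mixing_scores_one(self):
        # co-located batch pairs: every region is a 50/50 mix
        base = np.repeat(np.arange(30.0)[:, None], 2, axis=0)
        batches = np.tile(["b1", "b2"], 30)
        val = batch_entropy(base, batches, n_probes=20, k_neighbors=10, rng=0)
        np.testing.assert_allclose(val, 1.0, atol=1e-9)

    def test_pure_regions_score_zero(self):
        emb = np.vstack([np.random.default_rng(0).normal(size=(30, 2)),
                         np.random.default_rng(1).normal(size=(30, 2)) + 1000])
        batches = np.array(["b1"] * 30 + ["b2"] * 30)
        val = batch_entropy(emb, batches, n_probes=20, k_neighbors=10, rng=0)
        np.testing.assert_allclose(val, 0.0, atol=1e-12)

    def test_three_batch_loop_oracle(self, rng):
        emb = rng.normal(size=(60, 2))
        batches = rng.choice(["a", "b", "c"], 60)
        k = 15
        got = batch_entropy(emb, batches, n_probes=60, k_neighbors=k, rng=123)
        # direct recomputation over every cell (probes = all cells)
        from sklearn.neighbors import NearestNeighbors

        P = np.array([(batches == b).mean() for b in ("a", "b", "c")])
        _, idx = NearestNeighbors(n_neighbors=k).fit(emb).kneighbors(emb)
        vals = []
        for neigh in idx:
            p = np.array([(batches[neigh] == b).mean() for b in ("a", "b", "c")])
            w = (p / P) / (p / P).sum()
            nz = w[w > 0]
            vals.append(-np.sum(nz * np.log(nz)) / np.log(3))
        np.testing.assert_allclose(got, np.mean(vals), atol=1e-12)

    def test_mask_restricts_cells(self):
        emb = np.vstack([np.zeros((20, 1)), np.ones((20, 1)) * 1000])
        batches = np.array(["b1", "b2"] * 20)
        mask = np.array([True] * 20 + [False] * 20)
        val = batch_entropy(emb, batches, mask, n_probes=10, k_neighbors=10, rng=0)
        np.testing.assert_allclose(val, 1.0, atol=1e-9)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            batch_entropy(np.zeros((5, 1)), ["a", "b"] * 2 + ["a"], k_neighbors=50)

    def test_seed_reproducible(self, rng):
        emb = rng.normal(size=(100, 2))
        batches = rng.choice(["a", "b"], 100)
        v1 = batch_entropy(emb, batches, n_probes=30, k_neighbors=10, rng=7)
        v2 = batch_entropy(emb, batches, n_probes=30, k_neighbors=10, rng=7)
        assert v1 == v2


class TestFoscttm:
    def test_identical_embeddings_zero(self, rng):
        z = rng.normal(size=(50, 4))
        assert foscttm(z, z) == 0.0

    def test_reversed_grid_hand_count(self):
        zx = np.arange(4.0)[:, None]
        zy = zx[::-1].copy()
        # full 4x4 distance table gives s = t = (3,1,1,3); average = 0.5
        np.testing.assert_allclose(foscttm(zx, zy), 0.5, atol=1e-12)

    def test_null_expectation_half(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            vals.append(foscttm(r.normal(size=(200, 5)), r.normal(size=(200, 5))))
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_unequal_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            foscttm(rng.normal(size=(4, 2)), rng.normal(size=(5, 2)))

    def test_shared_isometry_invariance(self, rng):
        zx, zy = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3)
        np.testing.assert_allclose(foscttm(zx, zy),
                                   foscttm(zx @ Q + shift, zy @ Q + shift),
                                   atol=1e-12)


def test_compute_report_end_to_end(rng):
    ref = np.vstack([rng.normal(size=(40, 3)), rng.normal(size=(40, 3)) + 8])
    query = ref + rng.normal(scale=0.1, size=ref.shape)
    labels = np.array(["a"] * 40 + ["b"] * 40)
    rep = compute_report(ref, query, labels, labels, paired=True,
                         batch_entropy_kwargs=dict(k_neighbors=20, n_probes=40))
    assert rep.ari == 1.0
    assert rep.foscttm is not None and rep.foscttm < 0.05
    assert 0 <= rep.silhouette_scaled <= 1
    assert rep.batch_entropy is not None
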