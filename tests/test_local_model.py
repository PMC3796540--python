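import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqvote import (
    ClassPrototype,
    LocalClassifierBank,
    PointGaussian,
    SequencePattern,
    SyntheticSpec,
    adaptive_kmeans_prototypes,
    euclidean_cost,
    fit_class_prototype,
    generate_synthetic_pair_dataset,
    local_accuracies,
    local_accuracy,
    local_label,
    mahalanobis_cost,
    preselect_prototype,
)
from seqvote.local_model import bank_from_dict, bank_to_dict

from conftest import euclidean_bank_1d


class TestCosts:
    def test_euclidean_identity_and_345(self):
        assert euclidean_cost([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert euclidean_cost([3.0, 4.0], [0.0, 0.0]) == 5.0
        assert euclidean_cost([0.3], [1.0]) == pytest.approx(0.7)

    def test_euclidean_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_cost([1.0], [1.0, 2.0])

    def test_mahalanobis_examples(self):
        g = PointGaussian(np.zeros(2), np.diag([4.0, 1.0]))
        assert mahalanobis_cost(np.array([2.0, 0.0]), g) == pytest.approx(1.0)
        assert mahalanobis_cost(np.zeros(2), g) == 0.0

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_identity_covariance_reduces_to_euclidean(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 5))
        x, m = rng.standard_normal(d), rng.standard_normal(d)
        g = PointGaussian(m, np.eye(d))
        assert mahalanobis_cost(x, g) == pytest.approx(euclidean_cost(x, m))

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(ValueError):
            PointGaussian(np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestFitPrototype:
    def test_single_sample_mean_and_eps_identity(self):
        s = SequencePattern("a", "A", np.array([[1.0, 2.0], [3.0, 4.0]]))
        p = fit_class_prototype([s], eps=0.5)
        np.testing.assert_allclose(p.means, s.points)
        np.testing.assert_allclose(p.covariances, 0.5 * np.eye(2)[None].repeat(2, 0))

    def test_symmetric_samples_mean(self):
        m = np.array([[1.0, 1.0]])
        a = SequencePattern("a", "A", m + [[0.5, -0.25]])
        b = SequencePattern("b", "A", m - [[0.5, -0.25]])
        p = fit_class_prototype([a, b])
        np.testing.assert_allclose(p.means, m)

    def test_hand_computed_covariance(self):
        # samples at t=0: (0,0), (1,0), (0,1); mean (1/3, 1/3)
        # sample covariance (ddof=1): [[1/3, -1/6], [-1/6, 1/3]]
        pts = [np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])]
        samples = [SequencePattern(str(i), "A", p) for i, p in enumerate(pts)]
        p = fit_class_prototype(samples, eps=0.0)
        np.testing.assert_allclose(p.means[0], [1 / 3, 1 / 3])
        np.testing.assert_allclose(
            p.covariances[0], [[1 / 3, -1 / 6], [-1 / 6, 1 / 3]], atol=1e-12
        )

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            fit_class_prototype([])


class TestLocalLabel:
    def test_zero_cost_wins(self, three_point_bank):
        label, (c0, c1) = local_label(three_point_bank, 0, np.array([0.0]))
        assert label == 0 and c0 == 0.0 and c1 == 1.0

    def test_tie_goes_to_zero(self, three_point_bank):
        label, costs = local_label(three_point_bank, 1, np.array([0.5]))
        assert label == 0
        assert costs[0] == pytest.approx(costs[1])

    def test_closer_to_one_wins(self):
        bank = euclidean_bank_1d([0.0], [1.0])
        # 2-d analogue of comparing 0.9*sqrt(2) vs 0.1*sqrt(2) collapses to 1-d
        label, _ = local_label(bank, 0, np.array([0.9]))
        assert label == 1


class TestLocalAccuracy:
    def test_perfect_and_counting(self, three_point_bank):
        pats = [
            SequencePattern("a", "0", np.full((3, 1), 0.1)),
            SequencePattern("b", "0", np.full((3, 1), 0.2)),
            SequencePattern("c", "1", np.full((3, 1), 0.9)),
            SequencePattern("d", "1", np.array([[0.8], [0.8], [0.3]])),
        ]
        sides = [0, 0, 1, 1]
        accs = local_accuracies(three_point_bank, pats, sides)
        np.testing.assert_allclose(accs, [1.0, 1.0, 0.75])
        assert local_accuracy(three_point_bank, 2, pats, sides) == 0.75

    def test_order_invariance(self, three_point_bank):
        rng = np.random.default_rng(3)
        pats = [SequencePattern(str(i), None, rng.random((3, 1))) for i in range(8)]
        sides = list(rng.integers(0, 2, 8))
        a = local_accuracies(three_point_bank, pats, sides)
        order = rng.permutation(8)
        b = local_accuracies(three_point_bank, [pats[i] for i in order],
                             [sides[i] for i in order])
        np.testing.assert_allclose(a, b)

    def test_chance_level_on_identical_distributions(self):
        # both classes drawn from the same distribution: accuracy ~ 0.5
        spec = SyntheticSpec(n_points=4, dim=2, noise_scale=0.2,
                             confusable_segment=(0, 4), n_train=400,
                             n_test=1, seed=2)
        train, _ = generate_synthetic_pair_dataset(spec)
        protos = {c: fit_class_prototype([s for s in train if s.class_id == c], c)
                  for c in ("0", "1")}
        bank = LocalClassifierBank(protos["0"], protos["1"])
        sides = [0 if s.class_id == "0" else 1 for s in train]
        accs = local_accuracies(bank, train, sides)
        assert np.all(np.abs(accs - 0.5) < 3 * np.sqrt(0.25 / len(train)) + 0.05)

    def test_empty_sample_set_rejected(self, three_point_bank):
        with pytest.raises(ValueError):
            local_accuracies(three_point_bank, [], [])


def _cluster_samples(center, n, rng, scale=0.05, T=4, cls="A"):
    return [SequencePattern(f"{cls}{center[0]}-{i}", cls,
                            np.asarray(center) + scale * rng.standard_normal((T, 2)))
            for i in range(n)]


class TestAdaptiveKMeans:
    def test_infinite_threshold_single_prototype(self):
        rng = np.random.default_rng(0)
        classes = {"A": _cluster_samples([0.0, 0.0], 5, rng),
                   "B": _cluster_samples([5.0, 5.0], 5, rng, cls="B")}
        out = adaptive_kmeans_prototypes(classes, cost_threshold=np.inf, seed=0)
        assert [len(v) for v in out.values()] == [1, 1]

    def test_two_separated_groups_get_two_clusters(self):
        rng = np.random.default_rng(1)
        # class A: two identical-shape groups 10 apart -> one-cluster cost ~ 100,
        # two-cluster cost ~ noise; a threshold in between forces k=2 for A only
        a = _cluster_samples([0.0, 0.0], 6, rng) + _cluster_samples([10.0, 10.0], 6, rng)
        b = _cluster_samples([5.0, 5.0], 6, rng, cls="B")
        out = adaptive_kmeans_prototypes({"A": a, "B": b}, cost_threshold=1.0, seed=0)
        assert len(out["A"]) == 2
        assert len(out["B"]) == 1
        # cluster centers recover the two groups
        centers = sorted(float(p.means.mean()) for p in out["A"])
        assert centers[0] == pytest.approx(0.0, abs=0.2)
        assert centers[1] == pytest.approx(10.0, abs=0.2)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        classes = {"A": _cluster_samples([0, 0], 8, rng) + _cluster_samples([8, 8], 8, rng)}
        a = adaptive_kmeans_prototypes(classes, cost_threshold=1.0, seed=42)
        b = adaptive_kmeans_prototypes(classes, cost_threshold=1.0, seed=42)
        for pa, pb in zip(a["A"], b["A"]):
            np.testing.assert_array_equal(pa.means, pb.means)

    def test_cost_nonincreasing_in_k(self):
        rng = np.random.default_rng(3)
        X = np.stack([s.points.ravel() for s in
                      _cluster_samples([0, 0], 10, rng, scale=1.0)])
        from seqvote.local_model import _class_cost
        costs = [_class_cost(X, k, seed=0)[0] for k in (1, 2, 3)]
        assert costs[0] >= costs[1] >= costs[2]

    def test_k_capped_at_sample_count_warns(self):
        rng = np.random.default_rng(4)
        # an unattainable threshold of exactly 0: even one cluster per sample
        # leaves cost 0, which is not strictly below it
        classes = {"A": _cluster_samples([0, 0], 2, rng, scale=3.0)}
        with pytest.warns(UserWarning, match="exceed sample count"):
            out = adaptive_kmeans_prototypes(classes, cost_threshold=0.0, seed=0)
        assert len(out["A"]) == 2


class TestPreselect:
    def test_single_prototype(self, three_point_bank):
        p = three_point_bank.prototype_0
        pat = SequencePattern("x", None, np.full((3, 1), 0.4))
        assert preselect_prototype(pat, [p]) is p

    def test_exact_mean_sequence_wins(self):
        rng = np.random.default_rng(5)
        protos = [ClassPrototype("A", j, rng.random((3, 2)),
                                 np.broadcast_to(np.eye(2), (3, 2, 2)).copy())
                  for j in range(3)]
        pat = SequencePattern("x", None, protos[2].means.copy())
        assert preselect_prototype(pat, protos).cluster_id == 2

    def test_hand_computed_sums(self):
        eye = np.broadcast_to(np.eye(1), (2, 1, 1)).copy()
        p0 = ClassPrototype("A", 0, np.array([[0.0], [0.0]]), eye)
        p1 = ClassPrototype("A", 1, np.array([[1.0], [1.0]]), eye.copy())
        # pattern (0.4, 0.4): sums 0.8 vs 1.2 -> cluster 0
        pat = SequencePattern("x", None, np.full((2, 1), 0.4))
        assert preselect_prototype(pat, [p1, p0]).cluster_id == 0
        # pattern (0.6, 0.6): sums 1.2 vs 0.8 -> cluster 1
        pat2 = SequencePattern("y", None, np.full((2, 1), 0.6))
        assert preselect_prototype(pat2, [p1, p0]).cluster_id == 1


def test_bank_json_roundtrip(three_point_bank):
    d = bank_to_dict(three_point_bank)
    back = bank_from_dict(d)
    np.testing.assert_array_equal(back.prototype_0.means, three_point_bank.prototype_0.means)
    np.testing.assert_array_equal(back.prototype_1.covariances,
                                  three_point_bank.prototype_1.covariances)
    assert back.metric == "euclidean"
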