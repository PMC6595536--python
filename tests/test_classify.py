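"""KNN / CV tests, including exhaustive brute-force oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import distance as sp_dist

from apneaebr.classify import (
    CvScheme,
    KnnConfig,
    cross_validate,
    cv_split,
    distance,
    knn_predict,
    knn_predict_batch,
    pairwise_distances,
)
from apneaebr.errors import ConfigError, DataError

SCIPY_METRICS = {
    "euclidean": sp_dist.euclidean,
    "cityblock": sp_dist.cityblock,
    "cosine": sp_dist.cosine,
    "correlation": sp_dist.correlation,
}


def oracle_knn(train_X, train_y, x, k, metric, tie_rule="apnea"):
    """Independent exhaustive-search KNN using scipy distances and explicit
    (distance, index) sorting."""
    scored = sorted(
        (SCIPY_METRICS[metric](x, row), i) for i, row in enumerate(train_X)
    )
    votes = [train_y[i] for _, i in scored[:k]]
    n_apnea = sum(v == "apnea" for v in votes)
    score = n_apnea / k
    if n_apnea * 2 == k:
        label = "apnea" if tie_rule == "apnea" else "non_apnea"
    else:
        label = "apnea" if n_apnea * 2 > k else "non_apnea"
    return label, score


class TestDistance:
    def test_euclidean_345(self):
        assert distance([0.0, 0.0], [3.0, 4.0], "euclidean") == 5.0

    def test_cityblock(self):
        assert distance([1.0, 2.0], [4.0, 0.0], "cityblock") == 5.0

    def test_cosine_self_and_scale(self, rng):
        u = rng.random(6) + 0.1
        assert distance(u, u, "cosine") == pytest.approx(0.0, abs=1e-12)
        assert distance(u, 5.0 * u, "cosine") == pytest.approx(0.0, abs=1e-12)

    def test_cosine_orthogonal(self):
        assert distance([1.0, 0.0], [0.0, 2.0], "cosine") == pytest.approx(1.0)

    def test_cosine_zero_vector_raises(self):
        with pytest.raises(DataError, match="zero"):
            distance([0.0, 0.0], [1.0, 2.0], "cosine")

    def test_correlation_constant_vector_raises(self):
        with pytest.raises(DataError, match="constant"):
            distance([2.0, 2.0], [1.0, 3.0], "correlation")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigError):
            distance([1.0], [2.0], "chebyshev")

    @pytest.mark.parametrize("metric", sorted(SCIPY_METRICS))
    def test_matches_scipy(self, rng, metric):
        for _ in range(50):
            u, v = rng.random((2, 8)) + 0.05
            assert distance(u, v, metric) == pytest.approx(
                SCIPY_METRICS[metric](u, v), abs=1e-12
            )

    @pytest.mark.parametrize("metric", sorted(SCIPY_METRICS))
    def test_pairwise_matches_cdist(self, rng, metric):
        X = rng.random((12, 5)) + 0.05
        Y = rng.random((9, 5)) + 0.05
        np.testing.assert_allclose(
            pairwise_distances(X, Y, metric),
            sp_dist.cdist(X, Y, metric),
            atol=1e-10,
        )


class TestKnnPredict:
    def test_k1_exact_match(self, rng):
        X = rng.random((10, 4)) + 0.1
        y = np.array(["apnea"] * 5 + ["non_apnea"] * 5, dtype=object)
        label, score = knn_predict(X, y, X[7], KnnConfig(k=1))
        assert label == "non_apnea" and score == 0.0

    def test_majority_two_of_three(self):
        X = np.array([[1.0, 0.0], [1.0, 0.01], [0.0, 1.0]])
        y = np.array(["apnea", "apnea", "non_apnea"], dtype=object)
        label, score = knn_predict(X, y, [1.0, 0.005], KnnConfig(k=3))
        assert label == "apnea" and score == pytest.approx(2 / 3)

    def test_vote_tie_rules(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array(["apnea", "non_apnea"], dtype=object)
        test = [2**-0.5, 2**-0.5]  # equidistant
        assert knn_predict(X, y, test, KnnConfig(k=2, tie_rule="apnea"))[0] == "apnea"
        assert (
            knn_predict(X, y, test, KnnConfig(k=2, tie_rule="non_apnea"))[0]
            == "non_apnea"
        )

    def test_empty_train_raises(self):
        with pytest.raises(DataError):
            knn_predict(np.empty((0, 3)), [], [1.0, 2.0, 3.0])

    def test_k_larger_than_train_raises(self, rng):
        with pytest.raises(ConfigError):
            knn_predict(rng.random((3, 2)), ["apnea"] * 3, [0.5, 0.5], KnnConfig(k=4))

    def test_cosine_invariant_to_positive_scaling(self, rng):
        X = rng.random((20, 5)) + 0.1
        y = np.array(["apnea"] * 10 + ["non_apnea"] * 10, dtype=object)
        T = rng.random((6, 5)) + 0.1
        scales = rng.uniform(0.5, 5.0, size=(20, 1))
        p1, s1 = knn_predict_batch(X, y, T, KnnConfig(k=3))
        p2, s2 = knn_predict_batch(X * scales, y, T * 7.0, KnnConfig(k=3))
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("metric", sorted(SCIPY_METRICS))
    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_oracle_equivalence(self, metric, k):
        rng = np.random.default_rng(1000 + k)
        for case in range(25):
            n = int(rng.integers(8, 41))
            X = rng.random((n, 6)) + 0.05
            y = np.array(
                ["apnea" if b else "non_apnea" for b in rng.integers(0, 2, n)],
                dtype=object,
            )
            x = rng.random(6) + 0.05
            got = knn_predict(X, y, x, KnnConfig(k=k, distance=metric))
            want = oracle_knn(X, y, x, k, metric)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1])


class TestCvSplit:
    def labels(self, n_apnea, n_non):
        return np.array(
            ["apnea"] * n_apnea + ["non_apnea"] * n_non, dtype=object
        )

    def test_leave_one_out(self):
        folds = cv_split(self.labels(3, 3), CvScheme(kind="leave_one_out"))
        assert len(folds) == 6
        tests = sorted(int(t[0]) for _, t in folds)
        assert tests == list(range(6))
        for train, test in folds:
            assert len(test) == 1 and len(train) == 5
            assert set(train) | set(test) == set(range(6))

    def test_stratified_five_fold_balanced(self):
        folds = cv_split(self.labels(5, 5), CvScheme(kind="m_fold", m=5, seed=0))
        y = self.labels(5, 5)
        for _, test in folds:
            counts = {c: int(np.sum(y[test] == c)) for c in ("apnea", "non_apnea")}
            assert counts == {"apnea": 1, "non_apnea": 1}

    def test_folds_partition_indices(self):
        y = self.labels(13, 17)
        folds = cv_split(y, CvScheme(kind="m_fold", m=4, seed=5))
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test.tolist()) == list(range(30))
        for (_, t1), (_, t2) in zip(folds, folds[1:]):
            assert not set(t1) & set(t2)

    def test_per_fold_class_counts_within_one(self):
        y = self.labels(11, 11)
        folds = cv_split(y, CvScheme(kind="m_fold", m=4, seed=1))
        for cls in ("apnea", "non_apnea"):
            sizes = [int(np.sum(y[t] == cls)) for _, t in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_seed_determinism(self):
        y = self.labels(10, 10)
        a = cv_split(y, CvScheme(kind="m_fold", m=5, seed=3))
        b = cv_split(y, CvScheme(kind="m_fold", m=5, seed=3))
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_m_larger_than_n_rejected(self):
        with pytest.raises(ConfigError):
            cv_split(self.labels(2, 2), CvScheme(kind="m_fold", m=10))

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            cv_split(self.labels(5, 0), CvScheme(kind="leave_one_out"))


def test_cross_validate_covers_every_sample(rng):
    X = rng.random((24, 5)) + 0.1
    y = np.array(["apnea"] * 12 + ["non_apnea"] * 12, dtype=object)
    pred, scores = cross_validate(X, y, KnnConfig(k=3), CvScheme(kind="m_fold", m=4))
    assert pred.shape == (24,) and scores.shape == (24,)
    assert set(pred) <= {"apnea", "non_apnea"}
    assert np.all((scores >= 0) & (scores <= 1))


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=40, deadline=None)
def test_knn_property_oracle_equivalence(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 30))
    k = int(rng.choice([1, 3, 5]))
    if k > n:
        k = 1
    metric = str(rng.choice(["euclidean", "cityblock", "cosine", "correlation"]))
    X = rng.random((n, 4)) + 0.05
    y = np.array(
        ["apnea" if b else "non_apnea" for b in rng.integers(0, 2, n)], dtype=object
    )
    x = rng.random(4) + 0.05
    got = knn_predict(X, y, x, KnnConfig(k=k, distance=metric))
    want = oracle_knn(X, y, x, k, metric)
    assert got[0] == want[0] and got[1] == pytest.approx(want[1])
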