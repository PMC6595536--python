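"""K-nearest-neighbour classification and cross-validation, from first
principles.

The classifier is deliberately small and brute-force-verifiable: all
pairwise distances are computed explicitly, neighbours are taken in stable
sorted order (distance ties broken by lower training index), and the
prediction is the majority label among the k nearest with a deterministic
vote-tie rule.  The apnea score is the fraction of the k neighbours
labelled apnea, which serves as the ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "KnnConfig",
    "CvScheme",
    "DISTANCES",
    "distance",
    "pairwise_distances",
    "knn_predict",
    "knn_predict_batch",
    "cv_split",
    "cross_validate",
]

APNEA = "apnea"


def _euclidean(u: np.ndarray, v: np.ndarray) -> float:
    d = u - v
    return float(np.sqrt(np.dot(d, d)))


def _cityblock(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.sum(np.abs(u - v)))


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DataError("cosine distance undefined for a zero vector")
    # rounding can push the quotient infinitesimally past 1
    return float(max(0.0, 1.0 - np.dot(u, v) / (nu * nv)))


def _correlation(u: np.ndarray, v: np.ndarray) -> float:
    uc, vc = u - u.mean(), v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0.0 or nv == 0.0:
        raise DataError("correlation distance undefined for a constant vector")
    return float(max(0.0, 1.0 - np.dot(uc, vc) / (nu * nv)))


DISTANCES = {
    "euclidean": _euclidean,
    "cityblock": _cityblock,
    "cosine": _cosine,
    "correlation": _correlation,
}


def distance(u, v, metric: str = "cosine") -> float:
    """Distance between two equal-length vectors under the named metric."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise DataError("distance needs two 1-D vectors of equal length")
    try:
        return DISTANCES[metric](u, v)
    except KeyError:
        raise ConfigError(
            f"unknown distance {metric!r}; choose from {sorted(DISTANCES)}"
        ) from None


def pairwise_distances(X: np.ndarray, Y: np.ndarray, metric: str = "cosine") -> np.ndarray:
    """Dense (len(X), len(Y)) distance matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if metric == "euclidean":
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Y**2, axis=1)[None, :]
            - 2.0 * X @ Y.T
        )
        return np.sqrt(np.maximum(d2, 0.0))
    if metric == "cityblock":
        return np.sum(np.abs(X[:, None, :] - Y[None, :, :]), axis=2)
    if metric == "cosine":
        nx = np.linalg.norm(X, axis=1)
        ny = np.linalg.norm(Y, axis=1)
        if (nx == 0).any() or (ny == 0).any():
            raise DataError("cosine distance undefined for a zero vector")
        return np.maximum(0.0, 1.0 - (X @ Y.T) / np.outer(nx, ny))
    if metric == "correlation":
        Xc = X - X.mean(axis=1, keepdims=True)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        nx = np.linalg.norm(Xc, axis=1)
        ny = np.linalg.norm(Yc, axis=1)
        if (nx == 0).any() or (ny == 0).any():
            raise DataError("correlation distance undefined for a constant vector")
        return np.maximum(0.0, 1.0 - (Xc @ Yc.T) / np.outer(nx, ny))
    raise ConfigError(f"unknown distance {metric!r}; choose from {sorted(DISTANCES)}")


@dataclass(frozen=True)
class KnnConfig:
    k: int = 5
    distance: str = "cosine"
    tie_rule: str = "apnea"  # vote-tie winner for even k

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if self.distance not in DISTANCES:
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.tie_rule not in ("apnea", "non_apnea"):
            raise ConfigError("tie_rule must be 'apnea' or 'non_apnea'")


@dataclass(frozen=True)
class CvScheme:
    kind: str = "leave_one_out"  # or "m_fold"
    m: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_out", "m_fold"):
            raise ConfigError("kind must be 'leave_one_out' or 'm_fold'")
        if self.kind == "m_fold" and self.m < 2:
            raise ConfigError("m_fold needs m >= 2")


def knn_predict_batch(
    train_features: np.ndarray,
    train_labels,
    test_features: np.ndarray,
    config: KnnConfig = KnnConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and apnea scores for a batch of test vectors.

    Distance ties are broken by lower training index (stable sort); a
    majority-vote tie goes to ``config.tie_rule``.
    """
    train_features = np.atleast_2d(np.asarray(train_features, dtype=float))
    train_labels = np.asarray(train_labels, dtype=object)
    test_features = np.atleast_2d(np.asarray(test_features, dtype=float))
    n_train = train_features.shape[0]
    if n_train == 0:
        raise DataError("empty training set")
    if config.k > n_train:
        raise ConfigError(f"k={config.k} exceeds training-set size {n_train}")

    dists = pairwise_distances(test_features, train_features, config.distance)
    order = np.argsort(dists, axis=1, kind="stable")[:, : config.k]
    neighbour_is_apnea = (train_labels.astype(str) == APNEA)[order]
    scores = neighbour_is_apnea.mean(axis=1)
    if config.tie_rule == "apnea":
        predictions = np.where(scores >= 0.5, APNEA, "non_apnea")
    else:
        predictions = np.where(scores > 0.5, APNEA, "non_apnea")
    return predictions.astype(object), scores


def knn_predict(
    train_features,
    train_labels,
    test_feature,
    config: KnnConfig = KnnConfig(),
) -> tuple[str, float]:
    """Single-vector convenience wrapper around :func:`knn_predict_batch`."""
    labels, scores = knn_predict_batch(
        train_features, train_labels, np.atleast_2d(test_feature), config
    )
    return str(labels[0]), float(scores[0])


def cv_split(labels, scheme: CvScheme = CvScheme()) -> list[tuple[np.ndarray, np.ndarray]]:
    """Train/test index folds for the chosen cross-validation scheme.

    Leave-one-out yields n singleton test folds in index order; m-fold
    partitions are seeded and, when stratified, spread each class across
    folds so per-fold class counts differ by at most one.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n < 2:
        raise DataError("cross-validation needs at least 2 samples")
    if len(np.unique(labels.astype(str))) < 2:
        raise DataError("cross-validation needs both classes present")
    all_idx = np.arange(n)
    if scheme.kind == "leave_one_out":
        return [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    if scheme.m > n:
        raise ConfigError(f"m={scheme.m} exceeds sample count {n}")
    rng = np.random.default_rng(scheme.seed)
    fold_of = np.empty(n, dtype=int)
    if scheme.stratified:
        for cls in np.unique(labels.astype(str)):
            idx = np.flatnonzero(labels.astype(str) == cls)
            idx = rng.permutation(idx)
            fold_of[idx] = np.arange(idx.size) % scheme.m
    else:
        perm = rng.permutation(n)
        fold_of[perm] = np.arange(n) % scheme.m
    return [
        (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
        for f in range(scheme.m)
    ]


def cross_validate(
    features: np.ndarray,
    labels,
    knn_config: KnnConfig = KnnConfig(),
    scheme: CvScheme = CvScheme(),
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold predictions and apnea scores for every sample."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=object)
    predictions = np.empty(labels.size, dtype=object)
    scores = np.empty(labels.size, dtype=float)
    for train_idx, test_idx in cv_split(labels, scheme):
        cfg = knn_config
        if cfg.k > train_idx.size:
            raise ConfigError(
                f"k={cfg.k} exceeds fold training size {train_idx.size}"
            )
        p, s = knn_predict_batch(
            features[train_idx], labels[train_idx], features[test_idx], cfg
        )
        predictions[test_idx] = p
        scores[test_idx] = s
    return predictions, scores
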