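"""Confusion matrices, sensitivity/specificity/accuracy, ROC-AUC, the
geometrical separability index, and per-subject report aggregation.

Percentages follow the report convention: two decimal places, rounded
half-away-from-zero.  Aggregates use the arithmetic mean over subjects,
the sample (n-1) standard deviation and the linear-interpolation IQR.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import CvScheme, KnnConfig, cross_validate, pairwise_distances
from .errors import DataError

__all__ = [
    "ConfusionMatrix",
    "SubjectResult",
    "metrics",
    "roc_auc",
    "gsi",
    "aggregate",
    "round2",
    "evaluate_subject",
    "build_report",
    "write_report",
]

APNEA = "apnea"
METRIC_COLUMNS = ("sensitivity", "specificity", "accuracy", "auc", "gsi")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (the tables' print rule)."""
    return float(np.sign(x) * np.floor(abs(x) * 100.0 + 0.5) / 100.0)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise DataError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive: str = APNEA) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object).astype(str)
        y_pred = np.asarray(y_pred, dtype=object).astype(str)
        if y_true.shape != y_pred.shape:
            raise DataError("y_true and y_pred differ in length")
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
        )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) of a confusion matrix."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise DataError("metrics undefined: one class has no frames")
    sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn)
    specificity = 100.0 * cm.tn / (cm.tn + cm.fp)
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    return sensitivity, specificity, accuracy


def roc_auc(scores, labels, positive: str = APNEA) -> float:
    """Area under the empirical ROC curve.

    Mann-Whitney formulation: the probability that a random positive
    outscores a random negative, ties counted half — exact on the discrete
    score grid a KNN produces.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    u = float(ranks[pos].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def gsi(features, labels, metric: str = "euclidean") -> float:
    """Geometrical separability index: the fraction of points whose nearest
    neighbour (self excluded, distance ties to the lower index) shares
    their class label."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=object).astype(str)
    n = features.shape[0]
    if n < 2:
        raise DataError("gsi needs at least 2 points")
    dists = pairwise_distances(features, features, metric)
    np.fill_diagonal(dists, np.inf)
    nearest = np.argmin(dists, axis=1)  # argmin takes the lower index on ties
    return float(np.mean(labels[nearest] == labels))


def aggregate(values_per_subject: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Mean, sample SD and linear-interpolation IQR of each metric column."""
    if len(values_per_subject) < 2:
        raise DataError("aggregation needs at least 2 subjects")
    frame = pd.DataFrame(values_per_subject).T
    out: dict[str, dict[str, float]] = {"mean": {}, "sd": {}, "iqr": {}}
    for col in frame.columns:
        v = frame[col].to_numpy(dtype=float)
        out["mean"][col] = float(np.mean(v))
        out["sd"][col] = float(np.std(v, ddof=1))
        q1, q3 = np.percentile(v, [25, 75])
        out["iqr"][col] = float(q3 - q1)
    return out


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    cm: ConfusionMatrix
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    gsi: float

    def metric_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "gsi": self.gsi,
        }


def evaluate_subject(
    subject_id: str,
    features,
    labels,
    knn_config: KnnConfig = KnnConfig(),
    scheme: CvScheme = CvScheme(),
    gsi_metric: str = "euclidean",
) -> SubjectResult:
    """Cross-validated evaluation of one subject's feature matrix."""
    predictions, scores = cross_validate(features, labels, knn_config, scheme)
    cm = ConfusionMatrix.from_predictions(labels, predictions)
    sens, spec, acc = metrics(cm)
    return SubjectResult(
        subject_id=subject_id,
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=roc_auc(scores, labels),
        gsi=gsi(features, labels, gsi_metric),
    )


def build_report(results: list[SubjectResult]) -> pd.DataFrame:
    """Per-subject rows plus mean / sd / iqr aggregate rows.

    Percent metrics are printed at 2 dp (half away from zero); AUC and GSI
    at 4 dp.
    """
    rows = []
    for r in results:
        row = {"subject": r.subject_id, **asdict(r.cm)}
        row.update(
            {
                "sensitivity": round2(r.sensitivity),
                "specificity": round2(r.specificity),
                "accuracy": round2(r.accuracy),
                "auc": round(r.auc, 4),
                "gsi": round(r.gsi, 4),
            }
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    if len(results) >= 2:
        agg = aggregate({r.subject_id: r.metric_dict() for r in results})
        for name, vals in agg.items():
            row = {"subject": name}
            for col in ("sensitivity", "specificity", "accuracy"):
                row[col] = round2(vals[col])
            for col in ("auc", "gsi"):
                row[col] = round(vals[col], 4)
            rows.append(row)
        frame = pd.DataFrame(rows)
    return frame


def write_report(path, results: list[SubjectResult], json_path=None) -> pd.DataFrame:
    frame = build_report(results)
    frame.to_csv(path, index=False)
    if json_path is not None:
        frame.to_json(json_path, orient="records", indent=2)
    return frame
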