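"""Incremental feature selection (IFS) with LOOCV classification.

The mRMR ranking orders transcripts but does not say how many to keep. IFS
evaluates the nested prefixes of the ranking — top 1, top 2, ... top k_max
transcripts — by training a classifier on each prefix and scoring it with
leave-one-out cross-validation. Performance per prefix is summarized as
sensitivity, specificity, accuracy and the Matthews correlation coefficient
(MCC); the optimal prefix size is the smallest k attaining the maximal MCC,
the peak of the IFS curve. MCC is the peak criterion because the two cell
classes are of quite different sizes and MCC is robust to that imbalance.

The default classifier mirrors the documented defaults of the classical
libsvm interface: RBF kernel, cost 1, kernel width gamma = 1 / n_features,
with per-feature standardization whose statistics are computed on the
training fold only (so the held-out cell never leaks into scaling).
Features enter the classifier as log2(FPKM+1) values; the three-state
discretization is a mutual-information device only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np
from sklearn.svm import SVC

from .expression_io import ExpressionMatrix
from .mrmr import RankedTranscripts
from .preprocessing import apply_transform


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positives = tumor cells."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sn/Sp/ACC in [0,1] and MCC in [-1,1]; NaN marks 0/0 Sn or Sp."""

    sn: float
    sp: float
    acc: float
    mcc: float


def confusion_to_metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """Sn, Sp, ACC and MCC from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/n and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A zero denominator yields NaN for Sn/Sp (undefined, not poor) and 0 for
    MCC by convention.
    """
    if c.n == 0:
        raise ValueError("at least one sample required")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    acc = (c.tp + c.tn) / c.n
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return PerformanceMetrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


class ClassifierContract(Protocol):
    """fit/predict pair; identical inputs must yield identical predictions."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ClassifierContract": ...

    def predict(self, x: np.ndarray) -> np.ndarray: ...

    def clone(self) -> "ClassifierContract": ...


class SvmClassifier:
    """RBF support-vector classifier with libsvm-style defaults.

    Cost 1, gamma = 1/n_features, per-feature standardization fitted on the
    training data only. Deterministic for fixed inputs.
    """

    def __init__(self, cost: float = 1.0) -> None:
        self.cost = cost
        self._svc: SVC | None = None
        self._mean: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def clone(self) -> "SvmClassifier":
        return SvmClassifier(cost=self.cost)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SvmClassifier":
        x = np.asarray(x, dtype=float)
        self._mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0  # constant feature: center only
        self._scale = sd
        self._svc = SVC(C=self.cost, kernel="rbf", gamma=1.0 / x.shape[1])
        self._svc.fit((x - self._mean) / self._scale, np.asarray(y))
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise RuntimeError("classifier is not fitted")
        x = np.asarray(x, dtype=float)
        return self._svc.predict((x - self._mean) / self._scale)


def loocv_predict(
    features: np.ndarray, labels: np.ndarray, clf: ClassifierContract
) -> np.ndarray:
    """Leave-one-out predictions over a cells x features matrix."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    for cls in np.unique(labels):
        if np.sum(labels == cls) < 2:
            raise ValueError(
                f"class {cls!r} has fewer than 2 cells; a training fold "
                "would lose the class entirely"
            )
    preds = np.empty(n, dtype=labels.dtype)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        model = clf.clone().fit(features[mask], labels[mask])
        preds[i] = model.predict(features[i : i + 1])[0]
    return preds


def _counts_from_predictions(labels: np.ndarray, preds: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    preds = np.asarray(preds).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (preds == 1))),
        tn=int(np.sum((labels == 0) & (preds == 0))),
        fp=int(np.sum((labels == 0) & (preds == 1))),
        fn=int(np.sum((labels == 1) & (preds == 0))),
    )


def loocv_evaluate(
    x: ExpressionMatrix | np.ndarray,
    clf: ClassifierContract | None = None,
    labels: np.ndarray | None = None,
    transform: str = "log2p1",
) -> ConfusionCounts:
    """LOOCV confusion counts for a transcript-restricted matrix.

    ``x`` may be an :class:`ExpressionMatrix` (features are its transformed
    transcripts) or a plain cells x features array with ``labels`` given.
    """
    if clf is None:
        clf = SvmClassifier()
    if isinstance(x, ExpressionMatrix):
        x.require_both_classes()
        features = apply_transform(x, transform).values.T
        labels = x.labels
    else:
        if labels is None:
            raise ValueError("labels are required with an array input")
        features = np.asarray(x, dtype=float)
    preds = loocv_predict(features, labels, clf)
    return _counts_from_predictions(labels, preds)


@dataclass
class IfsCurve:
    """Per-cardinality LOOCV performance along the ranking prefixes."""

    points: list[tuple[int, PerformanceMetrics, ConfusionCounts]]
    peak_k: int

    @property
    def ks(self) -> list[int]:
        return [k for k, _, _ in self.points]

    @property
    def mccs(self) -> list[float]:
        return [m.mcc for _, m, _ in self.points]

    def metrics_at(self, k: int) -> PerformanceMetrics:
        for kk, m, _ in self.points:
            if kk == k:
                return m
        raise KeyError(k)

    @property
    def peak_metrics(self) -> PerformanceMetrics:
        return self.metrics_at(self.peak_k)


def select_peak(points) -> int:
    """Smallest k attaining the maximal MCC (accepts a curve or its points)."""
    if isinstance(points, IfsCurve):
        points = points.points
    if not points:
        raise ValueError("empty curve")
    best_mcc = max(m.mcc for _, m, _ in points)
    return min(k for k, m, _ in points if m.mcc == best_mcc)


def run_ifs(
    x: ExpressionMatrix,
    ranks: RankedTranscripts,
    k_max: int,
    clf: ClassifierContract | None = None,
    transform: str = "log2p1",
) -> IfsCurve:
    """Evaluate nested top-k transcript sets for k = 1..k_max by LOOCV."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > len(ranks.order):
        raise ValueError(f"k_max={k_max} exceeds ranking length {len(ranks.order)}")
    if clf is None:
        clf = SvmClassifier()
    x.require_both_classes()
    ordered = apply_transform(x, transform).values[ranks.order[:k_max]].T
    labels = x.labels
    points: list[tuple[int, PerformanceMetrics, ConfusionCounts]] = []
    for k in range(1, k_max + 1):
        preds = loocv_predict(ordered[:, :k], labels, clf)
        counts = _counts_from_predictions(labels, preds)
        points.append((k, confusion_to_metrics(counts), counts))
    return IfsCurve(points=points, peak_k=select_peak(points))


def curve_to_records(curve: IfsCurve) -> list[dict]:
    """Flatten an IFS curve for TSV output."""
    return [
        {
            "k": k,
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc,
        }
        for k, m, c in curve.points
    ]
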