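"""Confusion-matrix metrics, ROC/C-statistic, and printed-value reconstruction.

Any metric with a zero denominator is reported as ``None`` (never 0).  The
C-statistic is the ROC AUC; :func:`roc` computes it both by trapezoidal
integration and by pairwise concordance and asserts the two agree.

:func:`reconstruct_cm` inverts rounded published metrics back to the integer
confusion matrices that could have produced them, by exhaustive enumeration
at a known n and positive count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .corpus_model import POSITIVE_LABEL, PatientVisit
from .feature_extraction import FeatureCatalog, extract_feature_matrix


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (fpr, tpr), threshold descending
    thresholds: list[float]
    auc: float


def confusion(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be 1-D vectors of equal length")
    if len(y) < 1:
        raise ValueError("need at least one case")
    return ConfusionMatrix(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix) -> MetricSet:
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _auc_concordance(y: np.ndarray, scores: np.ndarray) -> float:
    pos = scores[y == 1]
    neg = scores[y == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def roc(labels: Sequence[int], scores: Sequence[float]) -> RocCurve:
    """ROC curve over all distinct-score thresholds; AUC by trapezoid.

    The trapezoidal AUC is cross-checked against pairwise concordance (ties
    counted half) and the two must agree to 1e-12.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    thresholds: list[float] = [math.inf]
    tp = fp = 0
    for i in range(len(y_sorted)):
        tp += y_sorted[i] == 1
        fp += y_sorted[i] == 0
        if i + 1 < len(y_sorted) and s_sorted[i + 1] == s_sorted[i]:
            continue  # emit one point per distinct score
        points.append((fp / n_neg, tp / n_pos))
        thresholds.append(float(s_sorted[i]))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
        thresholds.append(-math.inf)

    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    concordance = _auc_concordance(y, s)
    if abs(auc - concordance) > 1e-12:
        raise AssertionError(
            f"trapezoidal AUC {auc!r} disagrees with concordance AUC {concordance!r}"
        )
    return RocCurve(points=points, thresholds=thresholds, auc=auc)


# ---------------------------------------------------------------------------
# reconstruction of integer confusion matrices from printed metrics
# ---------------------------------------------------------------------------

def round_half_up(x: float, decimals: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def _truncate(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale) / scale


def _matches(value: float | None, reported: float | None, decimals: int, rounding: str) -> bool:
    if reported is None:
        return True  # unreported metric constrains nothing
    if value is None:
        return False
    target = round_half_up(reported, decimals)
    if rounding == "half_up":
        return round_half_up(value, decimals) == target
    if rounding == "truncate":
        return _truncate(value, decimals) == target
    if rounding == "either":
        return round_half_up(value, decimals) == target or _truncate(value, decimals) == target
    raise ValueError(f"unknown rounding mode {rounding!r}")


def reconstruct_cm(
    n: int,
    n_pos: int,
    reported: MetricSet,
    decimals: int = 4,
    rounding: str = "half_up",
) -> list[ConfusionMatrix]:
    """All integer confusion matrices consistent with rounded printed metrics.

    Enumerates tp in [0, n_pos] and fp in [0, n - n_pos]; a matrix is
    consistent when each reported metric matches under the given rounding
    convention ("half_up", "truncate", or "either" — some publications mix
    conventions).  May return an empty list (inconsistent report).
    """
    if n_pos > n:
        raise ValueError("n_pos cannot exceed n")
    hits: list[ConfusionMatrix] = []
    n_neg = n - n_pos
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            cm = ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)
            m = metrics(cm)
            if all(
                _matches(getattr(m, name), getattr(reported, name), decimals, rounding)
                for name in MetricSet.__dataclass_fields__
            ):
                hits.append(cm)
    return hits


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    confusion_matrix: ConfusionMatrix
    metric_set: MetricSet
    roc_curve: RocCurve
    threshold: float
    n: int
    model_kind: str
    visit_ids: list[str] = field(default_factory=list)
    probabilities: list[float] = field(default_factory=list)

    @property
    def c_statistic(self) -> float:
        return self.roc_curve.auc

    def to_dict(self) -> dict:
        cm = self.confusion_matrix
        return {
            "model_kind": self.model_kind,
            "n": self.n,
            "threshold": self.threshold,
            "confusion_matrix": {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            "metrics": self.metric_set.to_dict(),
            "c_statistic": self.c_statistic,
            "roc_points": self.roc_curve.points,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_roc_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("threshold,fpr,tpr\n")
            for thr, (fpr, tpr) in zip(self.roc_curve.thresholds, self.roc_curve.points):
                fh.write(f"{thr},{fpr},{tpr}\n")


def evaluate(model, visits: Sequence[PatientVisit], catalog: FeatureCatalog) -> EvaluationReport:
    """Extract features, predict, and score one labeled corpus end to end."""
    unlabeled = [v.visit_id for v in visits if v.label is None]
    if unlabeled:
        raise ValueError(f"evaluation requires labels; unlabeled visits: {unlabeled[:3]}")
    X, visit_ids = extract_feature_matrix(visits, catalog)
    y = np.array([1 if v.label == POSITIVE_LABEL else 0 for v in visits])
    probs = model.predict_proba(X)
    thr = model.config.threshold
    yhat = (probs >= thr).astype(int)
    cm = confusion(y, yhat)
    return EvaluationReport(
        confusion_matrix=cm,
        metric_set=metrics(cm),
        roc_curve=roc(y, probs),
        threshold=thr,
        n=len(visits),
        model_kind=model.config.model_kind,
        visit_ids=visit_ids,
        probabilities=[float(p) for p in probs],
    )
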