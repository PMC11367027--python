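"""One-vs-rest evaluation: confusion matrices, metrics, ROC, CV planning.

Each class is scored as an independent binary absent/present problem with
its own 2x2 confusion matrix.  The six reported metrics (accuracy,
precision, sensitivity, specificity, F-score, MCC) use the standard
definitions and are expressed in percent; the macro average is the
unweighted arithmetic mean over classes.  A confusion matrix can also be
reconstructed from a printed summary (correct counts per side plus
sensitivity/specificity) for fixture construction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (matches hand-rounded tables)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class BinaryConfusion:
    """2x2 one-vs-rest counts; ``positive_label`` names the positive side."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: str = "present"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "BinaryConfusion":
        """Same data with the opposite positive convention."""
        other = "absent" if self.positive_label == "present" else "present"
        return BinaryConfusion(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp,
                               positive_label=other)


@dataclass(frozen=True)
class ClassMetrics:
    """The six per-class metrics, in percent (MCC in [-100, 100])."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    fscore: float
    mcc: float

    def rounded(self, ndigits: int = 2) -> "ClassMetrics":
        return ClassMetrics(**{k: round_half_up(v, ndigits)
                               for k, v in asdict(self).items()})


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               class_index: int,
                               positive_label: str = "present") -> BinaryConfusion:
    """Tally one-vs-rest counts for one class from binary label matrices."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    if y_true.size == 0:
        raise ValueError("empty input")
    t = y_true[:, class_index].astype(bool)
    p = y_pred[:, class_index].astype(bool)
    if positive_label == "absent":
        t, p = ~t, ~p
    elif positive_label != "present":
        raise ValueError("positive_label must be 'present' or 'absent'")
    return BinaryConfusion(
        tp=int(np.sum(t & p)), fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)), tn=int(np.sum(~t & ~p)),
        positive_label=positive_label)


def metrics_from_confusion(cm: BinaryConfusion) -> ClassMetrics:
    """The six metrics from counts; a zero denominator yields 0 with a warning."""
    tp, fn, fp, tn = cm.tp, cm.fn, cm.fp, cm.tn
    n = cm.n
    if n < 1:
        raise ValueError("empty confusion matrix")

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"zero denominator for {name}; reporting 0",
                          RuntimeWarning, stacklevel=3)
            return 0.0
        return num / den

    accuracy = (tp + tn) / n
    precision = safe(tp, tp + fp, "precision")
    sensitivity = safe(tp, tp + fn, "sensitivity")
    specificity = safe(tn, tn + fp, "specificity")
    fscore = safe(2.0 * precision * sensitivity, precision + sensitivity, "fscore")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = safe(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return ClassMetrics(accuracy=100 * accuracy, precision=100 * precision,
                        sensitivity=100 * sensitivity,
                        specificity=100 * specificity,
                        fscore=100 * fscore, mcc=100 * mcc)


def reconstruct_confusion(diag_pos: int, diag_neg: int, total: int,
                          sensitivity: float, specificity: float,
                          positive_label: str = "absent") -> BinaryConfusion:
    """Invert a printed summary into integer counts.

    ``diag_pos``/``diag_neg`` are the correctly classified counts on the
    positive/negative side (the confusion-matrix diagonal); ``sensitivity``
    and ``specificity`` are in percent.  The recovered counts must tie out to
    ``total`` exactly, else an error naming the residual is raised.
    """
    fn = round(diag_pos / (sensitivity / 100.0) - diag_pos)
    fp = round(diag_neg / (specificity / 100.0) - diag_neg)
    cm = BinaryConfusion(tp=diag_pos, fn=int(fn), fp=int(fp), tn=diag_neg,
                         positive_label=positive_label)
    if cm.n != total:
        raise ValueError(f"inconsistent summary: counts sum to {cm.n}, "
                         f"expected {total} (residual {total - cm.n})")
    return cm


def macro_average(metrics: list[ClassMetrics]) -> ClassMetrics:
    """Unweighted arithmetic mean per field (unrounded; round for reporting)."""
    if not metrics:
        raise ValueError("empty metrics list")
    fields = ("accuracy", "precision", "sensitivity", "specificity",
              "fscore", "mcc")
    return ClassMetrics(**{f: float(np.mean([getattr(m, f) for m in metrics]))
                           for f in fields})


def kfold_plan(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Seeded fold assignment of n indices into k folds of near-equal size."""
    if k > n:
        raise ValueError("k must not exceed n")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=np.int64)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for fold, size in enumerate(sizes):
        assignment[perm[start:start + size]] = fold
        start += size
    return assignment


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) over a threshold sweep and the trapezoid AUC.

    Returns AUC in [0, 1]; report writers multiply by 100.  Requires both
    classes present.
    """
    y = np.asarray(y_true).astype(bool).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("shape mismatch")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last index of each distinct score (full threshold sweep)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


# ---------------------------------------------------------------------------
# Full reports
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class confusions/metrics, macro metrics, and per-class ROC AUC."""

    vocabulary: tuple[str, ...]
    confusions: dict[str, BinaryConfusion]
    per_class: dict[str, ClassMetrics]
    macro: ClassMetrics
    auc: dict[str, float] = field(default_factory=dict)   # percent
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "vocabulary": list(self.vocabulary),
            "confusions": {c: asdict(cm) for c, cm in self.confusions.items()},
            "per_class": {c: asdict(m) for c, m in self.per_class.items()},
            "per_class_rounded": {c: asdict(m.rounded())
                                  for c, m in self.per_class.items()},
            "macro": asdict(self.macro),
            "macro_rounded": asdict(self.macro.rounded()),
            "auc": self.auc,
            "extra": self.extra,
        }


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         scores: np.ndarray | None,
                         vocabulary: tuple[str, ...],
                         positive_label: str = "present") -> EvalReport:
    """Full one-vs-rest report for multi-label predictions."""
    confusions, per_class, auc = {}, {}, {}
    for j, cls in enumerate(vocabulary):
        cm = confusion_from_predictions(y_true, y_pred, j, positive_label)
        confusions[cls] = cm
        per_class[cls] = metrics_from_confusion(cm)
        if scores is not None:
            col = np.asarray(y_true)[:, j]
            if 0 < col.sum() < col.size:
                auc[cls] = 100.0 * roc_auc(col, np.asarray(scores)[:, j])[1]
    macro = macro_average(list(per_class.values()))
    return EvalReport(vocabulary=tuple(vocabulary), confusions=confusions,
                      per_class=per_class, macro=macro, auc=auc)


def write_metrics_csv(report: EvalReport, path) -> None:
    """Table-style CSV: one row per class plus an Average row, six metrics."""
    import pandas as pd

    rows = []
    for cls in report.vocabulary:
        m = report.per_class[cls].rounded()
        rows.append({"class": cls, **asdict(m)})
    rows.append({"class": "Average", **asdict(report.macro.rounded())})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_report_json(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
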