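"""Leave-one-subject-out evaluation and performance metrics.

Metrics follow the standard one-vs-rest construction per intensity class:
precision, recall (= sensitivity), specificity, accuracy, F1, and the
geometric mean G = sqrt(Se * Sp).  ROC curves are computed per internal
node of the hierarchy (where graded binary scores exist) and the AUC by the
trapezoid rule, which equals the Mann-Whitney pair statistic with ties
counted one half.

Leave-one-subject-out (LOSO) cross-validation holds out every window of one
subject per fold; feature selection and training are re-run from scratch
inside each fold so no information from the held-out subject leaks into the
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from oxiflow.classifiers import BhcSpec, predict_node, predict_bhc_batch, train_bhc
from oxiflow.synthetic_data import Intensity

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix2x2",
    "ClassMetrics",
    "LosoReport",
    "ovr_confusion",
    "metrics_from_confusion",
    "g_metric",
    "weighted_summary",
    "roc_auc",
    "loso_evaluate",
    "round_half_up",
    "as_percent",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matches how printed percentages are rounded)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def as_percent(fraction: float, ndigits: int = 1) -> float:
    return round_half_up(100.0 * fraction, ndigits)


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """One-vs-rest counts for a target class: tp, fn, fp, tn."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class fractions in [0, 1]; g is the geometric mean of Se and Sp."""

    precision: float
    recall: float
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    g: float


def ovr_confusion(y_true, y_pred, target) -> ConfusionMatrix2x2:
    """One-vs-rest 2x2 confusion counts for ``target``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    t = y_true == target
    p = y_pred == target
    return ConfusionMatrix2x2(
        tp=int(np.sum(t & p)),
        fn=int(np.sum(t & ~p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.info("degenerate metric %s: 0/0 defined as 0", name)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix2x2) -> ClassMetrics:
    """All per-class metrics from one 2x2 matrix (0/0 defined as 0)."""
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    accuracy = (cm.tp + cm.tn) / cm.total
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    return ClassMetrics(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        sensitivity=recall,
        specificity=specificity,
        g=g_metric(recall, specificity),
    )


def g_metric(se: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity (same scale as inputs)."""
    if se < 0 or sp < 0:
        raise ValueError("sensitivity and specificity must be non-negative")
    return float(np.sqrt(se * sp))


def weighted_summary(per_class) -> dict:
    """Support-weighted averages of per-class precision/recall/F1.

    ``per_class`` is a list of (ClassMetrics, support) pairs.
    """
    if not per_class:
        raise ValueError("no per-class metrics given")
    supports = np.array([s for _, s in per_class], dtype=float)
    if np.any(supports <= 0):
        raise ValueError("supports must be positive")
    out = {}
    for name in ("precision", "recall", "f1", "accuracy"):
        vals = np.array([getattr(m, name) for m, _ in per_class])
        out[name] = float(np.sum(vals * supports) / supports.sum())
    return out


def roc_auc(scores, y):
    """ROC curve over all unique score thresholds and its trapezoid AUC.

    The trapezoid AUC equals the Mann-Whitney statistic
    P(score+ > score-) + 0.5 * P(score+ = score-).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and y length mismatch")
    npos = int(np.sum(y == 1))
    nneg = int(np.sum(y == 0))
    if npos == 0 or nneg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    tp = np.cumsum(ys == 1)
    fp = np.cumsum(ys == 0)
    # keep only the last index of each tied score group
    last = np.r_[np.diff(ss) != 0, True]
    tpr = np.r_[0.0, tp[last] / npos]
    fpr = np.r_[0.0, fp[last] / nneg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class LosoReport:
    """Pooled LOSO predictions with per-class and node-level metrics."""

    folds: list = field(default_factory=list)
    y_true: np.ndarray = None
    y_pred: np.ndarray = None
    per_class: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    accuracy: float = 0.0
    node_roc: dict = field(default_factory=dict)
    node_auc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready report with percentages rounded half-up to 1 decimal."""
        rows = []
        for cls, (cm, m, support) in self.per_class.items():
            rows.append(
                {
                    "class": int(cls),
                    "tp": cm.tp,
                    "fn": cm.fn,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "support": int(support),
                    "precision_pct": as_percent(m.precision),
                    "recall_pct": as_percent(m.recall),
                    "accuracy_pct": as_percent(m.accuracy),
                    "f1_pct": as_percent(m.f1),
                    "g_pct": as_percent(m.g),
                }
            )
        return {
            "n_folds": len(self.folds),
            "n_windows": int(self.y_true.size),
            "accuracy_pct": as_percent(self.accuracy),
            "per_class": rows,
            "weighted": {k: as_percent(v) for k, v in self.weighted.items()},
            "node_auc": {k: round(v, 4) for k, v in self.node_auc.items()},
            "fold_subjects": [f["subject"] for f in self.folds],
        }


def loso_evaluate(X, y, subjects, spec: BhcSpec | None = None) -> LosoReport:
    """Leave-one-subject-out evaluation of the full selection + BHC pipeline.

    For each held-out subject the wrapper selection and node training run on
    the remaining subjects only; the held-out windows are then predicted and
    pooled.  Also pools per-node graded scores for ROC/AUC: phi1 scores on
    all windows (sedentary vs active truth) and phi2 scores on truly active
    windows (light vs moderate truth).
    """
    if spec is None:
        spec = BhcSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("LOSO needs at least two subjects")
    if not np.array_equal(np.unique(y), [0, 1, 2]):
        raise ValueError("all three intensity classes must be present overall")

    report = LosoReport()
    all_true, all_pred = [], []
    phi1_scores, phi1_truth = [], []
    phi2_scores, phi2_truth = [], []
    for subject in uniq:
        test = subjects == subject
        if not test.any():
            logger.warning("subject %s has no windows; skipped", subject)
            continue
        train = ~test
        model = train_bhc(X[train], y[train], spec=spec)
        pred = predict_bhc_batch(model, X[test])
        report.folds.append(
            {"subject": str(subject), "y_true": y[test], "y_pred": pred}
        )
        all_true.append(y[test])
        all_pred.append(pred)
        _, s1 = predict_node(model.phi1, X[test])
        phi1_scores.append(np.atleast_1d(s1))
        phi1_truth.append((y[test] > 0).astype(int))
        act = y[test] > 0
        if act.any():
            _, s2 = predict_node(model.phi2, X[test][act])
            phi2_scores.append(np.atleast_1d(s2))
            phi2_truth.append((y[test][act] == 2).astype(int))

    report.y_true = np.concatenate(all_true)
    report.y_pred = np.concatenate(all_pred)
    report.accuracy = float(np.mean(report.y_true == report.y_pred))

    per_class_list = []
    for cls in Intensity:
        cm = ovr_confusion(report.y_true, report.y_pred, int(cls))
        m = metrics_from_confusion(cm)
        support = int(np.sum(report.y_true == int(cls)))
        report.per_class[cls] = (cm, m, support)
        per_class_list.append((m, support))
    report.weighted = weighted_summary(per_class_list)

    for name, sc, tr in (
        ("phi1", phi1_scores, phi1_truth),
        ("phi2", phi2_scores, phi2_truth),
    ):
        s = np.concatenate(sc)
        t = np.concatenate(tr)
        curve, auc = roc_auc(s, t)
        report.node_roc[name] = curve
        report.node_auc[name] = auc
    return report
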