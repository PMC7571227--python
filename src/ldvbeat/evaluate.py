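"""Confusion-matrix metrics, ROC/AUC and repeated-measures ANOVA.

Per-class recall Rec_i = TP_i/(TP_i+FN_i), precision
Prec_i = TP_i/(TP_i+FP_i) and their harmonic mean f1_i are computed for the
beat and no-beat classes; macro averages are the unweighted two-class means,
which represent performance fairly under the heavy class imbalance of
full-length signals.  ROC curves are swept over the unique beat
probabilities, with AUC equal to the Mann-Whitney pair-ordering statistic
(tied positive-negative pairs count 1/2).

Classifier comparisons across LOSO folds use a one-way repeated-measures
ANOVA with subjects as blocks: F = MS_treatment / MS_error on
(k-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .windowing import BEAT, NO_BEAT


@dataclass
class ClassMetrics:
    """One class's confusion counts and derived metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    recall: float
    precision: float
    f1: float
    recall_defined: bool = True
    precision_defined: bool = True


@dataclass
class MetricsReport:
    """Per-class and macro-averaged confusion-matrix metrics."""

    per_class: dict[int, ClassMetrics]
    macro_recall: float
    macro_precision: float
    macro_f1: float

    @property
    def beat(self) -> ClassMetrics:
        return self.per_class[BEAT]

    @property
    def no_beat(self) -> ClassMetrics:
        return self.per_class[NO_BEAT]


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """Per-class recall/precision/f1 and their macro averages.

    A class absent from ``y_true`` has undefined recall; it is flagged and
    excluded from the macro averages with a warning.  Undefined precision
    (no predicted positives) is reported as 0 with a flag, the conservative
    convention.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length 1-D, length >= 1")

    per_class: dict[int, ClassMetrics] = {}
    for cls in (NO_BEAT, BEAT):
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        tn = int(np.sum((y_true != cls) & (y_pred != cls)))
        rec_def = tp + fn > 0
        prec_def = tp + fp > 0
        rec = tp / (tp + fn) if rec_def else float("nan")
        prec = tp / (tp + fp) if prec_def else 0.0
        if not prec_def:
            f1 = 0.0
        elif not rec_def:
            f1 = float("nan")
        else:
            f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[cls] = ClassMetrics(tp, fp, fn, tn, rec, prec, f1, rec_def, prec_def)

    present = [c for c in per_class.values() if c.recall_defined]
    if len(present) < 2:
        warnings.warn("a class is absent from y_true; macro averages cover "
                      "the present class only")
    macro_rec = float(np.mean([c.recall for c in present]))
    macro_prec = float(np.mean([c.precision for c in present]))
    macro_f1 = float(np.mean([c.f1 for c in present]))
    return MetricsReport(per_class, macro_rec, macro_prec, macro_f1)


@dataclass
class ROCResult:
    """A receiver-operating-characteristic curve and its trapezoidal area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, y_true) -> ROCResult:
    """ROC curve and AUC from beat probabilities against true labels.

    The threshold sweep covers the unique scores; the curve runs from
    (0, 0) to (1, 1) with nondecreasing rates and AUC the trapezoidal area,
    equal to the probability that a random beat window outscores a random
    no-beat window (ties counted 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs both classes in y_true")
    fpr, tpr, thresholds = _sk_roc_curve(y_true, scores, pos_label=BEAT)
    return ROCResult(thresholds, fpr, tpr, float(_sk_auc(fpr, tpr)))


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA summary."""

    F: float
    p: float
    df_treatment: int
    df_error: int


def rm_anova(metric_matrix) -> AnovaResult:
    """One-way repeated-measures ANOVA on a (subjects x classifiers) matrix.

    Subjects are blocks; F = MS_treatment / MS_error on degrees of freedom
    (k-1, (n-1)(k-1)).  A constant matrix gives the degenerate F = 0, p = 1.
    No sphericity correction is applied.
    """
    M = np.asarray(metric_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 classifiers")
    if np.isnan(M).any():
        raise ValueError("missing cells are not supported")
    n, k = M.shape
    grand = M.mean()
    ss_treat = n * np.sum((M.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((M.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_treat - ss_subj
    df_t = k - 1
    df_e = (n - 1) * (k - 1)
    # numerical guard: tiny negative residual SS from cancellation
    ss_err = max(ss_err, 0.0)
    if ss_treat <= 0:
        return AnovaResult(0.0, 1.0, df_t, df_e)
    if ss_err == 0:
        return AnovaResult(float("inf"), 0.0, df_t, df_e)
    F = (ss_treat / df_t) / (ss_err / df_e)
    p = float(stats.f.sf(F, df_t, df_e))
    return AnovaResult(float(F), p, df_t, df_e)


def aggregate_loso(per_fold_reports: list[MetricsReport]) -> dict:
    """Summarize LOSO folds: median and quartiles per metric, pooled counts.

    The returned dict maps metric names (``beat_f1``, ``no_beat_precision``,
    ``macro_f1``, ...) to ``{"median", "q1", "q3"}`` and carries the pooled
    confusion counts under ``"pooled"``.
    """
    if not per_fold_reports:
        raise ValueError("need at least one fold")

    def values(getter):
        return np.array([getter(r) for r in per_fold_reports], dtype=float)

    named = {
        "beat_precision": lambda r: r.beat.precision,
        "beat_recall": lambda r: r.beat.recall,
        "beat_f1": lambda r: r.beat.f1,
        "no_beat_precision": lambda r: r.no_beat.precision,
        "no_beat_recall": lambda r: r.no_beat.recall,
        "no_beat_f1": lambda r: r.no_beat.f1,
        "macro_precision": lambda r: r.macro_precision,
        "macro_recall": lambda r: r.macro_recall,
        "macro_f1": lambda r: r.macro_f1,
    }
    out: dict = {}
    for name, getter in named.items():
        v = values(getter)
        out[name] = {
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
        }
    pooled = {}
    for cls, label in ((BEAT, "beat"), (NO_BEAT, "no_beat")):
        pooled[label] = {
            stat: int(sum(getattr(r.per_class[cls], stat) for r in per_fold_reports))
            for stat in ("tp", "fp", "fn", "tn")
        }
    out["pooled"] = pooled
    return out
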