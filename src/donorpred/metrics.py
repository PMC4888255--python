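"""ROC and precision--recall areas for splice-site classifier evaluation.

``auc_roc`` is the trapezoidal area under the ROC curve traced by sweeping
a threshold over the distinct classifier scores, the exact finite-sample
version of the textbook sum  sum_i { (1-beta_i) d(alpha) + 1/2 d(1-beta)
d(alpha) }  over false-positive-rate steps.  It equals the Mann--Whitney
pair statistic with ties counted one half.

``auc_pr`` is the area under the precision--recall curve with
Davis--Goadrich interpolation: between two achievable points the true
positives are stepped continuously with false positives accrued in
proportion, which makes precision a hyperbolic (not linear) function of
recall.  The area of each segment is integrated in closed form.

Both areas are invariant under strictly increasing transforms of the
scores; ties are grouped so that all instances sharing a score change
classification together.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd


def _validate(scores: Sequence[float], labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray([bool(v) for v in labels])
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if s.size == 0:
        raise ValueError("empty input")
    return s, y


def _sweep_counts(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (tp, fp) after each distinct threshold, descending scores.

    Tied scores form a single curve point.  The arrays start implicitly at
    (0, 0); the last entry is (P, N).
    """
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    # indices of the last occurrence of each distinct score
    distinct = np.flatnonzero(np.diff(s_sorted)) if s_sorted.size > 1 else np.array([], int)
    last = np.r_[distinct, s_sorted.size - 1]
    tp = np.cumsum(y_sorted)[last].astype(float)
    fp = np.cumsum(~y_sorted)[last].astype(float)
    return tp, fp


def auc_roc(scores: Sequence[float], labels: Sequence) -> float:
    """Trapezoidal area under the ROC curve of a threshold sweep."""
    s, y = _validate(scores, labels)
    P = int(y.sum())
    N = int((~y).sum())
    if P == 0 or N == 0:
        raise ValueError("both classes must be present to trace a ROC curve")
    tp, fp = _sweep_counts(s, y)
    tpr = np.r_[0.0, tp / P]
    fpr = np.r_[0.0, fp / N]
    return float(np.sum((tpr[1:] + tpr[:-1]) / 2.0 * np.diff(fpr)))


def auc_pr(scores: Sequence[float], labels: Sequence) -> float:
    """Area under the Davis--Goadrich interpolated precision--recall curve.

    Between consecutive achievable points A and B, intermediate true
    positives x in (tp_A, tp_B) accrue false positives linearly,
    fp(x) = fp_A + s (x - tp_A) with s = (fp_B - fp_A) / (tp_B - tp_A),
    so precision(x) = x / ((1+s) x + b) with b = fp_A - s tp_A.  The exact
    segment area is  [x/a - (b/a^2) ln(a x + b)] / P  with a = 1 + s.
    The sweep is anchored at (tp, fp) = (0, 0), which extends the curve to
    recall 0 at the precision of the first achievable point.
    """
    s, y = _validate(scores, labels)
    P = int(y.sum())
    if P == 0:
        raise ValueError("at least one positive is required for a PR curve")
    tp, fp = _sweep_counts(s, y)
    tp = np.r_[0.0, tp]
    fp = np.r_[0.0, fp]
    area = 0.0
    for k in range(1, tp.size):
        tp_a, fp_a, tp_b, fp_b = tp[k - 1], fp[k - 1], tp[k], fp[k]
        if tp_b == tp_a:  # recall does not advance; no area
            continue
        slope = (fp_b - fp_a) / (tp_b - tp_a)
        a = 1.0 + slope
        b = fp_a - slope * tp_a
        if abs(b) < 1e-12:
            area += (tp_b - tp_a) / a
        else:
            area += (tp_b - tp_a) / a - (b / a**2) * (
                math.log(a * tp_b + b) - math.log(a * tp_a + b)
            )
    return area / P


def roc_curve_table(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """The swept ROC points (fpr, tpr) including the (0,0) endpoint."""
    s, y = _validate(scores, labels)
    P, N = int(y.sum()), int((~y).sum())
    if P == 0 or N == 0:
        raise ValueError("both classes must be present to trace a ROC curve")
    tp, fp = _sweep_counts(s, y)
    return pd.DataFrame(
        {"fpr": np.r_[0.0, fp / N], "tpr": np.r_[0.0, tp / P]}
    )


def pr_curve_table(scores: Sequence[float], labels: Sequence) -> pd.DataFrame:
    """Achievable PR points plus unit-step interpolated points.

    Intermediate true-positive counts between achievable points are stepped
    one at a time with proportional false positives, yielding the standard
    plotted form of the interpolated curve.
    """
    s, y = _validate(scores, labels)
    P = int(y.sum())
    if P == 0:
        raise ValueError("at least one positive is required for a PR curve")
    tp, fp = _sweep_counts(s, y)
    tp = np.r_[0.0, tp]
    fp = np.r_[0.0, fp]
    rec, prec = [], []
    for k in range(1, tp.size):
        tp_a, fp_a, tp_b, fp_b = tp[k - 1], fp[k - 1], tp[k], fp[k]
        if tp_b == tp_a:
            if tp_b > 0:
                rec.append(tp_b / P)
                prec.append(tp_b / (tp_b + fp_b))
            continue
        slope = (fp_b - fp_a) / (tp_b - tp_a)
        x = tp_a + 1.0 if tp_a.is_integer() else math.ceil(tp_a)
        grid = np.arange(x, tp_b + 0.5)
        for xv in grid:
            fpv = fp_a + slope * (xv - tp_a)
            rec.append(xv / P)
            prec.append(xv / (xv + fpv))
    return pd.DataFrame({"recall": rec, "precision": prec}).drop_duplicates(
        ignore_index=True
    )
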