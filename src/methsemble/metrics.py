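"""Binary-classification evaluation and TOPSIS multi-criteria ranking.

Sensitivity, specificity, accuracy and the Matthews correlation coefficient
are computed directly from the confusion matrix; ROC/AUC ranks instances by a
continuous (here: quantized vote) score.  TOPSIS ranks competing classifiers
by closeness to the ideal point across several evaluation criteria at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class ConfusionMatrix:
    """The four cells: tp = true positives, tn, fp, fn (all counts >= 0)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.total < 1:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """Sn/Sp/Acc in [0,1], MCC in [-1,1]; undefined metrics are NaN+flag."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "flags": list(self.flags),
        }


def confusion(labels: Sequence[int], calls: Sequence[int]) -> ConfusionMatrix:
    """Exact confusion-matrix counts from equal-length binary vectors."""
    y = np.asarray(labels).astype(int)
    c = np.asarray(calls).astype(int)
    if y.shape != c.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {c.shape} calls")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (c == 1))),
        tn=int(np.sum((y == 0) & (c == 0))),
        fp=int(np.sum((y == 0) & (c == 1))),
        fn=int(np.sum((y == 1) & (c == 0))),
    )


def evaluate(cm: ConfusionMatrix) -> EvaluationReport:
    """Sensitivity, specificity, accuracy and MCC from the confusion matrix.

    Sn = tp/(tp+fn), Sp = tn/(tn+fp), Acc = (tp+tn)/total,
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).

    A zero marginal leaves the affected ratio undefined (NaN) and MCC is
    reported as 0 by convention; either case is flagged.
    """
    flags: list[str] = []
    if cm.tp + cm.fn > 0:
        sn = cm.tp / (cm.tp + cm.fn)
    else:
        sn, flags = math.nan, flags + ["sensitivity undefined: no positives"]
    if cm.tn + cm.fp > 0:
        sp = cm.tn / (cm.tn + cm.fp)
    else:
        sp, flags = math.nan, flags + ["specificity undefined: no negatives"]
    acc = (cm.tp + cm.tn) / cm.total

    # integer numerator/denominator keep MCC exact for the analytic cases
    num = cm.tp * cm.tn - cm.fp * cm.fn
    den = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
           * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    if den == 0:
        mcc = 0.0
        flags.append("mcc undefined (zero marginal): reported as 0")
    else:
        mcc = num / math.sqrt(den)
    return EvaluationReport(sn, sp, acc, mcc, tuple(flags))


def roc_auc(labels: Sequence[int], scores: Sequence[float]
            ) -> tuple[float, np.ndarray]:
    """AUC by the trapezoidal rule over the unique-threshold ROC curve.

    Equals the Mann-Whitney statistic with ties counted 1/2, so it is
    well-defined for the heavily tied 4-level ensemble vote scores.
    Returns ``(auc, roc_points)`` with roc_points an (m, 2) array of
    (FPR, TPR) pairs, monotone in both coordinates.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class TopsisResult:
    """Closeness scores in [0,1] (1 = at the ideal point) and ranks (1 = best)."""

    alternatives: tuple[str, ...]
    criteria: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "rank": self.ranks},
            index=list(self.alternatives),
        )


def topsis(decision_matrix: pd.DataFrame,
           weights: Sequence[float] | None = None,
           directions: Sequence[str] | None = None) -> TopsisResult:
    """Rank alternatives (rows) over criteria (columns) by TOPSIS.

    Steps: vector (L2) normalization per column -> weighting -> ideal and
    anti-ideal points (per ``directions``: "benefit" = larger is better,
    "cost" = smaller) -> Euclidean distances d+ and d- -> closeness
    C = d- / (d+ + d-), ranked descending.  Weights default to equal and
    are normalized to sum to 1; zero-norm (all-zero) columns are skipped.
    Ties in closeness are broken by alternative name for a stable order.
    """
    X = decision_matrix.to_numpy(dtype=float)
    alts = tuple(str(a) for a in decision_matrix.index)
    crits = tuple(str(c) for c in decision_matrix.columns)
    n, m = X.shape
    if n < 2:
        raise ValueError("TOPSIS needs at least two alternatives")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != m or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, one per criterion")
        w = w / w.sum()
    if directions is None:
        directions = ["benefit"] * m
    if len(directions) != m:
        raise ValueError("one direction per criterion required")

    norms = np.linalg.norm(X, axis=0)
    keep = norms > 0
    V = np.zeros_like(X)
    V[:, keep] = X[:, keep] / norms[keep] * w[keep]

    ideal = np.empty(m)
    anti = np.empty(m)
    for j, d in enumerate(directions):
        if d not in ("benefit", "cost"):
            raise ValueError(f"direction must be 'benefit' or 'cost', got {d!r}")
        col = V[:, j]
        ideal[j] = col.max() if d == "benefit" else col.min()
        anti[j] = col.min() if d == "benefit" else col.max()

    d_plus = np.linalg.norm(V - ideal, axis=1)
    d_minus = np.linalg.norm(V - anti, axis=1)
    denom = d_plus + d_minus
    scores = np.where(denom > 0, d_minus / np.where(denom > 0, denom, 1.0), 0.5)

    order = sorted(range(n), key=lambda i: (-scores[i], alts[i]))
    ranks = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return TopsisResult(alts, crits, scores, ranks)
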