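"""Confusion-matrix metrics, ROC/AUC with midrank ties, and panel PCA.

AUC is computed two ways on purpose: by trapezoidal integration of the
threshold-swept ROC curve and by the midrank Mann-Whitney statistic
U / (n1 * n0).  With midrank tie handling the two are identical, which the
test suite asserts to 1e-12; disagreement would indicate a defect in either
path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix


@dataclass
class EvalReport:
    """Binary-classification report; undefined ratios are None, never 0."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(y_true, y_pred, positive=1) -> EvalReport:
    """Standard confusion-matrix metrics for binary labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    t = y_true == positive
    p = y_pred == positive
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    prec = _ratio(tp, tp + fp)
    sens = _ratio(tp, tp + fn)
    f1 = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=_ratio(tp + tn, tp + fp + fn + tn),
        sensitivity=sens,
        specificity=_ratio(tn, tn + fp),
        precision=prec,
        f1=f1,
    )


def roc_auc(scores, y_true, positive=1) -> tuple[np.ndarray, float]:
    """ROC points from a threshold sweep and the midrank AUC.

    Returns (points, auc) where points is an (m, 2) array of (FPR, TPR)
    running from (0, 0) to (1, 1).  The returned AUC is the midrank
    Mann-Whitney value; trapezoidal integration of the points equals it
    exactly (ties collapse to single sweep thresholds, giving the diagonal
    segments midranks imply).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true) == positive
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep only the last index of each tied score block
    last = np.r_[ss[1:] != ss[:-1], True]
    points = np.vstack(
        [
            np.r_[0.0, fps[last] / n0],
            np.r_[0.0, tps[last] / n1],
        ]
    ).T
    ranks = rankdata(scores)  # midranks
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return points, float(auc)


def trapezoid_auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC polyline (FPR, TPR) pairs."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def pca_project(
    expr: ExpressionMatrix, panel: list[str], n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered SVD projection of samples onto the top panel components.

    The sign of each component is fixed by making its largest-magnitude
    gene loading positive.  Returns (coordinates, explained variance ratio).
    """
    X = expr.panel_matrix(panel)  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least three samples")
    if X.shape[0] < n_components:
        raise ValueError("fewer samples than components")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(n_components):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    coords = u[:, :n_components] * s[:n_components]
    var = s**2
    evr = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=expr.sample_ids, columns=cols), evr


def write_report(report: EvalReport, path) -> None:
    """Validate and serialize an evaluation report to JSON."""
    payload = report.to_dict()
    for key in ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc"):
        val = payload[key]
        if val is not None and not (0.0 <= val <= 1.0):
            raise ValueError(f"{key}={val} outside [0, 1]")
    for fpr, tpr in payload["roc_points"]:
        if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
            raise ValueError("ROC point outside the unit square")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
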