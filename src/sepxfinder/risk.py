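"""Weighted z-score risk model over the hub-gene panel.

Each sample's risk score is  RS = sum_i w_i * (e_i - u_i) / s_i  with u_i
and s_i the mean and standard deviation of gene i "among whole samples" of
the dataset being scored, and w_i a per-gene weight.  The default weights
are +/-1 with the sign chosen so the disease class scores higher (the panel
genes are down-regulated in disease, so their weights are -1); weights
proportional to the discovery logFC and fully custom weights are also
supported.  Because the score is a sum of within-dataset z-scores, refitting
u and s on each new dataset makes the score transferable across platforms
(microarray, RNA-seq, -ddCt qPCR).

The binary cutoff is read off the density plot: the crossing point of the
two class-wise Gaussian-kernel density estimates located between the class
means (Silverman bandwidth), with Youden's J as the alternative.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

WEIGHT_MODES = ("signed_unit", "logfc", "custom")


def density_cutoff(scores, labels, method: str = "density_intersection") -> float:
    """Classification cutoff between the two class score distributions.

    ``density_intersection`` finds where the class-wise KDEs cross between
    the class means; with no crossing there (effectively identical
    distributions) it falls back to the midpoint of the class means with a
    warning.  ``youden`` maximizes sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("cutoff requires exactly two classes")
    s0, s1 = scores[labels == classes[0]], scores[labels == classes[1]]
    m0, m1 = float(np.mean(s0)), float(np.mean(s1))
    if np.isclose(m0, m1):
        raise ValueError("class means coincide; no cutoff between them")
    lo, hi = sorted((m0, m1))
    if method == "youden":
        from .metrics import roc_auc  # local import avoids a cycle

        y = (labels == classes[np.argmax([m0, m1])]).astype(int)
        thresholds = np.unique(scores)
        best, best_j = 0.5 * (lo + hi), -np.inf
        for thr in thresholds:
            pred = scores >= thr
            tpr = pred[y == 1].mean()
            fpr = pred[y == 0].mean()
            j = tpr - fpr
            if j > best_j:
                best_j, best = j, float(thr)
        return min(max(best, np.nextafter(lo, hi)), np.nextafter(hi, lo))
    if method != "density_intersection":
        raise ValueError(f"unknown cutoff method {method!r}")
    if s0.std(ddof=0) == 0 or s1.std(ddof=0) == 0:
        # degenerate constant class: KDE undefined, fall back to midpoint
        warnings.warn("constant class scores: midpoint cutoff fallback", stacklevel=2)
        return 0.5 * (lo + hi)
    kde0 = gaussian_kde(s0, bw_method="silverman")
    kde1 = gaussian_kde(s1, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)[1:-1]
    diff = kde1(grid) - kde0(grid)
    signs = np.sign(diff)
    crossings = np.flatnonzero(np.diff(signs) != 0)
    if crossings.size == 0:
        warnings.warn(
            "class densities do not cross between the means: midpoint fallback",
            stacklevel=2,
        )
        return 0.5 * (lo + hi)
    mid = 0.5 * (lo + hi)
    # linear interpolation at each crossing; pick the one nearest the midpoint
    cuts = []
    for i in crossings:
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        cuts.append(x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0))
    return float(min(cuts, key=lambda c: abs(c - mid)))


class RiskScorer(BaseEstimator, TransformerMixin):
    """Panel risk score: weighted sum of per-gene z-scores.

    Parameters
    ----------
    weight_mode : {"signed_unit", "logfc", "custom"}
        ``signed_unit``: w_i = sign(logFC_i) (disease scores higher for a
        down-regulated panel); ``logfc``: w_i = logFC_i; ``custom``: the
        ``weights`` argument as given.
    logfc : array-like, optional
        Per-gene discovery log2 fold changes (required for the first two
        modes).
    weights : array-like, optional
        Explicit weights for ``custom`` mode.
    cutoff_method : str
        Passed to :func:`density_cutoff` when ``fit`` receives labels.

    Attributes
    ----------
    u_, s_ : per-gene mean / SD over the reference ("whole") sample set.
    w_ : per-gene weights.
    cutoff_ : score threshold (present only when labels were supplied).
    """

    def __init__(
        self,
        weight_mode: str = "signed_unit",
        logfc=None,
        weights=None,
        cutoff_method: str = "density_intersection",
    ):
        self.weight_mode = weight_mode
        self.logfc = logfc
        self.weights = weights
        self.cutoff_method = cutoff_method

    def _resolve_weights(self, n_features: int) -> np.ndarray:
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
        if self.weight_mode == "custom":
            if self.weights is None:
                raise ValueError("custom weight_mode requires weights")
            w = np.asarray(self.weights, dtype=float)
        else:
            if self.logfc is None:
                raise ValueError(f"weight_mode {self.weight_mode!r} requires logfc")
            lfc = np.asarray(self.logfc, dtype=float)
            w = np.sign(lfc) if self.weight_mode == "signed_unit" else lfc.copy()
        if w.size != n_features:
            raise ValueError("weight length does not match feature count")
        return w

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x genes")
        self.u_ = X.mean(axis=0)
        self.s_ = X.std(axis=0, ddof=1)
        if np.any(self.s_ <= 0):
            bad = np.flatnonzero(self.s_ <= 0).tolist()
            raise ValueError(f"constant gene(s) at columns {bad}: s_i = 0")
        self.w_ = self._resolve_weights(X.shape[1])
        self.n_features_in_ = X.shape[1]
        if y is not None:
            scores = self.transform(X)
            self.cutoff_ = density_cutoff(scores, y, self.cutoff_method)
        return self

    def refit_reference(self, X) -> "RiskScorer":
        """New scorer with u, s recomputed on ``X`` (per-dataset transfer).

        Weights and cutoff method carry over; the cutoff does not (it must
        be re-derived on the new dataset's scores if needed).
        """
        new = RiskScorer(
            weight_mode="custom", weights=self.w_.copy(), cutoff_method=self.cutoff_method
        )
        return new.fit(X)

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "u_"):
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return ((X - self.u_) / self.s_) @ self.w_

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cutoff_"):
            raise ValueError("no cutoff fitted: fit with labels first")
        return (self.transform(X) >= self.cutoff_).astype(int)

    def to_dict(self) -> dict:
        return {
            "kind": "risk",
            "panel": list(getattr(self, "panel_", [])),
            "w": self.w_.tolist(),
            "u": self.u_.tolist(),
            "s": self.s_.tolist(),
            "cutoff": float(self.cutoff_) if hasattr(self, "cutoff_") else None,
            "params": {"weight_mode": self.weight_mode, "cutoff_method": self.cutoff_method},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RiskScorer":
        model = cls(
            weight_mode="custom",
            weights=payload["w"],
            cutoff_method=payload.get("params", {}).get("cutoff_method", "density_intersection"),
        )
        model.u_ = np.asarray(payload["u"], dtype=float)
        model.s_ = np.asarray(payload["s"], dtype=float)
        model.w_ = np.asarray(payload["w"], dtype=float)
        model.n_features_in_ = model.w_.size
        if payload.get("cutoff") is not None:
            model.cutoff_ = float(payload["cutoff"])
        if payload.get("panel"):
            model.panel_ = list(payload["panel"])
        return model


def fit_risk_model(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    panel: list[str],
    weight_mode: str = "signed_unit",
    deg_table: pd.DataFrame | None = None,
    custom_w=None,
    positive: str = "SS",
    negative: str = "HC",
    fit_cutoff: bool = True,
    cutoff_sample_ids: list[str] | None = None,
) -> RiskScorer:
    """Fit the risk model on a dataset (u, s over all its samples).

    Weights derive from ``deg_table`` logFC for the sign-based modes.  When
    ``fit_cutoff`` is true the density cutoff is derived from the scores of
    the two labelled cohorts (optionally restricted to
    ``cutoff_sample_ids``, e.g. a training split).
    """
    panel = list(panel)
    X = expr.panel_matrix(panel)
    logfc = None
    if weight_mode in ("signed_unit", "logfc"):
        if deg_table is None:
            raise ValueError(f"weight_mode {weight_mode!r} requires a DEG table")
        missing = [g for g in panel if g not in deg_table.index]
        if missing:
            raise KeyError(f"panel genes missing from DEG table: {missing}")
        logfc = deg_table.loc[panel, "logFC"].to_numpy()
    model = RiskScorer(weight_mode=weight_mode, logfc=logfc, weights=custom_w)
    model.fit(X)
    model.panel_ = panel
    model.class_labels_ = (negative, positive)
    if fit_cutoff:
        sub = sheet[sheet["cohort"].isin([negative, positive])]
        if cutoff_sample_ids is not None:
            sub = sub[sub["sample_id"].isin(set(cutoff_sample_ids))]
        ids = [s for s in sub["sample_id"] if s in expr.values.columns]
        scores = model.transform(expr.subset_samples(ids).panel_matrix(panel))
        y = (sub.set_index("sample_id").loc[ids, "cohort"] == positive).astype(int)
        model.cutoff_ = density_cutoff(scores, y.to_numpy(), model.cutoff_method)
    return model


def score_samples(
    model: RiskScorer, expr: ExpressionMatrix, refit_reference: bool = False
) -> pd.Series:
    """Per-sample risk scores; optionally re-standardize u, s on this dataset."""
    scorer = model
    X = expr.panel_matrix(model.panel_) if hasattr(model, "panel_") else expr.values.to_numpy().T
    if refit_reference:
        scorer = model.refit_reference(X)
    return pd.Series(scorer.transform(X), index=expr.sample_ids, name="RS")
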