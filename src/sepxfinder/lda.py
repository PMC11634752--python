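"""Two-class Fisher linear discriminant scoring of a gene panel.

The discriminant direction w solves S_p w = mu1 - mu0 with S_p the pooled
within-class covariance, and is rescaled so the projected within-class
variance w' S_p w equals 1: LD1 gaps are expressed in pooled-SD units and
are therefore comparable across datasets and platforms.  Projection centres
at the midpoint of the two class means, which keeps LD1 offsets independent
of the case/control mix of the dataset the model was fitted in — a
prerequisite for pooling LD1 values from several cohorts into one stacked
dataset.  Orientation is fixed so the positive (disease) class scores
higher.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split as _sk_split

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """Stratified train/test split protocol (default the 50/50 routine)."""

    train_fraction: float = 0.5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def train_test_split_sheet(
    sheet: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[list[str], list[str]]:
    """Split sample ids into disjoint, exhaustive train/test sets.

    Stratification keeps per-cohort train counts within one sample of the
    target fraction; every class needs at least two samples.
    """
    spec = spec or SplitSpec()
    ids = sheet["sample_id"].tolist()
    strat = sheet["cohort"] if spec.stratified else None
    if spec.stratified:
        counts = sheet["cohort"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"cohorts with <2 samples cannot be stratified: {dict(small)}"
            )
    train, test = _sk_split(
        ids,
        train_size=spec.train_fraction,
        stratify=strat,
        random_state=spec.seed,
        shuffle=True,
    )
    return list(train), list(test)


class LinearDiscriminantScorer(BaseEstimator, ClassifierMixin):
    """Fisher LDA for two classes with unit pooled within-class LD1 variance.

    Parameters
    ----------
    ridge : float or "auto"
        Diagonal repair added to a singular pooled covariance; ``"auto"``
        uses 1e-6 * trace(S_p)/d and is only applied when the plain solve
        fails (panel size can exceed class counts in small cohorts).
    priors : "proportional" or "uniform"
        Class priors for the Gaussian posterior; proportional to training
        counts by default.

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_ : (2,) array, negative class first.
    means_ : (2, d) class mean vectors.
    pooled_cov_ : (d, d) pooled within-class covariance.
    direction_ : (d,) discriminant vector, w' S_p w = 1, positive class high.
    center_ : (d,) midpoint of the class means (LD1 zero point).
    priors_ : (2,) class priors.
    proj_means_ : (2,) projected class means on LD1.
    """

    def __init__(self, ridge="auto", priors: str = "proportional"):
        self.ridge = ridge
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x features)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required, got {classes.size}")
        masks = [y == c for c in classes]
        n = np.array([m.sum() for m in masks])
        if np.any(n < 2):
            raise ValueError("each class needs at least two samples")
        d = X.shape[1]
        means = np.vstack([X[m].mean(axis=0) for m in masks])
        scatter = sum(
            (X[m] - means[i]).T @ (X[m] - means[i]) for i, m in enumerate(masks)
        )
        pooled = scatter / (n.sum() - 2)
        delta = means[1] - means[0]
        scale = float(np.max(np.abs(means)))
        if np.linalg.norm(delta) <= 1e-12 * max(scale, 1.0):
            raise ValueError("degenerate model: identical class means")
        w, used_ridge = self._solve_direction(pooled, delta, d)
        solved = pooled + used_ridge * np.eye(d)
        v = float(w @ solved @ w)
        if v <= 0:
            raise LinAlgError("pooled covariance not positive along direction")
        w = w / np.sqrt(v)
        if w @ means[1] < w @ means[0]:  # positive class must score higher
            w = -w
        self.classes_ = classes
        self.means_ = means
        self.pooled_cov_ = pooled
        self.direction_ = w
        self.center_ = (means[0] + means[1]) / 2.0
        if self.priors == "uniform":
            self.priors_ = np.array([0.5, 0.5])
        else:
            self.priors_ = n / n.sum()
        self.proj_means_ = (means - self.center_) @ w
        self.ridge_used_ = used_ridge
        self.n_features_in_ = d
        return self

    def _solve_direction(self, pooled, delta, d):
        well_conditioned = np.linalg.cond(pooled) < 1e10
        if well_conditioned:
            try:
                w = solve(pooled, delta, assume_a="sym")
                if np.all(np.isfinite(w)):
                    return w, 0.0
            except LinAlgError:
                pass
        ridge = (
            1e-6 * np.trace(pooled) / d if self.ridge == "auto" else float(self.ridge)
        )
        if ridge <= 0:
            ridge = 1e-8
        repaired = pooled + ridge * np.eye(d)
        logger.warning("singular pooled covariance: ridge repair %.3g", ridge)
        try:
            return solve(repaired, delta, assume_a="sym"), ridge
        except LinAlgError as exc:
            raise LinAlgError("pooled covariance singular beyond ridge repair") from exc

    def transform(self, X) -> np.ndarray:
        """LD1 = w'(x - center), one value per sample."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.center_) @ self.direction_

    def decision_function(self, X) -> np.ndarray:
        """Log posterior odds of the positive class."""
        ld1 = self.transform(X)
        m0, m1 = self.proj_means_
        log_odds = (
            np.log(self.priors_[1] / self.priors_[0])
            - 0.5 * ((ld1 - m1) ** 2 - (ld1 - m0) ** 2)
        )
        return log_odds

    def predict_proba(self, X) -> np.ndarray:
        log_odds = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-log_odds))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        idx = (self.decision_function(X) >= 0).astype(int)
        return self.classes_[idx]

    def _check_fitted(self) -> None:
        if not hasattr(self, "direction_"):
            raise ValueError("model is not fitted")

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "kind": "lda",
            "classes": self.classes_.tolist(),
            "means": self.means_.tolist(),
            "pooled_cov": self.pooled_cov_.tolist(),
            "direction": self.direction_.tolist(),
            "center": self.center_.tolist(),
            "priors": self.priors_.tolist(),
            "params": {"ridge": self.ridge, "priors": self.priors},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LinearDiscriminantScorer":
        model = cls(**payload.get("params", {}))
        model.classes_ = np.asarray(payload["classes"])
        model.means_ = np.asarray(payload["means"], dtype=float)
        model.pooled_cov_ = np.asarray(payload["pooled_cov"], dtype=float)
        model.direction_ = np.asarray(payload["direction"], dtype=float)
        model.center_ = np.asarray(payload["center"], dtype=float)
        model.priors_ = np.asarray(payload["priors"], dtype=float)
        model.proj_means_ = (model.means_ - model.center_) @ model.direction_
        model.n_features_in_ = model.direction_.size
        model.ridge_used_ = 0.0
        return model


def fit_lda(
    expr: ExpressionMatrix,
    sheet: pd.DataFrame,
    panel: list[str],
    negative: str = "HC",
    positive: str = "SS",
    ridge="auto",
    priors: str = "proportional",
    sample_ids: list[str] | None = None,
) -> LinearDiscriminantScorer:
    """Fit the discriminant on panel expression of two cohorts.

    ``sample_ids`` restricts fitting (e.g. to a training split); only
    samples of the two cohorts are used.  Class 0 is ``negative``, class 1
    ``positive``; LD1 is oriented so the positive cohort scores higher.
    """
    sub = sheet[sheet["cohort"].isin([negative, positive])]
    if sample_ids is not None:
        sub = sub[sub["sample_id"].isin(set(sample_ids))]
    ids = [s for s in sub["sample_id"] if s in expr.values.columns]
    cohort = sub.set_index("sample_id").loc[ids, "cohort"]
    X = expr.subset_samples(ids).panel_matrix(panel)
    y = (cohort == positive).astype(int).to_numpy()
    model = LinearDiscriminantScorer(ridge=ridge, priors=priors).fit(X, y)
    model.panel_ = list(panel)
    model.class_labels_ = (negative, positive)
    return model


def project_ld1(model: LinearDiscriminantScorer, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample LD1 values for an expression matrix (panel taken from fit)."""
    X = expr.panel_matrix(model.panel_)
    return pd.Series(model.transform(X), index=expr.sample_ids, name="LD1")


def classify_lda(
    model: LinearDiscriminantScorer, expr: ExpressionMatrix
) -> tuple[pd.Series, pd.DataFrame]:
    """Posterior-argmax cohort labels and class posteriors per sample."""
    X = expr.panel_matrix(model.panel_)
    proba = model.predict_proba(X)
    labels = np.asarray(model.class_labels_, dtype=object)[proba.argmax(axis=1)]
    return (
        pd.Series(labels, index=expr.sample_ids, name="label"),
        pd.DataFrame(proba, index=expr.sample_ids, columns=list(model.class_labels_)),
    )
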