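"""The stacked meta-model: (LD1, risk score) -> L1-penalized logistic regression.

The two stage-1 scores become the features of a stacked dataset (label 1
for the target cohort, 0 for the reference).  The meta-model minimizes

    (1/n) * sum_i -loglik_i + lambda * (alpha * ||b||_1 + (1-alpha)/2 * ||b||_2^2)

with an unpenalized intercept, solved by cyclic coordinate descent on the
IRLS quadratic approximation (the glmnet algorithm), over a decreasing
lambda path from lambda_max (the smallest lambda with all slopes zero,
available in closed form from the null-model score) down four decades.
lambda is chosen at the minimum mean cross-validated binomial deviance over
stratified, seeded folds; the one-standard-error value is reported as well.
Features are standardized internally and the scaling stored, so fitted
coefficients transfer to new cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0  # logits beyond this are numerically saturated
_WEIGHT_FLOOR = 1e-5  # IRLS weight floor, as in glmnet


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood (probabilities clipped)."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def fit_penalized_logistic(
    Z: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    intercept: float | None = None,
    coef: np.ndarray | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Elastic-net logistic fit at a single lambda (features NOT standardized here).

    Returns (intercept, coefficients, converged).  Warm starts via
    ``intercept`` / ``coef``.  The intercept is never penalized.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = Z.shape
    b0 = float(np.log(y.mean() / (1 - y.mean()))) if intercept is None else float(intercept)
    b = np.zeros(d) if coef is None else np.asarray(coef, dtype=float).copy()
    converged = False
    inv_n = 1.0 / n
    for _ in range(max_iter):
        eta = b0 + Z @ b
        p = _sigmoid(eta)
        w = np.maximum(p * (1 - p), _WEIGHT_FLOOR)
        z_work = eta + (y - p) / w
        b0_old, b_old = b0, b.copy()
        wZ = w[:, None] * Z
        denom = wZ.T @ Z * inv_n  # d x d weighted Gram; diagonal feeds updates
        w_sum = float(w.sum()) * inv_n
        # inner cyclic coordinate descent on the weighted least-squares
        # problem; the quadratic need not be solved exactly, the outer IRLS
        # loop re-centres it anyway
        for _ in range(50):
            max_delta = 0.0
            resid = z_work - b0 - Z @ b
            for j in range(d):
                r_j = resid + Z[:, j] * b[j]
                rho = float(wZ[:, j] @ r_j) * inv_n
                new = _soft_threshold(rho, lam * alpha) / (denom[j, j] + lam * (1 - alpha))
                if new != b[j]:
                    resid = r_j - Z[:, j] * new
                    max_delta = max(max_delta, abs(new - b[j]))
                    b[j] = new
                else:
                    resid = r_j - Z[:, j] * b[j]
            new_b0 = b0 + float(w @ resid) * inv_n / w_sum
            max_delta = max(max_delta, abs(new_b0 - b0))
            resid += b0 - new_b0
            b0 = new_b0
            if max_delta < tol:
                break
        delta = abs(b0 - b0_old)
        if d:
            delta = max(delta, float(np.max(np.abs(b - b_old))))
        if delta < tol:
            converged = True
            break
    return b0, b, converged


def lambda_max(Z: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> float:
    """Smallest lambda at which every slope is zero (closed form at the null model)."""
    y = np.asarray(y, dtype=float)
    score = np.abs(Z.T @ (y - y.mean())) / len(y)
    a = max(alpha, 1e-3)  # glmnet convention for near-ridge mixing
    return float(score.max() / a)


def make_lambda_path(lmax: float, n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), n_lambda)


def build_stacked_dataset(
    per_dataset: list[tuple[pd.Series, pd.Series, pd.DataFrame]],
    target: str = "SS",
    reference: str = "HC",
    keep_cohorts: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Concatenate (LD1, RS) rows across datasets with binary labels.

    Each element of ``per_dataset`` is (LD1 series, risk-score series,
    sample sheet); the two series must cover identical samples.  Rows are
    restricted to the ``target`` and ``reference`` cohorts (label 1 / 0);
    ``keep_cohorts`` can add extra cohorts (label NaN) for later scoring,
    e.g. sepsis rows to be separated from septic shock.
    """
    keep = {target, reference} | set(keep_cohorts or ())
    frames = []
    for ld1, rs, sheet in per_dataset:
        if set(ld1.index) != set(rs.index):
            raise ValueError("LD1 and risk-score series cover different samples")
        if ld1.isna().any() or rs.isna().any():
            raise ValueError("missing feature values in stacked dataset")
        sub = sheet[sheet["cohort"].isin(keep)]
        ids = [s for s in sub["sample_id"] if s in ld1.index]
        cohorts = sub.set_index("sample_id").loc[ids, "cohort"]
        label = np.where(
            cohorts == target, 1.0, np.where(cohorts == reference, 0.0, np.nan)
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": ids,
                    "dataset_id": sub.set_index("sample_id").loc[ids, "dataset_id"].to_numpy(),
                    "cohort": cohorts.to_numpy(),
                    "LD1": ld1.loc[ids].to_numpy(),
                    "RS": rs.loc[ids].to_numpy(),
                    "label": label,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if out.empty:
        raise ValueError("stacked dataset is empty")
    return out


class SepxFindeR(BaseEstimator, ClassifierMixin):
    """L1-penalized logistic meta-model on the (LD1, RS) stacked features.

    Parameters
    ----------
    alpha : float
        Elastic-net mixing; 1 (default) is the pure L1 lasso.
    nfold : int
        Cross-validation folds (default 20); reduced, with a log message,
        when a class has fewer samples than folds.
    n_lambda : int
        Length of the lambda path (four decades below lambda_max).
    random_state : int
        Seed for the stratified folds.
    tol : float
        Coordinate-descent convergence tolerance.
    threshold : float
        Probability cutoff for :meth:`predict`; ties classify positive.
    lambda_rule : {"min", "1se"}
        Use the deviance-minimizing lambda or the one-SE rule.

    Attributes
    ----------
    intercept_, coef_ : fitted meta-model on standardized features.
    lambda_path_, cv_deviance_, cv_deviance_se_ : the CV curve.
    lambda_star_, lambda_1se_ : selected penalties.
    scale_mean_, scale_sd_ : stored feature standardization.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        nfold: int = 20,
        n_lambda: int = 100,
        random_state: int = 0,
        tol: float = 1e-7,
        threshold: float = 0.5,
        lambda_rule: str = "min",
    ):
        self.alpha = alpha
        self.nfold = nfold
        self.n_lambda = n_lambda
        self.random_state = random_state
        self.tol = tol
        self.threshold = threshold
        self.lambda_rule = lambda_rule

    # -- fitting -----------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean_) / self.scale_sd_

    def _fit_path(self, Z, y, path):
        """Warm-started coefficient path; returns (intercepts, coefs, truncated_at).

        Once the training fit saturates (deviance numerically zero under
        complete separation) smaller lambdas can only inflate the
        coefficients without changing any prediction, so the saturated
        solution is carried forward instead of being ground out.
        """
        b0 = float(np.log(y.mean() / (1 - y.mean())))
        b = np.zeros(Z.shape[1])
        b0s, bs = [], []
        truncated = None
        saturated = False
        for i, lam in enumerate(path):
            if not saturated:
                b0, b, _ = fit_penalized_logistic(
                    Z, y, lam, self.alpha, self.tol, intercept=b0, coef=b
                )
                if not np.all(np.isfinite(b)) or np.max(np.abs(b)) > 1e6:
                    truncated = i  # complete separation: coefficients diverge
                    logger.warning("lambda path truncated at index %d (separation)", i)
                    break
                train_dev = binomial_deviance(y, _sigmoid(b0 + Z @ b))
                if train_dev < 1e-5:
                    # fully separated fit: every sample's probability is
                    # within ~1e-5 of its label, so smaller lambdas cannot
                    # change any prediction worth cross-validating
                    saturated = True
            b0s.append(b0)
            bs.append(b.copy())
        return np.array(b0s), np.array(bs), truncated

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be samples x features")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        classes = np.unique(y)
        if classes.size != 2 or not set(classes) <= {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1 with both classes present")
        self.scale_mean_ = X.mean(axis=0)
        self.scale_sd_ = X.std(axis=0, ddof=0)
        if np.any(self.scale_sd_ <= 0):
            raise ValueError("constant feature cannot be standardized")
        Z = self._standardize(X)

        lmax = lambda_max(Z, y, self.alpha)
        path = make_lambda_path(lmax, self.n_lambda)
        b0s, bs, truncated = self._fit_path(Z, y, path)
        if truncated is not None:
            path = path[:truncated]
            if len(path) == 0:
                raise ValueError("no usable lambda: separation at lambda_max")
        self.path_truncated_ = truncated is not None

        n_min = int(min((y == 0).sum(), (y == 1).sum()))
        nfold = min(self.nfold, n_min)
        if nfold < self.nfold:
            logger.info("nfold reduced from %d to %d (class counts)", self.nfold, nfold)
        if nfold < 2:
            raise ValueError("need at least two samples per class for CV")
        self.nfold_used_ = nfold

        folds = StratifiedKFold(n_splits=nfold, shuffle=True, random_state=self.random_state)
        dev = np.full((nfold, len(path)), np.nan)
        for f, (tr, va) in enumerate(folds.split(Z, y)):
            fb0s, fbs, _ = self._fit_path(Z[tr], y[tr], path)
            for i in range(len(fb0s)):
                p_va = _sigmoid(fb0s[i] + Z[va] @ fbs[i])
                dev[f, i] = binomial_deviance(y[va], p_va)

        counts = np.sum(~np.isnan(dev), axis=0)
        mean_dev = np.full(len(path), np.inf)
        se_dev = np.full(len(path), np.inf)
        ok = counts > 1
        with np.errstate(invalid="ignore"):
            mean_dev[ok] = np.nanmean(dev[:, ok], axis=0)
            se_dev[ok] = np.nanstd(dev[:, ok], axis=0, ddof=1) / np.sqrt(counts[ok])
        i_star = int(np.argmin(mean_dev))
        within = np.flatnonzero(mean_dev <= mean_dev[i_star] + se_dev[i_star])
        i_1se = int(within.min()) if within.size else i_star  # largest lambda within 1 SE

        self.lambda_path_ = path
        self.cv_deviance_ = mean_dev
        self.cv_deviance_se_ = se_dev
        self.lambda_star_ = float(path[i_star])
        self.lambda_1se_ = float(path[i_1se])
        i_use = i_1se if self.lambda_rule == "1se" else i_star
        self.lambda_used_ = float(path[i_use])
        self.intercept_ = float(b0s[i_use])
        self.coef_ = bs[i_use].copy()
        self.intercept_path_ = b0s
        self.coef_path_ = bs
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        logger.info(
            "SepxFindeR fitted: lambda*=%.4g, coef=%s, nfold=%d",
            self.lambda_star_, np.round(self.coef_, 4).tolist(), nfold,
        )
        return self

    # -- prediction --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        return self.intercept_ + self._standardize(X) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "sepxfinder",
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "lambda_path": self.lambda_path_.tolist(),
            "cv_deviance": self.cv_deviance_.tolist(),
            "cv_deviance_se": self.cv_deviance_se_.tolist(),
            "lambda_star": self.lambda_star_,
            "lambda_1se": self.lambda_1se_,
            "scale_mean": self.scale_mean_.tolist(),
            "scale_sd": self.scale_sd_.tolist(),
            "params": self.get_params(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SepxFindeR":
        model = cls(**payload.get("params", {}))
        model.intercept_ = float(payload["intercept"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.lambda_path_ = np.asarray(payload["lambda_path"], dtype=float)
        model.cv_deviance_ = np.asarray(payload["cv_deviance"], dtype=float)
        model.cv_deviance_se_ = np.asarray(payload["cv_deviance_se"], dtype=float)
        model.lambda_star_ = float(payload["lambda_star"])
        model.lambda_1se_ = float(payload["lambda_1se"])
        model.scale_mean_ = np.asarray(payload["scale_mean"], dtype=float)
        model.scale_sd_ = np.asarray(payload["scale_sd"], dtype=float)
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = model.coef_.size
        return model


def fit_lasso_cv(
    data: pd.DataFrame,
    alpha: float = 1.0,
    nfold: int = 20,
    n_lambda: int = 100,
    seed: int = 0,
    tol: float = 1e-7,
) -> SepxFindeR:
    """Fit the meta-model on the labelled rows of a stacked dataset."""
    labelled = data.dropna(subset=["label"])
    X = labelled[["LD1", "RS"]].to_numpy()
    y = labelled["label"].to_numpy()
    return SepxFindeR(
        alpha=alpha, nfold=nfold, n_lambda=n_lambda, random_state=seed, tol=tol
    ).fit(X, y)


def predict_proba(model: SepxFindeR, features) -> np.ndarray:
    """Positive-class probability for (LD1, RS) rows."""
    X = features[["LD1", "RS"]].to_numpy() if isinstance(features, pd.DataFrame) else features
    return model.predict_proba(X)[:, 1]


def classify(model: SepxFindeR, features) -> np.ndarray:
    """Binary labels at the model's probability threshold (ties positive)."""
    X = features[["LD1", "RS"]].to_numpy() if isinstance(features, pd.DataFrame) else features
    return model.predict(X)
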