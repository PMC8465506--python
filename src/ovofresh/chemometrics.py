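"""PCA, NIPALS partial least squares, leave-one-out RMSECV and fit metrics.

PLS here is single-response (PLS1): the response is one freshness index
at a time.  Predictors and response are mean-centered but not
variance-scaled — derivative/SNV pretreatments already equalize scales,
and autoscaling is exposed as an option rather than a default.  "Full
cross-validation" means leave-one-out with re-centering inside every
fold, the standard chemometrics meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .spectra_io import ValidationError

__all__ = [
    "PCAModel",
    "PLSModel",
    "EvalReport",
    "pca_fit",
    "pca_transform",
    "pls_fit",
    "pls_predict",
    "loo_rmsecv",
    "rmsep",
    "pearson_r",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PCAModel:
    """Mean spectrum, orthonormal loadings and per-component variance shares."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray            # [n_variables x k]
    explained_ratio: np.ndarray     # length k, fractions of total variance


def pca_fit(X: np.ndarray, k: int) -> PCAModel:
    """Principal component analysis of a spectra matrix.

    Computed by singular value decomposition of the column-mean-centered
    matrix (numerically stabler than forming the covariance).  Component
    signs are fixed by making the largest-magnitude loading entry of each
    component positive, so score plots are reproducible.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if k < 1 or k > min(n - 1, p):
        raise ValidationError(
            f"k={k} out of range for {n} samples x {p} variables"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((s ** 2).sum())
    if total <= 0:
        raise ValidationError("constant matrix: total variance is zero")
    loadings = Vt[:k].T.copy()
    for j in range(k):
        peak = np.argmax(np.abs(loadings[:, j]))
        if loadings[peak, j] < 0:
            loadings[:, j] *= -1.0
    ratio = (s[:k] ** 2) / total
    return PCAModel(mean_spectrum=mean, loadings=loadings,
                    explained_ratio=ratio)


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the fitted components: ``(X - mean) @ loadings``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean_spectrum.size:
        raise ValidationError(
            f"{X.shape[1]} variables but the model was fit on "
            f"{model.mean_spectrum.size}"
        )
    return (X - model.mean_spectrum) @ model.loadings


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)

@dataclass(frozen=True)
class PLSModel:
    """A fitted single-response PLS regression.

    ``regression_vector`` collapses the sequential latent-variable model
    into one vector b so that predictions are
    ``y_mean + (X - x_mean) @ b``.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # W  [n_variables x n_lv]
    x_loadings: np.ndarray     # P  [n_variables x n_lv]
    y_loadings: np.ndarray     # q  [n_lv]
    regression_vector: np.ndarray
    x_scale: np.ndarray | None = None


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Extract up to n_lv components from centered data.

    With a single response the NIPALS inner loop converges in one pass,
    so each component is a closed-form step: w = X'y (normalized),
    t = Xw, p = X't/t't, q = y't/t't, then X and y are deflated.
    Extraction stops early once the residual covariance vanishes.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    y = yc.copy()
    scale0 = np.linalg.norm(Xc) * np.linalg.norm(yc) + 1e-300
    extracted = 0
    for a in range(n_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= 1e-13 * scale0:
            break
        w /= wn
        t = X @ w
        tt = t @ t
        if tt <= 0:
            break
        p_a = (X.T @ t) / tt
        q_a = (y @ t) / tt
        X -= np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        extracted = a + 1
    return W[:, :extracted], P[:, :extracted], q[:extracted], extracted


def pls_fit(X: np.ndarray, y: np.ndarray, n_lv: int,
            autoscale: bool = False) -> PLSModel:
    """Fit a PLS1 regression with ``n_lv`` latent variables.

    ``autoscale=True`` additionally divides each predictor column by its
    sample standard deviation (columns with zero variance are left
    unscaled).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError(f"{n} rows of X but {y.size} responses")
    if np.std(y) == 0:
        raise ValidationError("response has zero variance")
    if n_lv < 1 or n_lv > min(n - 1, p):
        raise ValidationError(
            f"n_lv={n_lv} out of range for {n} samples x {p} variables"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    scale = None
    if autoscale:
        scale = Xc.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        Xc = Xc / scale
    W, P, q, extracted = _nipals_pls1(Xc, y - y_mean, n_lv)
    if extracted == 0:
        raise ValidationError("no latent variable could be extracted")
    # b = W (P'W)^-1 q ; P'W is unit upper triangular for NIPALS
    b = W @ np.linalg.solve(P.T @ W, q)
    if scale is not None:
        b = b / scale
    return PLSModel(n_lv=extracted, x_mean=x_mean, y_mean=y_mean,
                    weights=W, x_loadings=P, y_loadings=q,
                    regression_vector=b, x_scale=scale)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses: ``y_mean + (X - x_mean) @ regression_vector``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValidationError(
            f"{X.shape[1]} variables but the model was fit on "
            f"{model.x_mean.size}"
        )
    return model.y_mean + (X - model.x_mean) @ model.regression_vector


def _loo_predictions(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Held-out predictions for every sample at 1..max_lv latent variables.

    Each fold refits from scratch on its remaining n-1 samples (with its
    own centering); all n folds are advanced together through the NIPALS
    recursion as one batched computation, which is algebraically
    identical to a per-fold loop.  The held-out spectrum is deflated
    through its fold's components, yielding its prediction at every
    intermediate LV count in one pass.  Returns an [n x max_lv] matrix.
    """
    n, p = X.shape
    # fold f = all samples except f, in original order
    keep = np.array([[j for j in range(n) if j != f] for f in range(n)])
    X3 = X[keep]                                   # [n x (n-1) x p]
    y2 = y[keep]                                   # [n x (n-1)]
    x_mean = X3.mean(axis=1, keepdims=True)
    y_mean = y2.mean(axis=1)
    X3 = X3 - x_mean
    y2 = y2 - y_mean[:, None]
    scale0 = np.linalg.norm(X3, axis=(1, 2)) * np.linalg.norm(y2, axis=1) \
        + 1e-300

    x_res = X - x_mean[:, 0, :]                    # held-out residuals
    pred = y_mean.copy()
    preds = np.empty((n, max_lv))
    for a in range(max_lv):
        w = np.matmul(y2[:, None, :], X3)[:, 0, :]
        wn = np.linalg.norm(w, axis=1)
        active = wn > 1e-13 * scale0
        w = np.where(active[:, None], w / np.where(wn > 0, wn, 1.0)[:, None],
                     0.0)
        t = np.matmul(X3, w[:, :, None])[:, :, 0]
        tt = (t * t).sum(axis=1)
        safe_tt = np.where(tt > 0, tt, 1.0)
        p_a = np.matmul(t[:, None, :], X3)[:, 0, :] / safe_tt[:, None]
        q_a = np.where(active, (y2 * t).sum(axis=1) / safe_tt, 0.0)
        X3 -= t[:, :, None] * p_a[:, None, :]
        y2 -= q_a[:, None] * t
        t_out = (x_res * w).sum(axis=1)
        pred = pred + t_out * q_a
        x_res = x_res - t_out[:, None] * p_a
        preds[:, a] = pred
    return preds


def loo_rmsecv(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """Leave-one-out RMSECV for each latent-variable count 1..max_lv.

    Every fold re-centers (and refits) on its own n-1 samples, so no
    information from the held-out spectrum enters its prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValidationError("leave-one-out needs at least 3 samples")
    if max_lv < 1 or max_lv > min(n - 2, p):
        raise ValidationError(
            f"max_lv={max_lv} out of range for LOO on {n} samples x "
            f"{p} variables"
        )
    preds = _loo_predictions(X, y, max_lv)
    errs = preds - y[:, None]
    return np.sqrt((errs ** 2).mean(axis=0))


# ---------------------------------------------------------------------------
# Metrics and report container

def rmsep(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error of prediction, in response units."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    return float(np.sqrt(((y_true - y_pred) ** 2).mean()))


def pearson_r(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Sample Pearson correlation between reference and predicted values."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


@dataclass
class EvalReport:
    """Evaluation summary for a calibration or discrimination run.

    Regression runs fill ``rmsep`` / ``r_prediction`` / ``rmsecv_by_lv`` /
    ``chosen_lv``; classification runs fill ``confusion`` (rows = true
    class, columns = predicted) and ``accuracy_pct``.  ``details`` holds
    run-specific extras (per-day counts, selected regions, ...).
    """

    rmsep: float | None = None
    r_prediction: float | None = None
    rmsecv_by_lv: np.ndarray | None = None
    chosen_lv: int | None = None
    confusion: pd.DataFrame | None = None
    accuracy_pct: float | None = None
    details: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        if self.rmsep is not None:
            out["rmsep"] = self.rmsep
        if self.r_prediction is not None:
            out["r_prediction"] = self.r_prediction
        if self.rmsecv_by_lv is not None:
            out["rmsecv_by_lv"] = [float(v) for v in self.rmsecv_by_lv]
        if self.chosen_lv is not None:
            out["chosen_lv"] = int(self.chosen_lv)
        if self.confusion is not None:
            out["confusion"] = {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.to_dict(orient="index").items()
            }
        if self.accuracy_pct is not None:
            out["accuracy_pct"] = self.accuracy_pct
        out.update(self.details)
        return out
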