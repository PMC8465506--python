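"""Storage-day discrimination: LDA on PCA scores.

The qualitative pipeline compresses the pretreated spectra to a handful
of principal-component scores (13 by default) and classifies storage day
with a shared-covariance Gaussian discriminant — classical PCA-LDA.
Pooling the within-class covariance across the seven day groups keeps
the decision boundaries linear; a small ridge regularization guards the
near-singular case of many score dimensions on few samples per class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import EvalReport, pca_fit, pca_transform
from .preprocess import PreprocessConfig, apply_preprocess
from .spectra_io import SpectraSet, SplitPlan, ValidationError

__all__ = [
    "LDAModel",
    "lda_fit",
    "lda_predict",
    "qualify_pipeline",
    "accuracy_from_counts",
]


@dataclass(frozen=True)
class LDAModel:
    """Class means, pooled within-class covariance and priors."""

    classes: tuple
    class_means: np.ndarray          # [n_classes x n_scores]
    pooled_covariance: np.ndarray    # [n_scores x n_scores], regularized
    priors: np.ndarray
    regularization: float


def lda_fit(scores: np.ndarray, labels: Sequence, regularization: float | None = None,
            priors: str = "equal") -> LDAModel:
    """Fit linear discriminant analysis on (PCA) scores.

    Covariance is pooled across classes and ridge-regularized by
    ``regularization * identity``; the default regularization is
    ``1e-6 * trace(cov)/n_scores``, enough to keep the pooled matrix
    positive definite when the score dimension approaches the per-class
    sample counts.  Priors are equal by default (balanced design) or
    empirical class frequencies with ``priors='empirical'``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    n, d = scores.shape
    if labels.size != n:
        raise ValidationError(f"{n} score rows but {labels.size} labels")
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValidationError("LDA needs at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    thin = [c for c, k in counts.items() if k < 2]
    if thin:
        raise ValidationError(f"class(es) {thin} have fewer than 2 samples")

    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        centered = scores[labels == c] - mu
        pooled += centered.T @ centered
    pooled /= (n - len(classes))

    if regularization is None:
        regularization = 1e-6 * np.trace(pooled) / d
    if regularization < 0:
        raise ValidationError("regularization must be >= 0")
    pooled = pooled + regularization * np.eye(d)
    eigvals = np.linalg.eigvalsh(pooled)
    if eigvals.min() <= 0:
        raise ValidationError(
            "pooled covariance singular; increase regularization "
            f"(smallest eigenvalue {eigvals.min():g})"
        )
    if priors == "equal":
        pr = np.full(len(classes), 1.0 / len(classes))
    elif priors == "empirical":
        pr = np.array([counts[c] / n for c in classes])
    else:
        raise ValidationError(f"unknown priors mode {priors!r}")
    return LDAModel(classes=classes, class_means=means,
                    pooled_covariance=pooled, priors=pr,
                    regularization=float(regularization))


def lda_predict(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Classify scores by the shared-covariance Gaussian discriminant.

    delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + log pi_k, with ties
    broken toward the earlier class label.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    d = model.class_means.shape[1]
    if scores.shape[1] != d:
        raise ValidationError(
            f"scores have {scores.shape[1]} dimensions, model expects {d}"
        )
    Sinv_mu = np.linalg.solve(model.pooled_covariance, model.class_means.T)
    lin = scores @ Sinv_mu                                     # [n x k]
    const = -0.5 * np.einsum("ij,ji->i", model.class_means, Sinv_mu) \
        + np.log(model.priors)
    delta = lin + const
    # argmax keeps the first (earlier-class) index on exact ties
    winners = np.argmax(delta, axis=1)
    return np.asarray([model.classes[i] for i in winners])


def accuracy_from_counts(per_class_counts: Sequence[tuple[int, int]]) -> float:
    """Overall percent correct from per-class (correct, total) pairs.

    Reported to one decimal, rounding half away from zero (so 66/70
    -> 94.3, 38/70 -> 54.3).
    """
    if not per_class_counts:
        raise ValidationError("empty count list")
    correct = sum(c for c, _ in per_class_counts)
    total = sum(t for _, t in per_class_counts)
    if total <= 0 or any(t <= 0 for _, t in per_class_counts):
        raise ValidationError("all class totals must be positive")
    pct = 100.0 * correct / total
    return float(np.floor(pct * 10 + 0.5) / 10)


def _per_day_counts(true_days: np.ndarray, pred_days: np.ndarray
                    ) -> dict[int, tuple[int, int]]:
    out = {}
    for day in sorted(set(true_days.tolist())):
        mask = true_days == day
        out[int(day)] = (int((pred_days[mask] == day).sum()), int(mask.sum()))
    return out


def qualify_pipeline(s: SpectraSet, cfg: PreprocessConfig, n_pcs: int,
                     split: SplitPlan, regularization: float | None = None
                     ) -> EvalReport:
    """Pretreat -> PCA (calibration only) -> LDA -> per-day accuracy report.

    The PCA model and the LDA discriminants are fit on calibration
    samples only; prediction samples are merely projected and
    classified, so the accuracy on them is an honest out-of-sample
    estimate.  The report mirrors the per-day train/test count layout of
    a storage-trial discrimination table.
    """
    if split.n_samples != s.n_samples:
        raise ValidationError("split does not cover this spectra set")
    cal = np.asarray(split.calibration_indices)
    pred = np.asarray(split.prediction_indices)
    pretreated = apply_preprocess(s, cfg, calibration_indices=cal)
    days = pretreated.metadata["storage_day"].to_numpy(dtype=int)

    pca = pca_fit(pretreated.absorbance[cal], n_pcs)
    scores_cal = pca_transform(pca, pretreated.absorbance[cal])
    scores_pred = pca_transform(pca, pretreated.absorbance[pred])

    lda = lda_fit(scores_cal, days[cal], regularization=regularization)
    yhat_cal = lda_predict(lda, scores_cal)
    yhat_pred = lda_predict(lda, scores_pred)

    train_counts = _per_day_counts(days[cal], yhat_cal)
    test_counts = _per_day_counts(days[pred], yhat_pred)
    classes = sorted(set(days.tolist()))
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(days[pred], yhat_pred):
        confusion.loc[int(t), int(p)] += 1

    return EvalReport(
        confusion=confusion,
        accuracy_pct=accuracy_from_counts(list(test_counts.values())),
        details={
            "n_pcs": n_pcs,
            "train_counts": train_counts,
            "test_counts": test_counts,
            "train_accuracy_pct": accuracy_from_counts(
                list(train_counts.values())),
            "explained_ratio": pca.explained_ratio.tolist(),
        },
    )
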