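"""Row-wise spectral pretreatments: SNV, MSC and Savitzky-Golay derivatives.

All pretreatments operate per spectrum (or against a reference computed
from calibration rows only), so applying them before a calibration/
prediction split leaks no information from the prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet, ValidationError

__all__ = [
    "PreprocessConfig",
    "snv",
    "msc",
    "sg_derivative",
    "apply_preprocess",
]

METHODS = ("none", "snv", "msc", "deriv1", "deriv2")


@dataclass(frozen=True)
class PreprocessConfig:
    """Pretreatment choice and Savitzky-Golay smoother settings.

    The derivative default (window 15 points, polynomial order 2) is
    ordinary chemometrics practice: plain finite differencing amplifies
    detector noise, so derivatives are taken through a local polynomial
    fit.  ``msc_reference='calibration_mean'`` computes the MSC reference
    from calibration rows only.
    """

    method: str = "deriv1"
    sg_window: int = 15
    sg_polyorder: int = 2
    msc_reference: str = "calibration_mean"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown preprocessing method {self.method!r}; "
                f"expected one of {METHODS}"
            )
        if self.sg_window % 2 == 0 or self.sg_window < self.sg_polyorder + 2:
            raise ValidationError(
                f"sg_window must be odd and >= sg_polyorder + 2, got "
                f"window={self.sg_window}, polyorder={self.sg_polyorder}"
            )
        order = {"deriv1": 1, "deriv2": 2}.get(self.method, 0)
        if order > self.sg_polyorder:
            raise ValidationError(
                f"derivative order {order} exceeds sg_polyorder "
                f"{self.sg_polyorder}"
            )


def snv(x: np.ndarray, sample_id: str | None = None) -> np.ndarray:
    """Standard normal variate: center a spectrum and scale to unit sd.

    Uses the sample (n-1 denominator) standard deviation.  Removes
    per-spectrum additive offsets and multiplicative scatter: for any
    a > 0, ``snv(a*x + b) == snv(x)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("snv needs a 1-D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        who = f" (sample {sample_id})" if sample_id else ""
        raise ValidationError(f"zero-variance spectrum{who}: SNV undefined")
    return (x - x.mean()) / sd


def snv_matrix(X: np.ndarray,
               sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Apply :func:`snv` to every row of a spectra matrix."""
    X = np.asarray(X, dtype=float)
    ids = sample_ids if sample_ids is not None else [None] * X.shape[0]
    return np.vstack([snv(row, sid) for row, sid in zip(X, ids)]) \
        if X.shape[0] else X.copy()


def msc(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference by ordinary least squares,
    ``x = a*reference + b``, and corrected to ``(x - b)/a``, undoing the
    per-spectrum affine scatter distortion.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 1 or reference.size != X.shape[1]:
        raise ValidationError("reference must match the spectra grid")
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise ValidationError("MSC reference has zero variance")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        a = (ref_c @ (x - x.mean())) / denom
        b = x.mean() - a * reference.mean()
        if abs(a) < 1e-12:
            raise ValidationError(
                f"degenerate MSC slope for row {i}: fitted a = {a:g}"
            )
        out[i] = (x - b) / a
    return out


def sg_derivative(X: np.ndarray, order: int,
                  cfg: PreprocessConfig, step: float = 1.0) -> np.ndarray:
    """Savitzky-Golay derivative of each spectrum row.

    The derivative is scaled by the grid increment ``step`` so units are
    absorbance per nm (or per cm^-1).  Edges are handled by evaluating
    the edge polynomial fits, so output length equals input length and
    downstream interval bookkeeping is unaffected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if order < 1 or order > cfg.sg_polyorder:
        raise ValidationError(
            f"derivative order {order} invalid for polyorder {cfg.sg_polyorder}"
        )
    if X.shape[1] < cfg.sg_window:
        raise ValidationError(
            f"spectrum has {X.shape[1]} points, fewer than the "
            f"{cfg.sg_window}-point smoothing window"
        )
    return savgol_filter(X, window_length=cfg.sg_window,
                         polyorder=cfg.sg_polyorder, deriv=order,
                         delta=step, axis=1, mode="interp")


def apply_preprocess(s: SpectraSet, cfg: PreprocessConfig,
                     calibration_indices: Sequence[int] | None = None
                     ) -> SpectraSet:
    """Apply the configured pretreatment to a whole spectra collection.

    SNV and derivatives are strictly per-row.  For MSC with
    ``msc_reference='calibration_mean'`` the reference spectrum is the
    mean of the calibration rows only and is reused unchanged for
    prediction rows, so the prediction set never influences the model.
    """
    if cfg.method == "none":
        return s.with_absorbance(s.absorbance.copy())
    if cfg.method == "snv":
        return s.with_absorbance(snv_matrix(s.absorbance, s.sample_ids))
    if cfg.method == "msc":
        if cfg.msc_reference == "calibration_mean":
            if calibration_indices is None or len(calibration_indices) == 0:
                raise ValidationError(
                    "MSC with calibration_mean reference needs non-empty "
                    "calibration_indices"
                )
            reference = s.absorbance[np.asarray(calibration_indices)].mean(axis=0)
        else:
            raise ValidationError(
                "supplied-reference MSC requires calling msc() directly"
            )
        return s.with_absorbance(msc(s.absorbance, reference))
    order = {"deriv1": 1, "deriv2": 2}[cfg.method]
    step = s.grid.uniform_step()
    return s.with_absorbance(sg_derivative(s.absorbance, order, cfg, step))
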