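"""Synergy interval PLS: interval partition, combinatorial search, evaluation.

Si-PLS splits the spectral axis into equidistant intervals, fits a PLS
calibration on every combination of two or three intervals, scores each
by leave-one-out RMSECV over a range of latent-variable counts, and
keeps the global minimizer.  The winning intervals are then reported as
wavelength regions, merging adjacent intervals into contiguous ranges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (EvalReport, loo_rmsecv, pearson_r, pls_fit,
                           pls_predict, rmsep)
from .spectra_io import ValidationError, WavelengthGrid

__all__ = [
    "IntervalPartition",
    "SiPLSResult",
    "partition",
    "enumerate_combos",
    "sipls_search",
    "evaluate_sipls",
    "format_regions",
]


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous half-open index ranges covering a variable axis."""

    n_variables: int
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for start, end in self.intervals:
            if start != pos or end <= start:
                raise ValidationError(
                    f"intervals must be contiguous half-open ranges, got "
                    f"{self.intervals}"
                )
            pos = end
        if pos != self.n_variables:
            raise ValidationError(
                f"intervals cover {pos} of {self.n_variables} variables"
            )
        lengths = [e - s for s, e in self.intervals]
        if max(lengths) - min(lengths) > 1:
            raise ValidationError("interval lengths may differ by at most 1")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def columns(self, combo: Sequence[int]) -> np.ndarray:
        """Variable indices of the given interval combination, in order."""
        return np.concatenate(
            [np.arange(*self.intervals[i]) for i in sorted(combo)]
        )


def partition(n_variables: int, n_intervals: int) -> IntervalPartition:
    """Split ``n_variables`` into ``n_intervals`` near-equal intervals.

    With remainder ``r = n_variables mod n_intervals``, the first r
    intervals get one extra variable (remainder-first rule), so lengths
    differ by at most one and the split is reproducible.
    """
    if n_intervals < 2 or n_intervals > n_variables:
        raise ValidationError(
            f"need 2 <= n_intervals <= n_variables, got "
            f"{n_intervals} for {n_variables} variables"
        )
    base, r = divmod(n_variables, n_intervals)
    bounds = [0]
    for i in range(n_intervals):
        bounds.append(bounds[-1] + base + (1 if i < r else 0))
    intervals = tuple(zip(bounds[:-1], bounds[1:]))
    return IntervalPartition(n_variables=n_variables, intervals=intervals)


def enumerate_combos(n_intervals: int,
                     sizes: Iterable[int] = (2, 3)) -> list[tuple[int, ...]]:
    """All unordered interval combinations of the given sizes.

    Deterministic order: ascending size, then lexicographic.  For 25
    intervals and sizes {2, 3} this is C(25,2) + C(25,3) = 2600 combos.
    """
    sizes = sorted(set(sizes))
    if not sizes:
        raise ValidationError("sizes must be non-empty")
    if any(s < 1 or s > n_intervals for s in sizes):
        raise ValidationError(
            f"combination sizes {sizes} invalid for {n_intervals} intervals"
        )
    combos: list[tuple[int, ...]] = []
    for size in sizes:
        combos.extend(itertools.combinations(range(n_intervals), size))
    return combos


@dataclass
class SiPLSResult:
    """Outcome of a synergy-interval search.

    ``table`` has one row per evaluated (combo, lv) pair; ``best_combo``
    attains the minimum RMSECV, with ties broken toward fewer latent
    variables and then the lexicographically smallest combination.
    """

    best_combo: tuple[int, ...]
    best_lv: int
    best_rmsecv: float
    selected_regions: list[tuple[float, float]]
    table: pd.DataFrame
    partition: IntervalPartition
    grid: WavelengthGrid

    def region_string(self) -> str:
        return format_regions(self.selected_regions)


def format_regions(regions: Sequence[tuple[float, float]]) -> str:
    """Render wavelength regions like ``"666-689, 905-965"`` (nm rounded)."""
    return ", ".join(f"{lo:.0f}–{hi:.0f}" for lo, hi in regions)


def combo_regions(part: IntervalPartition, combo: Sequence[int],
                  grid: WavelengthGrid) -> list[tuple[float, float]]:
    """Wavelength ranges of a combination, merging adjacent intervals."""
    merged: list[list[int]] = []
    for i in sorted(combo):
        if merged and merged[-1][1] == i - 1:
            merged[-1][1] = i
        else:
            merged.append([i, i])
    out = []
    for lo, hi in merged:
        start = part.intervals[lo][0]
        end = part.intervals[hi][1]
        out.append((float(grid.values[start]), float(grid.values[end - 1])))
    return out


def sipls_search(X_cal: np.ndarray, y_cal: np.ndarray, grid: WavelengthGrid,
                 n_intervals: int = 25, sizes: Iterable[int] = (2, 3),
                 max_lv: int = 15) -> SiPLSResult:
    """Exhaustive Si-PLS search over interval combinations.

    For every combination the member intervals' columns are concatenated
    and leave-one-out RMSECV is computed for 1..max_lv latent variables
    (capped at what the combination's size supports).  Deterministic
    given its inputs; sample order does not matter beyond floating-point
    round-off.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    n, p = X_cal.shape
    if p != len(grid):
        raise ValidationError(f"{p} columns but grid has {len(grid)} points")
    if np.std(y_cal) == 0:
        raise ValidationError("response has zero variance")
    part = partition(p, n_intervals)
    combos = enumerate_combos(n_intervals, sizes)

    rows = []
    best: tuple[float, int, tuple[int, ...]] | None = None
    for combo in combos:
        cols = part.columns(combo)
        lv_cap = min(max_lv, len(cols), n - 2)
        curve = loo_rmsecv(X_cal[:, cols], y_cal, lv_cap)
        for lv0, value in enumerate(curve):
            rows.append((combo, lv0 + 1, float(value)))
        k = int(np.argmin(curve))  # argmin returns the first (fewest-LV) tie
        cand = (float(curve[k]), k + 1, combo)
        if best is None or cand < best:
            best = cand
    assert best is not None
    best_rmsecv, best_lv, best_combo = best
    table = pd.DataFrame(rows, columns=["combo", "lv", "rmsecv"])
    return SiPLSResult(
        best_combo=best_combo,
        best_lv=best_lv,
        best_rmsecv=best_rmsecv,
        selected_regions=combo_regions(part, best_combo, grid),
        table=table,
        partition=part,
        grid=grid,
    )


def evaluate_sipls(result: SiPLSResult, X_cal: np.ndarray, y_cal: np.ndarray,
                   X_pred: np.ndarray, y_pred: np.ndarray) -> EvalReport:
    """Refit the winning model on calibration data and score the prediction set.

    Reports RMSEP and the prediction-set correlation R(t), the winning
    combination's RMSECV curve, and the selected wavelength regions.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_pred = np.asarray(X_pred, dtype=float)
    if X_cal.shape[1] != X_pred.shape[1]:
        raise ValidationError("calibration and prediction grids differ")
    cols = result.partition.columns(result.best_combo)
    model = pls_fit(X_cal[:, cols], y_cal, result.best_lv)
    yhat = pls_predict(model, X_pred[:, cols])
    curve = result.table[
        result.table["combo"] == result.best_combo
    ].sort_values("lv")["rmsecv"].to_numpy()
    return EvalReport(
        rmsep=rmsep(y_pred, yhat),
        r_prediction=pearson_r(y_pred, yhat),
        rmsecv_by_lv=curve,
        chosen_lv=result.best_lv,
        details={
            "selected_regions": result.selected_regions,
            "selected_regions_str": result.region_string(),
            "best_combo": list(result.best_combo),
            "best_rmsecv": result.best_rmsecv,
            "y_predicted": yhat.tolist(),
        },
    )
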