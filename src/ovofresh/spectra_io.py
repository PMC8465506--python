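"""Spectra containers, wavelength-grid construction and tabular I/O.

The pipeline's canonical interchange format is plain CSV: a wide spectra
table (rows = egg samples, columns = wavelengths) plus a sample-metadata
table keyed by ``sample_id``.  A small JSON sidecar preserves the grid
definition (unit, endpoints, step, dialect) across round trips.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraSet",
    "SplitPlan",
    "make_grid",
    "read_spectra",
    "write_spectra",
    "make_split",
]

#: Storage days of the cross-sectional shelf-life design (days).
STUDY_DAYS = (1, 3, 5, 7, 9, 11, 13)

#: Temperature groups: room temperature and refrigerated storage.
TEMP_GROUPS = ("25C", "4C")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class WavelengthGrid:
    """An ordered spectral axis in nm or cm^-1.

    Parameters
    ----------
    values
        Strictly increasing, finite, positive axis values.
    unit
        ``"nm"`` for wavelength or ``"cm-1"`` for wavenumber.
    step
        Declared uniform increment, or None for a non-uniform axis.
    dialect
        Grid construction convention used (see :func:`make_grid`), kept
        for provenance only.
    """

    values: np.ndarray
    unit: str = "nm"
    step: float | None = None
    dialect: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("grid values must be finite and positive")
        if values.size > 1 and np.any(np.diff(values) <= 0):
            raise ValidationError("grid values must be strictly increasing")
        if self.unit not in ("nm", "cm-1"):
            raise ValidationError(f"unknown grid unit {self.unit!r}")
        if self.step is not None and values.size > 1:
            dev = np.abs(np.diff(values) - self.step)
            if dev.max() >= 1e-9 * self.step:
                raise ValidationError(
                    "grid declared uniform but successive differences "
                    f"deviate from step by up to {dev.max():g}"
                )

    def __len__(self) -> int:
        return self.values.size

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def is_uniform(self) -> bool:
        if self.step is not None:
            return True
        if len(self) < 2:
            return True
        d = np.diff(self.values)
        return bool(np.abs(d - d.mean()).max() < 1e-9 * abs(d.mean()))

    def uniform_step(self) -> float:
        """Return the uniform increment, raising on a non-uniform axis."""
        if self.step is not None:
            return float(self.step)
        if not self.is_uniform:
            raise ValidationError("grid is not uniform")
        if len(self) < 2:
            raise ValidationError("grid with a single point has no step")
        return float(np.diff(self.values).mean())


def make_grid(
    start: float,
    stop: float,
    step: float,
    unit: str = "nm",
    dialect: str = "count_floor_steps",
) -> WavelengthGrid:
    """Build a uniform spectral axis under one of two endpoint conventions.

    Instrument software disagrees on whether the nominal start point is
    emitted.  Both conventions seen in practice are supported explicitly:

    ``count_floor_steps``
        ``floor((stop - start)/step)`` points at ``start + k*step`` for
        ``k = 1..floor`` (the start point itself is not emitted).
        550-985 nm at 0.21 nm gives 2071 variables.
    ``inclusive_points``
        ``1 + floor((stop - start)/step)`` points beginning at ``start``.
        4000-10000 cm^-1 at 3.856 cm^-1 gives 1557 variables.
    """
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    if stop <= start:
        raise ValidationError(f"stop ({stop}) must exceed start ({start})")
    n_steps = math.floor((stop - start) / step)
    if dialect == "count_floor_steps":
        values = start + step * np.arange(1, n_steps + 1)
    elif dialect == "inclusive_points":
        values = start + step * np.arange(0, n_steps + 1)
    else:
        raise ValidationError(f"unknown grid dialect {dialect!r}")
    return WavelengthGrid(values=values, unit=unit, step=step, dialect=dialect)


_META_COLUMNS = ["sample_id", "storage_day", "temp_group", "replicate"]


@dataclass
class SpectraSet:
    """Absorbance matrix on a shared wavelength axis with per-sample metadata.

    ``metadata`` is a DataFrame with columns ``sample_id`` (unique strings),
    ``storage_day`` (positive int, days), ``temp_group`` (``"25C"``/``"4C"``)
    and ``replicate`` (int), aligned row-for-row with ``absorbance``.
    """

    absorbance: np.ndarray
    grid: WavelengthGrid
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValidationError("absorbance must be 2-D (samples x variables)")
        if self.absorbance.shape[1] != len(self.grid):
            raise ValidationError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {len(self.grid)} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValidationError("absorbance contains missing/non-finite values")
        missing = [c for c in _META_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise ValidationError(f"metadata lacks columns {missing}")
        if len(self.metadata) != self.absorbance.shape[0]:
            raise ValidationError(
                f"{self.absorbance.shape[0]} spectra but "
                f"{len(self.metadata)} metadata rows"
            )
        ids = self.metadata["sample_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicated sample_id(s): {dupes}")
        bad = set(self.metadata["temp_group"]) - set(TEMP_GROUPS)
        if bad:
            raise ValidationError(f"unknown temp_group value(s): {sorted(bad)}")
        if (self.metadata["storage_day"].astype(int) <= 0).any():
            raise ValidationError("storage_day must be a positive integer")
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.metadata["sample_id"].astype(str).tolist()

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replacement matrix on the same grid."""
        return SpectraSet(absorbance=absorbance, grid=self.grid,
                          metadata=self.metadata.copy())

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            absorbance=self.absorbance[idx],
            grid=self.grid,
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint calibration/prediction index lists covering all samples."""

    calibration_indices: tuple[int, ...]
    prediction_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration_indices), set(self.prediction_indices)
        if cal & pred:
            raise ValidationError("calibration and prediction sets overlap")

    @property
    def n_samples(self) -> int:
        return len(self.calibration_indices) + len(self.prediction_indices)


def make_split(s: SpectraSet) -> SplitPlan:
    """Every-third-sample calibration/prediction split.

    Samples are stably sorted by (storage_day, replicate); every third
    sample in that order (1-based positions 3, 6, 9, ...) forms the
    prediction set and the remainder the calibration set.  With 15 eggs
    per day over 7 days this yields 70 calibration / 35 prediction
    spectra, 10/5 within each day subgroup.
    """
    if s.n_samples < 3:
        raise ValidationError("need at least 3 samples to split")
    order = s.metadata.sort_values(
        ["storage_day", "replicate"], kind="stable"
    ).index.to_numpy()
    pred = order[2::3]
    cal = np.setdiff1d(order, pred)
    return SplitPlan(
        calibration_indices=tuple(int(i) for i in np.sort(cal)),
        prediction_indices=tuple(int(i) for i in np.sort(pred)),
    )


def _sidecar_path(spectra_path: Path) -> Path:
    return spectra_path.with_suffix(spectra_path.suffix + ".grid.json")


def write_spectra(s: SpectraSet, spectra_path: str | Path,
                  metadata_path: str | Path) -> None:
    """Write a SpectraSet as wide spectra CSV + metadata CSV + grid sidecar.

    Floats are written with 17 significant digits so a read-back is
    bit-identical.
    """
    spectra_path = Path(spectra_path)
    metadata_path = Path(metadata_path)
    wide = pd.DataFrame(
        s.absorbance, columns=[format(v, ".17g") for v in s.grid.values]
    )
    wide.insert(0, "sample_id", s.sample_ids)
    wide.to_csv(spectra_path, index=False, float_format="%.17g")
    s.metadata[_META_COLUMNS].to_csv(metadata_path, index=False)
    sidecar = {
        "unit": s.grid.unit,
        "start": s.grid.start if len(s.grid) else None,
        "stop": s.grid.stop if len(s.grid) else None,
        "step": s.grid.step,
        "dialect": s.grid.dialect,
    }
    _sidecar_path(spectra_path).write_text(json.dumps(sidecar, indent=1))


def read_spectra(spectra_path: str | Path,
                 metadata_path: str | Path) -> SpectraSet:
    """Read a SpectraSet written by :func:`write_spectra`.

    The spectra table must be wide CSV with ``sample_id`` first and numeric
    monotone wavelength headers; the metadata table is joined on
    ``sample_id`` and fixes the sample order.
    """
    spectra_path = Path(spectra_path)
    wide = pd.read_csv(spectra_path, dtype={"sample_id": str},
                       float_precision="round_trip")
    if wide.columns[0] != "sample_id":
        raise ValidationError("first spectra column must be 'sample_id'")
    try:
        wavelengths = np.array([float(c) for c in wide.columns[1:]])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavelength header: {exc}") from exc
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})

    spec_ids = wide["sample_id"].tolist()
    if len(set(spec_ids)) != len(spec_ids):
        raise ValidationError("duplicated sample_id in spectra file")
    missing_in_meta = sorted(set(spec_ids) - set(meta["sample_id"]))
    missing_in_spec = sorted(set(meta["sample_id"]) - set(spec_ids))
    if missing_in_meta or missing_in_spec:
        raise ValidationError(
            f"sample_id mismatch between files: only in spectra "
            f"{missing_in_meta}, only in metadata {missing_in_spec}"
        )

    step = dialect = unit = None
    sidecar = _sidecar_path(spectra_path)
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        step, dialect = info.get("step"), info.get("dialect")
        unit = info.get("unit")
    grid = WavelengthGrid(values=wavelengths, unit=unit or "nm",
                          step=step, dialect=dialect)

    wide = wide.set_index("sample_id").loc[meta["sample_id"]]
    return SpectraSet(absorbance=wide.to_numpy(dtype=float), grid=grid,
                      metadata=meta)
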