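"""Destructive freshness measurements: weight loss, yolk index, Haugh unit.

These are the reference ("wet chemistry") quantities the spectral
calibration predicts.  The Haugh unit combines thick-albumen height h (mm)
and egg mass m (g) as ``HU = 100 * log10(h + 7.57 - 1.7 * m**0.37)``;
fresher eggs have taller albumen and higher HU.  USDA-style grading puts
the AA/A boundary at HU = 72 (boundary inclusive: HU = 72 is grade AA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import ValidationError

__all__ = [
    "EggRecord",
    "FreshnessIndices",
    "weight_loss",
    "yolk_index",
    "haugh_unit",
    "grade",
    "index_table",
    "mean_albumen_height",
    "GRADE_BOUNDARY_HU",
]

#: Haugh-unit boundary between grade AA and grade A.
GRADE_BOUNDARY_HU = 72.0


@dataclass(frozen=True)
class EggRecord:
    """One egg's destructive measurements.

    mass_original / mass_current in g (current mass is also the ``m`` of
    the Haugh formula); albumen and yolk heights and yolk diameter in mm.
    """

    mass_original: float
    mass_current: float
    albumen_height: float
    yolk_height: float
    yolk_diameter: float

    def __post_init__(self) -> None:
        vals = (self.mass_original, self.mass_current, self.albumen_height,
                self.yolk_height, self.yolk_diameter)
        if any(v <= 0 or not math.isfinite(v) for v in vals):
            raise ValidationError(f"all measurements must be positive: {self}")
        if self.mass_current > self.mass_original:
            raise ValidationError(
                f"stored mass {self.mass_current} g exceeds original mass "
                f"{self.mass_original} g"
            )

    def indices(self) -> "FreshnessIndices":
        hu = haugh_unit(self.albumen_height, self.mass_current)
        return FreshnessIndices(
            haugh_unit=hu,
            yolk_index=yolk_index(self.yolk_height, self.yolk_diameter),
            weight_loss=weight_loss(self.mass_original, self.mass_current),
            grade=grade(hu),
        )


@dataclass(frozen=True)
class FreshnessIndices:
    """Derived freshness values for one egg."""

    haugh_unit: float
    yolk_index: float
    weight_loss: float
    grade: str


def weight_loss(w_org: float, w_tst: float) -> float:
    """Percent mass lost relative to the fresh egg.

    ``WR% = (W_org - W_tst) / W_org * 100``; driven by water and CO2
    escaping through shell pores, so it can only grow during storage.
    """
    if w_org <= 0:
        raise ValidationError(f"original mass must be positive, got {w_org}")
    if w_tst > w_org:
        raise ValidationError(
            f"stored mass {w_tst} g exceeds original mass {w_org} g "
            "(evaporation cannot add mass)"
        )
    return 100.0 * (w_org - w_tst) / w_org


def yolk_index(yolk_height: float, yolk_diameter: float) -> float:
    """Yolk height over yolk diameter; the yolk flattens as the egg ages."""
    if yolk_height <= 0 or yolk_diameter <= 0:
        raise ValidationError(
            f"yolk height/diameter must be positive, got "
            f"h={yolk_height}, d={yolk_diameter}"
        )
    return yolk_height / yolk_diameter


def haugh_unit(albumen_height: float, egg_mass: float) -> float:
    """Haugh unit from thick-albumen height (mm) and egg mass (g)."""
    if egg_mass <= 0:
        raise ValidationError(f"egg mass must be positive, got {egg_mass}")
    arg = albumen_height + 7.57 - 1.7 * egg_mass ** 0.37
    if arg <= 0:
        raise ValidationError(
            f"Haugh log argument non-positive (h={albumen_height} mm, "
            f"m={egg_mass} g gives {arg:g})"
        )
    return 100.0 * math.log10(arg)


def grade(hu: float) -> str:
    """USDA-style grade from the Haugh unit; HU >= 72 is AA, below is A."""
    if not math.isfinite(hu):
        raise ValidationError(f"Haugh unit must be finite, got {hu}")
    return "AA" if hu >= GRADE_BOUNDARY_HU else "A"


def mean_albumen_height(h1: float, h2: float, h3: float) -> float:
    """Average of the three albumen-height readings taken around the yolk."""
    return (h1 + h2 + h3) / 3.0


def _trend_r2(day_means: pd.Series) -> float:
    """Squared Pearson correlation of per-day means against storage day."""
    days = day_means.index.to_numpy(dtype=float)
    vals = day_means.to_numpy(dtype=float)
    if len(vals) < 2 or np.std(vals) == 0 or np.std(days) == 0:
        return float("nan")
    return float(np.corrcoef(days, vals)[0, 1] ** 2)


def index_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-day, per-group summary of the three freshness indices.

    ``records`` needs columns ``storage_day``, ``temp_group``,
    ``haugh_unit``, ``yolk_index``, ``weight_loss`` (one row per egg).
    Returns a table of mean and sd per (day, group) cell, with one extra
    row per group holding the squared Pearson correlation of the per-day
    means against storage day (reported as NaN when undefined, e.g. a
    flat trend).
    """
    needed = {"storage_day", "temp_group",
              "haugh_unit", "yolk_index", "weight_loss"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"records lack columns {sorted(missing)}")
    out_rows = []
    for group, sub in records.groupby("temp_group", sort=True):
        counts = sub.groupby("storage_day").size()
        if (counts < 2).any():
            thin = counts[counts < 2].index.tolist()
            raise ValidationError(
                f"group {group}: day(s) {thin} have fewer than 2 eggs"
            )
        means = sub.groupby("storage_day")[
            ["haugh_unit", "yolk_index", "weight_loss"]].mean()
        sds = sub.groupby("storage_day")[
            ["haugh_unit", "yolk_index", "weight_loss"]].std(ddof=1)
        for day in means.index:
            out_rows.append({
                "temp_group": group, "storage_day": int(day),
                **{f"{c}_mean": means.loc[day, c] for c in means.columns},
                **{f"{c}_sd": sds.loc[day, c] for c in sds.columns},
            })
        out_rows.append({
            "temp_group": group, "storage_day": None,
            **{f"{c}_mean": _trend_r2(means[c]) for c in means.columns},
        })
    table = pd.DataFrame(out_rows)
    table["row"] = np.where(table["storage_day"].isna(), "R2", "day")
    return table
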