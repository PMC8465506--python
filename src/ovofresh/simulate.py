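"""Synthetic egg storage trial: freshness trajectories and vis-NIR spectra.

The generator emulates a two-regime shelf-life study: 15 eggs per
storage day (1, 3, ..., 13 days) at room temperature (25 °C, regime A)
and refrigerated (4 °C, regime B).  Per-day Haugh unit, yolk index and
weight-loss distributions follow the published trajectory tables for
each regime (monotone decline of HU/YI and fast weight loss at 25 °C;
irregular HU/YI and slow weight loss at 4 °C).

Spectra are diffuse-transmittance absorbance on a 550-985 nm grid:
a smooth baseline plus Gaussian absorption bands whose amplitudes are
linear in the egg's freshness indices, degraded by the artifact family
scatter correction is designed for (per-sample multiplicative and
additive scatter), a smooth per-egg structure term (shell-to-shell
variability unrelated to freshness), and white detector noise.  All
ground truth (indices, scatter draws, informative variables) is kept in
a :class:`SimTruth` record so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freshness import FreshnessIndices, grade
from .spectra_io import (STUDY_DAYS, SpectraSet, ValidationError,
                         WavelengthGrid, make_grid)

__all__ = [
    "AbsorptionBand",
    "SimConfig",
    "SimTruth",
    "simulate_indices",
    "simulate_spectrum",
    "generate_dataset",
    "INDEX_TABLE",
]

# Per-day (mean, sd) of the three freshness indices in each storage regime:
# the trajectory the generator reproduces.  Regime A (25 °C) declines
# steadily and loses weight fast; regime B (4 °C) drifts irregularly in
# HU/YI and loses weight slowly.
INDEX_TABLE: dict[str, dict[int, dict[str, tuple[float, float]]]] = {
    "A": {
        1:  {"hu": (84.94, 4.05), "yi": (0.36, 0.041), "wr": (0.117, 0.0246)},
        3:  {"hu": (81.75, 4.59), "yi": (0.32, 0.11),  "wr": (0.637, 0.055)},
        5:  {"hu": (80.01, 1.85), "yi": (0.32, 0.042), "wr": (0.954, 0.132)},
        7:  {"hu": (79.35, 4.09), "yi": (0.28, 0.038), "wr": (1.526, 0.281)},
        9:  {"hu": (70.95, 5.11), "yi": (0.26, 0.11),  "wr": (2.068, 0.299)},
        11: {"hu": (65.96, 5.62), "yi": (0.24, 0.032), "wr": (2.760, 0.446)},
        13: {"hu": (59.19, 1.87), "yi": (0.20, 0.031), "wr": (3.286, 0.467)},
    },
    "B": {
        1:  {"hu": (85.89, 4.73), "yi": (0.42, 0.027),  "wr": (0.173, 0.043)},
        3:  {"hu": (89.78, 2.65), "yi": (0.443, 0.027), "wr": (0.325, 0.066)},
        5:  {"hu": (92.75, 4.17), "yi": (0.433, 0.025), "wr": (0.469, 0.054)},
        7:  {"hu": (92.63, 2.76), "yi": (0.443, 0.02),  "wr": (0.66, 0.18)},
        9:  {"hu": (94.57, 3.25), "yi": (0.437, 0.034), "wr": (1.04, 0.14)},
        11: {"hu": (94.65, 2.98), "yi": (0.449, 0.02),  "wr": (1.22, 0.17)},
        13: {"hu": (92.05, 2.56), "yi": (0.430, 0.019), "wr": (1.52, 0.20)},
    },
}

# Reference index values subtracted before the index-to-amplitude map, so
# band amplitudes are perturbations around a common baseline spectrum.
_REF_HU, _REF_YI, _REF_WR = 75.0, 0.30, 1.5


@dataclass(frozen=True)
class AbsorptionBand:
    """A Gaussian absorption band with linear couplings to the egg state.

    ``coupling_hu/yi/wr`` are absorbance units per unit of index (per
    Haugh unit, per unit yolk index, per percent weight loss).
    ``coupling_deg`` couples the band to the latent degradation state
    (0 = fresh, 1 = fully aged at room temperature), the physicochemical
    progression — albumen liquefaction, water migration — that the
    destructive indices track only noisily.
    """

    center_nm: float
    width_nm: float
    coupling_hu: float = 0.0
    coupling_yi: float = 0.0
    coupling_wr: float = 0.0
    coupling_deg: float = 0.0

    def amplitude(self, idx: FreshnessIndices,
                  degradation: float = 0.0) -> float:
        return (self.coupling_hu * (idx.haugh_unit - _REF_HU)
                + self.coupling_yi * (idx.yolk_index - _REF_YI)
                + self.coupling_wr * (idx.weight_loss - _REF_WR)
                + self.coupling_deg * degradation)

    def shape(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.center_nm) / self.width_nm
        return np.exp(-0.5 * z * z)


# Default bands sit inside the wavelength regions where C-H/O-H/N-H
# overtones respond to albumen protein and water changes (650-777 nm and
# 899-965 nm), so interval selection has a physically placed truth.
DEFAULT_BANDS: tuple[AbsorptionBand, ...] = (
    AbsorptionBand(665.0, 15.0, coupling_hu=5.0e-4, coupling_yi=0.025,
                   coupling_wr=2.5e-4, coupling_deg=0.15),
    AbsorptionBand(760.0, 25.0, coupling_hu=2.5e-4, coupling_yi=0.05,
                   coupling_wr=7.5e-4, coupling_deg=-0.12),
    AbsorptionBand(930.0, 18.0, coupling_hu=5.0e-4, coupling_yi=0.01,
                   coupling_wr=1.25e-3, coupling_deg=0.18),
)

# Broad fixed components used for the per-egg smooth structure term.
_STRUCTURE_CENTERS = np.array([610.0, 700.0, 790.0, 880.0, 955.0])
_STRUCTURE_WIDTH = 60.0


@dataclass(frozen=True)
class Interferent:
    """An absorption band that varies egg to egg but carries no
    freshness information (e.g. shell pigment), so informative-region
    selection must learn to avoid it."""

    center_nm: float
    width_nm: float
    amplitude_sd: float


# Shell protoporphyrin-like pigment band in the visible, and a broad
# featureless absorber between the informative regions.
DEFAULT_INTERFERENTS: tuple[Interferent, ...] = (
    Interferent(585.0, 12.0, 0.04),
    Interferent(850.0, 20.0, 0.03),
)


def _default_grid() -> WavelengthGrid:
    return make_grid(550.0, 985.0, 0.21, unit="nm",
                     dialect="count_floor_steps")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic storage trial.

    scatter_sd_mult / scatter_sd_add are the log-sd of the per-sample
    multiplicative scatter factor and the sd of the additive offset;
    structure_sd scales a smooth per-egg spectral component unrelated to
    freshness (shell variability); noise_sd is white detector noise per
    variable, inflated by up to edge_noise_mult at the ends of the
    wavelength range where detector sensitivity drops; interferents are
    freshness-blind absorption bands (shell pigment); index_noise_scale
    multiplies the per-day index sds (0 collapses every egg onto the day
    means).
    """

    regime: str = "A"
    days: tuple[int, ...] = STUDY_DAYS
    eggs_per_day: int = 15
    grid: WavelengthGrid = field(default_factory=_default_grid)
    bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS
    interferents: tuple[Interferent, ...] = DEFAULT_INTERFERENTS
    edge_noise_mult: float = 20.0
    scatter_sd_mult: float = 0.08
    scatter_sd_add: float = 0.04
    structure_sd: float = 0.003
    noise_sd: float = 0.002
    index_noise_scale: float = 1.0
    degradation_span: float | None = None
    degradation_sd: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("A", "B"):
            raise ValidationError("regime must be 'A' (25C) or 'B' (4C)")
        if self.eggs_per_day < 2:
            raise ValidationError("eggs_per_day must be >= 2")
        sds = (self.scatter_sd_mult, self.scatter_sd_add,
               self.structure_sd, self.noise_sd, self.index_noise_scale,
               self.degradation_sd)
        if any(s < 0 for s in sds):
            raise ValidationError("all sd parameters must be >= 0")
        if self.edge_noise_mult < 1:
            raise ValidationError("edge_noise_mult must be >= 1")
        lo, hi = self.grid.start, self.grid.stop
        for b in self.bands:
            if not (lo <= b.center_nm <= hi):
                raise ValidationError(
                    f"band center {b.center_nm} nm outside grid "
                    f"[{lo:.2f}, {hi:.2f}]"
                )

    @property
    def temp_group(self) -> str:
        return "25C" if self.regime == "A" else "4C"

    @property
    def resolved_degradation_span(self) -> float:
        """How far the latent degradation state travels over the trial.

        Room-temperature storage ages an egg from fresh (0) to fully
        aged (1) over the 13-day trial; refrigeration nearly arrests
        the underlying physicochemistry, so the refrigerated default
        only reaches 0.04 even though slow evaporation continues.
        """
        if self.degradation_span is not None:
            return self.degradation_span
        return 1.0 if self.regime == "A" else 0.04

    def degradation_mean(self, day: int) -> float:
        first, last = min(self.days), max(self.days)
        if last == first:
            return 0.0
        return self.resolved_degradation_span * (day - first) / (last - first)


@dataclass
class SimTruth:
    """Ground truth bookkeeping for one generated dataset."""

    indices: list[FreshnessIndices]
    scatter_mult: np.ndarray
    scatter_add: np.ndarray
    informative_mask: np.ndarray    # bool per variable: under a planted band

    def __post_init__(self) -> None:
        if not self.informative_mask.any():
            raise ValidationError("informative mask is empty")


def simulate_indices(day: int, regime: str, rng: np.random.Generator,
                     index_noise_scale: float = 1.0,
                     strict: bool = True) -> FreshnessIndices:
    """Draw one egg's freshness indices for a storage day and regime.

    Each index is normal around the regime's per-day mean with the
    per-day sd (times ``index_noise_scale``); weight loss is truncated
    at 0.  With ``strict=False`` a day outside the trial design falls
    back to the nearest designed day.
    """
    table = INDEX_TABLE[regime]
    if day not in table:
        if strict:
            raise ValidationError(
                f"day {day} outside the trial design {sorted(table)}"
            )
        day = min(table, key=lambda d: abs(d - day))
    cell = table[day]
    hu = rng.normal(cell["hu"][0], cell["hu"][1] * index_noise_scale)
    yi = rng.normal(cell["yi"][0], cell["yi"][1] * index_noise_scale)
    wr = rng.normal(cell["wr"][0], cell["wr"][1] * index_noise_scale)
    wr = max(wr, 0.0)
    yi = max(yi, 1e-3)
    return FreshnessIndices(haugh_unit=hu, yolk_index=yi,
                            weight_loss=wr, grade=grade(hu))


def baseline_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth instrument/egg baseline: gentle slope plus a broad hump."""
    w = np.asarray(wavelengths, dtype=float)
    return (0.45 + 5e-4 * (w - 550.0)
            + 0.30 * np.exp(-0.5 * ((w - 800.0) / 180.0) ** 2))


def simulate_spectrum(idx: FreshnessIndices, cfg: SimConfig,
                      rng: np.random.Generator,
                      degradation: float = 0.0
                      ) -> tuple[np.ndarray, float, float]:
    """One egg's absorbance spectrum given its freshness state.

    Returns ``(spectrum, scatter_mult, scatter_add)``.  The clean
    spectrum is baseline + state-coupled bands + smooth per-egg
    structure; scatter multiplies then shifts it, and white noise is
    added last.  ``degradation`` is the egg's latent aging state (see
    :class:`AbsorptionBand`).
    """
    w = cfg.grid.values
    clean = baseline_spectrum(w)
    for band in cfg.bands:
        clean = clean + band.amplitude(idx, degradation) * band.shape(w)
    for intf in cfg.interferents:
        amp = rng.normal(0.0, intf.amplitude_sd)
        clean = clean + amp * np.exp(
            -0.5 * ((w - intf.center_nm) / intf.width_nm) ** 2)
    if cfg.structure_sd > 0:
        amps = rng.normal(0.0, cfg.structure_sd, size=_STRUCTURE_CENTERS.size)
        for c, a in zip(_STRUCTURE_CENTERS, amps):
            clean = clean + a * np.exp(-0.5 * ((w - c) / _STRUCTURE_WIDTH) ** 2)
    mult = float(np.exp(rng.normal(0.0, cfg.scatter_sd_mult))) \
        if cfg.scatter_sd_mult > 0 else 1.0
    add = float(rng.normal(0.0, cfg.scatter_sd_add)) \
        if cfg.scatter_sd_add > 0 else 0.0
    spectrum = clean * mult + add
    if cfg.noise_sd > 0:
        # detector sensitivity drops toward the range edges, so white
        # noise grows there (up to edge_noise_mult at the endpoints)
        ramp = (np.clip((610.0 - w) / 60.0, 0.0, 1.0)
                + np.clip((w - 955.0) / 30.0, 0.0, 1.0))
        sd = cfg.noise_sd * (1.0 + (cfg.edge_noise_mult - 1.0) * ramp)
        spectrum = spectrum + rng.normal(0.0, 1.0, size=w.size) * sd
    return spectrum, mult, add


def _back_solve_destructive(idx: FreshnessIndices, rng: np.random.Generator
                            ) -> dict[str, float]:
    """Destructive measurements consistent with the drawn indices.

    Original mass and yolk diameter are free anatomical draws; stored
    mass, albumen height and yolk height are solved so that the
    weight-loss, Haugh and yolk-index formulas reproduce the drawn
    values exactly.
    """
    w_org = float(np.clip(rng.normal(60.0, 2.0), 48.0, 75.0))
    w_tst = w_org * (1.0 - idx.weight_loss / 100.0)
    albumen = 10.0 ** (idx.haugh_unit / 100.0) - 7.57 + 1.7 * w_tst ** 0.37
    d_yolk = float(np.clip(rng.normal(40.0, 1.5), 32.0, 48.0))
    h_yolk = idx.yolk_index * d_yolk
    return {
        "mass_original_g": w_org,
        "mass_current_g": w_tst,
        "albumen_height_mm": albumen,
        "yolk_height_mm": h_yolk,
        "yolk_diameter_mm": d_yolk,
    }


def generate_dataset(cfg: SimConfig
                     ) -> tuple[SpectraSet, pd.DataFrame, SimTruth]:
    """Generate a full storage-trial dataset under one regime.

    Returns the spectra collection, the destructive-measurement table
    (from which the freshness formulas recover the drawn indices
    exactly) and the ground-truth record.  Deterministic given
    ``cfg.seed``; all randomness flows through a single generator.
    """
    rng = np.random.default_rng(cfg.seed)
    w = cfg.grid.values
    rows_meta, rows_destr, spectra = [], [], []
    indices: list[FreshnessIndices] = []
    mults, adds = [], []
    for day in cfg.days:
        for rep in range(1, cfg.eggs_per_day + 1):
            idx = simulate_indices(day, cfg.regime, rng,
                                   cfg.index_noise_scale)
            degradation = cfg.degradation_mean(day) \
                + rng.normal(0.0, cfg.degradation_sd)
            spec, mult, add = simulate_spectrum(idx, cfg, rng, degradation)
            sid = f"{cfg.regime}_d{day:02d}_r{rep:02d}"
            rows_meta.append({"sample_id": sid, "storage_day": day,
                              "temp_group": cfg.temp_group,
                              "replicate": rep})
            rows_destr.append({"sample_id": sid,
                               **_back_solve_destructive(idx, rng)})
            spectra.append(spec)
            indices.append(idx)
            mults.append(mult)
            adds.append(add)
    mask = np.zeros(w.size, dtype=bool)
    for band in cfg.bands:
        mask |= np.abs(w - band.center_nm) <= 2.0 * band.width_nm
    truth = SimTruth(indices=indices,
                     scatter_mult=np.array(mults),
                     scatter_add=np.array(adds),
                     informative_mask=mask)
    sset = SpectraSet(absorbance=np.vstack(spectra), grid=cfg.grid,
                      metadata=pd.DataFrame(rows_meta))
    return sset, pd.DataFrame(rows_destr), truth


def indices_frame(truth: SimTruth, metadata: pd.DataFrame) -> pd.DataFrame:
    """Tabulate the true indices next to the sample metadata."""
    df = metadata[["sample_id", "storage_day", "temp_group"]].copy()
    df["haugh_unit"] = [i.haugh_unit for i in truth.indices]
    df["yolk_index"] = [i.yolk_index for i in truth.indices]
    df["weight_loss"] = [i.weight_loss for i in truth.indices]
    df["grade"] = [i.grade for i in truth.indices]
    return df
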