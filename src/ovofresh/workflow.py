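"""End-to-end orchestration: config handling, the two analyses, reports.

``run_qualitative`` reproduces the storage-day discrimination table
(per-day train/test correct counts and overall percentages);
``run_quantitative`` reproduces the calibration summary (per response:
effective wavelength regions, latent-variable count, RMSEP, R(t)).
Both consume a :class:`PipelineConfig`, either simulating a trial or
loading spectra/metadata/destructive CSVs, and write their reports under
``output_dir``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .chemometrics import EvalReport
from .discriminate import qualify_pipeline
from .freshness import EggRecord
from .preprocess import PreprocessConfig, apply_preprocess
from .simulate import (AbsorptionBand, SimConfig, generate_dataset,
                       indices_frame)
from .sipls import evaluate_sipls, sipls_search
from .spectra_io import (SpectraSet, ValidationError, make_grid, make_split,
                         read_spectra)

__all__ = ["PipelineConfig", "run_qualitative", "run_quantitative",
           "load_inputs", "response_vector"]

log = logging.getLogger("ovofresh")

RESPONSES = ("hu", "yi", "wr")
_RESPONSE_COLUMN = {"hu": "haugh_unit", "yi": "yolk_index",
                    "wr": "weight_loss"}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``input_paths`` (dict
    with keys spectra, metadata, destructive) must be set.
    """

    simulate: SimConfig | None = None
    input_paths: dict[str, str] | None = None
    preprocess: PreprocessConfig | None = None
    n_pcs: int = 13
    n_intervals: int = 25
    combo_sizes: tuple[int, ...] = (2, 3)
    max_lv: int = 15
    responses: tuple[str, ...] = RESPONSES
    output_dir: str = "ovofresh_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_paths is None):
            raise ValidationError(
                "config must set exactly one of 'simulate' or 'input_paths'"
            )
        bad = set(self.responses) - set(RESPONSES)
        if bad:
            raise ValidationError(
                f"unknown response(s) {sorted(bad)}; expected {RESPONSES}"
            )

    @property
    def qualify_preprocess(self) -> PreprocessConfig:
        """Pretreatment for the discrimination analysis (default SNV).

        SNV removes multiplicative and additive scatter without
        amplifying the noisy grid-edge channels that derivative
        filtering inflates, which matters when the whole spectrum feeds
        PCA.
        """
        return self.preprocess or PreprocessConfig(method="snv")

    @property
    def quantify_preprocess(self) -> PreprocessConfig:
        """Pretreatment for Si-PLS calibration (default first derivative).

        Interval selection discards the noisy edge regions anyway, and
        the derivative sharpens overlapping bands for regression.
        """
        return self.preprocess or PreprocessConfig(method="deriv1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sim = None
        if "simulate" in raw:
            s = dict(raw["simulate"])
            if "grid" in s:
                g = s["grid"]
                s["grid"] = make_grid(g["start"], g["stop"], g["step"],
                                      g.get("unit", "nm"),
                                      g.get("dialect", "count_floor_steps"))
            if "bands" in s:
                s["bands"] = tuple(AbsorptionBand(**b) for b in s["bands"])
            if "days" in s:
                s["days"] = tuple(s["days"])
            sim = SimConfig(**s)
        pre = PreprocessConfig(**raw["preprocess"]) \
            if "preprocess" in raw else None
        qual = raw.get("qualify", {})
        quant = raw.get("quantify", {})
        return cls(
            simulate=sim,
            input_paths=raw.get("input"),
            preprocess=pre,
            n_pcs=int(qual.get("n_pcs", 13)),
            n_intervals=int(quant.get("n_intervals", 25)),
            combo_sizes=tuple(quant.get("combo_sizes", (2, 3))),
            max_lv=int(quant.get("max_lv", 15)),
            responses=tuple(quant.get("responses", RESPONSES)),
            output_dir=raw.get("output_dir", "ovofresh_out"),
            log_level=raw.get("log_level", "INFO"),
        )

    def resolved(self) -> dict[str, Any]:
        """Plain-dict view of the full configuration, for logging."""
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            out["simulate"]["grid"] = {
                "start": self.simulate.grid.start,
                "stop": self.simulate.grid.stop,
                "step": self.simulate.grid.step,
                "unit": self.simulate.grid.unit,
                "dialect": self.simulate.grid.dialect,
                "n_variables": len(self.simulate.grid),
            }
        return out


def load_inputs(cfg: PipelineConfig
                ) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate or load the spectra set and the per-sample index table."""
    if cfg.simulate is not None:
        log.info("simulating regime %s trial (seed %d)",
                 cfg.simulate.regime, cfg.simulate.seed)
        sset, destructive, truth = generate_dataset(cfg.simulate)
        indices = indices_frame(truth, sset.metadata)
    else:
        paths = cfg.input_paths
        for key in ("spectra", "metadata", "destructive"):
            if key not in paths:
                raise ValidationError(f"input paths lack '{key}'")
        log.info("loading spectra from %s", paths["spectra"])
        sset = read_spectra(paths["spectra"], paths["metadata"])
        destructive = pd.read_csv(paths["destructive"],
                                  dtype={"sample_id": str})
        indices = destructive_to_indices(destructive)
        indices = sset.metadata[["sample_id", "storage_day",
                                 "temp_group"]].merge(indices, on="sample_id")
    return sset, indices


def destructive_to_indices(destructive: pd.DataFrame) -> pd.DataFrame:
    """Apply the freshness formulas to a destructive-measurement table."""
    rows = []
    for _, r in destructive.iterrows():
        rec = EggRecord(
            mass_original=r["mass_original_g"],
            mass_current=r["mass_current_g"],
            albumen_height=r["albumen_height_mm"],
            yolk_height=r["yolk_height_mm"],
            yolk_diameter=r["yolk_diameter_mm"],
        )
        idx = rec.indices()
        rows.append({"sample_id": r["sample_id"],
                     "haugh_unit": idx.haugh_unit,
                     "yolk_index": idx.yolk_index,
                     "weight_loss": idx.weight_loss,
                     "grade": idx.grade})
    return pd.DataFrame(rows)


def response_vector(indices: pd.DataFrame, response: str) -> np.ndarray:
    if response not in _RESPONSE_COLUMN:
        raise ValidationError(f"unknown response {response!r}")
    return indices[_RESPONSE_COLUMN[response]].to_numpy(dtype=float)


def _outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_qualitative(cfg: PipelineConfig) -> EvalReport:
    """Discrimination analysis: split, preprocess, PCA-LDA, count table."""
    logging.basicConfig(level=cfg.log_level)
    log.info("resolved config: %s", json.dumps(cfg.resolved(), default=str))
    sset, _ = load_inputs(cfg)
    split = make_split(sset)
    log.info("split: %d calibration / %d prediction",
             len(split.calibration_indices), len(split.prediction_indices))
    report = qualify_pipeline(sset, cfg.qualify_preprocess, cfg.n_pcs, split)
    out = _outdir(cfg)
    payload = report.to_dict()
    (out / "qualify_report.json").write_text(
        json.dumps(payload, indent=1, default=str))
    rows = []
    for day in sorted(report.details["train_counts"]):
        tr = report.details["train_counts"][day]
        te = report.details["test_counts"].get(day, (0, 0))
        rows.append({"storage_day": day,
                     "train": f"{tr[0]}/{tr[1]}", "test": f"{te[0]}/{te[1]}"})
    rows.append({"storage_day": "total_pct",
                 "train": report.details["train_accuracy_pct"],
                 "test": report.accuracy_pct})
    pd.DataFrame(rows).to_csv(out / "qualify_counts.csv", index=False)
    log.info("qualitative accuracy: train %.1f%% / test %.1f%%",
             report.details["train_accuracy_pct"], report.accuracy_pct)
    return report


def run_quantitative(cfg: PipelineConfig) -> pd.DataFrame:
    """Si-PLS calibration of each requested freshness index.

    Returns one summary row per response: effective spectral regions
    (nm), latent-variable count, RMSEP and R(t) on the prediction set.
    A failure in one response is logged and does not abort the others.
    """
    logging.basicConfig(level=cfg.log_level)
    log.info("resolved config: %s", json.dumps(cfg.resolved(), default=str))
    sset, indices = load_inputs(cfg)
    split = make_split(sset)
    cal = np.asarray(split.calibration_indices)
    pred = np.asarray(split.prediction_indices)
    pretreated = apply_preprocess(sset, cfg.quantify_preprocess,
                                  calibration_indices=cal)
    out = _outdir(cfg)
    rows = []
    for response in cfg.responses:
        try:
            y = response_vector(indices, response)
            log.info("Si-PLS search for %s: %d intervals, sizes %s, "
                     "max %d LVs", response, cfg.n_intervals,
                     cfg.combo_sizes, cfg.max_lv)
            result = sipls_search(pretreated.absorbance[cal], y[cal],
                                  pretreated.grid, cfg.n_intervals,
                                  cfg.combo_sizes, cfg.max_lv)
            report = evaluate_sipls(result, pretreated.absorbance[cal],
                                    y[cal], pretreated.absorbance[pred],
                                    y[pred])
            result.table.assign(
                combo=result.table["combo"].map(
                    lambda c: "+".join(map(str, c)))
            ).to_csv(out / f"sipls_{response}_table.csv", index=False)
            rows.append({
                "response": response,
                "effective_region_nm": result.region_string(),
                "n_lv": report.chosen_lv,
                "rmsecv": result.best_rmsecv,
                "rmsep": report.rmsep,
                "r_prediction": report.r_prediction,
            })
            log.info("%s: region %s, %d LVs, RMSEP %.5g, R(t) %.3f",
                     response, result.region_string(), report.chosen_lv,
                     report.rmsep, report.r_prediction)
        except ValidationError as exc:
            log.error("response %s failed: %s", response, exc)
            rows.append({"response": response, "error": str(exc)})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "quantify_summary.csv", index=False)
    (out / "quantify_summary.json").write_text(
        json.dumps(rows, indent=1, default=str))
    return summary
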