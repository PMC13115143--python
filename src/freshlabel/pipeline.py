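"""Pipeline orchestration: simulate → fit → calibrate → predict → validate.

Ties the stages together around CSV interfaces so a whole study can be
re-run from files: per-temperature kinetic fits, the Arrhenius law, the
ΔE→TVB-N calibration (built by merging colorimeter and TVB-N series on
(temperature, time, replicate)), and the validation table. Every numeric
constant a run uses ends up in the JSON run report.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .colorimetry import delta_e_series, read_colorimeter_csv
from .kinetics import (
    ArrheniusModel,
    KineticFit,
    TvbnObservation,
    fit_arrhenius,
    fit_first_order,
    read_tvbn_csv,
)
from .shelflife import (
    PUBLISHED_CALIBRATION,
    Calibration,
    ShelfLifeModel,
    calibrate_delta_e,
)
from .validation import (
    build_validation_table,
    read_validation_design_csv,
    write_validation_report,
)

logger = logging.getLogger("freshlabel")

__all__ = ["PipelineConfig", "run_pipeline", "fit_kinetics_study", "build_calibration"]

PRESETS = ("published", "fitted")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    tvbn_csv: Union[str, Path]
    colors_csv: Union[str, Path]
    validation_csv: Union[str, Path]
    out_dir: Union[str, Path]
    preset: str = "published"
    threshold: float = 30.0
    rounding: Optional[float] = 0.1  # None = full precision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.rounding is not None and self.rounding <= 0:
            raise ValueError(f"rounding must be positive or None, got {self.rounding}")


def fit_kinetics_study(
    observations: Sequence[TvbnObservation],
) -> tuple[list[KineticFit], ArrheniusModel]:
    """Per-temperature first-order fits plus the cross-temperature Arrhenius fit."""
    temps = sorted({o.temperature_C for o in observations})
    fits = [
        fit_first_order([o for o in observations if o.temperature_C == T])
        for T in temps
    ]
    return fits, fit_arrhenius(fits)


def build_calibration(
    tvbn: Sequence[TvbnObservation], colors_csv: Union[str, Path]
) -> Calibration:
    """ΔE→TVB-N calibration from matched colorimeter and TVB-N series.

    Label readings are reduced to ΔE vs their own t=0 baseline and merged
    with the TVB-N table on (temperature, time, replicate).
    """
    de = delta_e_series(read_colorimeter_csv(colors_csv))
    tv = pd.DataFrame(
        {
            "time_h": [o.time_h for o in tvbn],
            "temperature_C": [o.temperature_C for o in tvbn],
            "replicate": [o.replicate for o in tvbn],
            "tvbn": [o.tvbn for o in tvbn],
        }
    )
    merged = de.merge(tv, on=["time_h", "temperature_C", "replicate"])
    if merged.empty:
        raise ValueError("no (temperature, time, replicate) overlap between series")
    return calibrate_delta_e(list(zip(merged.delta_e, merged.tvbn)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write fit report, calibration, and
    validation table under ``config.out_dir``. Returns the run report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: preset=%s seed=%d", config.preset, config.seed)

    tvbn = read_tvbn_csv(config.tvbn_csv)
    fits, arrhenius = fit_kinetics_study(tvbn)
    fitted_calib = build_calibration(tvbn, config.colors_csv)

    if config.preset == "published":
        model = ShelfLifeModel.published()
        calib = PUBLISHED_CALIBRATION
    else:
        model = ShelfLifeModel.from_arrhenius(arrhenius, threshold=config.threshold)
        calib = fitted_calib

    design = read_validation_design_csv(config.validation_csv)
    records, summaries, within_10pct = build_validation_table(
        design, calib, model, round_to=config.rounding
    )
    write_validation_report(records, summaries, out_dir / "validation_report.csv")

    report = {
        "version": __version__,
        "config": {
            "preset": config.preset,
            "threshold": config.threshold,
            "rounding_h": config.rounding,
            "seed": config.seed,
        },
        "kinetics": {
            "per_temperature": [
                {
                    "temperature_C": f.temperature_C,
                    "k_per_h": f.k,
                    "a0_fit": f.a0_fit,
                    "r_squared": None if math.isnan(f.r_squared) else f.r_squared,
                    "n_points": f.n_points,
                    "degenerate": f.degenerate,
                }
                for f in fits
            ],
            "arrhenius": {
                "slope_K": arrhenius.slope_K,
                "intercept": arrhenius.intercept,
                "ea_J_per_mol": arrhenius.ea,
                "k0_per_h": arrhenius.k0,
                "r_squared": arrhenius.r_squared,
            },
        },
        "calibration_fitted": {
            "slope": fitted_calib.slope,
            "intercept": fitted_calib.intercept,
            "r_squared": fitted_calib.r_squared,
        },
        "model_used": {
            "k0_per_h": model.arrhenius.k0,
            "slope_K": model.arrhenius.slope_K,
            "threshold_mg_per_100g": model.threshold,
            "log_threshold": model.log_threshold,
            "calibration_slope": calib.slope,
            "calibration_intercept": calib.intercept,
        },
        "validation": {
            "n_records": len(records),
            "max_re_percent": max(r.re_percent for r in records),
            "all_within_10_percent": within_10pct,
            "summaries": [
                {
                    "temperature_C": s.temperature_C,
                    "mae_h": s.mae_h,
                    "rmse_h": s.rmse_h,
                    "n": s.n,
                }
                for s in summaries
            ],
        },
    }
    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline done: report at %s", report_path)
    return report
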