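"""Prediction-accuracy metrics and validation-table construction.

Quantifies how well the label-based shelf-life predictor matches observed
remaining shelf-life: relative error RE = |pred − obs|/obs × 100%, mean
absolute error (MAE) and root-mean-square error (RMSE) per storage
temperature, plus the Pearson correlation used for the ΔE–TVB-N
relationship.

The validation table mirrors the published layout: one row per
(temperature, sampling time) with the rounded prediction and its RE, and
per-temperature MAE/RMSE summaries computed from those rounded
predictions (matching how the printed table derives its summary columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .shelflife import Calibration, ShelfLifeModel, predict_from_label

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "relative_error",
    "mae",
    "rmse",
    "pearson_r",
    "build_validation_table",
    "read_validation_design_csv",
    "write_validation_report",
]


@dataclass(frozen=True)
class ValidationRecord:
    """One validation row: a prediction against an observed shelf-life."""

    temperature_C: float
    time_h: float
    delta_e: float
    predicted_h: float
    observed_h: float
    re_percent: float

    def __post_init__(self) -> None:
        if self.observed_h <= 0:
            raise ValueError(
                f"observed_h must be > 0 (RE denominator), got {self.observed_h}"
            )


@dataclass(frozen=True)
class ValidationSummary:
    """Per-temperature error summary. rmse_h >= mae_h always."""

    temperature_C: float
    mae_h: float
    rmse_h: float
    n: int


def relative_error(predicted: float, observed: float) -> float:
    """RE = |predicted − observed| / observed × 100, in percent."""
    if not math.isfinite(observed) or observed <= 0:
        raise ValueError(f"observed must be > 0, got {observed!r}")
    return abs(predicted - observed) / observed * 100.0


def mae(records: Sequence[ValidationRecord]) -> float:
    """Mean absolute error of predicted vs observed hours."""
    if not records:
        raise ValueError("empty record set")
    return float(np.mean([abs(r.predicted_h - r.observed_h) for r in records]))


def rmse(records: Sequence[ValidationRecord]) -> float:
    """Root-mean-square error of predicted vs observed hours."""
    if not records:
        raise ValueError("empty record set")
    return float(
        np.sqrt(np.mean([(r.predicted_h - r.observed_h) ** 2 for r in records]))
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >= 3 points, got {x.size}")
    if np.allclose(x, x[0], rtol=0.0, atol=1e-12) or np.allclose(
        y, y[0], rtol=0.0, atol=1e-12
    ):
        raise ValueError("constant series: correlation is undefined")
    return float(stats.pearsonr(x, y).statistic)


def build_validation_table(
    experiments: Iterable[Tuple[float, float, float, float]],
    calib: Calibration,
    model: ShelfLifeModel,
    round_to: float | None = 0.1,
) -> tuple[list[ValidationRecord], list[ValidationSummary], bool]:
    """Build a validation report from (temperature_C, time_h, ΔE, observed_h) rows.

    Predictions come from the label model; by default they are rounded to
    0.1 h before RE/MAE/RMSE are computed, matching the convention of the
    published table (pass ``round_to=None`` for full precision). Returns
    the records, per-temperature summaries, and a flag that is True when
    every record's RE is <= 10%.
    """
    rows = list(experiments)
    if not rows:
        raise ValueError("empty validation design")
    records: list[ValidationRecord] = []
    for temperature_C, time_h, delta_e, observed_h in rows:
        pred = predict_from_label(delta_e, temperature_C, calib, model).remaining_h
        if round_to is not None:
            pred = round(pred / round_to) * round_to
        records.append(
            ValidationRecord(
                temperature_C=temperature_C,
                time_h=time_h,
                delta_e=delta_e,
                predicted_h=pred,
                observed_h=observed_h,
                re_percent=relative_error(pred, observed_h),
            )
        )
    summaries = []
    for temp in sorted({r.temperature_C for r in records}):
        group = [r for r in records if r.temperature_C == temp]
        summaries.append(
            ValidationSummary(
                temperature_C=temp, mae_h=mae(group), rmse_h=rmse(group), n=len(group)
            )
        )
    within_10pct = all(r.re_percent <= 10.0 for r in records)
    return records, summaries, within_10pct


def read_validation_design_csv(
    path: Union[str, Path],
) -> list[Tuple[float, float, float, float]]:
    """Read a validation design CSV with columns
    ``temperature_C, time_h, delta_e, observed_h``."""
    df = pd.read_csv(path)
    required = {"temperature_C", "time_h", "delta_e", "observed_h"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        (float(r.temperature_C), float(r.time_h), float(r.delta_e), float(r.observed_h))
        for r in df.itertuples()
    ]


def write_validation_report(
    records: Sequence[ValidationRecord],
    summaries: Sequence[ValidationSummary],
    path: Union[str, Path],
) -> None:
    """Write the validation table and per-temperature summaries to CSV."""
    rec_df = pd.DataFrame([vars(r) for r in records])
    sum_df = pd.DataFrame([vars(s) for s in summaries])
    merged = rec_df.merge(
        sum_df[["temperature_C", "mae_h", "rmse_h"]], on="temperature_C", how="left"
    )
    merged.to_csv(path, index=False)
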