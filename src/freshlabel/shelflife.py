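"""Remaining shelf-life prediction from TVB-N or from label color change.

The remaining shelf-life of a product whose freshness index follows
first-order kinetics is the time left until the index reaches a spoilage
threshold:

    t_RSL = (ln(threshold) − ln(A)) / k(T)

with A the current TVB-N (mg/100 g), threshold 30 mg/100 g for shrimp,
and k(T) the Arrhenius rate. A colorimetric label whose ΔE tracks TVB-N
linearly (TVB-N = slope·ΔE + intercept) turns this into a label-based
predictor: read ΔE, map to TVB-N, divide by the rate.

Two model modes are provided. The *published* preset carries the study's
printed constants (k0 = 1.7×10⁹ h⁻¹, exponent −7091.4/T, numerator
constant 3.401, calibration 1.43·ΔE + 0.6) exactly as printed — note
3.401 is the rounded ln 30, and reproducing the published prediction
table requires using it verbatim. The *fitted* mode derives everything
from data via :mod:`freshlabel.kinetics` and uses full-precision
ln(threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

from .kinetics import ArrheniusModel, rate_at_temperature

__all__ = [
    "Calibration",
    "ShelfLifeModel",
    "PredictionResult",
    "PUBLISHED_CALIBRATION",
    "remaining_shelf_life",
    "calibrate_delta_e",
    "tvbn_from_delta_e",
    "predict_from_label",
]

#: Default spoilage threshold for shrimp TVB-N, mg/100 g.
DEFAULT_THRESHOLD = 30.0

#: Published Arrhenius constants of the shrimp spoilage model.
PUBLISHED_K0 = 1.7e9  # h^-1
PUBLISHED_SLOPE_K = -7091.4  # kelvin (= -Ea/R)
#: Published numerator constant, the rounded ln 30.
PUBLISHED_LOG_THRESHOLD = 3.401


@dataclass(frozen=True)
class Calibration:
    """Linear map from label ΔE to TVB-N: tvbn = slope·ΔE + intercept."""

    slope: float
    intercept: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(
                f"calibration slope must be > 0 for a spoilage-tracking label, "
                f"got {self.slope}"
            )


#: The published ΔE→TVB-N calibration line (R² = 0.88 as reported).
PUBLISHED_CALIBRATION = Calibration(slope=1.43, intercept=0.6, r_squared=0.88)


@dataclass(frozen=True)
class ShelfLifeModel:
    """Threshold-based remaining-shelf-life model.

    arrhenius     : temperature law for the spoilage rate k(T)
    threshold     : spoilage TVB-N, mg/100 g
    log_threshold : numerator constant of the shelf-life formula; the
                    published preset uses the printed rounded value 3.401,
                    fitted models use ln(threshold) at full precision.
    """

    arrhenius: ArrheniusModel
    threshold: float = DEFAULT_THRESHOLD
    log_threshold: float = math.log(DEFAULT_THRESHOLD)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if abs(self.log_threshold - math.log(self.threshold)) > 1e-3:
            raise ValueError(
                f"log_threshold {self.log_threshold} is not ln(threshold) "
                f"= {math.log(self.threshold):.6f} to within 1e-3"
            )

    @classmethod
    def published(cls) -> "ShelfLifeModel":
        """The study's printed constants, used verbatim."""
        return cls(
            arrhenius=ArrheniusModel.from_constants(
                k0=PUBLISHED_K0, slope_K=PUBLISHED_SLOPE_K
            ),
            threshold=DEFAULT_THRESHOLD,
            log_threshold=PUBLISHED_LOG_THRESHOLD,
        )

    @classmethod
    def from_arrhenius(
        cls, model: ArrheniusModel, threshold: float = DEFAULT_THRESHOLD
    ) -> "ShelfLifeModel":
        """Fitted-model mode: full-precision ln(threshold) numerator."""
        return cls(
            arrhenius=model, threshold=threshold, log_threshold=math.log(threshold)
        )


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of a shelf-life prediction.

    remaining_h is signed: negative once the estimated TVB-N exceeds the
    threshold. ``spoiled`` is exactly ``remaining_h <= 0``.
    """

    remaining_h: float
    tvbn_estimate: float
    spoiled: bool


def remaining_shelf_life(
    current_tvbn: float, temperature_C: float, model: ShelfLifeModel
) -> PredictionResult:
    """Hours until TVB-N reaches the spoilage threshold at constant temperature.

    remaining_h = (log_threshold − ln(current_tvbn)) / k(T); negative when
    the product is already past the threshold.
    """
    if not math.isfinite(current_tvbn) or current_tvbn <= 0:
        raise ValueError(f"current_tvbn must be > 0, got {current_tvbn!r}")
    k = rate_at_temperature(model.arrhenius, temperature_C)
    remaining = (model.log_threshold - math.log(current_tvbn)) / k
    return PredictionResult(
        remaining_h=remaining,
        tvbn_estimate=current_tvbn,
        spoiled=remaining <= 0.0,
    )


def calibrate_delta_e(pairs: Iterable[Tuple[float, float]]) -> Calibration:
    """Fit the ΔE→TVB-N line by ordinary least squares.

    ``pairs`` are (ΔE, tvbn) tuples; needs >= 3 pairs with non-constant ΔE.
    r_squared is the squared Pearson correlation.
    """
    data = list(pairs)
    if len(data) < 3:
        raise ValueError(f"need >= 3 calibration pairs, got {len(data)}")
    x = np.array([p[0] for p in data], dtype=float)
    y = np.array([p[1] for p in data], dtype=float)
    if np.allclose(x, x[0], rtol=0.0, atol=1e-12):
        raise ValueError("constant ΔE values: calibration slope is undefined")
    res = stats.linregress(x, y)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
    )


def tvbn_from_delta_e(delta_e: float, calib: Calibration) -> float:
    """TVB-N estimate (mg/100 g) for a label color change ΔE."""
    if not math.isfinite(delta_e) or delta_e < 0:
        raise ValueError(f"delta_e must be >= 0, got {delta_e!r}")
    return calib.slope * delta_e + calib.intercept


def predict_from_label(
    delta_e: float,
    temperature_C: float,
    calib: Calibration = PUBLISHED_CALIBRATION,
    model: ShelfLifeModel | None = None,
) -> PredictionResult:
    """Remaining shelf-life from a label reading: ΔE → TVB-N → t_RSL.

    Exactly the composition ``remaining_shelf_life(tvbn_from_delta_e(...))``.
    """
    if model is None:
        model = ShelfLifeModel.published()
    tvbn = tvbn_from_delta_e(delta_e, calib)
    return remaining_shelf_life(tvbn, temperature_C, model)
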