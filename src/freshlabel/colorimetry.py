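"""Colorimetric and film-property computations for intelligent freshness labels.

Covers the scalar color arithmetic the label workflow needs: CIE76 color
difference (ΔE) between CIELAB readings, pigment photodegradation
bookkeeping, the conventional ΔE perceptibility classification, and
gravimetric water-vapor permeability (WVP) of the label film.

All functions operate on plain scalars or the small dataclasses below;
colorimeter time series are read from / written to CSV via pandas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

__all__ = [
    "LabColor",
    "ColorObservation",
    "WvpInput",
    "delta_e",
    "degradation_rate",
    "degradation_reduction",
    "color_stability_class",
    "wvp",
    "delta_e_series",
    "read_colorimeter_csv",
    "write_delta_e_series",
]


@dataclass(frozen=True)
class LabColor:
    """A CIELAB color: lightness L* in [0, 100], a* (green-red), b* (blue-yellow)."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("L", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"LabColor.{name} must be finite, got {v!r}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")


@dataclass(frozen=True)
class ColorObservation:
    """One colorimeter reading of a label during storage."""

    time_h: float
    temperature_C: float
    color: LabColor
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError(f"time_h must be finite and >= 0, got {self.time_h}")


@dataclass(frozen=True)
class WvpInput:
    """Gravimetric water-vapor-permeability measurement of a label film.

    delta_m : mass gained by the desiccant cup (g), >= 0
    d       : film thickness (m)
    A       : permeable area (m^2)
    t       : elapsed time (s)
    delta_p : water-vapor pressure difference across the film (Pa)
    """

    delta_m: float
    d: float
    A: float
    t: float
    delta_p: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_m) or self.delta_m < 0:
            raise ValueError(f"delta_m must be >= 0, got {self.delta_m}")
        for name in ("d", "A", "t", "delta_p"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


def delta_e(reference: LabColor, sample: LabColor) -> float:
    """CIE76 color difference: Euclidean distance between two Lab colors.

    Symmetric, non-negative, zero iff the colors are identical.
    """
    return math.sqrt(
        (sample.L - reference.L) ** 2
        + (sample.a - reference.a) ** 2
        + (sample.b - reference.b) ** 2
    )


def degradation_rate(c0: float, ct: float) -> float:
    """Percent pigment degraded: (c0 - ct) / c0 * 100.

    c0 is the initial concentration (> 0), ct the concentration after
    exposure (>= 0). Returns a value in (-inf, 100]; 0 when nothing degraded.
    """
    if not math.isfinite(c0) or c0 <= 0:
        raise ValueError(f"initial concentration c0 must be > 0, got {c0!r}")
    if not math.isfinite(ct) or ct < 0:
        raise ValueError(f"concentration ct must be >= 0, got {ct!r}")
    return (c0 - ct) / c0 * 100.0


def degradation_reduction(rate_control: float, rate_treated: float) -> float:
    """Percentage-point reduction in degradation: control minus treated.

    Negative when the treated sample degrades more than the control.
    """
    for name, v in (("rate_control", rate_control), ("rate_treated", rate_treated)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must lie in [0, 100], got {v}")
    return rate_control - rate_treated


#: Perceptibility bands for the maximum ΔE a label exhibits during storage.
#: ΔE <= 2 is imperceptible to the eye, 2 < ΔE <= 3 a mild difference,
#: anything larger a noticeable difference.
_STABILITY_BOUNDS = ((2.0, "no_noticeable"), (3.0, "mild"))


def color_stability_class(max_delta_e: float) -> str:
    """Classify a label's maximum storage ΔE as color-stability category.

    Returns one of ``"no_noticeable"`` (ΔE <= 2), ``"mild"`` (2 < ΔE <= 3)
    or ``"noticeable"`` (ΔE > 3); both boundaries are inclusive on the
    milder side.
    """
    if not math.isfinite(max_delta_e) or max_delta_e < 0:
        raise ValueError(f"max_delta_e must be >= 0, got {max_delta_e!r}")
    for bound, label in _STABILITY_BOUNDS:
        if max_delta_e <= bound:
            return label
    return "noticeable"


def wvp(inp: WvpInput) -> float:
    """Water-vapor permeability (Δm·d)/(A·t·Δp), in g·m⁻¹·Pa⁻¹·s⁻¹."""
    return (inp.delta_m * inp.d) / (inp.A * inp.t * inp.delta_p)


# ---------------------------------------------------------------------------
# Colorimeter time series
# ---------------------------------------------------------------------------


def delta_e_series(observations: Iterable[ColorObservation]) -> pd.DataFrame:
    """ΔE of each reading relative to the t=0 reading of the same series.

    A series is one (temperature, replicate) pair; its earliest reading,
    which must be at time 0, is the reference color. Returns a DataFrame
    with columns ``time_h, temperature_C, replicate, delta_e`` sorted by
    temperature, replicate, time.
    """
    obs = sorted(observations, key=lambda o: (o.temperature_C, o.replicate, o.time_h))
    if not obs:
        raise ValueError("no color observations supplied")
    rows = []
    ref: LabColor | None = None
    key = None
    for o in obs:
        k = (o.temperature_C, o.replicate)
        if k != key:
            if o.time_h != 0:
                raise ValueError(
                    f"series (T={o.temperature_C} °C, replicate {o.replicate}) "
                    f"has no time-0 reference reading (first time is {o.time_h} h)"
                )
            key, ref = k, o.color
        rows.append(
            {
                "time_h": o.time_h,
                "temperature_C": o.temperature_C,
                "replicate": o.replicate,
                "delta_e": delta_e(ref, o.color),
            }
        )
    return pd.DataFrame(rows)


def read_colorimeter_csv(path: Union[str, Path]) -> list[ColorObservation]:
    """Read colorimeter readings from CSV with columns
    ``time_h, temperature_C, replicate, L, a, b``."""
    df = pd.read_csv(path)
    required = {"time_h", "temperature_C", "replicate", "L", "a", "b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        ColorObservation(
            time_h=float(r.time_h),
            temperature_C=float(r.temperature_C),
            color=LabColor(float(r.L), float(r.a), float(r.b)),
            replicate=str(r.replicate),
        )
        for r in df.itertuples()
    ]


def write_delta_e_series(series: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a ΔE series DataFrame (as produced by :func:`delta_e_series`) to CSV."""
    series.to_csv(path, index=False)
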