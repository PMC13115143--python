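"""First-order spoilage kinetics and the Arrhenius temperature law.

TVB-N (total volatile basic nitrogen) accumulates in spoiling seafood
approximately exponentially, A(t) = A0·exp(k·t). Fitting ln A against
time at each storage temperature yields a rate constant k(T); regressing
ln k on 1/T (kelvin) then gives the Arrhenius parameters — activation
energy Ea = −slope·R and pre-exponential factor k0 = exp(intercept).

Both regressions are ordinary least squares on the linearized model, the
standard practice in food-kinetics studies; R² is reported on the
linearized scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAS_CONSTANT",
    "ABSOLUTE_ZERO_C",
    "TvbnObservation",
    "KineticFit",
    "ArrheniusModel",
    "fit_first_order",
    "fit_arrhenius",
    "rate_at_temperature",
    "read_tvbn_csv",
]

#: Universal gas constant, J/(mol·K).
GAS_CONSTANT = 8.314

#: Offset between °C and kelvin.
ABSOLUTE_ZERO_C = -273.15


def celsius_to_kelvin(temperature_C: float) -> float:
    if temperature_C <= ABSOLUTE_ZERO_C:
        raise ValueError(f"temperature {temperature_C} °C is at or below absolute zero")
    return temperature_C + 273.15


@dataclass(frozen=True)
class TvbnObservation:
    """One TVB-N measurement: mg/100 g at a given storage time and temperature."""

    time_h: float
    temperature_C: float
    tvbn: float
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValueError(f"time_h must be finite and >= 0, got {self.time_h!r}")
        if not math.isfinite(self.tvbn) or self.tvbn <= 0:
            raise ValueError(
                f"tvbn must be > 0 (log-linearization requires it), got {self.tvbn!r}"
            )


@dataclass(frozen=True)
class KineticFit:
    """Per-temperature first-order fit: A(t) = a0_fit·exp(k·t).

    ``degenerate`` is set when the data carry no usable slope information
    (constant series); k is then 0 and r_squared is NaN.
    """

    temperature_C: float
    k: float
    a0_fit: float
    r_squared: float
    n_points: int
    degenerate: bool = False


@dataclass(frozen=True)
class ArrheniusModel:
    """Temperature law for the spoilage rate: k(T) = k0·exp(slope_K / T).

    slope_K is the slope of ln k vs 1/T (kelvin), so slope_K = −Ea/R;
    ea is in J/mol, k0 in h⁻¹. r_squared is NaN for models built directly
    from published constants rather than fitted.
    """

    slope_K: float
    intercept: float
    ea: float
    k0: float
    r_squared: float = float("nan")
    gas_constant: float = GAS_CONSTANT

    @classmethod
    def from_constants(cls, k0: float, slope_K: float) -> "ArrheniusModel":
        """Build a model from stated constants (k0 in h⁻¹, slope_K in kelvin)."""
        if k0 <= 0:
            raise ValueError(f"k0 must be > 0, got {k0}")
        return cls(
            slope_K=slope_K,
            intercept=math.log(k0),
            ea=-slope_K * GAS_CONSTANT,
            k0=k0,
        )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and r² of an ordinary least-squares line."""
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def fit_first_order(series: Iterable[TvbnObservation]) -> KineticFit:
    """Fit A(t) = A0·exp(k·t) to one temperature's TVB-N series.

    Ordinary least squares of ln(tvbn) on time; replicates enter as
    individual observations. Requires >= 3 distinct time points and a
    single temperature. A constant series yields a degenerate fit
    (k = 0, r² = NaN) rather than an error.
    """
    obs = list(series)
    if not obs:
        raise ValueError("empty TVB-N series")
    temps = {o.temperature_C for o in obs}
    if len(temps) > 1:
        raise ValueError(f"mixed temperatures in one series: {sorted(temps)}")
    times = np.array([o.time_h for o in obs], dtype=float)
    if len(set(times.tolist())) < 3:
        raise ValueError(
            f"need >= 3 distinct time points, got {len(set(times.tolist()))}"
        )
    log_a = np.log([o.tvbn for o in obs])
    if np.allclose(log_a, log_a[0], rtol=0.0, atol=1e-12):
        return KineticFit(
            temperature_C=obs[0].temperature_C,
            k=0.0,
            a0_fit=float(np.exp(log_a[0])),
            r_squared=float("nan"),
            n_points=len(obs),
            degenerate=True,
        )
    slope, intercept, r2 = _ols(times, log_a)
    return KineticFit(
        temperature_C=obs[0].temperature_C,
        k=slope,
        a0_fit=float(np.exp(intercept)),
        r_squared=r2,
        n_points=len(obs),
    )


def fit_arrhenius(fits: Sequence[KineticFit]) -> ArrheniusModel:
    """Fit ln k = intercept + slope_K·(1/T) across per-temperature fits.

    Requires >= 3 fits at distinct temperatures, all with k > 0. Returns
    the fitted slope and intercept together with the derived activation
    energy ea = −slope_K·R (J/mol) and pre-exponential k0 = exp(intercept).
    """
    usable = [f for f in fits if not f.degenerate]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 non-degenerate fits, got {len(usable)}")
    temps = [f.temperature_C for f in usable]
    if len(set(temps)) != len(temps):
        raise ValueError(f"duplicate temperatures: {sorted(temps)}")
    for f in usable:
        if f.k <= 0:
            raise ValueError(
                f"rate constant must be > 0 for Arrhenius fitting "
                f"(k={f.k} at {f.temperature_C} °C)"
            )
    inv_T = np.array([1.0 / celsius_to_kelvin(t) for t in temps])
    ln_k = np.log([f.k for f in usable])
    slope, intercept, r2 = _ols(inv_T, ln_k)
    return ArrheniusModel(
        slope_K=slope,
        intercept=intercept,
        ea=-slope * GAS_CONSTANT,
        k0=float(np.exp(intercept)),
        r_squared=r2,
    )


def rate_at_temperature(model: ArrheniusModel, temperature_C: float) -> float:
    """Spoilage rate constant k(T) = k0·exp(slope_K / T_kelvin), in h⁻¹.

    Strictly increasing in temperature for positive activation energy.
    """
    T = celsius_to_kelvin(temperature_C)
    return model.k0 * math.exp(model.slope_K / T)


def read_tvbn_csv(path: Union[str, Path]) -> list[TvbnObservation]:
    """Read TVB-N measurements from CSV with columns
    ``time_h, temperature_C, replicate, tvbn_mg_per_100g``."""
    df = pd.read_csv(path)
    required = {"time_h", "temperature_C", "replicate", "tvbn_mg_per_100g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return [
        TvbnObservation(
            time_h=float(r.time_h),
            temperature_C=float(r.temperature_C),
            tvbn=float(r.tvbn_mg_per_100g),
            replicate=str(r.replicate),
        )
        for r in df.itertuples()
    ]
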