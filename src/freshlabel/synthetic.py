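"""Synthetic data generator for the whole label-based shelf-life pipeline.

Emulates the storage study the models are fitted on, so every stage is
testable without laboratory data:

* TVB-N trajectories A(t) = A0·exp(k(T)·t) at the study's five storage
  temperatures and printed sampling schedules, with Arrhenius-governed
  rates, per-replicate initial values, and multiplicative lognormal
  measurement noise (keeps values positive and makes the log-linear OLS
  correctly specified).
* Label color readings whose ΔE from the fresh baseline tracks TVB-N
  through the inverse calibration line, moving along a fixed direction in
  Lab space plus per-channel Gaussian colorimeter noise. Real labels
  trace a curved red→blue→yellow path; only the scalar ΔE enters the
  analysis, so a straight path is an adequate and documented
  simplification.
* First-order pigment photobleaching series for UV-stability bookkeeping.
* Validation designs pairing a simulated label reading with the true
  remaining time until the underlying trajectory crosses the spoilage
  threshold.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .colorimetry import ColorObservation, LabColor, delta_e
from .kinetics import GAS_CONSTANT, ArrheniusModel, TvbnObservation, celsius_to_kelvin

__all__ = [
    "SimulationConfig",
    "DesignPoint",
    "simulate_tvbn_study",
    "simulate_label_readings",
    "simulate_photodegradation",
    "make_validation_design",
    "design_rows",
]

#: Sampling schedules of the storage study, hours, per temperature (°C).
DEFAULT_SCHEDULES: Dict[float, Tuple[float, ...]] = {
    0.0: tuple(float(t) for t in range(0, 241, 24)),
    4.0: tuple(float(t) for t in range(0, 193, 24)),
    12.0: tuple(float(t) for t in range(0, 64, 9)),
    20.0: tuple(float(t) for t in range(0, 43, 6)),
    28.0: tuple(float(t) for t in range(0, 25, 4)),
}

#: Validation sampling design: temperature °C → sampling times (h).
DEFAULT_VALIDATION_TIMES: Dict[float, Tuple[float, ...]] = {
    4.0: (24.0, 48.0, 72.0),
    10.0: (10.0, 26.0, 36.0),
    20.0: (10.0, 15.0, 20.0),
}

#: UV-stability photobleaching rates (h⁻¹) per label formulation; the
#: values reproduce the unshielded (GAB) and C-TiO2-shielded (GABT-0.05)
#: 24 h degradation percentages in the noiseless limit.
DEFAULT_PHOTOBLEACH_K: Dict[str, float] = {"GAB": 0.1723, "GABT-0.05": 0.0412}


def _unit(v: Tuple[float, float, float]) -> Tuple[float, float, float]:
    n = math.sqrt(sum(c * c for c in v))
    return (v[0] / n, v[1] / n, v[2] / n)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and design of the simulated storage study.

    Defaults are the study conditions: Ea = 58 958 J/mol, k0 = 1.7×10⁹ h⁻¹,
    A0 = 1.39 ± 0.06 mg/100 g, five temperatures with their printed
    schedules, three replicates, 5% lognormal noise on TVB-N, calibration
    line TVB-N = 1.43·ΔE + 0.6.
    """

    true_ea: float = 58958.0  # J/mol
    true_k0: float = 1.7e9  # h^-1
    true_a0: float = 1.39  # mg/100 g
    a0_sd: float = 0.06  # between-replicate spread of A0
    noise_sigma_ln: float = 0.05  # sd of ln-scale measurement noise
    temperatures_C: Tuple[float, ...] = (0.0, 4.0, 12.0, 20.0, 28.0)
    schedules: Dict[float, Tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )
    replicates: int = 3
    seed: int = 0
    calib_slope: float = 1.43
    calib_intercept: float = 0.6
    # Fresh anthocyanin label: light red. The color moves along a fixed
    # unit direction (darker, less red, more yellow) as TVB-N rises.
    baseline_lab: LabColor = LabColor(65.0, 20.0, 0.0)
    color_direction: Tuple[float, float, float] = (-1 / 3, -2 / 3, 2 / 3)
    color_noise_sd: float = 0.3
    photobleach_k: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHOTOBLEACH_K)
    )

    def __post_init__(self) -> None:
        if self.true_ea <= 0 or self.true_k0 <= 0 or self.true_a0 <= 0:
            raise ValueError("true_ea, true_k0 and true_a0 must be > 0")
        if self.noise_sigma_ln < 0 or self.color_noise_sd < 0 or self.a0_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if abs(sum(c * c for c in self.color_direction) - 1.0) > 1e-9:
            raise ValueError("color_direction must have unit Euclidean norm")
        for T in self.temperatures_C:
            sched = self.schedules.get(T)
            if sched is None:
                raise ValueError(f"no schedule for temperature {T} °C")
            if list(sched) != sorted(set(sched)) or sched[0] != 0:
                raise ValueError(
                    f"schedule for {T} °C must be strictly increasing from 0"
                )
        if any(k < 0 for k in self.photobleach_k.values()):
            raise ValueError("photobleach rates must be >= 0")

    def true_rate(self, temperature_C: float) -> float:
        """Ground-truth Arrhenius rate k(T), h⁻¹."""
        T = celsius_to_kelvin(temperature_C)
        return self.true_k0 * math.exp(-self.true_ea / (GAS_CONSTANT * T))

    def true_arrhenius(self) -> ArrheniusModel:
        """The generator's ground truth as an Arrhenius model object."""
        return ArrheniusModel.from_constants(
            k0=self.true_k0, slope_K=-self.true_ea / GAS_CONSTANT
        )


def simulate_tvbn_study(config: SimulationConfig) -> list[TvbnObservation]:
    """Simulate the multi-temperature TVB-N storage study.

    One observation per (temperature, time, replicate):
    value = A0_rep·exp(k(T)·t)·exp(ε), ε ~ N(0, noise_sigma_ln²), with
    A0_rep ~ N(true_a0, a0_sd) truncated below at 0.5. Deterministic for
    a fixed ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    out: list[TvbnObservation] = []
    for T in config.temperatures_C:
        k = config.true_rate(T)
        for rep in range(1, config.replicates + 1):
            if config.a0_sd > 0:
                a0 = max(0.5, rng.normal(config.true_a0, config.a0_sd))
            else:
                a0 = config.true_a0
            for t in config.schedules[T]:
                eps = rng.normal(0.0, config.noise_sigma_ln) if config.noise_sigma_ln > 0 else 0.0
                out.append(
                    TvbnObservation(
                        time_h=float(t),
                        temperature_C=float(T),
                        tvbn=a0 * math.exp(k * t) * math.exp(eps),
                        replicate=str(rep),
                    )
                )
    return out


def simulate_label_readings(
    tvbn_series: Iterable[TvbnObservation], config: SimulationConfig
) -> list[ColorObservation]:
    """Label color readings coupled to a TVB-N series.

    The true color change is ΔE = max(0, (TVB-N − intercept)/slope), the
    inverse of the calibration line (clamped at zero for TVB-N below the
    intercept); the reading is baseline + ΔE·direction + N(0, sd) noise
    per channel. With zero noise, ``delta_e(baseline, reading)`` equals
    the true ΔE exactly.
    """
    rng = np.random.default_rng([config.seed, 1])
    direction = config.color_direction
    if abs(sum(c * c for c in direction) - 1.0) > 1e-9:
        raise ValueError("color_direction must have unit Euclidean norm")
    base = config.baseline_lab
    out: list[ColorObservation] = []
    for obs in tvbn_series:
        de_true = max(0.0, (obs.tvbn - config.calib_intercept) / config.calib_slope)
        noise = (
            rng.normal(0.0, config.color_noise_sd, size=3)
            if config.color_noise_sd > 0
            else np.zeros(3)
        )
        out.append(
            ColorObservation(
                time_h=obs.time_h,
                temperature_C=obs.temperature_C,
                color=LabColor(
                    L=min(100.0, max(0.0, base.L + de_true * direction[0] + noise[0])),
                    a=base.a + de_true * direction[1] + noise[1],
                    b=base.b + de_true * direction[2] + noise[2],
                ),
                replicate=obs.replicate,
            )
        )
    return out


def simulate_photodegradation(
    photobleach_k: float,
    times: Sequence[float] = (0.0, 6.0, 12.0, 24.0),
    c0: float = 100.0,
    seed: int = 0,
    noise_sigma_ln: float = 0.0,
) -> list[Tuple[float, float]]:
    """First-order pigment photobleaching under UV: c(t) = c0·exp(−kp·t).

    Returns (time, concentration) pairs; optional lognormal noise. In the
    noiseless case the degradation percentage at time t is
    100·(1 − exp(−kp·t)).
    """
    if photobleach_k < 0:
        raise ValueError(f"photobleach rate must be >= 0, got {photobleach_k}")
    if c0 <= 0:
        raise ValueError(f"c0 must be > 0, got {c0}")
    rng = np.random.default_rng([seed, 2])
    out = []
    for t in times:
        eps = rng.normal(0.0, noise_sigma_ln) if noise_sigma_ln > 0 else 0.0
        out.append((float(t), c0 * math.exp(-photobleach_k * t) * math.exp(eps)))
    return out


@dataclass(frozen=True)
class DesignPoint:
    """One validation experiment: a label reading with ground-truth shelf-life.

    ``observed_h`` is the remaining time until the noiseless true TVB-N
    trajectory crosses the spoilage threshold; negative (and ``spoiled``)
    when sampled past spoilage.
    """

    temperature_C: float
    time_h: float
    delta_e: float
    observed_h: float
    spoiled: bool


def make_validation_design(
    config: SimulationConfig,
    validation_times: Dict[float, Tuple[float, ...]] | None = None,
    threshold: float = 30.0,
    reference: str = "baseline",
) -> list[DesignPoint]:
    """Simulate the validation experiment at the check temperatures.

    At each (temperature, sampling time): the TVB-N value is drawn with
    the study's lognormal noise, converted to a noisy label reading, and
    its measured ΔE recorded; observed_h is the closed-form time left
    until the *true* trajectory reaches the threshold.

    ``reference`` selects what the measured ΔE is taken against:
    ``"baseline"`` uses the fixed fresh-label color (the calibration
    line's zero point), ``"t0"`` the deployed label's own time-0 reading
    — the convention available when only colorimeter data exist.
    """
    if validation_times is None:
        validation_times = dict(DEFAULT_VALIDATION_TIMES)
    if reference not in ("baseline", "t0"):
        raise ValueError(f"reference must be 'baseline' or 't0', got {reference!r}")
    rng = np.random.default_rng([config.seed, 3])
    base = config.baseline_lab
    direction = config.color_direction
    out: list[DesignPoint] = []
    for T in sorted(validation_times):
        k = config.true_rate(T)
        crossing = math.log(threshold / config.true_a0) / k
        ref_color = base
        if reference == "t0":
            de0 = max(
                0.0, (config.true_a0 - config.calib_intercept) / config.calib_slope
            )
            noise0 = (
                rng.normal(0.0, config.color_noise_sd, size=3)
                if config.color_noise_sd > 0
                else np.zeros(3)
            )
            ref_color = LabColor(
                L=min(100.0, max(0.0, base.L + de0 * direction[0] + noise0[0])),
                a=base.a + de0 * direction[1] + noise0[1],
                b=base.b + de0 * direction[2] + noise0[2],
            )
        for t in validation_times[T]:
            true_tvbn = config.true_a0 * math.exp(k * t)
            eps = (
                rng.normal(0.0, config.noise_sigma_ln)
                if config.noise_sigma_ln > 0
                else 0.0
            )
            noisy_tvbn = true_tvbn * math.exp(eps)
            de_true = max(
                0.0, (noisy_tvbn - config.calib_intercept) / config.calib_slope
            )
            cnoise = (
                rng.normal(0.0, config.color_noise_sd, size=3)
                if config.color_noise_sd > 0
                else np.zeros(3)
            )
            reading = LabColor(
                L=min(100.0, max(0.0, base.L + de_true * direction[0] + cnoise[0])),
                a=base.a + de_true * direction[1] + cnoise[1],
                b=base.b + de_true * direction[2] + cnoise[2],
            )
            out.append(
                DesignPoint(
                    temperature_C=float(T),
                    time_h=float(t),
                    delta_e=delta_e(ref_color, reading),
                    observed_h=crossing - t,
                    spoiled=crossing - t <= 0.0,
                )
            )
    return out


def design_rows(
    design: Iterable[DesignPoint],
) -> list[Tuple[float, float, float, float]]:
    """Non-spoiled design points as (temperature, time, ΔE, observed_h) rows."""
    return [
        (d.temperature_C, d.time_h, d.delta_e, d.observed_h)
        for d in design
        if not d.spoiled
    ]
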