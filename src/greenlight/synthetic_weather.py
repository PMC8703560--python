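"""Seeded generator of greenhouse-level irradiance traces.

Each synthetic day is a half-sine clear-sky PPFD profile over the
daylight window, multiplied by a persistent three-state cloud attenuation
process (clear / partly cloudy / overcast, first-order Markov at 3-min
resolution) and by the greenhouse transmission fraction.  Irradiance is
sampled every 3 minutes and averaged into 15-min control steps, emulating
a quantum sensor polled on that schedule.

Two named presets emulate the irradiance regimes of a low-light winter
season (daily light integral ≈ 2.2 ± 0.6 mol m⁻² d⁻¹ under a 40%
transmission shade cloth) and a brighter, far more variable spring season
(≈ 7.45 ± 3.11 mol m⁻² d⁻¹).  Preset cloud parameters were calibrated by
Monte Carlo (scripts/calibrate_weather.py) against those summary
statistics and then frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phytomodel import PhotoperiodSpec
from .sunlight_markov import IrradianceTrace

__all__ = [
    "WeatherPreset",
    "WINTER_ATHENS",
    "SPRING_ATHENS",
    "PRESETS",
    "generate_days",
    "split_train_eval",
]

SAMPLES_PER_STEP = 5  # 3-min sensor samples per 15-min control step


@dataclass(frozen=True)
class WeatherPreset:
    """Parameters of one seasonal irradiance regime.

    ``clear_sky_peak_ppfd`` is the outdoor solar-noon PPFD on a cloudless
    day; ``transmission`` the fraction reaching the canopy through the
    greenhouse ceiling and shade cloth.  The cloud process stays in its
    current state with probability ``cloud_persistence`` per 3-min sample
    and otherwise redraws a state from ``state_weights``;
    ``attenuation_levels`` are the multiplicative factors for the clear,
    partly-cloudy and overcast states.  ``target_dli_mean``/``sd`` record
    the calibration reference (mol m⁻² d⁻¹), they do not enter the
    simulation.
    """

    name: str
    clear_sky_peak_ppfd: float
    day_length_hours: float
    sunrise_hour: float
    transmission: float = 0.40
    cloud_persistence: float = 0.995
    attenuation_levels: tuple = (1.0, 0.55, 0.2)
    state_weights: tuple = (1.0, 0.0, 0.0)
    photoperiod_start_hour: float = 4.5
    target_dli_mean: float = 0.0
    target_dli_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.transmission <= 1:
            raise ValueError("transmission must be in (0, 1]")
        if any(not 0 < a <= 1 for a in self.attenuation_levels):
            raise ValueError("attenuation levels must be in (0, 1]")
        if not 0 <= self.cloud_persistence < 1:
            raise ValueError("cloud_persistence must be in [0, 1)")


WINTER_ATHENS = WeatherPreset(
    name="winter_athens",
    clear_sky_peak_ppfd=1150.0,
    day_length_hours=10.0,
    sunrise_hour=7.6,
    transmission=0.40,
    cloud_persistence=0.980,
    attenuation_levels=(0.32, 0.20, 0.09),
    state_weights=(0.30, 0.45, 0.25),
    photoperiod_start_hour=4.5,
    target_dli_mean=2.22,
    target_dli_sd=0.6,
)

SPRING_ATHENS = WeatherPreset(
    name="spring_athens",
    clear_sky_peak_ppfd=1750.0,
    day_length_hours=13.0,
    sunrise_hour=6.9,
    transmission=0.40,
    cloud_persistence=0.986,
    attenuation_levels=(0.60, 0.30, 0.10),
    state_weights=(0.38, 0.34, 0.28),
    photoperiod_start_hour=5.0,
    target_dli_mean=7.45,
    target_dli_sd=3.11,
)

PRESETS = {p.name: p for p in (WINTER_ATHENS, SPRING_ATHENS)}


def _clear_sky_ppfd(hours: np.ndarray, preset: WeatherPreset) -> np.ndarray:
    """Outdoor clear-sky PPFD at the given clock hours (half-sine day)."""
    phase = (hours - preset.sunrise_hour) / preset.day_length_hours
    out = np.where(
        (phase > 0) & (phase < 1),
        preset.clear_sky_peak_ppfd * np.sin(np.pi * np.clip(phase, 0, 1)),
        0.0,
    )
    return out


def _cloud_states(rng: np.random.Generator, n: int, preset: WeatherPreset) -> np.ndarray:
    w = np.asarray(preset.state_weights, dtype=float)
    w = w / w.sum()
    states = np.empty(n, dtype=int)
    states[0] = rng.choice(len(w), p=w)
    stay = rng.random(n - 1) < preset.cloud_persistence
    redraws = rng.choice(len(w), size=n - 1, p=w)
    for i in range(1, n):
        states[i] = states[i - 1] if stay[i - 1] else redraws[i - 1]
    return states


def generate_days(
    preset: WeatherPreset,
    n_days: int,
    seed: int,
    photoperiod: PhotoperiodSpec | None = None,
    return_samples: bool = False,
):
    """Generate ``n_days`` of canopy-level irradiance, deterministically in ``seed``.

    Returns an :class:`IrradianceTrace` of shape (n_days, n_steps); with
    ``return_samples=True`` also the underlying 3-min samples of shape
    (n_days, n_steps, SAMPLES_PER_STEP), whose per-step mean equals the
    trace exactly.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if photoperiod is None:
        photoperiod = PhotoperiodSpec(start_hour=preset.photoperiod_start_hour)
    rng = np.random.default_rng(seed)

    T = photoperiod.n_steps
    n_samples = T * SAMPLES_PER_STEP
    sample_hours = (
        photoperiod.start_hour
        + (np.arange(n_samples) + 0.5) * (photoperiod.step_seconds / SAMPLES_PER_STEP) / 3600.0
    )
    clear = _clear_sky_ppfd(sample_hours, preset)
    att = np.asarray(preset.attenuation_levels, dtype=float)

    samples = np.empty((n_days, T, SAMPLES_PER_STEP))
    for d in range(n_days):
        states = _cloud_states(rng, n_samples, preset)
        ppfd = clear * att[states] * preset.transmission
        samples[d] = ppfd.reshape(T, SAMPLES_PER_STEP)

    trace = IrradianceTrace(
        samples.mean(axis=2), photoperiod.step_seconds, photoperiod.start_hour
    )
    return (trace, samples) if return_samples else trace


def split_train_eval(trace: IrradianceTrace, n_train: int):
    """Split a multi-day trace into disjoint training and evaluation sets."""
    if not 0 < n_train < trace.n_days:
        raise ValueError(f"n_train must be in (0, {trace.n_days})")
    return trace.subset(range(n_train)), trace.subset(range(n_train, trace.n_days))
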