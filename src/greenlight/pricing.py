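"""Electricity price profiles and conversion of light to monetary cost.

The optimizer's objective has units cents·(kWh)⁻¹·µmol m⁻² s⁻¹ (price ×
supplemental PPFD).  Converting supplemental PPFD to electrical power
uses the fixture efficacy (2.9 µmol J⁻¹ for the LED bars modelled here,
i.e. 2.9×10³ µmol kW⁻¹ s⁻¹); multiplying by the step length in hours and
the price then yields cents per square metre:

    step cost [cents/m²] = price [cents/kWh] × ppfd / (efficacy·10³) × step_hours

so the conversion factor q = step_hours / (efficacy·10³) satisfies
q·f = Σ step costs exactly, f being the optimizer objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phytomodel import PhotoperiodSpec

__all__ = [
    "PriceProfile",
    "ConversionSpec",
    "step_cost",
    "daily_cost",
    "percent_increase",
    "efficiency_ratio",
    "variable_price_fixture",
    "read_price_csv",
]

_VARIABLE_FIXTURE = Path(__file__).parent / "data" / "variable_price_synthetic_24h.csv"


@dataclass(frozen=True)
class ConversionSpec:
    """Light-to-cost conversion constants.

    ``efficacy`` is the LED photon efficacy in µmol J⁻¹; ``step_hours``
    the control-step length in hours.
    """

    efficacy: float = 2.9
    step_hours: float = 0.25

    @property
    def q(self) -> float:
        """cents/m² per (cents/kWh × µmol m⁻² s⁻¹): step_hours/(efficacy·10³)."""
        return self.step_hours / (self.efficacy * 1e3)


@dataclass
class PriceProfile:
    """Per-step electricity price C_t in cents/kWh over the photoperiod."""

    prices: np.ndarray
    kind: str = "fixed"  # "fixed" | "variable"

    def __post_init__(self) -> None:
        self.prices = np.atleast_1d(np.asarray(self.prices, dtype=float))
        if np.any(self.prices < 0):
            raise ValueError("prices must be non-negative")

    @classmethod
    def fixed(cls, cents_per_kwh: float, n_steps: int) -> "PriceProfile":
        return cls(np.full(n_steps, float(cents_per_kwh)), kind="fixed")

    @classmethod
    def from_hourly(
        cls, hourly: np.ndarray, photoperiod: PhotoperiodSpec
    ) -> "PriceProfile":
        """Expand a 24-value hourly profile onto the photoperiod steps.

        A price quoted for an hour is held constant across every control
        step that starts within that hour.
        """
        hourly = np.asarray(hourly, dtype=float)
        if hourly.shape != (24,):
            raise ValueError("hourly profile must have exactly 24 values")
        hours = np.floor(photoperiod.step_clock_hours()).astype(int) % 24
        return cls(hourly[hours], kind="variable")


def variable_price_fixture() -> np.ndarray:
    """Synthetic 24-h variable price profile (cents/kWh, one value per hour).

    A representative time-of-use shape — low overnight off-peak, a midday
    plateau and an evening peak — constructed for simulation studies.  It
    is not measured market data.
    """
    df = pd.read_csv(_VARIABLE_FIXTURE)
    return df.sort_values("hour")["price_cents_per_kwh"].to_numpy(dtype=float)


def read_price_csv(path: str | Path, photoperiod: PhotoperiodSpec) -> PriceProfile:
    """Read a price profile CSV with either ``hour`` (0–23) or ``step`` rows."""
    df = pd.read_csv(path)
    if "hour" in df.columns:
        hourly = df.sort_values("hour")["price_cents_per_kwh"].to_numpy(dtype=float)
        return PriceProfile.from_hourly(hourly, photoperiod)
    if "step" in df.columns:
        prices = df.sort_values("step")["price_cents_per_kwh"].to_numpy(dtype=float)
        if len(prices) != photoperiod.n_steps:
            raise ValueError(
                f"per-step price file has {len(prices)} rows, expected {photoperiod.n_steps}"
            )
        return PriceProfile(prices, kind="variable")
    raise ValueError("price CSV needs an 'hour' or 'step' column")


def step_cost(
    supplemental_ppfd: float, price: float, spec: ConversionSpec = ConversionSpec()
) -> float:
    """Electricity cost of one step's supplemental light, cents/m²."""
    if supplemental_ppfd < 0 or price < 0:
        raise ValueError("inputs must be non-negative")
    return price * supplemental_ppfd / (spec.efficacy * 1e3) * spec.step_hours


def daily_cost(
    supplemental_ppfd, profile: PriceProfile, spec: ConversionSpec = ConversionSpec()
) -> float:
    """Total daily cost of a supplemental PPFD series, cents/m²."""
    ppfd = np.asarray(supplemental_ppfd, dtype=float)
    if len(ppfd) != len(profile.prices):
        raise ValueError("plan and price profile lengths differ")
    return float(np.sum(profile.prices * ppfd) * spec.q)


def percent_increase(cost: float, reference_cost: float) -> float:
    """100·(c − c_ref)/c_ref; NaN marks the undefined zero-reference case."""
    if reference_cost == 0:
        return 0.0 if cost == 0 else float("nan")
    return 100.0 * (cost - reference_cost) / reference_cost


def efficiency_ratio(total_dry_weight_g: float, total_cost_cents: float) -> float:
    """Biomass produced per cent of electricity, g/cent."""
    if total_cost_cents <= 0:
        raise ValueError("total cost must be positive")
    return total_dry_weight_g / total_cost_cents
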