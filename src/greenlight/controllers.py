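"""Closed-loop supplemental-lighting strategies over a simulated day.

Three controllers are compared on the same day of sunlight:

* **baseline** — solves the full-horizon cost minimization once with
  perfect foreknowledge of the day's sunlight; the theoretical optimum
  and lower bound on cost.
* **predictive** — the deployable strategy: at every step it observes the
  current sunlight, banks the light already delivered as a credit against
  the daily photochemical requirement, forecasts the rest of the day with
  the Markov model, re-solves the remaining-horizon problem and commits
  only the current step's decision (receding horizon).
* **heuristic** — price- and forecast-blind: tops sunlight up to a fixed
  PPFD threshold each step, capped by the LED maximum.

LED output is commanded as a PWM duty cycle, modelled as linear in the
supplemental PPFD up to the fixture maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optimizer import LightingPlan, OptimizationInput, solve
from .phytomodel import (
    GREEN_TOWERS_LETTUCE,
    LightResponseParams,
    PhotoperiodSpec,
    etr_from_ppfd,
    integral_over_day,
    ppfd_from_etr,
)
from .pricing import ConversionSpec, PriceProfile, daily_cost
from .sunlight_markov import TransitionModel, predict_day, predict_remaining

__all__ = [
    "LEDSpec",
    "DayResult",
    "run_baseline",
    "run_predictive",
    "run_heuristic",
    "duty_cycle",
    "default_heuristic_threshold",
]


@dataclass(frozen=True)
class LEDSpec:
    """Supplemental-light fixture limits and efficacy.

    ``etr_cap`` is the maximum ETR the LEDs can add (Ū_LED); the PPFD
    maximum follows from the light response.  ``efficacy`` in µmol J⁻¹
    feeds the cost conversion.
    """

    etr_cap: float = 86.21
    efficacy: float = 2.9

    def ppfd_max(self, params: LightResponseParams = GREEN_TOWERS_LETTUCE) -> float:
        return ppfd_from_etr(self.etr_cap, params)


@dataclass
class DayResult:
    """Outcome of one controller over one simulated day."""

    controller: str
    sun_ppfd: np.ndarray
    supplemental_ppfd: np.ndarray
    supplemental_etr: np.ndarray
    duty_cycle: np.ndarray  # percent
    prices: np.ndarray
    dpi: float  # achieved daily photochemical integral, mol m-2 d-1
    dli: float  # achieved daily light integral, mol m-2 d-1
    cost_cents: float  # daily electricity cost, cents/m2
    feasible: bool = True
    shortfall: float = 0.0


def duty_cycle(supplemental_ppfd, ppfd_max_led: float):
    """PWM duty cycle (%) commanding a supplemental PPFD, linear dimming model.

    Out-of-range requests are clamped to [0, 100] with a warning.
    """
    import warnings

    p = np.asarray(supplemental_ppfd, dtype=float)
    if np.any(p < 0) or np.any(p > ppfd_max_led * (1 + 1e-9)):
        warnings.warn("supplemental PPFD outside [0, ppfd_max]; duty cycle clamped")
    out = np.clip(100.0 * p / ppfd_max_led, 0.0, 100.0)
    return float(out) if np.isscalar(supplemental_ppfd) else out


def default_heuristic_threshold(
    params: LightResponseParams = GREEN_TOWERS_LETTUCE,
    photoperiod: PhotoperiodSpec = PhotoperiodSpec(),
) -> float:
    """Minimal constant PPFD whose ETR over the photoperiod meets the DPI.

    The mean ETR needed is D̄·1e6/(T·m); inverting the light response at
    that rate gives ≈203.2 µmol m⁻² s⁻¹ for the default lettuce
    parameters.
    """
    mean_etr = params.dpi_target * 1e6 / (photoperiod.n_steps * photoperiod.step_seconds)
    return ppfd_from_etr(mean_etr, params)


def _result_from_supplemental(
    name: str,
    sun_ppfd: np.ndarray,
    supp_ppfd: np.ndarray,
    profile: PriceProfile,
    params: LightResponseParams,
    photoperiod: PhotoperiodSpec,
    led: LEDSpec,
    feasible: bool = True,
    shortfall: float = 0.0,
) -> DayResult:
    total_ppfd = sun_ppfd + supp_ppfd
    total_etr = etr_from_ppfd(total_ppfd, params)
    supp_etr = total_etr - etr_from_ppfd(sun_ppfd, params)
    conv = ConversionSpec(efficacy=led.efficacy, step_hours=photoperiod.step_seconds / 3600.0)
    return DayResult(
        controller=name,
        sun_ppfd=sun_ppfd,
        supplemental_ppfd=supp_ppfd,
        supplemental_etr=supp_etr,
        duty_cycle=duty_cycle(supp_ppfd, led.ppfd_max(params)),
        prices=profile.prices.copy(),
        dpi=integral_over_day(total_etr, photoperiod.step_seconds),
        dli=integral_over_day(total_ppfd, photoperiod.step_seconds),
        cost_cents=daily_cost(supp_ppfd, profile, conv),
        feasible=feasible,
        shortfall=shortfall,
    )


def run_baseline(
    sun_ppfd,
    profile: PriceProfile,
    params: LightResponseParams = GREEN_TOWERS_LETTUCE,
    photoperiod: PhotoperiodSpec = PhotoperiodSpec(),
    led: LEDSpec = LEDSpec(),
) -> DayResult:
    """Perfect-knowledge optimum: one full-horizon solve with the actual sun."""
    sun = np.asarray(sun_ppfd, dtype=float)
    inp = OptimizationInput(
        prices=profile.prices,
        sun_ppfd=sun,
        params=params,
        step_seconds=photoperiod.step_seconds,
        etr_cap=led.etr_cap,
    )
    plan = solve(inp)
    return _result_from_supplemental(
        "baseline", sun, plan.x_ppfd, profile, params, photoperiod, led,
        feasible=plan.feasible, shortfall=plan.shortfall,
    )


def run_predictive(
    sun_ppfd,
    model: TransitionModel | None,
    profile: PriceProfile,
    params: LightResponseParams = GREEN_TOWERS_LETTUCE,
    photoperiod: PhotoperiodSpec = PhotoperiodSpec(),
    led: LEDSpec = LEDSpec(),
    oracle: bool = False,
) -> DayResult:
    """Receding-horizon controller driven by the Markov sunlight forecast.

    With ``oracle=True`` the forecast is replaced by the true future
    sunlight, which reproduces the baseline exactly (the full problem is
    strictly convex, so re-solving suffixes of its unique optimum returns
    that optimum's suffix).
    """
    sun = np.asarray(sun_ppfd, dtype=float)
    T = photoperiod.n_steps
    if len(sun) != T:
        raise ValueError(f"expected {T} steps of sunlight, got {len(sun)}")
    if model is None and not oracle:
        raise ValueError("a fitted TransitionModel is required unless oracle=True")

    x_etr = np.zeros(T)
    credit = 0.0
    last_plan: LightingPlan | None = None
    for i in range(T):
        if oracle or i == T - 1:
            future = sun[i + 1 :]
        elif i == 0:
            # no informative measurement yet: historical per-step means
            future = predict_day(model)[1:]
        else:
            future = predict_remaining(model, i, sun[i])
        horizon_sun = np.concatenate(([sun[i]], future))
        inp = OptimizationInput(
            prices=profile.prices[i:],
            sun_ppfd=horizon_sun,
            params=params,
            step_seconds=photoperiod.step_seconds,
            etr_cap=led.etr_cap,
            credit_etr_sum=credit,
        )
        last_plan = solve(inp)
        x_etr[i] = last_plan.x_etr[0]
        credit += x_etr[i] + etr_from_ppfd(sun[i], params)

    # realized supplemental PPFD from realized sun and committed ETR
    total_etr = np.minimum(etr_from_ppfd(sun, params) + x_etr, params.a * (1 - 1e-12))
    supp_ppfd = np.maximum(ppfd_from_etr(total_etr, params) - sun, 0.0)
    required = params.dpi_target * 1e6 / photoperiod.step_seconds
    shortfall = max(0.0, required - credit)
    return _result_from_supplemental(
        "predictive", sun, supp_ppfd, profile, params, photoperiod, led,
        feasible=shortfall <= 1e-6 * required, shortfall=shortfall,
    )


def run_heuristic(
    sun_ppfd,
    profile: PriceProfile,
    params: LightResponseParams = GREEN_TOWERS_LETTUCE,
    photoperiod: PhotoperiodSpec = PhotoperiodSpec(),
    led: LEDSpec = LEDSpec(),
    threshold_ppfd: float | None = None,
) -> DayResult:
    """Threshold top-up: supply max(0, threshold − sun) each step, LED-capped."""
    sun = np.asarray(sun_ppfd, dtype=float)
    if threshold_ppfd is None:
        threshold_ppfd = default_heuristic_threshold(params, photoperiod)
    if threshold_ppfd <= 0:
        raise ValueError("threshold_ppfd must be positive")
    supp = np.minimum(np.maximum(threshold_ppfd - sun, 0.0), led.ppfd_max(params))
    return _result_from_supplemental(
        "heuristic", sun, supp, profile, params, photoperiod, led
    )
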