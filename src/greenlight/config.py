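"""Run configuration for the command-line tools.

A single YAML file describes a simulation study: the crop preset, the
photoperiod grid, the LED fixture, the electricity price profile, the
weather preset with seed and day counts, and predictor/heuristic
settings.  See ``RunConfig.from_yaml`` for the schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .controllers import LEDSpec
from .phytomodel import LightResponseParams, PhotoperiodSpec, load_crop_preset
from .pricing import PriceProfile, read_price_csv, variable_price_fixture
from .synthetic_weather import PRESETS, WeatherPreset

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    params: LightResponseParams
    photoperiod: PhotoperiodSpec
    led: LEDSpec
    price_profile: PriceProfile
    weather_preset: WeatherPreset
    seed: int
    n_train_days: int
    n_eval_days: int
    n_bins: int = 10
    smoothing: float = 1.0
    heuristic_threshold: float | None = None
    model_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration.

        Schema (keys with defaults may be omitted)::

            crop: green_towers_lettuce
            photoperiod: {start_hour: 4.5, hours: 16, step_seconds: 900}
            led: {etr_cap: 86.21, efficacy_umol_per_j: 2.9}
            price:
              kind: fixed | variable          # variable uses the packaged
              fixed_cents_per_kwh: 13.19      # synthetic 24-h fixture
              csv: prices.csv                 # optional override
            weather:
              preset: winter_athens | spring_athens
              seed: 42
              n_train_days: 20
              n_eval_days: 5
            predictor: {n_bins: 10, smoothing: 1.0, model: model.json}
            heuristic: {threshold_ppfd: null}
        """
        doc = yaml.safe_load(Path(path).read_text())

        crop = load_crop_preset(doc.get("crop", "green_towers_lettuce"))
        params: LightResponseParams = crop["params"]
        photoperiod: PhotoperiodSpec = crop["photoperiod"]
        if "photoperiod" in doc:
            p = doc["photoperiod"]
            photoperiod = PhotoperiodSpec.from_hours(
                photoperiod_hours=float(p.get("hours", photoperiod.hours)),
                step_seconds=int(p.get("step_seconds", photoperiod.step_seconds)),
                start_hour=float(p.get("start_hour", photoperiod.start_hour)),
            )

        led_doc = doc.get("led", {})
        led = LEDSpec(
            etr_cap=float(led_doc.get("etr_cap", 86.21)),
            efficacy=float(led_doc.get("efficacy_umol_per_j", 2.9)),
        )
        if not 0 <= led.etr_cap < params.a:
            raise ValueError("led.etr_cap must lie in [0, a)")

        w = doc.get("weather", {})
        preset_name = w.get("preset", "winter_athens")
        if preset_name not in PRESETS:
            raise ValueError(f"unknown weather preset {preset_name!r}")
        weather = PRESETS[preset_name]

        price_doc = doc.get("price", {"kind": "variable"})
        if "csv" in price_doc:
            csv = Path(price_doc["csv"])
            if not csv.exists():
                raise FileNotFoundError(f"price csv {csv} does not exist")
            profile = read_price_csv(csv, photoperiod)
        elif price_doc.get("kind", "variable") == "fixed":
            profile = PriceProfile.fixed(
                float(price_doc.get("fixed_cents_per_kwh", 13.19)), photoperiod.n_steps
            )
        else:
            profile = PriceProfile.from_hourly(variable_price_fixture(), photoperiod)

        pred = doc.get("predictor", {})
        heur = doc.get("heuristic", {})
        thr = heur.get("threshold_ppfd")
        return cls(
            params=params,
            photoperiod=photoperiod,
            led=led,
            price_profile=profile,
            weather_preset=weather,
            seed=int(w.get("seed", 0)),
            n_train_days=int(w.get("n_train_days", 20)),
            n_eval_days=int(w.get("n_eval_days", 5)),
            n_bins=int(pred.get("n_bins", 10)),
            smoothing=float(pred.get("smoothing", 1.0)),
            heuristic_threshold=float(thr) if thr is not None else None,
            model_path=pred.get("model"),
        )
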