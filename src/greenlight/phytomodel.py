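"""Plant light-response model and integral light metrics.

Photosynthetic light levels are measured as photosynthetic photon flux
density (PPFD, µmol m⁻² s⁻¹).  The plant-side quantity relevant for growth
is the electron transport rate through photosystem II (ETR, same units),
which saturates with increasing PPFD following an exponential rise to a
maximum:

    ETR = a · (1 − exp(−k · PPFD))

with asymptote ``a`` and initial-slope coefficient ``k``.  Integrating a
PPFD series over the day gives the daily light integral (DLI,
mol m⁻² d⁻¹); integrating the ETR series gives the daily photochemical
integral (DPI, mol m⁻² d⁻¹), which is the growth requirement used as the
optimization constraint throughout this package.

Units are fixed package-wide: instantaneous rates in µmol m⁻² s⁻¹ and
daily integrals in mol m⁻² d⁻¹.  The 1e-6 µmol→mol conversion lives only
in :func:`integral_over_day` so it can never be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "LightResponseParams",
    "PhotoperiodSpec",
    "etr_from_ppfd",
    "ppfd_from_etr",
    "integral_over_day",
    "load_crop_preset",
    "GREEN_TOWERS_LETTUCE",
]

_PRESET_FILE = Path(__file__).parent / "data" / "crop_presets.yaml"


@dataclass(frozen=True)
class LightResponseParams:
    """Crop light-response constants and daily light requirement.

    Parameters
    ----------
    a : float
        ETR asymptote, µmol m⁻² s⁻¹.
    k : float
        Initial-slope coefficient, per (µmol m⁻² s⁻¹).
    dpi_target : float
        Minimum daily photochemical integral the crop must receive,
        mol m⁻² d⁻¹.
    """

    a: float = 121.0
    k: float = 0.00277
    dpi_target: float = 3.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"ETR asymptote a must be positive, got {self.a}")
        if self.k <= 0:
            raise ValueError(f"slope coefficient k must be positive, got {self.k}")
        if self.dpi_target < 0:
            raise ValueError(f"dpi_target must be non-negative, got {self.dpi_target}")


@dataclass(frozen=True)
class PhotoperiodSpec:
    """Discretization of the daily lighting window into control steps.

    ``n_steps`` must equal the photoperiod length divided by the step
    length exactly; with the defaults (16 h photoperiod, 900 s steps)
    there are 64 control steps per day.  ``start_hour`` is the local
    clock time at which the photoperiod begins (e.g. 4.5 for 04:30).
    """

    step_seconds: int = 900
    n_steps: int = 64
    start_hour: float = 4.5

    def __post_init__(self) -> None:
        if self.step_seconds <= 0 or self.n_steps <= 0:
            raise ValueError("step_seconds and n_steps must be positive")

    @classmethod
    def from_hours(
        cls, photoperiod_hours: float, step_seconds: int = 900, start_hour: float = 4.5
    ) -> "PhotoperiodSpec":
        total = photoperiod_hours * 3600.0
        n = total / step_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"photoperiod of {photoperiod_hours} h is not an integer number "
                f"of {step_seconds}-s steps"
            )
        return cls(step_seconds=step_seconds, n_steps=int(round(n)), start_hour=start_hour)

    @property
    def hours(self) -> float:
        return self.n_steps * self.step_seconds / 3600.0

    def step_clock_hours(self) -> np.ndarray:
        """Local clock hour at the start of each control step."""
        return self.start_hour + np.arange(self.n_steps) * self.step_seconds / 3600.0


GREEN_TOWERS_LETTUCE = LightResponseParams(a=121.0, k=0.00277, dpi_target=3.0)


def etr_from_ppfd(ppfd, params: LightResponseParams = GREEN_TOWERS_LETTUCE):
    """Electron transport rate produced by a given PPFD.

    Applies ``a·(1 − exp(−k·ppfd))`` elementwise.  Strictly increasing and
    concave in ``ppfd``; bounded above by the asymptote ``a``.

    Raises
    ------
    ValueError
        If any input PPFD is negative.
    """
    p = np.asarray(ppfd, dtype=float)
    if np.any(p < 0):
        raise ValueError("PPFD must be non-negative")
    out = params.a * -np.expm1(-params.k * p)
    return float(out) if np.isscalar(ppfd) else out


def ppfd_from_etr(etr, params: LightResponseParams = GREEN_TOWERS_LETTUCE):
    """PPFD required to sustain a given ETR (inverse light response).

    Computes ``−ln(1 − etr/a)/k``.  Exact round-trip with
    :func:`etr_from_ppfd`.  Only ETR values strictly below the asymptote
    are reachable.

    Raises
    ------
    ValueError
        If any ETR is negative or at/above the asymptote ``a``.
    """
    e = np.asarray(etr, dtype=float)
    if np.any(e < 0):
        raise ValueError("ETR must be non-negative")
    if np.any(e >= params.a):
        raise ValueError(f"ETR must be below the asymptote a={params.a} (saturation)")
    out = -np.log1p(-e / params.a) / params.k
    return float(out) if np.isscalar(etr) else out


def integral_over_day(series, step_seconds: float) -> float:
    """Daily integral of a per-step rate series, in mol m⁻² d⁻¹.

    ``Σ value_t · step_seconds · 1e-6``: applied to an ETR series this is
    the DPI, applied to a PPFD series it is the DLI.  This is the single
    place in the package where µmol converts to mol.
    """
    v = np.asarray(series, dtype=float)
    if step_seconds <= 0:
        raise ValueError("step_seconds must be positive")
    if not np.all(np.isfinite(v)):
        raise ValueError("series must be finite")
    return float(v.sum() * step_seconds * 1e-6)


def load_crop_preset(name: str, path: str | Path | None = None) -> dict:
    """Load a named crop preset from the packaged (or a user) YAML file.

    Returns a dict with keys ``params`` (:class:`LightResponseParams`)
    and ``photoperiod`` (:class:`PhotoperiodSpec`).
    """
    presets = yaml.safe_load(Path(path or _PRESET_FILE).read_text())
    if name not in presets:
        raise KeyError(f"unknown crop preset {name!r}; available: {sorted(presets)}")
    p = presets[name]
    params = LightResponseParams(
        a=float(p["a"]), k=float(p["k"]), dpi_target=float(p["dpi_target"])
    )
    photoperiod = PhotoperiodSpec.from_hours(
        photoperiod_hours=float(p["photoperiod_hours"]),
        step_seconds=int(p["step_seconds"]),
        start_hour=float(p.get("start_hour", 4.5)),
    )
    return {"params": params, "photoperiod": photoperiod}
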