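"""Markov-chain model of within-day sunlight evolution.

Greenhouse-level sunlight PPFD at 15-min resolution is discretized into a
small number of intensity bins; step-to-step bin transitions observed in
historical days are counted, smoothed, and row-normalized into transition
matrices.  Forecasts are expectations: before any measurement is available
the forecast for every step of the day is the per-step historical mean;
once a measurement exists, a probability vector started at the measured
bin is propagated through the transition matrices and the forecast at
each future step is the probability-weighted mean of the bin
representative values.

The chain is first-order (conditions only on the latest measurement) and,
with enough training days, time-inhomogeneous: one transition matrix per
step-of-day, since sunlight dynamics at 08:00 differ from those at noon.
With fewer than 10 training days a single pooled matrix is used instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phytomodel import PhotoperiodSpec

__all__ = [
    "IrradianceTrace",
    "TransitionModel",
    "discretize",
    "fit",
    "predict_day",
    "predict_remaining",
    "read_irradiance_csv",
    "write_irradiance_csv",
]

logger = logging.getLogger(__name__)

#: minimum training days for per-step-of-day transition matrices
POOLING_THRESHOLD = 10


@dataclass
class IrradianceTrace:
    """Sunlight PPFD received at the canopy, per step, over one or more days.

    ``ppfd`` has shape (n_days, n_steps); every day covers the same
    photoperiod window on an equally spaced grid of ``step_seconds``.
    """

    ppfd: np.ndarray
    step_seconds: int = 900
    start_hour: float = 4.5

    def __post_init__(self) -> None:
        self.ppfd = np.atleast_2d(np.asarray(self.ppfd, dtype=float))
        if np.any(self.ppfd < 0):
            raise ValueError("irradiance PPFD must be non-negative")

    @property
    def n_days(self) -> int:
        return self.ppfd.shape[0]

    @property
    def n_steps(self) -> int:
        return self.ppfd.shape[1]

    def day(self, i: int) -> np.ndarray:
        return self.ppfd[i]

    def subset(self, day_indices) -> "IrradianceTrace":
        return IrradianceTrace(
            self.ppfd[np.asarray(day_indices)], self.step_seconds, self.start_hour
        )


@dataclass
class TransitionModel:
    """Fitted Markov model of step-to-step sunlight evolution.

    ``transition`` has shape (n_matrices, n_bins, n_bins); ``n_matrices``
    is ``n_steps - 1`` for a time-inhomogeneous fit (matrix ``t`` maps the
    bin distribution at step ``t`` to step ``t+1``) or 1 for a pooled fit.
    ``day_start_mean`` is the per-step arithmetic mean PPFD over training
    days, used as the whole-day forecast before any measurement exists.
    """

    bin_edges: np.ndarray
    bin_values: np.ndarray
    transition: np.ndarray
    day_start_mean: np.ndarray
    step_seconds: int = 900

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)

    @property
    def n_steps(self) -> int:
        return len(self.day_start_mean)

    @property
    def time_inhomogeneous(self) -> bool:
        return self.transition.shape[0] > 1

    def matrix_for(self, from_step: int) -> np.ndarray:
        """Transition matrix mapping step ``from_step`` to ``from_step+1``."""
        if self.time_inhomogeneous:
            return self.transition[from_step]
        return self.transition[0]

    # -- serialization (portable JSON schema) --------------------------------

    def to_json(self, path: str | Path) -> None:
        """Write the model to a single portable JSON file.

        Schema: ``{"bin_edges": [...], "bin_values": [...],
        "transition": [[[...]]], "day_start_mean": [...],
        "step_seconds": int}``.
        """
        doc = {
            "bin_edges": self.bin_edges.tolist(),
            "bin_values": self.bin_values.tolist(),
            "transition": self.transition.tolist(),
            "day_start_mean": self.day_start_mean.tolist(),
            "step_seconds": self.step_seconds,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            bin_edges=np.asarray(doc["bin_edges"], dtype=float),
            bin_values=np.asarray(doc["bin_values"], dtype=float),
            transition=np.asarray(doc["transition"], dtype=float),
            day_start_mean=np.asarray(doc["day_start_mean"], dtype=float),
            step_seconds=int(doc["step_seconds"]),
        )


def discretize(ppfd: float, bin_edges: np.ndarray) -> int:
    """Bin index i such that edges[i] <= ppfd < edges[i+1] (top bin closed).

    Values outside [first, last] edge are clamped to the boundary bin with
    a logged warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(edges) - 1
    if ppfd < edges[0] or ppfd > edges[-1]:
        logger.warning(
            "PPFD %.1f outside binning range [%.1f, %.1f]; clamped", ppfd, edges[0], edges[-1]
        )
        return 0 if ppfd < edges[0] else n_bins - 1
    if ppfd == edges[-1]:  # top bin closed above
        return n_bins - 1
    return int(np.searchsorted(edges, ppfd, side="right") - 1)


def _discretize_array(ppfd: np.ndarray, edges: np.ndarray) -> np.ndarray:
    n_bins = len(edges) - 1
    idx = np.searchsorted(edges, ppfd, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def fit(
    trace: IrradianceTrace,
    n_bins: int = 10,
    smoothing: float = 1.0,
    time_inhomogeneous: bool | None = None,
) -> TransitionModel:
    """Estimate a transition model from at least two complete training days.

    Transition counts of consecutive-step bin pairs (never across a day
    boundary) are add-``smoothing`` (Laplace by default) smoothed and
    row-normalized.  Bin edges span [0, training maximum] in ``n_bins``
    equal widths; bin representative values are midpoints.

    With ``time_inhomogeneous=None`` a per-step-of-day fit is used when
    the training set has at least ``POOLING_THRESHOLD`` days, otherwise a
    single pooled matrix.
    """
    if trace.n_days < 2:
        raise ValueError("fitting a transition model requires at least 2 training days")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    if time_inhomogeneous is None:
        time_inhomogeneous = trace.n_days >= POOLING_THRESHOLD

    top = max(float(trace.ppfd.max()), 1e-9)
    edges = np.linspace(0.0, top, n_bins + 1)
    values = 0.5 * (edges[:-1] + edges[1:])
    bins = _discretize_array(trace.ppfd, edges)  # (n_days, T)

    T = trace.n_steps
    n_mat = T - 1 if time_inhomogeneous else 1
    counts = np.zeros((n_mat, n_bins, n_bins))
    for t in range(T - 1):
        m = t if time_inhomogeneous else 0
        np.add.at(counts[m], (bins[:, t], bins[:, t + 1]), 1)

    counts += smoothing
    row_sums = counts.sum(axis=2)
    if np.any(row_sums == 0):
        raise ValueError(
            "some transition rows have no observations; refit with smoothing > 0"
        )
    transition = counts / row_sums[:, :, None]

    return TransitionModel(
        bin_edges=edges,
        bin_values=values,
        transition=transition,
        day_start_mean=trace.ppfd.mean(axis=0),
        step_seconds=trace.step_seconds,
    )


def predict_day(model: TransitionModel) -> np.ndarray:
    """Expected PPFD for every step of the day, before any measurement.

    Early in the morning no in-day information exists, so the forecast is
    the per-step historical mean over the training days.
    """
    return model.day_start_mean.copy()


def predict_remaining(
    model: TransitionModel, current_step: int, current_ppfd: float
) -> np.ndarray:
    """Expected PPFD for steps ``current_step+1 .. n_steps-1``.

    The probability vector starts as the indicator of the measured bin and
    is propagated by the successive transition matrices; each future
    step's forecast is the probability-weighted mean of bin values.
    """
    T = model.n_steps
    if not 0 <= current_step < T - 1:
        raise ValueError(f"current_step must be in [0, {T - 2}]")
    p = np.zeros(model.n_bins)
    p[discretize(current_ppfd, model.bin_edges)] = 1.0
    out = np.empty(T - 1 - current_step)
    for j, t in enumerate(range(current_step, T - 1)):
        p = p @ model.matrix_for(t)
        out[j] = p @ model.bin_values
    return out


# -- CSV I/O -----------------------------------------------------------------


def read_irradiance_csv(path: str | Path, photoperiod: PhotoperiodSpec) -> IrradianceTrace:
    """Read an irradiance trace from CSV.

    Expected columns: ``timestamp`` (ISO 8601, local) and
    ``ppfd_umol_m2_s``.  Rows are grouped by calendar date; each date must
    contribute exactly ``photoperiod.n_steps`` equally spaced rows.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df = df.sort_values("timestamp")
    days = []
    for _, grp in df.groupby(df["timestamp"].dt.date, sort=True):
        if len(grp) != photoperiod.n_steps:
            raise ValueError(
                f"day {grp['timestamp'].iloc[0].date()} has {len(grp)} rows, "
                f"expected {photoperiod.n_steps}"
            )
        deltas = grp["timestamp"].diff().dropna().dt.total_seconds()
        if not np.allclose(deltas, photoperiod.step_seconds):
            raise ValueError("irradiance rows are not equally spaced")
        days.append(grp["ppfd_umol_m2_s"].to_numpy(dtype=float))
    return IrradianceTrace(
        np.vstack(days), photoperiod.step_seconds, photoperiod.start_hour
    )


def write_irradiance_csv(
    trace: IrradianceTrace, path: str | Path, start_date: str = "2021-01-01"
) -> None:
    """Write a trace in the same CSV dialect as :func:`read_irradiance_csv`."""
    base = pd.Timestamp(start_date) + pd.Timedelta(hours=trace.start_hour)
    rows = []
    for d in range(trace.n_days):
        t0 = base + pd.Timedelta(days=d)
        ts = t0 + pd.to_timedelta(np.arange(trace.n_steps) * trace.step_seconds, unit="s")
        rows.append(pd.DataFrame({"timestamp": ts, "ppfd_umol_m2_s": trace.ppfd[d]}))
    pd.concat(rows).to_csv(path, index=False)
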