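"""Core containers shared across the pipeline.

Times are seconds on the session clock (t = 0 at session start). Event
sequences (licks, spikes, calcium events) are strictly increasing 1-D float
arrays. Trial and lick tables are pandas DataFrames with the documented
column schemas (see :mod:`licktime.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or event sequence violates its schema."""


class InvalidConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


class InsufficientDataError(ValueError):
    """Raised when a precondition on the amount of data is not met."""


def _as_sorted_times(x, name: str, *, strict: bool = True) -> np.ndarray:
    t = np.asarray(x, dtype=float).ravel()
    if t.size and not np.all(np.isfinite(t)):
        raise ValidationError(f"{name}: non-finite times")
    d = np.diff(t)
    if strict:
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise ValidationError(
                f"{name}: times not strictly increasing at index {i + 1}"
            )
    elif np.any(d < 0):
        raise ValidationError(f"{name}: times not sorted")
    return t


@dataclass
class Session:
    """Behavioral backbone: the trial table plus all lick times.

    ``trials`` columns: ``trial_id, start_s, water_s, rewarded`` and
    optionally ``opto_on_s, opto_off_s`` (absolute seconds; NaN when the
    trial carries no water / no stimulus). ``licks`` columns:
    ``trial_id, time_s``.
    """

    trials: pd.DataFrame
    licks: pd.DataFrame
    interval_s: float = 10.0

    def __post_init__(self) -> None:
        t = self.trials
        for col in ("trial_id", "start_s", "water_s", "rewarded"):
            if col not in t.columns:
                raise ValidationError(f"trials table missing column {col!r}")
        starts = t["start_s"].to_numpy(float)
        if np.any(np.diff(starts) <= 0):
            raise ValidationError("trial starts must be strictly increasing")
        if t["trial_id"].duplicated().any():
            raise ValidationError("duplicate trial_id in trials table")
        for col in ("trial_id", "time_s"):
            if col not in self.licks.columns:
                raise ValidationError(f"licks table missing column {col!r}")
        _as_sorted_times(self.licks["time_s"], "licks", strict=True)
        known = set(t["trial_id"])
        orphans = ~self.licks["trial_id"].isin(known)
        if orphans.any():
            row = int(np.argmax(orphans.to_numpy()))
            raise ValidationError(
                f"licks row {row}: trial_id "
                f"{self.licks['trial_id'].iloc[row]!r} not present in trials"
            )

    @property
    def lick_times(self) -> np.ndarray:
        return self.licks["time_s"].to_numpy(float)

    @property
    def water_times(self) -> np.ndarray:
        """Delivery times of actually-dispensed water (rewarded trials)."""
        w = self.trials["water_s"].to_numpy(float)
        return w[np.isfinite(w)]

    def scheduled_water(self) -> pd.Series:
        """Per-trial scheduled water time (start + interval), rewarded or not."""
        return self.trials["start_s"] + self.interval_s

    @property
    def duration_s(self) -> float:
        last_start = float(self.trials["start_s"].iloc[-1])
        end = last_start + 2.0 * self.interval_s
        if len(self.licks):
            end = max(end, float(self.licks["time_s"].iloc[-1]) + 1.0)
        return end

    def trial_water_or_scheduled(self) -> np.ndarray:
        """Water time where dispensed, otherwise the scheduled time."""
        w = self.trials["water_s"].to_numpy(float).copy()
        sched = self.scheduled_water().to_numpy(float)
        w[~np.isfinite(w)] = sched[~np.isfinite(w)]
        return w


@dataclass
class Bout:
    """A maximal run of licks separated from neighbours by silent gaps."""

    lick_times: np.ndarray
    trial_id: int
    isolated: bool
    context: str  # "pre_water" | "post_water"

    def __post_init__(self) -> None:
        self.lick_times = _as_sorted_times(self.lick_times, "bout licks")
        if self.lick_times.size == 0:
            raise ValidationError("a bout must contain at least one lick")
        if self.context not in ("pre_water", "post_water"):
            raise ValidationError(f"unknown bout context {self.context!r}")

    @property
    def first_lick_s(self) -> float:
        return float(self.lick_times[0])

    @property
    def last_lick_s(self) -> float:
        return float(self.lick_times[-1])

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bout_id": np.arange(len(bouts)),
            "trial_id": [b.trial_id for b in bouts],
            "first_lick_s": [b.first_lick_s for b in bouts],
            "last_lick_s": [b.last_lick_s for b in bouts],
            "n_licks": [b.n_licks for b in bouts],
            "isolated": [b.isolated for b in bouts],
            "context": [b.context for b in bouts],
        }
    )


@dataclass
class RateSeries:
    """A rate signal sampled at ``times`` (Hz), with optional dispersion."""

    times: np.ndarray
    values: np.ndarray
    bin_width_s: Optional[float] = None
    sem: Optional[np.ndarray] = None
    n: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("RateSeries axes must have equal length")
        if np.any(self.values < -1e-12):
            raise ValidationError("RateSeries values must be non-negative")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)


@dataclass
class SpikeTrain:
    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_sorted_times(self.times, f"spikes[{self.unit_id}]")


@dataclass
class CalciumEventTrain:
    dendrite_id: str
    region_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = _as_sorted_times(
            self.times, f"calcium[{self.dendrite_id}]"
        )
        if self.times.size and self.times[0] < 0:
            raise ValidationError("calcium event times must be non-negative")


@dataclass
class UnitChannelProfile:
    """Per-channel mean spike-peak amplitude for one sorted unit (µV)."""

    unit_id: str
    peak_uv: np.ndarray
    has_complex_spikes: bool = False
    noise_floor_uv: float = 30.0

    def __post_init__(self) -> None:
        self.peak_uv = np.asarray(self.peak_uv, dtype=float).ravel()
        if self.peak_uv.size == 0:
            raise ValidationError("channel profile needs at least one channel")
        if np.any(self.peak_uv < 0):
            raise ValidationError("peak amplitudes must be non-negative")


@dataclass
class UnitClassification:
    unit_id: str
    label: str  # PC_unambiguous | PC_putative | MLI | other
    channel_count: int


@dataclass
class EntrainmentResult:
    """Per-unit entrainment of spiking to the lick cycle."""

    unit_id: str
    n_spikes: int
    resultant_length: float
    resultant_angle: float
    rayleigh_p: float
    q_value: float = float("nan")
    entrained: bool = False
    histogram: Optional[np.ndarray] = None      # 20 bins, width pi/10
    density_grid: Optional[np.ndarray] = None   # phase grid points
    density: Optional[np.ndarray] = None
    suprathreshold_mask: Optional[np.ndarray] = None


@dataclass
class AlignedResponse:
    """Event-triggered binned rate relative to a baseline."""

    unit_id: str
    event: str                      # first_lick | last_lick | water
    bin_edges: np.ndarray           # length n_bins + 1, seconds re event
    mean_delta_rate: np.ndarray     # Hz per bin, aligned mean minus baseline
    sem: np.ndarray
    baseline_rate: float
    n_events: int
    rate_matrix: Optional[np.ndarray] = None  # n_events x n_bins raw rates

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.size != self.mean_delta_rate.size + 1:
            raise ValidationError("bin_edges must bracket the rate bins")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin_edges must increase")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RampClassification:
    unit_id: str
    event: str                      # first_lick | last_lick
    modulation: str                 # positive | negative | none
    onset_time_s: Optional[float] = None  # re event; None when modulation=none
    context: str = "any"            # pre_water | post_water | any


@dataclass
class GroundTruth:
    """Book-keeping emitted by the generator for downstream recovery tests."""

    unit_specs: dict = field(default_factory=dict)
    dendrite_specs: dict = field(default_factory=dict)
    bouts: Optional[pd.DataFrame] = None   # trial_id, onset_s, offset_s, context
    opto: Optional[pd.DataFrame] = None    # trial_id, stimulated, rebound
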