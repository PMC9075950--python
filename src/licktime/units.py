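"""Unit classification: unambiguous PCs, putative PCs, opto-tagged MLIs.

Purkinje cells have large somata relative to silicon-probe pad spacing, so
their spikes appear on many channels; units with complex spikes in the
recording are unambiguous PCs, and complex-spike-free units whose mean
spike peak clears the noise floor (~30 µV) on at least 7 channels are
putative PCs. Molecular-layer interneurons are identified by short-latency
responses to light pulses in animals expressing ChR2 in that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    InsufficientDataError,
    UnitChannelProfile,
    UnitClassification,
    ValidationError,
)

CHANNEL_THRESHOLD = 7
NOISE_FLOOR_UV = 30.0


def channel_count(
    profile: UnitChannelProfile, noise_floor_uv: Optional[float] = None
) -> int:
    """Number of channels whose mean spike peak is strictly above the floor."""
    floor = profile.noise_floor_uv if noise_floor_uv is None else noise_floor_uv
    return int(np.sum(profile.peak_uv > floor))


def classify_unit(
    profile: UnitChannelProfile,
    channel_threshold: int = CHANNEL_THRESHOLD,
    noise_floor_uv: Optional[float] = None,
) -> UnitClassification:
    """Two-stage PC rule: complex spikes dominate; otherwise a wide spatial
    footprint (>= ``channel_threshold`` channels above the floor) marks a
    putative PC; everything else is ``other`` (MLIs only via the opto-tag)."""
    n = channel_count(profile, noise_floor_uv)
    if profile.has_complex_spikes:
        label = "PC_unambiguous"
    elif n >= channel_threshold:
        label = "PC_putative"
    else:
        label = "other"
    return UnitClassification(
        unit_id=profile.unit_id, label=label, channel_count=n
    )


@dataclass
class RosterSummary:
    counts: dict[str, int]
    pc_set: list[str]
    classifications: list[UnitClassification]

    @property
    def n_pc(self) -> int:
        return len(self.pc_set)


def classify_roster(
    profiles: Sequence[UnitChannelProfile],
    channel_threshold: int = CHANNEL_THRESHOLD,
    noise_floor_uv: Optional[float] = None,
) -> RosterSummary:
    """Classify every unit; the PC set is unambiguous plus putative PCs."""
    if not profiles:
        raise ValidationError("classify_roster requires at least one profile")
    ids = [p.unit_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate unit_ids in roster")
    cls = [
        classify_unit(p, channel_threshold, noise_floor_uv) for p in profiles
    ]
    counts: dict[str, int] = {}
    for c in cls:
        counts[c.label] = counts.get(c.label, 0) + 1
    pc_set = [
        c.unit_id for c in cls if c.label in ("PC_unambiguous", "PC_putative")
    ]
    return RosterSummary(counts=counts, pc_set=pc_set, classifications=cls)


@dataclass
class OptoTagResult:
    tagged: bool
    p_value: float
    median_latency_s: float
    response_fraction: float
    chance_fraction: float


def optotag_short_latency(
    spike_times,
    pulse_times,
    latency_window_ms: float = 10.0,
    alpha: float = 0.05,
    session_duration_s: Optional[float] = None,
) -> OptoTagResult:
    """Flag a unit as opto-tagged when the fraction of light pulses followed
    by a spike within the latency window significantly exceeds the
    rate-matched chance level (one-sided binomial test).

    Chance is 1 - exp(-r*w) for a Poisson unit at the unit's overall mean
    rate r and window w.
    """
    spikes = np.asarray(spike_times, dtype=float)
    pulses = np.asarray(pulse_times, dtype=float)
    if pulses.size == 0:
        raise InsufficientDataError("optotag requires at least one pulse")
    if pulses.size < 10:
        raise InsufficientDataError(
            f"optotag requires >= 10 pulses, got {pulses.size}"
        )
    w = latency_window_ms / 1000.0
    if session_duration_s is None:
        span_candidates = [pulses.max() + 1.0]
        if spikes.size:
            span_candidates.append(spikes.max() + 1.0)
        session_duration_s = max(span_candidates)
    rate = spikes.size / session_duration_s
    chance = 1.0 - np.exp(-rate * w)

    latencies = []
    hits = 0
    for p in pulses:
        i = np.searchsorted(spikes, p, side="left")
        if i < spikes.size and spikes[i] - p < w:
            hits += 1
            latencies.append(spikes[i] - p)
    if spikes.size == 0:
        return OptoTagResult(
            tagged=False,
            p_value=1.0,
            median_latency_s=float("nan"),
            response_fraction=0.0,
            chance_fraction=0.0,
        )
    # binomtest needs p in (0, 1); a zero-rate unit cannot be tagged above
    chance = min(max(chance, 1e-12), 1.0 - 1e-12)
    test = stats.binomtest(hits, pulses.size, chance, alternative="greater")
    p_value = float(test.pvalue)
    return OptoTagResult(
        tagged=bool(p_value < alpha),
        p_value=p_value,
        median_latency_s=float(np.median(latencies)) if latencies else float("nan"),
        response_fraction=hits / pulses.size,
        chance_fraction=float(chance),
    )
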