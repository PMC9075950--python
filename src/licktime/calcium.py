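"""Dendritic calcium-event-rate analysis (climbing-fiber-evoked activity).

Each dendrite contributes an ordered list of calcium event times at a
spontaneous climbing-fiber rate of 1-2 Hz. Regions of interest are flagged
water-responsive when the region-averaged peri-water event rate peaks above
the baseline mean + 3 SD; per-dendrite initiation ramps are detected with
the same 3-SD rule over 100-ms bins in [-1.0, +0.5] s around the first
lick. The reference distribution for mean and SD is the pre-window
baseline [-3, -1) s before the event, since the raw event rate is too low
for a per-dendrite nonlicking estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import CalciumEventTrain, InsufficientDataError

BIN_S = 0.1
ONSET_WINDOW = (-1.0, 0.5)
BASELINE_WINDOW = (-3.0, -1.0)
SD_CUTOFF = 3.0
MIN_DENDRITES_PER_REGION = 5
MIN_BOUTS_FOR_ONSET = 20


def aligned_event_rate(
    event_times: np.ndarray,
    align_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float = BIN_S,
) -> tuple[np.ndarray, np.ndarray]:
    """(bin_edges, mean rate in Hz) of events around the alignment times."""
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for ev in align_times:
        counts += np.diff(np.searchsorted(event_times, ev + edges))
    rate = counts / (bin_s * max(1, align_times.size))
    return edges, rate


@dataclass
class RegionResponse:
    region_id: str
    responsive: Optional[bool]      # None when the region was skipped
    peak_rate_hz: float = float("nan")
    baseline_mean_hz: float = float("nan")
    baseline_sd_hz: float = float("nan")
    n_dendrites: int = 0
    skipped_reason: str = ""


def region_responsiveness(
    trains: Sequence[CalciumEventTrain],
    water_times: np.ndarray,
    *,
    peri_water_s: float = 0.5,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    sd_cutoff: float = SD_CUTOFF,
    min_dendrites: int = MIN_DENDRITES_PER_REGION,
) -> list[RegionResponse]:
    """Flag each region water-responsive when its dendrite-averaged aligned
    event rate peaks within +/- ``peri_water_s`` of water delivery above
    baseline mean + ``sd_cutoff`` SD of the baseline bins."""
    water_times = np.asarray(water_times, dtype=float)
    by_region: dict[str, list[CalciumEventTrain]] = {}
    for t in trains:
        by_region.setdefault(t.region_id, []).append(t)
    out = []
    for region_id in sorted(by_region):
        group = by_region[region_id]
        if len(group) < min_dendrites:
            out.append(
                RegionResponse(
                    region_id=region_id,
                    responsive=None,
                    n_dendrites=len(group),
                    skipped_reason=(
                        f"only {len(group)} dendrites "
                        f"(need >= {min_dendrites})"
                    ),
                )
            )
            continue
        window = (baseline_window[0], peri_water_s)
        rates = []
        for tr in group:
            _, r = aligned_event_rate(tr.times, water_times, window)
            rates.append(r)
        edges = window[0] + BIN_S * np.arange(len(rates[0]) + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean_rate = np.mean(rates, axis=0)
        base = mean_rate[
            (centers >= baseline_window[0]) & (centers < baseline_window[1])
        ]
        peri = mean_rate[np.abs(centers) <= peri_water_s]
        m, s = float(base.mean()), float(base.std(ddof=1))
        peak = float(peri.max())
        out.append(
            RegionResponse(
                region_id=region_id,
                responsive=bool(peak > m + sd_cutoff * s),
                peak_rate_hz=peak,
                baseline_mean_hz=m,
                baseline_sd_hz=s,
                n_dendrites=len(group),
            )
        )
    return out


def calcium_ramp_onset(
    train: CalciumEventTrain,
    first_lick_times,
    *,
    onset_window: tuple[float, float] = ONSET_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    sd_cutoff: float = SD_CUTOFF,
    min_bouts: int = MIN_BOUTS_FOR_ONSET,
) -> Optional[float]:
    """Onset = first 100-ms bin in [-1.0, +0.5] s around the first lick
    whose aligned event rate exceeds baseline mean + 3 SD; None if the
    rate never crosses. Requires >= ``min_bouts`` aligned bouts."""
    events = np.asarray(first_lick_times, dtype=float)
    if events.size < min_bouts:
        raise InsufficientDataError(
            f"onset detection needs >= {min_bouts} bouts, got {events.size}"
        )
    if train.times.size == 0:
        return None
    window = (baseline_window[0], onset_window[1])
    edges, rate = aligned_event_rate(train.times, events, window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    base = rate[(centers >= baseline_window[0]) & (centers < baseline_window[1])]
    m, s = float(base.mean()), float(base.std(ddof=1))
    in_win = (centers >= onset_window[0]) & (centers < onset_window[1])
    above = in_win & (rate > m + sd_cutoff * s)
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    return float(edges[i])


@dataclass
class TerminationRateChange:
    rate_before_hz: float
    rate_after_hz: float
    p_value: float
    n_trials: int
    underpowered: bool


def termination_rate_change(
    train: CalciumEventTrain,
    last_lick_times,
    water_times,
    *,
    window_s: float = 0.5,
    min_post_water_s: float = 2.0,
    min_trials_for_test: int = 6,
) -> Optional[TerminationRateChange]:
    """Mean event rate in the ``window_s`` before vs after the last lick,
    with a paired Wilcoxon signed-rank comparison at report stage.

    Included trials: the last lick falls >= ``min_post_water_s`` after the
    nearest preceding water delivery (rewarded trials), or any last lick
    when no water preceded it (omission trials). Returns None when no
    trial qualifies.
    """
    events = np.asarray(last_lick_times, dtype=float)
    water = np.asarray(water_times, dtype=float)
    keep = []
    for ev in events:
        idx = np.searchsorted(water, ev) - 1
        if idx < 0 or ev - water[idx] >= min_post_water_s:
            keep.append(ev)
    if not keep:
        return None
    keep_arr = np.asarray(keep)
    before = np.array(
        [
            np.diff(np.searchsorted(train.times, [ev - window_s, ev]))[0]
            / window_s
            for ev in keep_arr
        ]
    )
    after = np.array(
        [
            np.diff(np.searchsorted(train.times, [ev, ev + window_s]))[0]
            / window_s
            for ev in keep_arr
        ]
    )
    underpowered = keep_arr.size < min_trials_for_test
    if underpowered or np.all(before == after):
        p = float("nan")
    else:
        # low-rate paired counts carry many ties and zero differences;
        # Pratt zero handling + continuity correction keeps the test
        # from being anticonservative on such discrete data
        p = float(
            stats.wilcoxon(
                before, after, zero_method="pratt", correction=True
            ).pvalue
        )
    return TerminationRateChange(
        rate_before_hz=float(before.mean()),
        rate_after_hz=float(after.mean()),
        p_value=p,
        n_trials=int(keep_arr.size),
        underpowered=underpowered,
    )
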