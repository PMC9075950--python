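"""Lick-train parsing: rates, bouts, PSTHs, and optogenetic lick metrics.

Conventions: all analysis windows are half-open ``[lo, hi)``; a lick exactly
at the water time counts as post-water. The instantaneous lick rate is the
inverse of the inter-lick interval. A new bout begins when an inter-lick
interval reaches the bout break (default 1.0 s, set between the rhythmic
ILI ceiling of 175 ms and the 2-s isolation criterion); a bout is
"isolated"/"well-separated" when at least 2 s of non-licking precede it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    Bout,
    RateSeries,
    Session,
    ValidationError,
    _as_sorted_times,
)

ISOLATION_S = 2.0
BOUT_BREAK_S = 1.0


def instantaneous_lick_rate(licks) -> RateSeries:
    """1/ILI at each lick after the first; empty series for < 2 licks."""
    t = _as_sorted_times(licks, "licks")
    if t.size < 2:
        return RateSeries(times=np.empty(0), values=np.empty(0))
    ili = np.diff(t)
    return RateSeries(times=t[1:], values=1.0 / ili)


def _water_reference(session: Optional[Session]) -> Optional[dict]:
    if session is None:
        return None
    w = session.trial_water_or_scheduled()
    return dict(zip(session.trials["trial_id"], w))


def segment_bouts(
    licks,
    bout_break_s: float = BOUT_BREAK_S,
    isolation_s: float = ISOLATION_S,
    session: Optional[Session] = None,
    lick_trial_ids=None,
) -> list[Bout]:
    """Partition licks into maximal runs with internal gaps < ``bout_break_s``.

    Context (pre/post water) is labeled by comparing the bout's first lick
    with its trial's water time (scheduled time on omission trials); it
    defaults to ``pre_water`` when no session is supplied. A bout's trial is
    the trial of its first lick when per-lick trial ids are available,
    otherwise the trial whose span contains the first lick.
    """
    t = _as_sorted_times(licks, "licks")
    if t.size == 0:
        return []
    if bout_break_s <= 0:
        raise ValidationError("bout_break_s must be positive")
    gaps = np.diff(t)
    breaks = np.nonzero(gaps >= bout_break_s)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [t.size - 1]])

    water_by_trial = _water_reference(session)
    if lick_trial_ids is None and session is not None:
        lick_trial_ids = session.licks["trial_id"].to_numpy()
    trial_starts = (
        session.trials["start_s"].to_numpy(float) if session is not None else None
    )
    trial_ids = (
        session.trials["trial_id"].to_numpy() if session is not None else None
    )

    bouts = []
    for s, e in zip(starts, ends):
        first = t[s]
        prev_gap = np.inf if s == 0 else first - t[s - 1]
        if lick_trial_ids is not None:
            tid = int(lick_trial_ids[s])
        elif trial_starts is not None:
            tid = int(
                trial_ids[
                    max(0, np.searchsorted(trial_starts, first, side="right") - 1)
                ]
            )
        else:
            tid = -1
        context = "pre_water"
        if water_by_trial is not None and tid in water_by_trial:
            w = water_by_trial[tid]
            if np.isfinite(w) and first >= w:
                context = "post_water"
        bouts.append(
            Bout(
                lick_times=t[s : e + 1],
                trial_id=tid,
                isolated=bool(prev_gap >= isolation_s),
                context=context,
            )
        )
    return bouts


def _binned_rate_per_trial(
    licks: np.ndarray, events: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """n_events x n_bins lick rates (Hz): counts in event-relative bins."""
    widths = np.diff(edges)
    rates = np.empty((events.size, widths.size))
    for i, ev in enumerate(events):
        counts = np.diff(np.searchsorted(licks, ev + edges))
        rates[i] = counts / widths
    return rates


@dataclass
class PSTHResult:
    series: RateSeries
    n_trials: int
    n_excluded: int
    reason: str = ""


def trial_averaged_lick_psth(
    session: Session,
    align: str,
    window: tuple[float, float] = (-2.0, 4.0),
    bin_s: float = 0.1,
    *,
    isolated_only: bool = False,
    bout_break_s: float = BOUT_BREAK_S,
) -> PSTHResult:
    """Mean binned lick rate across trials aligned to ``water``,
    ``first_lick``, or ``last_lick``, with SEM across trials.

    Trials lacking the alignment event are excluded and counted. First/last
    lick events are per-trial bout boundaries (first bout's first lick,
    last bout's last lick), optionally restricted to isolated bouts.
    """
    if align not in ("water", "first_lick", "last_lick"):
        raise ValidationError(f"unknown alignment {align!r}")
    lo, hi = window
    if not hi > lo:
        raise ValidationError("window must satisfy hi > lo")
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)

    events = []
    n_excl = 0
    if align == "water":
        for w in session.trials["water_s"]:
            if np.isfinite(w):
                events.append(float(w))
            else:
                n_excl += 1
    else:
        bouts = segment_bouts(
            session.lick_times, bout_break_s=bout_break_s, session=session
        )
        if isolated_only:
            bouts = [b for b in bouts if b.isolated]
        by_trial: dict[int, list[Bout]] = {}
        for b in bouts:
            by_trial.setdefault(b.trial_id, []).append(b)
        for tid in session.trials["trial_id"]:
            bs = by_trial.get(int(tid))
            if not bs:
                n_excl += 1
                continue
            events.append(
                bs[0].first_lick_s if align == "first_lick" else bs[-1].last_lick_s
            )
    if not events:
        return PSTHResult(
            series=RateSeries(
                times=lo + bin_s * (np.arange(n_bins) + 0.5),
                values=np.zeros(n_bins),
                bin_width_s=bin_s,
            ),
            n_trials=0,
            n_excluded=n_excl,
            reason="no trials contain the alignment event",
        )
    rates = _binned_rate_per_trial(session.lick_times, np.asarray(events), edges)
    mean = rates.mean(axis=0)
    sem = (
        rates.std(axis=0, ddof=1) / np.sqrt(rates.shape[0])
        if rates.shape[0] > 1
        else np.zeros(n_bins)
    )
    return PSTHResult(
        series=RateSeries(
            times=lo + bin_s * (np.arange(n_bins) + 0.5),
            values=mean,
            bin_width_s=bin_s,
            sem=sem,
            n=rates.shape[0],
        ),
        n_trials=rates.shape[0],
        n_excluded=n_excl,
    )


@dataclass
class InitiationHistogram:
    edges: np.ndarray       # seconds relative to water
    counts: np.ndarray
    n_pre: int
    n_post: int


def bout_initiation_histogram(
    bouts: list[Bout],
    water_by_trial: dict[int, float],
    bin_s: float = 0.25,
    window: tuple[float, float] = (-5.0, 2.0),
) -> InitiationHistogram:
    """Counts of first-lick times relative to the trial's water time."""
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    rel = np.array(
        [
            b.first_lick_s - water_by_trial[b.trial_id]
            for b in bouts
            if b.trial_id in water_by_trial
        ]
    )
    counts, _ = (
        np.histogram(rel, edges) if rel.size else (np.zeros(n_bins, int), edges)
    )
    n_pre = int(np.sum(rel < 0)) if rel.size else 0
    n_post = int(np.sum(rel >= 0)) if rel.size else 0
    return InitiationHistogram(
        edges=edges, counts=counts, n_pre=n_pre, n_post=n_post
    )


@dataclass
class OptoLickMetrics:
    variance_ratio: float           # stim during-window var / control var
    rate_during_stim: float
    rate_during_control: float
    rate_rebound_stim: float
    rate_rebound_control: float
    rebound_prob_stim: float
    rebound_prob_control: float
    n_stim_trials: int
    n_control_trials: int


def opto_lick_metrics(
    session: Session,
    *,
    rebound_window_s: float = 2.0,
    bin_s: float = 0.1,
    isolation_s: float = ISOLATION_S,
    bout_break_s: float = BOUT_BREAK_S,
) -> OptoLickMetrics:
    """Per-session optogenetic lick metrics.

    Stimulated trials carry finite ``opto_on_s``/``opto_off_s``; controls
    are the remaining unrewarded trials, evaluated over the matched time
    window. The lick variance during the stimulus is normalized to the same
    window of the control condition. The rebound probability is the
    fraction of trials with a well-separated bout initiation (>= 2 s of
    prior non-licking) inside ``[off, off + rebound_window_s)``.
    """
    trials = session.trials
    if "opto_on_s" not in trials.columns:
        raise ValidationError("session trials carry no opto window columns")
    unrewarded = ~trials["rewarded"].astype(bool)
    stim_mask = unrewarded & np.isfinite(trials["opto_on_s"].astype(float))
    ctrl_mask = unrewarded & ~np.isfinite(trials["opto_on_s"].astype(float))
    stim = trials[stim_mask]
    ctrl = trials[ctrl_mask]
    if len(stim) == 0:
        raise ValidationError("no stimulated trials in session")
    if len(ctrl) == 0:
        raise ValidationError("no control (unstimulated, unrewarded) trials")

    # matched window for controls: modal stimulus offsets re trial start
    on_off = (stim["opto_on_s"] - stim["start_s"]).to_numpy(float)
    dur = (stim["opto_off_s"] - stim["opto_on_s"]).to_numpy(float)
    w_on, w_dur = float(np.median(on_off)), float(np.median(dur))

    licks = session.lick_times
    n_bins = max(1, int(round(w_dur / bin_s)))
    edges = bin_s * np.arange(n_bins + 1)

    def group_rates(rows: pd.DataFrame, offset: float, width: float):
        starts = rows["start_s"].to_numpy(float) + offset
        e = width / n_bins * np.arange(n_bins + 1)
        return _binned_rate_per_trial(licks, starts, e)

    stim_during = group_rates(stim, w_on, w_dur)
    ctrl_during = group_rates(ctrl, w_on, w_dur)
    v_ctrl = float(np.var(ctrl_during, ddof=1)) if ctrl_during.size > 1 else np.nan
    v_stim = float(np.var(stim_during, ddof=1)) if stim_during.size > 1 else np.nan
    variance_ratio = v_stim / v_ctrl if v_ctrl and np.isfinite(v_ctrl) else np.nan

    reb_bins = max(1, int(round(rebound_window_s / bin_s)))
    stim_reb = _binned_rate_per_trial(
        licks,
        stim["start_s"].to_numpy(float) + w_on + w_dur,
        bin_s * np.arange(reb_bins + 1),
    )
    ctrl_reb = _binned_rate_per_trial(
        licks,
        ctrl["start_s"].to_numpy(float) + w_on + w_dur,
        bin_s * np.arange(reb_bins + 1),
    )

    bouts = [
        b
        for b in segment_bouts(
            licks,
            bout_break_s=bout_break_s,
            isolation_s=isolation_s,
            session=session,
        )
        if b.isolated
    ]
    onsets = np.array([b.first_lick_s for b in bouts])

    def rebound_fraction(rows: pd.DataFrame) -> float:
        if not len(rows):
            return float("nan")
        hits = 0
        for start in rows["start_s"].to_numpy(float):
            off = start + w_on + w_dur
            if onsets.size and np.any(
                (onsets >= off) & (onsets < off + rebound_window_s)
            ):
                hits += 1
        return hits / len(rows)

    return OptoLickMetrics(
        variance_ratio=variance_ratio,
        rate_during_stim=float(stim_during.mean()),
        rate_during_control=float(ctrl_during.mean()),
        rate_rebound_stim=float(stim_reb.mean()),
        rate_rebound_control=float(ctrl_reb.mean()),
        rebound_prob_stim=rebound_fraction(stim),
        rebound_prob_control=rebound_fraction(ctrl),
        n_stim_trials=len(stim),
        n_control_trials=len(ctrl),
    )
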