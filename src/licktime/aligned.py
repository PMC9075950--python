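"""Event-triggered simple-spike analysis around bout initiation/termination.

The change in spike rate (delta rate) is measured against the unit's
baseline firing during non-licking periods (>= 2 s from every lick). Units
are classified as positively modulated at bout initiation when the
trial-averaged delta-rate trace shows three consecutive bin-to-bin
increases (100-ms bins), each exceeding the trace's own bin-to-bin noise
floor, within [-1.0, +0.5] s of the first lick; the ramp onset is the left
edge of the first incremented bin of the earliest such run. The mirrored rule on decreases yields negative modulation.
Termination modulation compares the mean delta rate in the 300 ms
preceding the last lick with the spread of 100-ms bins in the alternative
baseline window 1-5 s before the last lick (+/- 2 SD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    AlignedResponse,
    Bout,
    InsufficientDataError,
    RampClassification,
    Session,
    ValidationError,
)

FIRST_LICK_WINDOW = (-1.0, 0.5)
BIN_S = 0.1
N_CONSECUTIVE = 3
TERM_WINDOW_S = 0.3
TERM_BASELINE = (-5.0, -1.0)
TERM_SD_CUTOFF = 2.0
BASELINE_EXCLUSION_S = 2.0


def nonlicking_intervals(
    licks: np.ndarray, duration_s: float, exclusion_s: float = BASELINE_EXCLUSION_S
) -> np.ndarray:
    """Complement of [lick - excl, lick + excl) unions within [0, duration)."""
    if licks.size == 0:
        return np.array([[0.0, duration_s]])
    lo = np.clip(licks - exclusion_s, 0.0, duration_s)
    hi = np.clip(licks + exclusion_s, 0.0, duration_s)
    merged = []
    cur_lo, cur_hi = lo[0], hi[0]
    for a, b in zip(lo[1:], hi[1:]):
        if a <= cur_hi:
            cur_hi = max(cur_hi, b)
        else:
            merged.append((cur_lo, cur_hi))
            cur_lo, cur_hi = a, b
    merged.append((cur_lo, cur_hi))
    out = []
    prev = 0.0
    for a, b in merged:
        if a > prev:
            out.append((prev, a))
        prev = b
    if prev < duration_s:
        out.append((prev, duration_s))
    return np.array(out) if out else np.empty((0, 2))


def baseline_rate(
    spikes,
    licks,
    duration_s: float,
    exclusion_s: float = BASELINE_EXCLUSION_S,
    min_time_s: float = 10.0,
) -> float:
    """Mean firing rate over all non-licking periods (>= ``exclusion_s``
    from every lick)."""
    spikes = np.asarray(spikes, dtype=float)
    licks = np.asarray(licks, dtype=float)
    intervals = nonlicking_intervals(licks, duration_s, exclusion_s)
    total = float(np.sum(intervals[:, 1] - intervals[:, 0])) if intervals.size else 0.0
    if total <= min_time_s:
        raise InsufficientDataError(
            f"only {total:.1f} s of non-licking time available "
            f"(need > {min_time_s:.1f} s)"
        )
    count = 0
    for a, b in intervals:
        i, j = np.searchsorted(spikes, [a, b])
        count += j - i
    return count / total


def aligned_delta_rate(
    spikes,
    events,
    window: tuple[float, float],
    bin_s: float = BIN_S,
    baseline: float = 0.0,
    *,
    unit_id: str = "",
    event_name: str = "first_lick",
    keep_matrix: bool = False,
) -> Optional[AlignedResponse]:
    """Per-bin mean rate across events minus ``baseline``, SEM across
    events. Returns None for an empty event list (explicit empty result)."""
    spikes = np.asarray(spikes, dtype=float)
    events = np.asarray(events, dtype=float)
    if events.size == 0:
        return None
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    if n_bins <= 0:
        raise ValidationError("window must span at least one bin")
    edges = lo + bin_s * np.arange(n_bins + 1)
    rates = np.empty((events.size, n_bins))
    for i, ev in enumerate(events):
        rates[i] = np.diff(np.searchsorted(spikes, ev + edges)) / bin_s
    mean = rates.mean(axis=0) - baseline
    sem = (
        rates.std(axis=0, ddof=1) / np.sqrt(events.size)
        if events.size > 1
        else np.zeros(n_bins)
    )
    return AlignedResponse(
        unit_id=unit_id,
        event=event_name,
        bin_edges=edges,
        mean_delta_rate=mean,
        sem=sem,
        baseline_rate=baseline,
        n_events=int(events.size),
        rate_matrix=rates if keep_matrix else None,
    )


def _earliest_run_onset(
    values: np.ndarray, edges: np.ndarray, sign: float, threshold: float
):
    """Left edge of the first incremented bin of the earliest run of
    ``N_CONSECUTIVE`` sign-matching bin-to-bin changes each exceeding
    ``threshold``, or None."""
    d = sign * np.diff(values)
    good = d > threshold
    for start in range(good.size - N_CONSECUTIVE + 1):
        if np.all(good[start : start + N_CONSECUTIVE]):
            return float(edges[start + 1])  # bin start+1 is first incremented
    return None


def _increment_threshold(response: AlignedResponse, n_sd: float) -> float:
    """Noise floor for a meaningful bin-to-bin change: ``n_sd`` times the
    SD of the difference of two bin means (sqrt(2) x per-bin SEM)."""
    if n_sd <= 0 or response.sem is None or not np.any(response.sem > 0):
        return 0.0
    return float(n_sd * np.sqrt(2.0) * np.median(response.sem))


def classify_first_lick_modulation(
    response: AlignedResponse,
    increment_threshold_sd: float = 1.0,
) -> RampClassification:
    """Apply the three-consecutive-increases rule over [-1.0, +0.5] s.

    Each of the three consecutive changes must exceed a noise floor of
    ``increment_threshold_sd`` x sqrt(2) x the median per-bin SEM, so that
    runs of sub-noise wiggles do not qualify; with no dispersion estimate
    (SEM absent or zero) the rule reduces to strict inequalities. Positive
    wins over negative when its earliest run starts no later (ties favour
    positive); otherwise the earlier-onset pattern wins.
    """
    lo, hi = FIRST_LICK_WINDOW
    n_expected = int(round((hi - lo) / BIN_S))
    if (
        response.mean_delta_rate.size != n_expected
        or abs(response.bin_edges[0] - lo) > 1e-9
        or abs(response.bin_edges[-1] - hi) > 1e-9
    ):
        raise ValidationError(
            "first-lick classification expects the 15 bins of [-1.0, +0.5] s"
        )
    v = response.mean_delta_rate
    e = response.bin_edges
    thr = _increment_threshold(response, increment_threshold_sd)
    pos = _earliest_run_onset(v, e, +1.0, thr)
    neg = _earliest_run_onset(v, e, -1.0, thr)
    if pos is None and neg is None:
        mod, onset = "none", None
    elif neg is None or (pos is not None and pos <= neg):
        mod, onset = "positive", pos
    else:
        mod, onset = "negative", neg
    return RampClassification(
        unit_id=response.unit_id,
        event="first_lick",
        modulation=mod,
        onset_time_s=onset,
    )


def classify_termination_modulation(
    spikes,
    last_lick_times,
    baseline: float = 0.0,
    *,
    unit_id: str = "",
    window_pre_s: float = TERM_WINDOW_S,
    alt_baseline: tuple[float, float] = TERM_BASELINE,
    sd_cutoff: float = TERM_SD_CUTOFF,
) -> RampClassification:
    """Mean delta rate in the 300 ms before the last lick vs +/- ``sd_cutoff``
    SD of the 100-ms bins in the alternative baseline (1-5 s pre-lick)."""
    events = np.asarray(last_lick_times, dtype=float)
    if events.size == 0:
        raise InsufficientDataError("no last-lick events supplied")
    resp = aligned_delta_rate(
        spikes,
        events,
        window=(alt_baseline[0], 0.0),
        bin_s=BIN_S,
        baseline=baseline,
        unit_id=unit_id,
        event_name="last_lick",
    )
    centers = resp.bin_centers
    base_mask = (centers >= alt_baseline[0]) & (centers < alt_baseline[1])
    win_mask = centers >= -window_pre_s
    base_bins = resp.mean_delta_rate[base_mask]
    stat = float(resp.mean_delta_rate[win_mask].mean())
    m, s = float(base_bins.mean()), float(base_bins.std(ddof=1))
    if stat > m + sd_cutoff * s:
        mod = "positive"
    elif stat < m - sd_cutoff * s:
        mod = "negative"
    else:
        mod = "none"
    return RampClassification(
        unit_id=unit_id,
        event="last_lick",
        modulation=mod,
        onset_time_s=-window_pre_s if mod != "none" else None,
    )


@dataclass
class ContextClassification:
    unit_id: str
    by_context: dict[str, RampClassification]   # context -> init classification
    termination: Optional[RampClassification]
    category: frozenset                         # tuning tags

    @property
    def tags(self) -> set:
        return set(self.category)


def split_by_context(bouts: Sequence[Bout]) -> dict[str, np.ndarray]:
    """First-lick event times split into pre/post-water sets."""
    out = {"pre_water": [], "post_water": []}
    for b in bouts:
        out[b.context].append(b.first_lick_s)
    return {k: np.asarray(v) for k, v in out.items()}


def classify_unit_by_context(
    unit_id: str,
    spikes,
    bouts: Sequence[Bout],
    baseline: float,
    *,
    min_events: int = 5,
) -> ContextClassification:
    """Per-context initiation classification plus termination, rolled into a
    tuning category: {pre-init+, post-init+, term+, negative-any} (negative
    responses are pooled into a single tag, being relatively rare)."""
    events = split_by_context(bouts)
    by_context: dict[str, RampClassification] = {}
    tags: set[str] = set()
    for ctx, ev in events.items():
        if ev.size < min_events:
            continue  # context unavailable
        resp = aligned_delta_rate(
            spikes,
            ev,
            FIRST_LICK_WINDOW,
            BIN_S,
            baseline,
            unit_id=unit_id,
            event_name="first_lick",
        )
        cls = classify_first_lick_modulation(resp)
        cls.context = ctx
        by_context[ctx] = cls
        if cls.modulation == "positive":
            tags.add("pre-init+" if ctx == "pre_water" else "post-init+")
        elif cls.modulation == "negative":
            tags.add("negative-any")
    last_licks = np.array([b.last_lick_s for b in bouts])
    term = None
    if last_licks.size >= min_events:
        term = classify_termination_modulation(
            spikes, last_licks, baseline, unit_id=unit_id
        )
        if term.modulation == "positive":
            tags.add("term+")
        elif term.modulation == "negative":
            tags.add("negative-any")
    return ContextClassification(
        unit_id=unit_id,
        by_context=by_context,
        termination=term,
        category=frozenset(tags),
    )


def population_onset_time(
    responses: Sequence[AlignedResponse],
) -> Optional[float]:
    """First-lick ramp rule applied to the unit-averaged delta-rate trace;
    the (negative) onset is the population's lead on the first lick."""
    if len(responses) < 5:
        raise InsufficientDataError(
            f"population onset needs >= 5 units, got {len(responses)}"
        )
    mats = np.vstack([r.mean_delta_rate for r in responses])
    pooled = AlignedResponse(
        unit_id="population",
        event=responses[0].event,
        bin_edges=responses[0].bin_edges,
        mean_delta_rate=mats.mean(axis=0),
        sem=mats.std(axis=0, ddof=1) / np.sqrt(len(responses)),
        baseline_rate=0.0,
        n_events=len(responses),
    )
    cls = classify_first_lick_modulation(pooled)
    return cls.onset_time_s if cls.modulation == "positive" else None


def peak_delta_rate(response: AlignedResponse, window=(0.0, 0.5)) -> float:
    """Max binned delta rate within ``window`` of the event (Hz)."""
    c = response.bin_centers
    sel = (c >= window[0]) & (c < window[1])
    return float(response.mean_delta_rate[sel].max())


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r: float
    n_bins: int
    degenerate: bool = False


def lickrate_spikerate_correlation(
    session: Session,
    spikes,
    *,
    bin_s: float = 1.0,
    min_bins: int = 10,
) -> CorrelationResult:
    """Least-squares line through per-1-s-bin (lick rate, spike rate) pairs.

    Trial inclusion: the trial's first lick occurs >= 2 s after trial start
    (enough pre-lick data) and its last lick leaves >= 1 s of post-lick
    recorded data before the session ends.
    """
    spikes = np.asarray(spikes, dtype=float)
    licks = session.lick_times
    trial_ids = session.licks["trial_id"].to_numpy()
    session_end = session.duration_s
    pairs_x, pairs_y = [], []
    for row in session.trials.itertuples(index=False):
        t_licks = licks[trial_ids == row.trial_id]
        if t_licks.size == 0:
            continue
        if t_licks[0] < row.start_s + 2.0:
            continue
        if t_licks[-1] > session_end - 1.0:
            continue
        # bins cover the trial's full licking span, through the
        # consumption period that runs past the scheduled water time
        trial_end = max(row.start_s + session.interval_s, t_licks[-1] + bin_s)
        edges = np.arange(row.start_s, trial_end + 1e-9, bin_s)
        lick_counts = np.diff(np.searchsorted(licks, edges))
        spike_counts = np.diff(np.searchsorted(spikes, edges))
        pairs_x.extend(lick_counts / bin_s)
        pairs_y.extend(spike_counts / bin_s)
    x = np.asarray(pairs_x)
    y = np.asarray(pairs_y)
    if x.size < min_bins:
        raise InsufficientDataError(
            f"only {x.size} qualifying 1-s bins (need >= {min_bins})"
        )
    return fit_rate_pairs(x, y)


def fit_rate_pairs(x, y) -> CorrelationResult:
    """Least-squares line through (lick rate, spike rate) pairs; a zero
    spread in lick rate yields an explicit degenerate result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        return CorrelationResult(
            slope=float("nan"),
            intercept=float("nan"),
            r=float("nan"),
            n_bins=int(x.size),
            degenerate=True,
        )
    fit = stats.linregress(x, y)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n_bins=int(x.size),
    )
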