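"""Ground-truth synthetic sessions for the interval-timing licking task.

The generator emulates the statistical structure the downstream analyses
assume: fixed-interval trials (water every ``interval_s`` seconds, a fixed
fraction withheld with no two consecutive omissions), one licking bout per
trial at 6-8 Hz that either anticipates water (exploratory) or reacts to it
(consummatory), inhomogeneous-Poisson spike trains with lick-phase tuning
and linear pre-event ramps, dendritic calcium events at climbing-fiber rates
(1-2 Hz) with peri-initiation transients in a responsive subpopulation, and
optogenetic trials with suppressed licking plus a post-stimulus rebound.

Every stochastic draw flows from the config seed through a single
``numpy.random.Generator``, so identical config + seed reproduces the
session exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    CalciumEventTrain,
    GroundTruth,
    InvalidConfigError,
    Session,
    SpikeTrain,
    UnitChannelProfile,
)

PC_CLASSES = ("PC_unambiguous", "PC_putative")
CELL_CLASSES = PC_CLASSES + ("MLI", "other")


# --------------------------------------------------------------------------
# Configuration

@dataclass
class SimConfig:
    """Session-level generative parameters.

    Defaults mirror the task as run: 10-s fixed interval, 20% of trials
    unrewarded (never two in a row), intra-bout inter-lick intervals of
    100-175 ms (6-8 Hz licking), exploratory bouts leading water by about a
    second, reactive bouts following it by ~360 ms, and a modest lick-rate
    boost during water consumption.
    """

    n_trials: int = 100
    interval_s: float = 10.0
    p_unrewarded: float = 0.20
    intra_bout_ili_range_ms: tuple[float, float] = (100.0, 175.0)
    p_pre_water_bout: float = 0.75
    pre_water_lead_s: float = 1.0
    reactive_latency_s: float = 0.36
    bout_len_range: tuple[int, int] = (12, 28)
    consummatory_rate_boost: float = 1.3
    p_no_bout: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise InvalidConfigError("n_trials must be positive")
        if not (0.0 <= self.p_unrewarded < 0.5):
            raise InvalidConfigError(
                "p_unrewarded must lie in [0, 0.5): the no-consecutive "
                "constraint cannot realize a higher omission fraction"
            )
        for name in ("p_pre_water_bout", "p_no_bout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        lo, hi = self.intra_bout_ili_range_ms
        if not (0.0 < lo <= hi < self.interval_s * 1000.0):
            raise InvalidConfigError(
                "intra_bout_ili_range_ms must satisfy 0 < low <= high < interval"
            )
        nlo, nhi = self.bout_len_range
        if not (2 <= nlo <= nhi):
            raise InvalidConfigError("bout_len_range must satisfy 2 <= min <= max")
        if self.consummatory_rate_boost <= 0:
            raise InvalidConfigError("consummatory_rate_boost must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# The ramp response keeps rising briefly past its event before relaxing:
# peak delta-rate occurs ~300 ms after the aligned lick, then decays over ~1 s.
RAMP_RISE_POST_S = 0.3
RAMP_DECAY_S = 1.0


@dataclass
class Ramp:
    """Linear intensity ramp around an event: zero at (event - onset_s),
    rising to the signed peak ``amplitude_hz`` at (event + RAMP_RISE_POST_S),
    then decaying linearly back to baseline over RAMP_DECAY_S."""

    onset_s: float = 0.0
    amplitude_hz: float = 0.0

    def validate(self) -> None:
        if self.onset_s < 0:
            raise InvalidConfigError("ramp onset_s must be >= 0")


@dataclass
class UnitSpec:
    """Generative parameters of one simulated unit."""

    unit_id: str
    cell_class: str = "PC_putative"
    baseline_rate_hz: float = 60.0
    modulation_depth_hz: float = 0.0
    preferred_phase: float = 0.0
    init_ramp: Ramp = field(default_factory=Ramp)
    term_ramp: Ramp = field(default_factory=Ramp)
    water_response_hz: float = 0.0
    # Optional per-context overrides of the initiation ramp; None -> init_ramp.
    init_ramp_pre: Optional[Ramp] = None
    init_ramp_post: Optional[Ramp] = None

    def validate(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise InvalidConfigError(f"unknown cell_class {self.cell_class!r}")
        if self.baseline_rate_hz <= 0:
            raise InvalidConfigError("baseline_rate_hz must be positive")
        if self.modulation_depth_hz < 0:
            raise InvalidConfigError("modulation_depth_hz must be >= 0")
        for r in (self.init_ramp, self.term_ramp,
                  self.init_ramp_pre, self.init_ramp_post):
            if r is not None:
                r.validate()

    def ramp_for_context(self, context: str) -> Ramp:
        if context == "pre_water" and self.init_ramp_pre is not None:
            return self.init_ramp_pre
        if context == "post_water" and self.init_ramp_post is not None:
            return self.init_ramp_post
        return self.init_ramp


@dataclass
class DendriteSpec:
    """Generative parameters of one simulated PC dendrite (calcium)."""

    dendrite_id: str
    region_id: str = "R0"
    baseline_hz: float = 1.5
    responsive: bool = False
    init_onset_s: float = 0.1       # true ramp onset before first licks
    init_amp_hz: float = 4.5        # added rate from onset to +0.3 s post lick
    water_amp_hz: float = 4.5       # added rate in [water, water + 0.5 s)

    def validate(self) -> None:
        if not (1.0 <= self.baseline_hz <= 2.0):
            raise InvalidConfigError(
                "baseline_hz must lie in the climbing-fiber range [1, 2] Hz"
            )
        if self.init_onset_s < 0:
            raise InvalidConfigError("init_onset_s must be >= 0")


@dataclass
class OptoConfig:
    """Optogenetic stimulation layout, windows relative to trial start."""

    p_stim: float = 0.5             # fraction of unrewarded trials stimulated
    # the default window brackets the whole span an exploratory bout can
    # occupy (onset >= start + 8.6, offset <= start + 14.53), so full
    # suppression really silences the trial's licking
    on_offset_s: float = 8.4        # window start, s after trial start
    duration_s: float = 6.2
    suppression: float = 1.0        # per-lick deletion probability in window
    ili_jitter_ms: float = 30.0     # jitter of surviving in-window licks
    rebound_prob: float = 0.5
    rebound_latency_s: float = 0.3
    rebound_len_range: tuple[int, int] = (6, 12)

    def validate(self, interval_s: float) -> None:
        if not (0.0 <= self.p_stim <= 1.0):
            raise InvalidConfigError("p_stim must lie in [0, 1]")
        if not (0.0 <= self.suppression <= 1.0):
            raise InvalidConfigError("suppression must lie in [0, 1]")
        if not (0.0 <= self.rebound_prob <= 1.0):
            raise InvalidConfigError("rebound_prob must lie in [0, 1]")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        # Licking for trial k extends into the consumption period past the
        # scheduled water time, so the window may reach up to 2x the interval.
        if self.on_offset_s < 0 or (
            self.on_offset_s + self.duration_s > 2.0 * interval_s
        ):
            raise InvalidConfigError(
                "opto window must lie within the trial's licking span "
                f"[0, {2.0 * interval_s}] s after trial start"
            )


# --------------------------------------------------------------------------
# Trials

def generate_trials(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw the trial table: starts, rewarded flags, water times.

    Unrewarded trials occur with marginal probability ``p_unrewarded`` under
    the no-two-consecutive constraint. The constraint is honoured by a
    two-state Markov chain with P(unrewarded | previous rewarded) =
    p/(1-p) and P(unrewarded | previous unrewarded) = 0, whose stationary
    unrewarded fraction is exactly p; the chain is initialized from
    stationarity so every trial has the nominal omission probability.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    p = config.p_unrewarded
    q = p / (1.0 - p) if p > 0 else 0.0
    n = config.n_trials
    unrewarded = np.zeros(n, dtype=bool)
    prev_unrewarded = bool(rng.random() < p)  # stationary initial state
    for i in range(n):
        if prev_unrewarded:
            unrewarded[i] = False
        else:
            unrewarded[i] = bool(rng.random() < q)
        prev_unrewarded = unrewarded[i]
    start = np.arange(n, dtype=float) * config.interval_s
    water = np.where(unrewarded, np.nan, start + config.interval_s)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "start_s": start,
            "water_s": water,
            "rewarded": ~unrewarded,
            "opto_on_s": np.full(n, np.nan),
            "opto_off_s": np.full(n, np.nan),
        }
    )


# --------------------------------------------------------------------------
# Licks

def _draw_bout(
    config: SimConfig,
    rng: np.random.Generator,
    onset: float,
    water: Optional[float],
) -> np.ndarray:
    """One bout of licks from ``onset``; ILIs shrink by the consummatory
    boost once the bout passes the water time (if any)."""
    lo, hi = (v / 1000.0 for v in config.intra_bout_ili_range_ms)
    n = int(rng.integers(config.bout_len_range[0], config.bout_len_range[1] + 1))
    times = np.empty(n)
    t = onset
    times[0] = t
    for i in range(1, n):
        ili = float(rng.uniform(lo, hi))
        if water is not None and t >= water:
            ili /= config.consummatory_rate_boost
        t += ili
        times[i] = t
    return times


def generate_licks(
    trials: pd.DataFrame,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per trial, draw (at most) one licking bout and record its ground truth.

    Rewarded trials start the bout before water with probability
    ``p_pre_water_bout`` (exploratory; Gaussian lead around
    ``pre_water_lead_s``) and otherwise react to water (Gaussian latency
    around ``reactive_latency_s``). Unrewarded trials, lacking any cue, are
    always exploratory. Returns ``(licks, true_bouts)`` where ``licks`` has
    columns ``trial_id, time_s`` and ``true_bouts`` has
    ``trial_id, onset_s, offset_s, n_licks, context``.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    lick_rows: list[tuple[int, float]] = []
    bout_rows: list[dict] = []
    for row in trials.itertuples(index=False):
        if rng.random() < config.p_no_bout:
            continue
        scheduled = row.start_s + config.interval_s
        rewarded = bool(row.rewarded)
        pre = (not rewarded) or (rng.random() < config.p_pre_water_bout)
        if pre:
            lead = float(
                np.clip(
                    rng.normal(config.pre_water_lead_s,
                               0.3 * config.pre_water_lead_s),
                    0.2,
                    1.4,
                )
            )
            onset = scheduled - lead
            water = row.water_s if rewarded else None
            context = "pre_water"
        else:
            latency = float(
                np.clip(
                    rng.normal(config.reactive_latency_s,
                               0.3 * config.reactive_latency_s),
                    0.05,
                    1.5,
                )
            )
            onset = row.water_s + latency
            water = row.water_s
            context = "post_water"
        times = _draw_bout(config, rng, onset, water)
        lick_rows.extend((int(row.trial_id), float(t)) for t in times)
        bout_rows.append(
            {
                "trial_id": int(row.trial_id),
                "onset_s": float(times[0]),
                "offset_s": float(times[-1]),
                "n_licks": len(times),
                "context": context,
            }
        )
    licks = pd.DataFrame(lick_rows, columns=["trial_id", "time_s"])
    licks = licks.sort_values("time_s", kind="stable").reset_index(drop=True)
    if len(licks) > 1 and np.any(np.diff(licks["time_s"].to_numpy()) <= 0):
        raise RuntimeError("generated licks are not strictly increasing")
    bouts = pd.DataFrame(
        bout_rows,
        columns=["trial_id", "onset_s", "offset_s", "n_licks", "context"],
    )
    return licks, bouts


# --------------------------------------------------------------------------
# Spike trains (inhomogeneous Poisson via thinning)

def unit_intensity(
    unit: UnitSpec,
    t: np.ndarray,
    lick_times: np.ndarray,
    true_bouts: pd.DataFrame,
    water_times: np.ndarray,
    *,
    phase_max_ili_s: float = 0.30,
    water_window_s: float = 1.0,
) -> np.ndarray:
    """Evaluate the generative intensity lambda(t) at sorted times ``t``.

    lambda = baseline
           + depth * cos(phase(t) - preferred)   while within a lick cycle
           + ramps around each bout's first and last lick (linear rise from
             the onset to a peak RAMP_RISE_POST_S after the event, linear
             decay over RAMP_DECAY_S)
           + a boxcar water response after each delivery,
    clipped at zero.
    """
    t = np.asarray(t, dtype=float)
    lam = np.full(t.shape, unit.baseline_rate_hz)

    if unit.modulation_depth_hz > 0 and lick_times.size >= 2:
        idx = np.searchsorted(lick_times, t, side="right") - 1
        valid = (idx >= 0) & (idx < lick_times.size - 1)
        iv = idx[valid]
        ili = lick_times[iv + 1] - lick_times[iv]
        in_cycle = ili <= phase_max_ili_s
        phase = 2.0 * np.pi * (t[valid] - lick_times[iv]) / ili
        contrib = np.where(
            in_cycle,
            unit.modulation_depth_hz * np.cos(phase - unit.preferred_phase),
            0.0,
        )
        lam[valid] += contrib

    if len(true_bouts):
        contexts = true_bouts["context"].to_numpy()
        for col, ramp_of in (
            ("onset_s", unit.ramp_for_context),
            ("offset_s", lambda ctx: unit.term_ramp),
        ):
            events = true_bouts[col].to_numpy(float)
            for e, ctx in zip(events, contexts):
                ramp = ramp_of(ctx)
                if ramp.amplitude_hz == 0:
                    continue
                t_on = e - ramp.onset_s
                t_peak = e + RAMP_RISE_POST_S
                t_end = t_peak + RAMP_DECAY_S
                i0, i1, i2 = np.searchsorted(t, [t_on, t_peak, t_end])
                rise = t[i0:i1]
                lam[i0:i1] += ramp.amplitude_hz * (
                    (rise - t_on) / (t_peak - t_on)
                )
                fall = t[i1:i2]
                lam[i1:i2] += ramp.amplitude_hz * (
                    1.0 - (fall - t_peak) / RAMP_DECAY_S
                )

    if unit.water_response_hz != 0 and water_times.size:
        prev = np.searchsorted(water_times, t, side="right") - 1
        has_prev = prev >= 0
        since = t - water_times[np.maximum(prev, 0)]
        lam[has_prev & (since < water_window_s)] += unit.water_response_hz
    return np.clip(lam, 0.0, None)


def _intensity_upper_bound(unit: UnitSpec) -> float:
    init_amps = [
        unit.init_ramp.amplitude_hz,
        unit.init_ramp_pre.amplitude_hz if unit.init_ramp_pre else 0.0,
        unit.init_ramp_post.amplitude_hz if unit.init_ramp_post else 0.0,
    ]
    # init and term ramps of a short bout can overlap; bound them additively
    return (
        unit.baseline_rate_hz
        + unit.modulation_depth_hz
        + max(0.0, *init_amps)
        + max(0.0, unit.term_ramp.amplitude_hz)
        + max(0.0, unit.water_response_hz)
    )


def _thinned_poisson(
    intensity_fn,
    lam_max: float,
    duration_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample an inhomogeneous Poisson process on [0, duration) by thinning
    a homogeneous process at the documented upper bound ``lam_max``."""
    if lam_max <= 0 or duration_s <= 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n))
    if n == 0:
        return cand
    accept = rng.uniform(0.0, lam_max, size=n) < intensity_fn(cand)
    return cand[accept]


def generate_spike_train(
    unit: UnitSpec,
    session: Session,
    true_bouts: pd.DataFrame,
    rng: np.random.Generator | int,
) -> SpikeTrain:
    """Thinning-based inhomogeneous-Poisson sample of the unit's intensity."""
    unit.validate()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    licks = session.lick_times
    water = session.water_times

    def lam(t):
        return unit_intensity(unit, t, licks, true_bouts, water)

    times = _thinned_poisson(
        lam, _intensity_upper_bound(unit), session.duration_s, rng
    )
    return SpikeTrain(unit_id=unit.unit_id, times=times)


# --------------------------------------------------------------------------
# Channel profiles

def generate_channel_profiles(
    units: Sequence[UnitSpec],
    rng: np.random.Generator,
    *,
    n_channels: int = 32,
    noise_floor_uv: float = 30.0,
) -> list[UnitChannelProfile]:
    """Spatial spike footprints: PCs light up many channels (>= 7) well above
    the ~30 µV noise floor; MLIs and others only a few (<= 3)."""
    profiles = []
    for unit in units:
        unit.validate()
        peaks = rng.uniform(5.0, 0.7 * noise_floor_uv, size=n_channels)
        if unit.cell_class in PC_CLASSES:
            k = int(rng.integers(7, min(15, n_channels) + 1))
        else:
            k = int(rng.integers(1, 4))
        hot = rng.choice(n_channels, size=k, replace=False)
        peaks[hot] = rng.uniform(2.0 * noise_floor_uv, 4.0 * noise_floor_uv, size=k)
        profiles.append(
            UnitChannelProfile(
                unit_id=unit.unit_id,
                peak_uv=peaks,
                has_complex_spikes=(unit.cell_class == "PC_unambiguous"),
                noise_floor_uv=noise_floor_uv,
            )
        )
    return profiles


# --------------------------------------------------------------------------
# Calcium events

def generate_calcium(
    session: Session,
    true_bouts: pd.DataFrame,
    specs: Sequence[DendriteSpec],
    rng: np.random.Generator,
    *,
    post_lick_s: float = 0.3,
    water_window_s: float = 0.5,
) -> list[CalciumEventTrain]:
    """Poisson calcium-event trains at climbing-fiber baseline rates, with a
    boxcar rate increase around bout initiation (from the true onset before
    the first lick to shortly after it) and around water delivery for
    responsive dendrites."""
    first_licks = (
        true_bouts["onset_s"].to_numpy(float) if len(true_bouts) else np.empty(0)
    )
    water = session.water_times
    trains = []
    for spec in specs:
        spec.validate()
        lam_max = spec.baseline_hz
        if spec.responsive:
            lam_max += max(0.0, spec.init_amp_hz) + max(0.0, spec.water_amp_hz)

        def lam(t, spec=spec):
            out = np.full(np.shape(t), spec.baseline_hz)
            if spec.responsive and first_licks.size:
                # inside [f - onset, f + post_lick) around each first lick
                for f in first_licks:
                    sel = (t >= f - spec.init_onset_s) & (t < f + post_lick_s)
                    out[sel] += spec.init_amp_hz
                for w in water:
                    sel = (t >= w) & (t < w + water_window_s)
                    out[sel] += spec.water_amp_hz
            return np.clip(out, 0.0, None)

        times = _thinned_poisson(lam, lam_max, session.duration_s, rng)
        trains.append(
            CalciumEventTrain(
                dendrite_id=spec.dendrite_id,
                region_id=spec.region_id,
                times=times,
            )
        )
    return trains


# --------------------------------------------------------------------------
# Optogenetic trials

def generate_opto(
    session: Session,
    true_bouts: pd.DataFrame,
    config: SimConfig,
    opto: OptoConfig,
    rng: np.random.Generator,
) -> tuple[Session, pd.DataFrame, pd.DataFrame]:
    """Annotate a subset of unrewarded trials with a photostimulus window,
    suppress/jitter their in-window licks, and add rebound bouts.

    Returns ``(session, true_bouts, opto_truth)`` where ``opto_truth`` has
    columns ``trial_id, stimulated, rebound``.
    """
    opto.validate(config.interval_s)
    trials = session.trials.copy()
    licks = session.licks.copy()
    bouts = true_bouts.copy()
    lo, hi = (v / 1000.0 for v in config.intra_bout_ili_range_ms)

    rows = []
    new_licks: list[tuple[int, float]] = []
    drop_mask = np.zeros(len(licks), dtype=bool)
    lick_t = licks["time_s"].to_numpy(float)
    lick_trial = licks["trial_id"].to_numpy()

    for i, row in enumerate(trials.itertuples(index=False)):
        if row.rewarded:
            continue
        stim = bool(rng.random() < opto.p_stim)
        rebound = False
        if stim:
            on = row.start_s + opto.on_offset_s
            off = on + opto.duration_s
            trials.loc[trials["trial_id"] == row.trial_id,
                       ["opto_on_s", "opto_off_s"]] = (on, off)
            in_window = (
                (lick_trial == row.trial_id) & (lick_t >= on) & (lick_t < off)
            )
            for j in np.nonzero(in_window)[0]:
                if rng.random() < opto.suppression:
                    drop_mask[j] = True
                elif opto.ili_jitter_ms > 0:
                    jit = rng.uniform(
                        -opto.ili_jitter_ms / 1000.0, opto.ili_jitter_ms / 1000.0
                    )
                    new_t = float(np.clip(lick_t[j] + jit, on, off - 1e-6))
                    drop_mask[j] = True
                    new_licks.append((int(row.trial_id), new_t))
            if rng.random() < opto.rebound_prob:
                rebound = True
                onset = off + abs(rng.normal(opto.rebound_latency_s, 0.1))
                n = int(
                    rng.integers(
                        opto.rebound_len_range[0], opto.rebound_len_range[1] + 1
                    )
                )
                t = onset
                times = [t]
                for _ in range(n - 1):
                    t += float(rng.uniform(lo, hi))
                    times.append(t)
                new_licks.extend((int(row.trial_id), ti) for ti in times)
                bouts = pd.concat(
                    [
                        bouts,
                        pd.DataFrame(
                            [
                                {
                                    "trial_id": int(row.trial_id),
                                    "onset_s": times[0],
                                    "offset_s": times[-1],
                                    "n_licks": n,
                                    "context": "pre_water",
                                }
                            ]
                        ),
                    ],
                    ignore_index=True,
                )
        rows.append(
            {"trial_id": int(row.trial_id), "stimulated": stim, "rebound": rebound}
        )

    kept = licks.loc[~drop_mask, ["trial_id", "time_s"]]
    if new_licks:
        kept = pd.concat(
            [kept, pd.DataFrame(new_licks, columns=["trial_id", "time_s"])],
            ignore_index=True,
        )
    kept = kept.sort_values("time_s", kind="stable").reset_index(drop=True)
    # Jitter can in principle collide two licks; nudge exact ties apart.
    t = kept["time_s"].to_numpy(float)
    for j in np.nonzero(np.diff(t) <= 0)[0]:
        t[j + 1] = np.nextafter(t[j], np.inf)
    kept["time_s"] = t

    out_session = Session(
        trials=trials, licks=kept, interval_s=session.interval_s
    )
    opto_truth = pd.DataFrame(rows, columns=["trial_id", "stimulated", "rebound"])
    bouts = bouts.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return out_session, bouts, opto_truth


# --------------------------------------------------------------------------
# Default rosters and the one-call session builder

def default_unit_specs(
    n_units: int, rng: np.random.Generator, *, baseline_range=(40.0, 90.0)
) -> list[UnitSpec]:
    """A heterogeneous PC-dominated roster: most units entrained with
    positive initiation ramps, a minority negative or unresponsive, plus a
    few MLIs/others with small footprints."""
    specs = []
    for i in range(n_units):
        u = rng.random()
        if u < 0.45:
            cls = "PC_unambiguous"
        elif u < 0.85:
            cls = "PC_putative"
        elif u < 0.95:
            cls = "MLI"
        else:
            cls = "other"
        base = float(rng.uniform(*baseline_range))
        if cls in PC_CLASSES:
            depth = float(rng.uniform(0.1, 0.5)) * base
            sign = 1.0 if rng.random() < 0.8 else -1.0
            # per-PC delta rates around motor transitions span tens of Hz
            init = Ramp(
                onset_s=float(rng.uniform(0.15, 0.5)),
                amplitude_hz=sign * float(rng.uniform(10.0, 35.0)),
            )
            term = Ramp(
                onset_s=float(rng.uniform(0.2, 0.4)),
                amplitude_hz=float(rng.uniform(-12.0, 18.0)),
            )
            water = float(rng.uniform(0.0, 10.0))
        else:
            depth, init, term, water = 0.0, Ramp(), Ramp(), 0.0
        specs.append(
            UnitSpec(
                unit_id=f"u{i:03d}",
                cell_class=cls,
                baseline_rate_hz=base,
                modulation_depth_hz=depth,
                preferred_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
                init_ramp=init,
                term_ramp=term,
                water_response_hz=water,
            )
        )
    return specs


def default_dendrite_specs(
    n_dendrites: int,
    rng: np.random.Generator,
    *,
    n_regions: int = 2,
    p_responsive_region: float = 0.5,
) -> list[DendriteSpec]:
    """Dendrites grouped into regions; responsiveness is a region property
    (task-responsive regions boost all their dendrites)."""
    region_resp = rng.random(n_regions) < p_responsive_region
    specs = []
    for i in range(n_dendrites):
        r = i % n_regions
        specs.append(
            DendriteSpec(
                dendrite_id=f"d{i:03d}",
                region_id=f"R{r}",
                baseline_hz=float(rng.uniform(1.0, 2.0)),
                responsive=bool(region_resp[r]),
                init_onset_s=0.1,
                init_amp_hz=4.5,
                water_amp_hz=4.5,
            )
        )
    return specs


@dataclass
class SessionBundle:
    """Everything one simulated session produces."""

    session: Session
    spikes: list[SpikeTrain]
    channel_profiles: list[UnitChannelProfile]
    calcium: list[CalciumEventTrain]
    truth: GroundTruth


def simulate_session(
    config: SimConfig,
    unit_specs: Optional[Sequence[UnitSpec]] = None,
    dendrite_specs: Optional[Sequence[DendriteSpec]] = None,
    opto: Optional[OptoConfig] = None,
    *,
    n_units: int = 12,
    n_dendrites: int = 10,
) -> SessionBundle:
    """Generate a complete synthetic session with its ground-truth record."""
    config.validate()
    rng = config.rng()
    trials = generate_trials(config, rng)
    licks, true_bouts = generate_licks(trials, config, rng)
    session = Session(trials=trials, licks=licks, interval_s=config.interval_s)
    if unit_specs is None:
        unit_specs = default_unit_specs(n_units, rng)
    if dendrite_specs is None:
        dendrite_specs = default_dendrite_specs(n_dendrites, rng)
    opto_truth = None
    if opto is not None:
        session, true_bouts, opto_truth = generate_opto(
            session, true_bouts, config, opto, rng
        )
    spikes = [
        generate_spike_train(u, session, true_bouts, rng) for u in unit_specs
    ]
    profiles = generate_channel_profiles(list(unit_specs), rng)
    calcium = generate_calcium(session, true_bouts, dendrite_specs, rng)
    truth = GroundTruth(
        unit_specs={u.unit_id: u for u in unit_specs},
        dendrite_specs={d.dendrite_id: d for d in dendrite_specs},
        bouts=true_bouts,
        opto=opto_truth,
    )
    return SessionBundle(
        session=session,
        spikes=spikes,
        channel_profiles=profiles,
        calcium=calcium,
        truth=truth,
    )


def stationary_unrewarded_fraction(p_unrewarded: float) -> float:
    """Stationary omission fraction of the constrained trial chain, solved
    from its transition matrix (independent check for the sampler)."""
    q = p_unrewarded / (1.0 - p_unrewarded)
    # states: 0 = rewarded, 1 = unrewarded
    P = np.array([[1.0 - q, q], [1.0, 0.0]])
    w, v = np.linalg.eig(P.T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi /= pi.sum()
    return float(pi[1])
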