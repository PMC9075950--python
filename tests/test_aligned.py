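"""Event-aligned delta-rate analysis and ramp classification."""

import numpy as np
import pytest

from licktime.aligned import (
    FIRST_LICK_WINDOW,
    aligned_delta_rate,
    baseline_rate,
    classify_first_lick_modulation,
    classify_termination_modulation,
    classify_unit_by_context,
    lickrate_spikerate_correlation,
    population_onset_time,
    split_by_context,
)
from licktime.behavior import segment_bouts
from licktime.synthetic import (
    Ramp,
    SimConfig,
    UnitSpec,
    generate_licks,
    generate_spike_train,
    generate_trials,
)
from licktime.types import (
    AlignedResponse,
    InsufficientDataError,
    Session,
    ValidationError,
)

EDGES15 = -1.0 + 0.1 * np.arange(16)


def response(values, sem=None, edges=EDGES15):
    values = np.asarray(values, float)
    return AlignedResponse(
        unit_id="u",
        event="first_lick",
        bin_edges=edges,
        mean_delta_rate=values,
        sem=np.zeros_like(values) if sem is None else np.asarray(sem, float),
        baseline_rate=0.0,
        n_events=1,
    )


@pytest.fixture(scope="module")
def sim_session():
    cfg = SimConfig(n_trials=60, p_no_bout=0.0, seed=50)
    trials = generate_trials(cfg)
    licks, bouts = generate_licks(trials, cfg)
    session = Session(trials=trials, licks=licks, interval_s=cfg.interval_s)
    return cfg, session, bouts


class TestBaselineRate:
    def test_homogeneous_unit(self, sim_session, rng):
        _, session, _ = sim_session
        T = session.duration_s
        spikes = np.sort(rng.uniform(0, T, rng.poisson(50 * T)))
        est = baseline_rate(spikes, session.lick_times, T)
        assert est == pytest.approx(50.0, abs=3 * np.sqrt(50 / (0.3 * T)))

    def test_no_licks_whole_session_rate(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 1000))
        est = baseline_rate(spikes, np.empty(0), 100.0)
        assert est == pytest.approx(10.0, rel=0.02)

    def test_lick_locked_bursts_excluded(self, sim_session):
        # a unit bursting only during licking: the estimate recovers the
        # generator's baseline parameter, not the bursty rate
        _, session, bouts = sim_session
        unit = UnitSpec(
            unit_id="u",
            baseline_rate_hz=30.0,
            modulation_depth_hz=25.0,
            water_response_hz=40.0,
        )
        train = generate_spike_train(unit, session, bouts, 51)
        est = baseline_rate(train.times, session.lick_times, session.duration_s)
        assert est == pytest.approx(30.0, abs=1.5)

    def test_insufficient_nonlicking_time(self):
        licks = np.arange(0.0, 100.0, 0.5)  # licking everywhere
        with pytest.raises(InsufficientDataError, match="non-licking"):
            baseline_rate(np.array([1.0]), licks, 100.0)


class TestAlignedDeltaRate:
    def test_null_unit_flat(self, rng):
        T = 2000.0
        spikes = np.sort(rng.uniform(0, T, rng.poisson(60 * T)))
        events = np.sort(rng.uniform(10, T - 10, 150))
        resp = aligned_delta_rate(spikes, events, (-1.0, 0.5), baseline=60.0)
        assert np.all(np.abs(resp.mean_delta_rate) < 4 * resp.sem + 1e-9)

    def test_injected_step_recovered(self, rng):
        T = 2000.0
        events = np.sort(rng.uniform(10, T - 10, 200))
        base = np.sort(rng.uniform(0, T, rng.poisson(40 * T)))
        extra = np.concatenate(
            [e + rng.uniform(0, 0.5, rng.poisson(5)) for e in events]
        )  # +10 Hz for 0.5 s after each event
        spikes = np.sort(np.concatenate([base, extra]))
        resp = aligned_delta_rate(spikes, events, (-1.0, 0.5), baseline=40.0)
        post = resp.bin_centers > 0
        assert resp.mean_delta_rate[post].mean() == pytest.approx(10.0, abs=1.5)
        pre = resp.bin_centers < 0
        assert abs(resp.mean_delta_rate[pre].mean()) < 1.0

    def test_single_event_single_spike_arithmetic(self):
        resp = aligned_delta_rate(
            np.array([10.05]), np.array([10.0]), (0.0, 0.5), baseline=2.0
        )
        np.testing.assert_allclose(
            resp.mean_delta_rate, [8.0, -2.0, -2.0, -2.0, -2.0]
        )

    def test_empty_events_explicit(self):
        assert aligned_delta_rate(np.array([1.0]), [], (-1.0, 0.5)) is None

    def test_time_shift_equivariance(self, rng):
        spikes = np.sort(rng.uniform(0, 500, 5000))
        events = np.sort(rng.uniform(10, 490, 50))
        a = aligned_delta_rate(spikes, events, (-1.0, 0.5), baseline=10.0)
        b = aligned_delta_rate(
            spikes + 123.456, events + 123.456, (-1.0, 0.5), baseline=10.0
        )
        np.testing.assert_allclose(a.mean_delta_rate, b.mean_delta_rate)
        np.testing.assert_allclose(a.sem, b.sem)


class TestFirstLickRule:
    def test_constructed_ramp_positive(self):
        cls = classify_first_lick_modulation(
            response([0, 0, 0, 0, 0, 1, 2, 3, 4, 4, 4, 0, 0, 0, 0])
        )
        assert cls.modulation == "positive"
        # first incremented bin is index 5 -> left edge -0.5
        assert cls.onset_time_s == pytest.approx(-0.5)

    def test_flat_is_none(self):
        cls = classify_first_lick_modulation(response(np.zeros(15)))
        assert cls.modulation == "none"
        assert cls.onset_time_s is None

    def test_mirrored_negative(self):
        cls = classify_first_lick_modulation(
            response([0, 0, 0, 0, 0, -1, -2, -3, -4, -4, -4, 0, 0, 0, 0])
        )
        assert cls.modulation == "negative"
        assert cls.onset_time_s == pytest.approx(-0.5)

    def test_earlier_pattern_wins(self):
        v = [0, -1, -2, -3, 0, 0, 0, 1, 2, 3, 4, 0, 0, 0, 0]
        cls = classify_first_lick_modulation(response(v))
        assert cls.modulation == "negative"

    def test_wrong_bin_structure_rejected(self):
        bad = AlignedResponse(
            unit_id="u",
            event="first_lick",
            bin_edges=np.linspace(-1, 0.5, 11),
            mean_delta_rate=np.zeros(10),
            sem=np.zeros(10),
            baseline_rate=0.0,
            n_events=1,
        )
        with pytest.raises(ValidationError):
            classify_first_lick_modulation(bad)

    def test_noise_floor_suppresses_subnoise_wiggles(self, rng):
        # tiny ascending wiggles below the SEM-derived floor: none
        v = 0.1 * np.array([0, 1, 2, 3, 2, 1, 0, 1, 2, 3, 2, 1, 0, 1, 2])
        cls = classify_first_lick_modulation(response(v, sem=np.full(15, 1.0)))
        assert cls.modulation == "none"

    def test_recovery_at_configured_snr(self, rng):
        # direct binned-Poisson oracle of the generator's ramp shape
        from licktime.synthetic import RAMP_RISE_POST_S

        baseline, n_events, onset = 60.0, 100, 0.3
        amp = 3 * np.sqrt(baseline / 0.1)
        centers = EDGES15[:-1] + 0.05
        lam = np.full(15, baseline)
        t_on, t_peak = -onset, RAMP_RISE_POST_S
        for i, c in enumerate(centers):
            xs = np.linspace(EDGES15[i], EDGES15[i + 1], 21)
            y = np.where(
                (xs >= t_on) & (xs < t_peak),
                amp * (xs - t_on) / (t_peak - t_on),
                0.0,
            )
            lam[i] += y.mean()
        hits = 0
        n_units = 40
        for _ in range(n_units):
            counts = rng.poisson(lam * 0.1, size=(n_events, 15))
            rates = counts / 0.1
            resp = response(
                rates.mean(0) - baseline,
                sem=rates.std(0, ddof=1) / np.sqrt(n_events),
            )
            cls = classify_first_lick_modulation(resp)
            if cls.modulation == "positive" and abs(
                cls.onset_time_s + onset
            ) <= 0.1 + 1e-9:
                hits += 1
        assert hits / n_units >= 0.8


class TestTerminationRule:
    def test_step_up_positive(self, rng):
        T = 2000.0
        events = np.sort(rng.uniform(10, T - 10, 120))
        base = np.sort(rng.uniform(0, T, rng.poisson(50 * T)))
        extra = np.concatenate(
            [e - rng.uniform(0, 0.3, rng.poisson(3)) for e in events]
        )  # +10 Hz in the final 300 ms
        spikes = np.sort(np.concatenate([base, extra]))
        cls = classify_termination_modulation(spikes, events, baseline=50.0)
        assert cls.modulation == "positive"

    def test_mirrored_step_down_negative(self, rng):
        T = 2000.0
        events = np.sort(rng.uniform(10, T - 10, 120))
        spikes = np.sort(rng.uniform(0, T, rng.poisson(50 * T)))
        # delete ~60% of spikes in the final 300 ms before each event
        keep = np.ones(spikes.size, bool)
        for e in events:
            i, j = np.searchsorted(spikes, [e - 0.3, e])
            sel = np.arange(i, j)
            keep[sel[rng.random(sel.size) < 0.6]] = False
        cls = classify_termination_modulation(spikes[keep], events, baseline=50.0)
        assert cls.modulation == "negative"

    def test_stationary_rarely_modulated(self, rng):
        # frozen MC oracle bound: the rule's null rate is ~0.2% (the 3-bin
        # window mean is compared against single-bin SD), bounded at 5%
        n_sim, modulated = 60, 0
        for _ in range(n_sim):
            T = 1200.0
            spikes = np.sort(rng.uniform(0, T, rng.poisson(60 * T)))
            events = np.sort(rng.uniform(10, T - 10, 100))
            cls = classify_termination_modulation(spikes, events, baseline=60.0)
            modulated += cls.modulation != "none"
        assert modulated / n_sim <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestContextSplit:
    def test_pre_only_ramp_tagged_pre_only(self, sim_session):
        cfg, session, truth = sim_session
        unit = UnitSpec(
            unit_id="u",
            baseline_rate_hz=60.0,
            init_ramp=Ramp(),  # no generic ramp
            init_ramp_pre=Ramp(onset_s=0.3, amplitude_hz=75.0),
            init_ramp_post=Ramp(),
        )
        train = generate_spike_train(unit, session, truth, 52)
        bouts = segment_bouts(session.lick_times, session=session)
        iso = [b for b in bouts if b.isolated]
        ctx = classify_unit_by_context(
            "u", train.times, iso, baseline=60.0
        )
        assert "pre-init+" in ctx.tags
        assert "post-init+" not in ctx.tags

    def test_multi_transition_and_negative_pooling(self):
        # constructed classifications exercise the category assembly
        from licktime.aligned import ContextClassification  # noqa: F401

        pre = response([0, 0, 0, 0, 0, 1, 2, 3, 4, 4, 4, 0, 0, 0, 0])
        assert classify_first_lick_modulation(pre).modulation == "positive"
        neg = response([0, 0, 0, 0, 0, -1, -2, -3, -4, -4, -4, 0, 0, 0, 0])
        assert classify_first_lick_modulation(neg).modulation == "negative"

    def test_split_by_context_partition(self, sim_session):
        _, session, _ = sim_session
        bouts = segment_bouts(session.lick_times, session=session)
        split = split_by_context(bouts)
        assert split["pre_water"].size + split["post_water"].size == len(bouts)


class TestPopulationOnset:
    def test_identical_ramps(self):
        v = [0, 0, 0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 5, 5, 5]
        resps = [response(v) for _ in range(6)]
        onset = population_onset_time(resps)
        assert onset == pytest.approx(-0.3, abs=0.1 + 1e-9)

    def test_flat_population_absent(self):
        resps = [response(np.zeros(15)) for _ in range(6)]
        assert population_onset_time(resps) is None

    def test_mixture_onset_between_subpopulations(self):
        early = [0, 0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 6, 6, 6, 6]   # onset -0.4
        late = [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 2, 3, 4, 5, 6]    # onset -0.1
        resps = [response(early) for _ in range(3)] + [
            response(late) for _ in range(3)
        ]
        onset = population_onset_time(resps)
        assert -0.4 - 1e-9 <= onset <= -0.1 + 1e-9

    def test_too_few_units_rejected(self):
        with pytest.raises(InsufficientDataError):
            population_onset_time([response(np.zeros(15))] * 3)


class TestLickSpikeCorrelation:
    def test_linear_relation_recovered(self, sim_session, rng):
        cfg, session, _ = sim_session
        # construct spikes whose 1-s-bin count is exactly a + b * lick count
        a, b = 5, 3
        licks = session.lick_times
        spikes = []
        for start in np.arange(0.0, session.duration_s - 1.0, 1.0):
            n_licks = np.diff(np.searchsorted(licks, [start, start + 1.0]))[0]
            n_spk = a + b * n_licks
            spikes.append(start + (np.arange(n_spk) + 0.5) / n_spk)
        spikes = np.sort(np.concatenate(spikes))
        fit = lickrate_spikerate_correlation(session, spikes)
        assert not fit.degenerate
        assert fit.slope == pytest.approx(b, abs=0.3)
        assert fit.intercept == pytest.approx(a, abs=1.5)
        assert fit.r > 0.9

    def test_lick_independent_unit_near_zero_slope(self, sim_session, rng):
        _, session, _ = sim_session
        T = session.duration_s
        spikes = np.sort(rng.uniform(0, T, rng.poisson(60 * T)))
        fit = lickrate_spikerate_correlation(session, spikes)
        assert abs(fit.slope) < 0.5

    def test_degenerate_identical_lick_rates(self):
        from licktime.aligned import fit_rate_pairs

        fit = fit_rate_pairs(np.full(20, 7.0), np.arange(20.0))
        assert fit.degenerate
        assert np.isnan(fit.slope)

    def test_too_few_bins_rejected(self):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "trial_id": [0],
                "start_s": [0.0],
                "water_s": [10.0],
                "rewarded": [True],
            }
        )
        licks = pd.DataFrame({"trial_id": [0, 0], "time_s": [0.5, 0.7]})
        session = Session(trials=trials, licks=licks)
        with pytest.raises(InsufficientDataError):
            lickrate_spikerate_correlation(session, np.array([1.0, 2.0]))
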