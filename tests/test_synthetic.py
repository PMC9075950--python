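"""Generator behavior: trial structure, licks, spike trains, footprints,
calcium, opto — against closed-form and Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest

from licktime.synthetic import (
    DendriteSpec,
    OptoConfig,
    Ramp,
    SimConfig,
    UnitSpec,
    generate_calcium,
    generate_channel_profiles,
    generate_licks,
    generate_opto,
    generate_spike_train,
    generate_trials,
    simulate_session,
    stationary_unrewarded_fraction,
    unit_intensity,
)
from licktime.types import InvalidConfigError, Session
from licktime.units import classify_unit


def make_session(trials, licks, interval_s=10.0):
    return Session(trials=trials, licks=licks, interval_s=interval_s)


class TestTrials:
    def test_all_rewarded_when_p_zero(self):
        t = generate_trials(SimConfig(n_trials=200, p_unrewarded=0.0, seed=1))
        assert t["rewarded"].all()
        assert np.isfinite(t["water_s"]).all()

    def test_no_two_consecutive_unrewarded(self):
        t = generate_trials(SimConfig(n_trials=5000, p_unrewarded=0.3, seed=2))
        unrew = (~t["rewarded"]).to_numpy()
        assert not np.any(unrew[:-1] & unrew[1:])

    def test_unrewarded_fraction_matches_chain_oracle(self):
        # Oracle: stationary distribution of the constrained two-state chain
        # (solved from its transition matrix) equals the nominal probability.
        p = 0.2
        assert stationary_unrewarded_fraction(p) == pytest.approx(p, abs=1e-12)
        t = generate_trials(SimConfig(n_trials=10_000, p_unrewarded=p, seed=3))
        frac = float((~t["rewarded"]).mean())
        # negative serial correlation keeps the SE below the binomial 0.004
        assert frac == pytest.approx(p, abs=0.015)

    def test_water_time_is_start_plus_interval(self):
        cfg = SimConfig(n_trials=50, seed=4)
        t = generate_trials(cfg)
        rew = t[t["rewarded"]]
        np.testing.assert_allclose(
            rew["water_s"], rew["start_s"] + cfg.interval_s
        )

    def test_determinism(self):
        cfg = SimConfig(n_trials=300, seed=11)
        pd.testing.assert_frame_equal(generate_trials(cfg), generate_trials(cfg))

    def test_invalid_n_trials(self):
        with pytest.raises(InvalidConfigError):
            generate_trials(SimConfig(n_trials=0))


class TestLicks:
    def test_degenerate_ili_range(self):
        cfg = SimConfig(
            n_trials=20,
            intra_bout_ili_range_ms=(125.0, 125.0),
            consummatory_rate_boost=1.0,
            p_no_bout=0.0,
            seed=5,
        )
        trials = generate_trials(cfg)
        licks, bouts = generate_licks(trials, cfg)
        for tid, grp in licks.groupby("trial_id"):
            ilis = np.diff(grp["time_s"].to_numpy())
            np.testing.assert_allclose(ilis, 0.125, rtol=1e-12)

    def test_ilis_within_configured_band(self):
        cfg = SimConfig(n_trials=50, p_no_bout=0.0, seed=6)
        trials = generate_trials(cfg)
        licks, _ = generate_licks(trials, cfg)
        lo = 0.100 / cfg.consummatory_rate_boost  # boosted consummatory floor
        for tid, grp in licks.groupby("trial_id"):
            ilis = np.diff(grp["time_s"].to_numpy())
            assert np.all(ilis >= lo - 1e-12)
            assert np.all(ilis <= 0.175 + 1e-12)

    def test_licks_strictly_increasing(self):
        cfg = SimConfig(n_trials=100, seed=7)
        licks, _ = generate_licks(generate_trials(cfg), cfg)
        assert np.all(np.diff(licks["time_s"].to_numpy()) > 0)

    def test_pre_water_fraction_binomial_oracle(self):
        cfg = SimConfig(
            n_trials=1000, p_pre_water_bout=0.7, p_no_bout=0.0, seed=8
        )
        trials = generate_trials(cfg)
        _, bouts = generate_licks(trials, cfg)
        rewarded_ids = set(trials.loc[trials["rewarded"], "trial_id"])
        rew = bouts[bouts["trial_id"].isin(rewarded_ids)]
        frac = (rew["context"] == "pre_water").mean()
        n = len(rew)
        assert frac == pytest.approx(0.7, abs=3 * np.sqrt(0.7 * 0.3 / n))
        # omission trials have no cue to react to
        unrew = bouts[~bouts["trial_id"].isin(rewarded_ids)]
        assert (unrew["context"] == "pre_water").all()

    def test_inverted_ili_range_rejected(self):
        cfg = SimConfig(intra_bout_ili_range_ms=(175.0, 100.0))
        with pytest.raises(InvalidConfigError):
            cfg.validate()


@pytest.fixture(scope="module")
def session_and_bouts():
    cfg = SimConfig(n_trials=60, p_no_bout=0.0, seed=9)
    trials = generate_trials(cfg)
    licks, bouts = generate_licks(trials, cfg)
    return make_session(trials, licks), bouts


class TestSpikeTrains:
    def test_homogeneous_limit(self, session_and_bouts):
        session, bouts = session_and_bouts
        unit = UnitSpec(unit_id="u", baseline_rate_hz=50.0)
        train = generate_spike_train(unit, session, bouts, 0)
        T = session.duration_s
        rate = train.times.size / T
        se = np.sqrt(50.0 / T)
        assert abs(rate - 50.0) < 3 * se

    def test_poisson_dispersion(self, session_and_bouts):
        # ramp-free, tuning-free unit: binned counts are Poisson, so the
        # variance/mean ratio over 1000 bins stays near 1
        session, bouts = session_and_bouts
        unit = UnitSpec(unit_id="u", baseline_rate_hz=40.0)
        train = generate_spike_train(unit, session, bouts, 1)
        edges = np.linspace(0.0, session.duration_s, 1001)
        counts = np.histogram(train.times, edges)[0]
        ratio = counts.var() / counts.mean()
        assert 0.8 < ratio < 1.2

    def test_init_ramp_elevates_pre_event_rate(self, session_and_bouts):
        session, bouts = session_and_bouts
        unit = UnitSpec(
            unit_id="u",
            baseline_rate_hz=40.0,
            init_ramp=Ramp(onset_s=0.3, amplitude_hz=10.0),
        )
        # analytic check on the intensity itself, then on realized spikes
        first = bouts["onset_s"].to_numpy()
        t_near = np.sort(np.concatenate([first - 0.15 + 0.0 * first]))
        t_far = np.sort(first - 0.75)
        lam_near = unit_intensity(
            unit, t_near, session.lick_times, bouts, session.water_times
        ).mean()
        lam_far = unit_intensity(
            unit, t_far, session.lick_times, bouts, session.water_times
        ).mean()
        assert lam_near > lam_far

        train = generate_spike_train(unit, session, bouts, 2)
        near = far = 0
        for f in first:
            near += np.diff(np.searchsorted(train.times, [f - 0.3, f]))[0]
            far += np.diff(np.searchsorted(train.times, [f - 1.0, f - 0.5]))[0]
        assert near / (0.3 * first.size) > far / (0.5 * first.size)

    def test_strong_phase_tuning_concentrates_phases(self, session_and_bouts):
        from licktime.entrainment import (
            mean_resultant,
            select_rhythmic_licks,
            spike_phases,
        )

        session, bouts = session_and_bouts
        unit = UnitSpec(
            unit_id="u",
            baseline_rate_hz=20.0,
            modulation_depth_hz=20.0,
            preferred_phase=np.pi / 2,
        )
        train = generate_spike_train(unit, session, bouts, 3)
        runs = select_rhythmic_licks(session.lick_times)
        phi = spike_phases(train.times, runs)
        r, ang = mean_resultant(phi)
        assert r > 0.3
        assert abs(np.angle(np.exp(1j * (ang - np.pi / 2)))) < 0.3

    def test_determinism(self, session_and_bouts):
        session, bouts = session_and_bouts
        unit = UnitSpec(unit_id="u", baseline_rate_hz=30.0)
        a = generate_spike_train(unit, session, bouts, 42).times
        b = generate_spike_train(unit, session, bouts, 42).times
        np.testing.assert_array_equal(a, b)


class TestChannelProfiles:
    def test_footprints_match_class(self, rng):
        pcs = [UnitSpec(unit_id=f"p{i}", cell_class="PC_putative") for i in range(10)]
        mlis = [UnitSpec(unit_id=f"m{i}", cell_class="MLI") for i in range(10)]
        for p in generate_channel_profiles(pcs, rng):
            assert np.sum(p.peak_uv > 30.0) >= 7
        for p in generate_channel_profiles(mlis, rng):
            assert np.sum(p.peak_uv > 30.0) <= 3

    def test_classifier_roundtrip_recovers_pc_vs_non_pc(self, rng):
        specs = []
        for i in range(100):
            cls = ("PC_unambiguous", "PC_putative", "MLI", "other")[i % 4]
            specs.append(UnitSpec(unit_id=f"u{i}", cell_class=cls))
        profiles = generate_channel_profiles(specs, rng)
        for spec, prof in zip(specs, profiles):
            is_pc = spec.cell_class.startswith("PC")
            label = classify_unit(prof).label
            assert label.startswith("PC") == is_pc


class TestCalcium:
    def test_baseline_event_count_poisson_mean(self, rng):
        cfg = SimConfig(n_trials=59, p_no_bout=1.0, seed=10)  # ~600 s, no licks
        trials = generate_trials(cfg)
        licks, bouts = generate_licks(trials, cfg)
        session = make_session(trials, licks)
        spec = DendriteSpec(dendrite_id="d", baseline_hz=1.5)
        (train,) = generate_calcium(session, bouts, [spec], rng)
        expected = 1.5 * session.duration_s
        assert abs(train.times.size - expected) < 3 * np.sqrt(expected)

    def test_baseline_out_of_cf_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            DendriteSpec(dendrite_id="d", baseline_hz=3.0).validate()


@pytest.fixture(scope="module")
def opto_base():
    cfg = SimConfig(n_trials=400, p_no_bout=0.0, seed=12)
    trials = generate_trials(cfg)
    licks, bouts = generate_licks(trials, cfg)
    return cfg, make_session(trials, licks), bouts


class TestOpto:
    def test_full_suppression_empties_every_window(self, opto_base, rng):
        cfg, session, bouts = opto_base
        opto = OptoConfig(suppression=1.0, rebound_prob=0.0)
        out, _, truth = generate_opto(session, bouts, cfg, opto, rng)
        stim = out.trials[np.isfinite(out.trials["opto_on_s"])]
        licks = out.licks["time_s"].to_numpy()
        for row in stim.itertuples(index=False):
            inside = np.sum((licks >= row.opto_on_s) & (licks < row.opto_off_s))
            assert inside == 0

    def test_rebound_fraction_binomial_oracle(self, rng):
        cfg = SimConfig(n_trials=2000, p_no_bout=0.0, seed=13)
        trials = generate_trials(cfg)
        licks, bouts = generate_licks(trials, cfg)
        session = make_session(trials, licks)
        opto = OptoConfig(p_stim=0.6, suppression=1.0, rebound_prob=0.5)
        _, _, truth = generate_opto(session, bouts, cfg, opto, rng)
        stim = truth[truth["stimulated"]]
        assert len(stim) > 150
        frac = stim["rebound"].mean()
        se = np.sqrt(0.25 / len(stim))
        assert frac == pytest.approx(0.5, abs=3 * se)

    def test_window_outside_trial_rejected(self, opto_base, rng):
        cfg, session, bouts = opto_base
        with pytest.raises(InvalidConfigError):
            generate_opto(
                session, bouts, cfg, OptoConfig(on_offset_s=19.5, duration_s=2.0),
                rng,
            )


class TestReproducibility:
    def test_identical_config_and_seed_identical_bundle(self):
        cfg = SimConfig(n_trials=15, seed=21)
        a = simulate_session(cfg, n_units=3, n_dendrites=4)
        b = simulate_session(cfg, n_units=3, n_dendrites=4)
        pd.testing.assert_frame_equal(a.session.trials, b.session.trials)
        pd.testing.assert_frame_equal(a.session.licks, b.session.licks)
        for ta, tb in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(ta.times, tb.times)
        for ca, cb in zip(a.calcium, b.calcium):
            np.testing.assert_array_equal(ca.times, cb.times)

    def test_all_times_within_session_span(self, small_bundle):
        T = small_bundle.session.duration_s
        assert np.all(small_bundle.session.lick_times >= 0)
        assert np.all(small_bundle.session.lick_times <= T)
        for tr in small_bundle.spikes:
            if tr.times.size:
                assert tr.times[0] >= 0 and tr.times[-1] <= T
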