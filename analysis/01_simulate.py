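#!/usr/bin/env python
"""Generate the study's synthetic session: 250 fixed-interval trials (10 s,
20% water omissions, never two in a row), one 6-8 Hz licking bout per trial
(75% exploratory), a 24-unit roster of PCs/MLIs with lick-phase tuning and
initiation/termination ramps, 12 PC dendrites in two imaging regions, and a
second opto session with full lick suppression plus 50% rebound probability.

Writes the session bundles under results/session/ and results/opto_session/.
"""

from pathlib import Path

from licktime.io import write_bundle
from licktime.synthetic import OptoConfig, SimConfig, simulate_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = SimConfig(n_trials=250, seed=0)
    bundle = simulate_session(cfg, n_units=24, n_dendrites=12)
    out = write_bundle(bundle, ROOT / "results" / "session", config=cfg)
    n_licks = len(bundle.session.licks)
    print(f"session: {cfg.n_trials} trials, {n_licks} licks, "
          f"{len(bundle.spikes)} units, {len(bundle.calcium)} dendrites "
          f"-> {out}")

    opto_cfg = SimConfig(n_trials=400, seed=1)
    opto_bundle = simulate_session(
        opto_cfg,
        opto=OptoConfig(suppression=1.0, rebound_prob=0.5),
        n_units=6,
        n_dendrites=0,
    )
    stim = opto_bundle.truth.opto["stimulated"].sum()
    out = write_bundle(
        opto_bundle, ROOT / "results" / "opto_session", config=opto_cfg
    )
    print(f"opto session: {opto_cfg.n_trials} trials, {stim} stimulated "
          f"omission trials -> {out}")


if __name__ == "__main__":
    main()
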