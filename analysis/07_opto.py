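#!/usr/bin/env python
"""Optogenetic perturbation metrics: lick suppression during the stimulus,
lick-rate variance normalized to the matched window of control trials, and
the probability of a rebound bout after the stimulus ends.

Reads results/opto_session/; writes results/opto/metrics.json.
"""

import json
from pathlib import Path

from licktime.behavior import opto_lick_metrics
from licktime.io import read_bundle

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = read_bundle(ROOT / "results" / "opto_session")
    out = ROOT / "results" / "opto"
    out.mkdir(parents=True, exist_ok=True)

    m = opto_lick_metrics(bundle.session)
    doc = {
        "variance_ratio": m.variance_ratio,
        "rate_during_stim_hz": m.rate_during_stim,
        "rate_during_control_hz": m.rate_during_control,
        "rate_rebound_stim_hz": m.rate_rebound_stim,
        "rate_rebound_control_hz": m.rate_rebound_control,
        "rebound_prob_stim": m.rebound_prob_stim,
        "rebound_prob_control": m.rebound_prob_control,
        "n_stim_trials": m.n_stim_trials,
        "n_control_trials": m.n_control_trials,
    }
    (out / "metrics.json").write_text(json.dumps(doc, indent=2))
    print(f"{m.n_stim_trials} stimulated vs {m.n_control_trials} control "
          f"omission trials")
    print(f"lick rate during stimulus: {m.rate_during_stim:.2f} Hz "
          f"(control {m.rate_during_control:.2f} Hz)")
    print(f"rebound bout probability: {m.rebound_prob_stim:.2f} "
          f"(control {m.rebound_prob_control:.2f})")

    truth = bundle.truth.opto
    if truth is not None and len(truth):
        configured = truth.loc[truth["stimulated"], "rebound"].mean()
        print(f"generator's configured rebound fraction: {configured:.2f}")


if __name__ == "__main__":
    main()
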