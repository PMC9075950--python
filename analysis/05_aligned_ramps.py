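#!/usr/bin/env python
"""Event-aligned delta-rate analysis: classify each PC's modulation around
bout initiation (pre- vs post-water contexts) and termination, compute the
population ramp onset, and relate spike rate to lick rate.

Reads results/session/ and results/units/; writes results/aligned/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from licktime.aligned import (
    FIRST_LICK_WINDOW,
    aligned_delta_rate,
    baseline_rate,
    classify_unit_by_context,
    lickrate_spikerate_correlation,
    population_onset_time,
)
from licktime.behavior import segment_bouts
from licktime.io import read_bundle
from licktime.types import InsufficientDataError

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = read_bundle(ROOT / "results" / "session")
    session = bundle.session
    cls = pd.read_csv(ROOT / "results" / "units" / "classification.csv")
    pc_ids = set(cls.loc[cls["label"].str.startswith("PC"), "unit_id"])
    out = ROOT / "results" / "aligned"
    out.mkdir(parents=True, exist_ok=True)

    bouts = [
        b
        for b in segment_bouts(session.lick_times, session=session)
        if b.isolated
    ]
    first_licks = np.array([b.first_lick_s for b in bouts])

    rows, responses, corr_rows = [], [], []
    for tr in bundle.spikes:
        if tr.unit_id not in pc_ids:
            continue
        base = baseline_rate(tr.times, session.lick_times, session.duration_s)
        ctx = classify_unit_by_context(tr.unit_id, tr.times, bouts, base)
        for context, c in ctx.by_context.items():
            rows.append(
                {"unit_id": tr.unit_id, "event": "first_lick",
                 "context": context, "modulation": c.modulation,
                 "onset_s": c.onset_time_s}
            )
        if ctx.termination is not None:
            rows.append(
                {"unit_id": tr.unit_id, "event": "last_lick", "context": "any",
                 "modulation": ctx.termination.modulation,
                 "onset_s": ctx.termination.onset_time_s}
            )
        responses.append(
            aligned_delta_rate(
                tr.times, first_licks, FIRST_LICK_WINDOW,
                baseline=base, unit_id=tr.unit_id,
            )
        )
        try:
            fit = lickrate_spikerate_correlation(session, tr.times)
            corr_rows.append(
                {"unit_id": tr.unit_id, "slope": fit.slope,
                 "intercept": fit.intercept, "r": fit.r, "n_bins": fit.n_bins}
            )
        except InsufficientDataError:
            pass

    df = pd.DataFrame(rows)
    df.to_csv(out / "ramp_classification.csv", index=False)
    pd.DataFrame(corr_rows).to_csv(out / "lick_spike_correlation.csv",
                                   index=False)

    init = df[df["event"] == "first_lick"]
    for context in ("pre_water", "post_water"):
        sub = init[init["context"] == context]
        npos = (sub["modulation"] == "positive").sum()
        nneg = (sub["modulation"] == "negative").sum()
        print(f"initiation ({context}): {npos}+ / {nneg}- of {len(sub)} PCs")
    term = df[df["event"] == "last_lick"]
    print(f"termination: {(term['modulation'] != 'none').sum()}"
          f"/{len(term)} PCs modulated")

    onset = population_onset_time(responses)
    if onset is not None:
        print(f"population ramp onset leads the first lick by "
              f"{-1000 * onset:.0f} ms")
    else:
        print("population trace shows no qualifying ramp")


if __name__ == "__main__":
    main()
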