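#!/usr/bin/env python
"""Segment licking bouts and characterize the behavior: trial-averaged lick
PSTHs aligned to water / first lick / last lick, and the histogram of
bout-initiation times relative to water allocation.

Reads results/session/; writes tables under results/behavior/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from licktime.behavior import (
    bout_initiation_histogram,
    segment_bouts,
    trial_averaged_lick_psth,
)
from licktime.io import read_bundle
from licktime.types import bouts_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = read_bundle(ROOT / "results" / "session")
    session = bundle.session
    out = ROOT / "results" / "behavior"
    out.mkdir(parents=True, exist_ok=True)

    bouts = segment_bouts(session.lick_times, session=session)
    bouts_to_frame(bouts).to_csv(out / "bouts.csv", index=False)
    iso = [b for b in bouts if b.isolated]
    pre = sum(b.context == "pre_water" for b in bouts)
    print(f"{len(bouts)} bouts ({len(iso)} well-separated); "
          f"{pre} exploratory (pre-water), {len(bouts) - pre} reactive")

    rows = []
    for align in ("water", "first_lick", "last_lick"):
        res = trial_averaged_lick_psth(session, align=align)
        for t, v, s in zip(res.series.times, res.series.values, res.series.sem):
            rows.append(
                {"align": align, "time_s": t, "rate_hz": v, "sem": s,
                 "n_trials": res.n_trials}
            )
        peak = res.series.values.max()
        print(f"PSTH aligned to {align}: peak {peak:.1f} Hz "
              f"over {res.n_trials} trials ({res.n_excluded} excluded)")
    pd.DataFrame(rows).to_csv(out / "lick_psth.csv", index=False)

    water = dict(zip(session.trials["trial_id"],
                     session.trials["start_s"] + session.interval_s))
    hist = bout_initiation_histogram(iso, water)
    pd.DataFrame(
        {"edge_lo_s": hist.edges[:-1], "edge_hi_s": hist.edges[1:],
         "count": hist.counts}
    ).to_csv(out / "initiation_histogram.csv", index=False)
    print(f"bout initiations: {hist.n_pre} pre-water, {hist.n_post} post-water")


if __name__ == "__main__":
    main()
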