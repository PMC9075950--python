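#!/usr/bin/env python
"""Climbing-fiber-evoked dendritic calcium events: flag water-responsive
imaging regions, detect per-dendrite initiation-ramp onsets (3-SD rule),
and check for a rate change at bout termination (expected null).

Reads results/session/; writes results/calcium/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from licktime.behavior import segment_bouts
from licktime.calcium import (
    calcium_ramp_onset,
    region_responsiveness,
    termination_rate_change,
)
from licktime.io import read_bundle
from licktime.types import InsufficientDataError

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = read_bundle(ROOT / "results" / "session")
    session = bundle.session
    out = ROOT / "results" / "calcium"
    out.mkdir(parents=True, exist_ok=True)

    regions = region_responsiveness(bundle.calcium, session.water_times)
    pd.DataFrame(
        [
            {"region_id": r.region_id, "responsive": r.responsive,
             "peak_rate_hz": r.peak_rate_hz, "n_dendrites": r.n_dendrites}
            for r in regions
        ]
    ).to_csv(out / "regions.csv", index=False)
    for r in regions:
        state = ("skipped: " + r.skipped_reason if r.responsive is None
                 else "water-responsive" if r.responsive else "unresponsive")
        print(f"region {r.region_id} ({r.n_dendrites} dendrites): {state}")

    bouts = [
        b
        for b in segment_bouts(session.lick_times, session=session)
        if b.isolated
    ]
    last = np.array([b.last_lick_s for b in bouts])

    # contexts are aligned separately: on post-water bouts the water
    # response precedes the first lick and would masquerade as an early
    # initiation ramp
    rows = []
    for context in ("pre_water", "post_water"):
        first = np.array(
            [b.first_lick_s for b in bouts if b.context == context]
        )
        for tr in bundle.calcium:
            try:
                onset = calcium_ramp_onset(tr, first)
            except InsufficientDataError:
                onset = None
            rows.append(
                {"dendrite_id": tr.dendrite_id, "region_id": tr.region_id,
                 "context": context, "onset_s": onset}
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "onsets.csv", index=False)
    for context, grp in df.groupby("context"):
        det = grp["onset_s"].notna()
        if det.any():
            print(f"initiation ramps ({context}): {det.sum()}/{len(grp)} "
                  f"dendrites, mean onset "
                  f"{grp.loc[det, 'onset_s'].mean():+.2f} s re first lick")
        else:
            print(f"initiation ramps ({context}): none detected")

    term_rows = []
    for tr in bundle.calcium:
        res = termination_rate_change(tr, last, session.water_times)
        if res is not None:
            term_rows.append(
                {"dendrite_id": tr.dendrite_id,
                 "rate_before_hz": res.rate_before_hz,
                 "rate_after_hz": res.rate_after_hz,
                 "p_value": res.p_value, "n_trials": res.n_trials}
            )
    tdf = pd.DataFrame(term_rows)
    tdf.to_csv(out / "termination.csv", index=False)
    sig = (tdf["p_value"] < 0.05).sum()
    print(f"termination rate change significant in {sig}/{len(tdf)} "
          f"dendrites (no change expected at bout termination)")


if __name__ == "__main__":
    main()
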