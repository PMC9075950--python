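#!/usr/bin/env python
"""Classify the recorded roster into unambiguous PCs (complex spikes),
putative PCs (spike footprint on >= 7 channels above the ~30 µV noise
floor), and the rest; verify the labels against the generator's classes.

Reads results/session/; writes results/units/classification.csv.
"""

from pathlib import Path

import pandas as pd

from licktime.io import read_bundle
from licktime.units import classify_roster

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = read_bundle(ROOT / "results" / "session")
    out = ROOT / "results" / "units"
    out.mkdir(parents=True, exist_ok=True)

    summary = classify_roster(bundle.channel_profiles)
    df = pd.DataFrame(
        [
            {"unit_id": c.unit_id, "label": c.label,
             "channel_count": c.channel_count}
            for c in summary.classifications
        ]
    )
    df.to_csv(out / "classification.csv", index=False)
    print("label counts:", summary.counts)
    print(f"PC analysis set: {summary.n_pc} units")

    truth = bundle.truth.unit_specs
    if truth:
        agree = sum(
            (truth[c.unit_id].cell_class.startswith("PC"))
            == c.label.startswith("PC")
            for c in summary.classifications
        )
        print(f"PC vs non-PC agreement with generator classes: "
              f"{agree}/{len(summary.classifications)}")


if __name__ == "__main__":
    main()
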