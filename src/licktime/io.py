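"""The session bundle on disk: plain comma-separated tables.

Schemas (all times in seconds from session start, microsecond precision):

- ``trials.csv``:   trial_id, start_s, water_s, rewarded, opto_on_s, opto_off_s
- ``licks.csv``:    trial_id, time_s
- ``spikes.csv``:   unit_id, time_s
- ``channels.csv``: unit_id, channel, peak_uv, has_cs
- ``calcium.csv``:  dendrite_id, region_id, time_s     (optional)

plus ``ground_truth.yaml`` and ``config.yaml`` when the bundle was
simulated. Validation checks types, sort order, and cross-references
(every trial_id in licks must exist in trials) and reports offending rows.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .types import (
    CalciumEventTrain,
    Session,
    SpikeTrain,
    UnitChannelProfile,
    ValidationError,
)
from .synthetic import SessionBundle, GroundTruth

TRIAL_COLUMNS = [
    "trial_id", "start_s", "water_s", "rewarded", "opto_on_s", "opto_off_s",
]


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing column(s) {missing}")


def _check_sorted(df: pd.DataFrame, col: str, name: str) -> None:
    v = df[col].to_numpy(float)
    if np.any(~np.isfinite(v)):
        row = int(np.argmax(~np.isfinite(v)))
        raise ValidationError(f"{name} row {row}: non-finite {col}")
    bad = np.nonzero(np.diff(v) < 0)[0]
    if bad.size:
        raise ValidationError(f"{name} row {int(bad[0]) + 1}: {col} not sorted")


def write_bundle(bundle: SessionBundle, out_dir, config=None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ses = bundle.session
    ses.trials[TRIAL_COLUMNS].to_csv(out / "trials.csv", index=False)
    ses.licks[["trial_id", "time_s"]].to_csv(out / "licks.csv", index=False)

    spike_rows = [
        {"unit_id": tr.unit_id, "time_s": t}
        for tr in bundle.spikes
        for t in tr.times
    ]
    pd.DataFrame(spike_rows, columns=["unit_id", "time_s"]).to_csv(
        out / "spikes.csv", index=False
    )
    chan_rows = [
        {
            "unit_id": p.unit_id,
            "channel": ch,
            "peak_uv": amp,
            "has_cs": p.has_complex_spikes,
        }
        for p in bundle.channel_profiles
        for ch, amp in enumerate(p.peak_uv)
    ]
    pd.DataFrame(
        chan_rows, columns=["unit_id", "channel", "peak_uv", "has_cs"]
    ).to_csv(out / "channels.csv", index=False)
    ca_rows = [
        {"dendrite_id": tr.dendrite_id, "region_id": tr.region_id, "time_s": t}
        for tr in bundle.calcium
        for t in tr.times
    ]
    pd.DataFrame(
        ca_rows, columns=["dendrite_id", "region_id", "time_s"]
    ).to_csv(out / "calcium.csv", index=False)

    truth = bundle.truth
    doc = {
        "unit_specs": {
            uid: dataclasses.asdict(spec)
            for uid, spec in truth.unit_specs.items()
        },
        "dendrite_specs": {
            did: dataclasses.asdict(spec)
            for did, spec in truth.dendrite_specs.items()
        },
        "bouts": (
            truth.bouts.to_dict("records") if truth.bouts is not None else []
        ),
        "opto": (
            truth.opto.to_dict("records") if truth.opto is not None else []
        ),
    }
    (out / "ground_truth.yaml").write_text(
        yaml.safe_dump(doc, sort_keys=False)
    )
    if config is not None:
        (out / "config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(config), sort_keys=False)
        )
    return out


def read_bundle(in_dir, interval_s: Optional[float] = None) -> SessionBundle:
    """Load and validate a session bundle directory."""
    src = Path(in_dir)
    for fname in ("trials.csv", "licks.csv", "spikes.csv", "channels.csv"):
        if not (src / fname).exists():
            raise ValidationError(f"bundle is missing {fname}")

    cfg_path = src / "config.yaml"
    if interval_s is None:
        interval_s = 10.0
        if cfg_path.exists():
            cfg = yaml.safe_load(cfg_path.read_text()) or {}
            interval_s = float(cfg.get("interval_s", 10.0))

    trials = pd.read_csv(src / "trials.csv")
    _require_columns(trials, TRIAL_COLUMNS[:4], "trials.csv")
    for col in ("opto_on_s", "opto_off_s"):
        if col not in trials.columns:
            trials[col] = np.nan
    _check_sorted(trials, "start_s", "trials.csv")
    w = trials["water_s"].to_numpy(float)
    s = trials["start_s"].to_numpy(float)
    bad = np.isfinite(w) & (w < s)
    if bad.any():
        raise ValidationError(
            f"trials.csv row {int(np.argmax(bad))}: water before trial start"
        )

    licks = pd.read_csv(src / "licks.csv")
    _require_columns(licks, ["trial_id", "time_s"], "licks.csv")
    _check_sorted(licks, "time_s", "licks.csv")
    known = set(trials["trial_id"])
    orphan = ~licks["trial_id"].isin(known)
    if orphan.any():
        row = int(np.argmax(orphan.to_numpy()))
        raise ValidationError(
            f"licks.csv row {row}: trial_id {licks['trial_id'].iloc[row]!r} "
            "not present in trials.csv"
        )
    session = Session(trials=trials, licks=licks, interval_s=interval_s)

    spikes_df = pd.read_csv(src / "spikes.csv")
    _require_columns(spikes_df, ["unit_id", "time_s"], "spikes.csv")
    spikes = []
    for uid, grp in spikes_df.groupby("unit_id", sort=True):
        t = np.sort(grp["time_s"].to_numpy(float))
        spikes.append(SpikeTrain(unit_id=str(uid), times=t))

    chan_df = pd.read_csv(src / "channels.csv")
    _require_columns(
        chan_df, ["unit_id", "channel", "peak_uv", "has_cs"], "channels.csv"
    )
    profiles = []
    for uid, grp in chan_df.groupby("unit_id", sort=True):
        grp = grp.sort_values("channel")
        profiles.append(
            UnitChannelProfile(
                unit_id=str(uid),
                peak_uv=grp["peak_uv"].to_numpy(float),
                has_complex_spikes=bool(grp["has_cs"].iloc[0]),
            )
        )

    calcium = []
    ca_path = src / "calcium.csv"
    if ca_path.exists():
        ca_df = pd.read_csv(ca_path)
        if len(ca_df):
            _require_columns(
                ca_df, ["dendrite_id", "region_id", "time_s"], "calcium.csv"
            )
            for (did, rid), grp in ca_df.groupby(
                ["dendrite_id", "region_id"], sort=True
            ):
                calcium.append(
                    CalciumEventTrain(
                        dendrite_id=str(did),
                        region_id=str(rid),
                        times=np.sort(grp["time_s"].to_numpy(float)),
                    )
                )

    truth = GroundTruth()
    gt_path = src / "ground_truth.yaml"
    if gt_path.exists():
        from .synthetic import DendriteSpec, Ramp, UnitSpec

        doc = yaml.safe_load(gt_path.read_text()) or {}

        def mk_ramp(d):
            return Ramp(**d) if d else None

        for uid, d in (doc.get("unit_specs") or {}).items():
            d = dict(d)
            for key in ("init_ramp", "term_ramp"):
                d[key] = Ramp(**d[key])
            for key in ("init_ramp_pre", "init_ramp_post"):
                d[key] = mk_ramp(d.get(key))
            truth.unit_specs[uid] = UnitSpec(**d)
        for did, d in (doc.get("dendrite_specs") or {}).items():
            truth.dendrite_specs[did] = DendriteSpec(**d)
        if doc.get("bouts"):
            truth.bouts = pd.DataFrame(doc["bouts"])
        if doc.get("opto"):
            truth.opto = pd.DataFrame(doc["opto"])

    return SessionBundle(
        session=session,
        spikes=spikes,
        channel_profiles=profiles,
        calcium=calcium,
        truth=truth,
    )
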