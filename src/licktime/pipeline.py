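"""End-to-end orchestration: simulate (or load) -> classify -> analyze ->
report. Every stage writes comma-separated tables plus a JSON summary; the
run log records every parameter and the count at every filter."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from . import aligned as al
from . import behavior as bh
from . import calcium as ca
from . import entrainment as en
from . import units as un
from .config import RunConfig, config_to_dict
from .io import read_bundle, write_bundle
from .synthetic import SessionBundle, simulate_session
from .types import InsufficientDataError, ValidationError, bouts_to_frame


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _get_bundle(cfg: RunConfig) -> SessionBundle:
    if cfg.bundle_dir is not None:
        return read_bundle(cfg.bundle_dir)
    if cfg.simulate is None:
        raise ValidationError(
            "config must either name a bundle_dir or request simulation"
        )
    return simulate_session(
        cfg.simulate,
        opto=cfg.opto,
        n_units=cfg.n_units,
        n_dendrites=cfg.n_dendrites,
    )


def stage_simulate(cfg: RunConfig, out: Path) -> SessionBundle:
    bundle = _get_bundle(cfg)
    write_bundle(bundle, out / "bundle", config=cfg.simulate)
    return bundle


def stage_classify_units(cfg: RunConfig, bundle: SessionBundle, out: Path):
    summary = un.classify_roster(
        bundle.channel_profiles,
        channel_threshold=cfg.classification.channel_threshold,
        noise_floor_uv=cfg.classification.noise_floor_uv,
    )
    df = pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "label": c.label,
                "channel_count": c.channel_count,
            }
            for c in summary.classifications
        ]
    )
    df.to_csv(out / "unit_classification.csv", index=False)
    return summary


def stage_bouts(cfg: RunConfig, bundle: SessionBundle, out: Path):
    bouts = bh.segment_bouts(
        bundle.session.lick_times,
        bout_break_s=cfg.behavior.bout_break_s,
        isolation_s=cfg.behavior.isolation_s,
        session=bundle.session,
    )
    bouts_to_frame(bouts).to_csv(out / "bouts.csv", index=False)
    return bouts


def stage_entrainment(cfg: RunConfig, bundle: SessionBundle, out: Path, pc_ids):
    trains = {
        tr.unit_id: tr.times for tr in bundle.spikes if tr.unit_id in pc_ids
    }
    results = en.analyze_population(
        trains, bundle.session.lick_times, fdr=cfg.entrainment.fdr
    )
    pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "n_spikes": r.n_spikes,
                "resultant_length": r.resultant_length,
                "resultant_angle": r.resultant_angle,
                "rayleigh_p": r.rayleigh_p,
                "q_value": r.q_value,
                "entrained": r.entrained,
            }
            for r in results
        ]
    ).to_csv(out / "entrainment.csv", index=False)
    dens = [r.density for r in results if r.density is not None]
    if dens:
        np.savetxt(out / "entrainment_density.csv", np.vstack(dens), delimiter=",")
    return results


def stage_align(cfg: RunConfig, bundle: SessionBundle, out: Path, bouts, pc_ids):
    session = bundle.session
    iso = [b for b in bouts if b.isolated]
    rows = []
    classifications = []
    for tr in bundle.spikes:
        if tr.unit_id not in pc_ids:
            continue
        try:
            base = al.baseline_rate(
                tr.times,
                session.lick_times,
                session.duration_s,
                exclusion_s=cfg.aligned.baseline_exclusion_s,
            )
        except InsufficientDataError:
            continue
        ctx = al.classify_unit_by_context(
            tr.unit_id,
            tr.times,
            iso,
            base,
            min_events=cfg.aligned.min_events_per_context,
        )
        classifications.append(ctx)
        for context, cls in ctx.by_context.items():
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "event": "first_lick",
                    "context": context,
                    "modulation": cls.modulation,
                    "onset_s": cls.onset_time_s,
                }
            )
        if ctx.termination is not None:
            rows.append(
                {
                    "unit_id": tr.unit_id,
                    "event": "last_lick",
                    "context": "any",
                    "modulation": ctx.termination.modulation,
                    "onset_s": ctx.termination.onset_time_s,
                }
            )
    pd.DataFrame(
        rows, columns=["unit_id", "event", "context", "modulation", "onset_s"]
    ).to_csv(out / "ramp_classification.csv", index=False)
    return classifications


def stage_calcium(cfg: RunConfig, bundle: SessionBundle, out: Path, bouts):
    if not bundle.calcium:
        return {"skipped": "no calcium table in bundle"}
    session = bundle.session
    water = session.water_times
    regions = ca.region_responsiveness(
        bundle.calcium,
        water,
        sd_cutoff=cfg.calcium.sd_cutoff,
        min_dendrites=cfg.calcium.min_dendrites_per_region,
        peri_water_s=cfg.calcium.peri_water_s,
    )
    first_licks = np.array([b.first_lick_s for b in bouts if b.isolated])
    rows = []
    for tr in bundle.calcium:
        try:
            onset = ca.calcium_ramp_onset(
                tr,
                first_licks,
                sd_cutoff=cfg.calcium.sd_cutoff,
                min_bouts=cfg.calcium.min_bouts_for_onset,
            )
        except InsufficientDataError:
            onset = None
        rows.append(
            {
                "dendrite_id": tr.dendrite_id,
                "region_id": tr.region_id,
                "onset_s": onset,
            }
        )
    pd.DataFrame(rows).to_csv(out / "calcium_onsets.csv", index=False)
    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "responsive": r.responsive,
                "peak_rate_hz": r.peak_rate_hz,
                "n_dendrites": r.n_dendrites,
                "skipped_reason": r.skipped_reason,
            }
            for r in regions
        ]
    ).to_csv(out / "calcium_regions.csv", index=False)
    return {
        "n_regions": len(regions),
        "n_responsive": sum(1 for r in regions if r.responsive),
        "n_onsets": sum(1 for r in rows if r["onset_s"] is not None),
    }


def stage_opto(cfg: RunConfig, bundle: SessionBundle, out: Path):
    trials = bundle.session.trials
    if not np.isfinite(trials["opto_on_s"].astype(float)).any():
        return {"skipped": "no stimulated trials in session"}
    m = bh.opto_lick_metrics(
        bundle.session,
        rebound_window_s=cfg.behavior.rebound_window_s,
        isolation_s=cfg.behavior.isolation_s,
        bout_break_s=cfg.behavior.bout_break_s,
    )
    d = dataclasses.asdict(m)
    (out / "opto_metrics.json").write_text(json.dumps(_jsonable(d), indent=2))
    return d


def _report(cfg, bundle, bouts, ent_results, ramp_cls, out: Path) -> dict:
    """Standard group comparisons over the run's outputs (report stage)."""
    report: dict = {}
    pre_onsets = [
        c.by_context["pre_water"].onset_time_s
        for c in ramp_cls
        if c.by_context.get("pre_water")
        and c.by_context["pre_water"].modulation == "positive"
    ]
    post_onsets = [
        c.by_context["post_water"].onset_time_s
        for c in ramp_cls
        if c.by_context.get("post_water")
        and c.by_context["post_water"].modulation == "positive"
    ]
    report["n_pre_positive"] = len(pre_onsets)
    report["n_post_positive"] = len(post_onsets)
    if len(pre_onsets) >= 2 and len(post_onsets) >= 2:
        t = sstats.ttest_ind(pre_onsets, post_onsets, equal_var=False)
        report["onset_pre_mean_s"] = float(np.mean(pre_onsets))
        report["onset_post_mean_s"] = float(np.mean(post_onsets))
        report["onset_ttest_p"] = float(t.pvalue)
    flagged = [r for r in ent_results if r.entrained]
    testable = [r for r in ent_results if np.isfinite(r.rayleigh_p)]
    report["n_entrained"] = len(flagged)
    report["n_testable"] = len(testable)
    if testable:
        report["entrained_fraction"] = len(flagged) / len(testable)
    report["n_bouts"] = len(bouts)
    report["n_isolated_bouts"] = sum(1 for b in bouts if b.isolated)
    return report


def run_pipeline(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "parameters": config_to_dict(cfg),
        "counts": {},
    }
    bundle = stage_simulate(cfg, out)
    log["counts"]["n_trials"] = len(bundle.session.trials)
    log["counts"]["n_licks"] = len(bundle.session.licks)
    log["counts"]["n_units"] = len(bundle.spikes)
    log["counts"]["n_dendrites"] = len(bundle.calcium)

    roster = stage_classify_units(cfg, bundle, out)
    pc_ids = set(roster.pc_set)
    log["counts"]["units_per_label"] = roster.counts
    log["counts"]["n_pc"] = len(pc_ids)

    bouts = stage_bouts(cfg, bundle, out)
    log["counts"]["n_bouts"] = len(bouts)
    log["counts"]["n_isolated_bouts"] = sum(1 for b in bouts if b.isolated)
    log["counts"]["bouts_per_context"] = {
        ctx: sum(1 for b in bouts if b.context == ctx)
        for ctx in ("pre_water", "post_water")
    }

    ent = stage_entrainment(cfg, bundle, out, pc_ids)
    log["counts"]["n_entrained"] = sum(1 for r in ent if r.entrained)

    ramp_cls = stage_align(cfg, bundle, out, bouts, pc_ids)
    log["counts"]["n_units_ramp_classified"] = len(ramp_cls)

    log["calcium"] = _jsonable(stage_calcium(cfg, bundle, out, bouts))
    log["opto"] = _jsonable(stage_opto(cfg, bundle, out))

    if cfg.report:
        log["report"] = _jsonable(
            _report(cfg, bundle, bouts, ent, ramp_cls, out)
        )
    (out / "run_log.json").write_text(json.dumps(_jsonable(log), indent=2))
    return log
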