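"""End-to-end analysis of one recording day (Pre-box, Track, Post-box).

Stages: event detection -> active-cell classification -> pairing/PDI ->
tuning statistics -> template construction -> rotation-sequence matching
-> ripple replay -> time-gap analysis. Each stage is a plain function so
the CLI (and tests) can run them individually; ``run_pipeline`` chains
them and emits a machine-readable report carrying the seed and shuffle
counts of every stochastic result.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import events as ev_mod
from . import sequences as seq_mod
from . import tuning as tun_mod
from .config import PipelineConfig
from .core import SessionRecording, TRAJECTORIES
from .cross_activation import classify_active_cells, pairing_analysis

logger = logging.getLogger(__name__)

BOX_SESSIONS = ("pre_box", "post_box")


def detect_day_events(day: dict, config: PipelineConfig) -> dict:
    """Rotation/lap/stop (and ripple) events for every session of a day."""
    out: dict = {}
    for name in BOX_SESSIONS:
        ses = day.get(name)
        if ses is None:
            continue
        rot = ev_mod.detect_rotation_events(
            ses.position, config.opening_center_deg,
            zone_half_width_deg=config.opening_zone_half_deg,
            min_span_deg=config.min_rotation_span_deg)
        stops = ev_mod.detect_stop_periods(
            ses.position, config.stop_speed_cm_s, config.stop_min_dur_s)
        entry = {"rotation_events": rot, "stops": stops,
                 "behavior": ev_mod.behavior_summary(
                     ses.position, rot, (), config.opening_center_deg,
                     config.opening_zone_half_deg)}
        if ses.lfp is not None:
            entry["ripple_events"] = ev_mod.detect_ripple_events(
                ses.lfp,
                peak_thresh_sd=config.ripple_peak_sd,
                edge_thresh_sd=config.ripple_edge_sd,
                band_hz=(config.ripple_band_low_hz,
                         config.ripple_band_high_hz),
                envelope_smooth_s=config.ripple_envelope_smooth_s,
                merge_gap_s=config.ripple_merge_gap_s,
                min_dur_s=config.ripple_min_dur_s,
                max_dur_s=config.ripple_max_dur_s)
        out[name] = entry
    track = day.get("track")
    if track is not None:
        laps = ev_mod.detect_lap_events(track.position,
                                        config.track_length_cm,
                                        config.end_zone_cm)
        stops = ev_mod.detect_stop_periods(
            track.position, config.stop_speed_cm_s, config.stop_min_dur_s)
        out["track"] = {
            "lap_events": laps,
            "laps_by_trajectory": {
                trj: [l for l in laps if l.trajectory == trj]
                for trj in TRAJECTORIES},
            "stops": stops,
            "behavior": ev_mod.behavior_summary(track.position, (), laps),
        }
    return out


def classification_stage(day: dict, events: dict,
                         config: PipelineConfig) -> dict:
    """Day-level and per-box-session active-cell classification."""
    track = day.get("track")
    laps_by_traj = events.get("track", {}).get("laps_by_trajectory", {})
    track_stops = events.get("track", {}).get("stops")
    all_cells = sorted({c for name in (*BOX_SESSIONS, "track")
                        if day.get(name) is not None
                        for c in day[name].spikes})
    rate_range = (config.active_rate_min_hz, config.active_rate_max_hz)

    # day-level: rotation events pooled over Pre- and Post-box
    pooled_rot, pooled_stops = [], []
    for name in BOX_SESSIONS:
        if name in events:
            pooled_rot += list(events[name]["rotation_events"])
            pooled_stops += [tuple(iv) for iv in events[name]["stops"]]
    box_spikes = {c: np.concatenate([
        day[name].spikes.get(c, np.empty(0)) for name in BOX_SESSIONS
        if day.get(name) is not None]) for c in all_cells}
    # box sessions share one clock per session; rotation events from each
    # session apply to that session's spikes only, so classify per session
    # and pool by union of event time
    day_df = None
    if track is not None:
        day_df = classify_active_cells(
            track.spikes, None, laps_by_traj, None, track_stops, rate_range)

    per_session_box_active: dict[str, set] = {}
    box_rates = {}
    for name in BOX_SESSIONS:
        if name not in events or day.get(name) is None:
            continue
        df = classify_active_cells(
            day[name].spikes, events[name]["rotation_events"], {},
            events[name]["stops"], None, rate_range)
        per_session_box_active[name] = set(df.index[df["box_active"]])
        box_rates[name] = df["box_rate"]

    box_active_pooled = set().union(*per_session_box_active.values()) \
        if per_session_box_active else set()
    track_active_by_traj = {}
    track_active = set()
    if day_df is not None:
        for trj in TRAJECTORIES:
            col = f"active_{trj}"
            if col in day_df:
                track_active_by_traj[trj] = set(
                    day_df.index[day_df[col]])
        track_active = set(day_df.index[day_df["track_active"]])

    common = box_active_pooled & track_active
    label = {}
    for c in all_cells:
        in_box, in_trk = c in box_active_pooled, c in track_active
        label[c] = ("common" if in_box and in_trk else
                    "rotation_only" if in_box else
                    "running_only" if in_trk else "inactive")
    return {
        "cells": all_cells,
        "n_total": len(all_cells),
        "labels": label,
        "common_cells": sorted(common),
        "box_active_by_session": per_session_box_active,
        "box_active_pooled": box_active_pooled,
        "track_active_by_trajectory": track_active_by_traj,
        "track_active": track_active,
        "track_df": day_df,
    }


def pairing_stage(cls: dict, day_name: str = "") -> pd.DataFrame:
    return pairing_analysis(cls["track_active_by_trajectory"],
                            cls["box_active_by_session"],
                            cls["n_total"], day=day_name)


def tuning_stage(day: dict, events: dict, cls: dict,
                 config: PipelineConfig,
                 rng: np.random.Generator,
                 per_cell_statistics: bool = True) -> dict:
    """Rate curves per trajectory plus per-cell tuning statistics.

    ``per_cell_statistics=False`` computes only the rate curves (enough
    for template construction), skipping rotation-consistency and the
    Rayleigh test; replicate simulations use this fast path.
    """
    track = day["track"]
    laps_by_traj = events["track"]["laps_by_trajectory"]
    stops = events["track"]["stops"]
    curves: dict[str, dict[int, tun_mod.RateCurve]] = {}
    si: dict[str, dict[int, float]] = {}
    for trj, laps in laps_by_traj.items():
        if not laps:
            continue
        curves[trj] = {}
        si[trj] = {}
        for cid in cls["track_active_by_trajectory"].get(trj, ()):
            curve = tun_mod.linear_rate_curve(
                track.spikes[cid], track.position, laps, stops,
                bin_cm=config.bin_cm, sigma_bins=config.sigma_bins,
                track_length_cm=config.track_length_cm,
                reward_zone_cm=config.reward_zone_cm)
            curves[trj][cid] = curve
            si[trj][cid] = tun_mod.spatial_information(
                curve, min_occupancy_s=config.min_occupancy_s)

    consistency = {}
    rayleigh_p = {}
    for name in BOX_SESSIONS:
        if not per_cell_statistics or name not in events:
            continue
        ses = day[name]
        rot = events[name]["rotation_events"]
        for cid in cls["box_active_by_session"].get(name, ()):
            consistency[(name, cid)] = tun_mod.rotation_consistency(
                ses.spikes[cid], ses.position, rot,
                n_shuffles=config.n_consistency_shuffles, rng=rng,
                bin_deg=config.bin_deg, sigma_bins=config.sigma_bins)
            rayleigh_p[(name, cid)] = tun_mod.rayleigh_hd_test(
                ses.spikes[cid], ses.position, rot,
                min_spikes=config.rayleigh_min_spikes)
    return {"curves_by_trajectory": curves, "spatial_information": si,
            "rotation_consistency": consistency, "rayleigh_p": rayleigh_p}


def template_stage(tuning: dict, cls: dict,
                   config: PipelineConfig) -> dict:
    return seq_mod.build_templates(
        tuning["curves_by_trajectory"], cls["common_cells"],
        min_cells=config.min_sequence_cells,
        peak_sd_criterion=config.template_peak_sd)


def rotation_candidates(day: dict, events: dict, templates: dict,
                        config: PipelineConfig) -> list:
    """Rotation candidate sequences pooled over Pre- and Post-box.

    Template cells from all same-day templates are pooled for extraction;
    scoring against each template restricts to its own cells.
    """
    tmpl_cells = sorted({c for t in templates.values() for c in t.cell_ids})
    cands = []
    for name in BOX_SESSIONS:
        if name not in events:
            continue
        ses = day[name]
        for ev in events[name]["rotation_events"]:
            cand = seq_mod.extract_rotation_sequence(
                ev, tmpl_cells, ses.spikes, ses.position,
                min_cells=config.min_sequence_cells,
                bin_deg=config.bin_deg, sigma_bins=config.sigma_bins)
            if cand is not None:
                cands.append((name, cand))
    return cands


def sequence_stage(day: dict, events: dict, templates: dict,
                   config: PipelineConfig,
                   rng: np.random.Generator) -> dict:
    cands = rotation_candidates(day, events, templates, config)
    group = seq_mod.count_matching_sequences(
        [c for _, c in cands], templates,
        n_template_sets=config.n_template_sets,
        n_shuffles=config.n_sequence_shuffles, rng=rng,
        min_cells=config.min_sequence_cells) if templates and cands else None
    return {"candidates": cands, "group": group}


def ripple_stage(day: dict, events: dict, templates: dict,
                 config: PipelineConfig, rng: np.random.Generator) -> dict:
    cands = []
    for name in BOX_SESSIONS:
        if name not in events or "ripple_events" not in events[name]:
            continue
        ses = day[name]
        tmpl_cells = sorted({c for t in templates.values()
                             for c in t.cell_ids})
        for rip in events[name]["ripple_events"]:
            cand = seq_mod.extract_ripple_sequence(
                rip, tmpl_cells, ses.spikes,
                min_cells=config.min_sequence_cells,
                sigma_s=config.ripple_rate_sigma_s)
            if cand is not None:
                cands.append((name, cand))
    group = seq_mod.count_matching_sequences(
        [c for _, c in cands], templates,
        n_template_sets=config.n_template_sets,
        n_shuffles=config.n_sequence_shuffles, rng=rng,
        min_cells=config.min_sequence_cells) if templates and cands else None
    return {"candidates": cands, "group": group}


def gap_stage(day: dict, events: dict, templates: dict, seq_result: dict,
              config: PipelineConfig, rng: np.random.Generator) -> list:
    """Time-gap z for every matching rotation sequence."""
    group = seq_result.get("group")
    if group is None or group.matched is None:
        return []
    laps = events["track"]["lap_events"]
    if not laps:
        return []
    track = day["track"]
    mean_lap = float(np.mean([l.duration for l in laps]))
    sp = track.position.speed()
    from .core import as_intervals, in_intervals
    moving = in_intervals(track.position.t, as_intervals(laps))
    mean_speed = float(sp[moving].mean()) if moving.any() else float("nan")

    out = []
    for (name, cand), matched in zip(seq_result["candidates"],
                                     group.matched):
        if not matched:
            continue
        # use the template this candidate matches best
        best, best_score = None, -1.0
        for tmpl in templates.values():
            shared = [c for c in cand.cell_ids if c in tmpl.cell_ids]
            if len(shared) < config.min_sequence_cells:
                continue
            s, _ = seq_mod.circular_match_score(shared, tmpl)
            if s > best_score:
                best, best_score = tmpl, s
        if best is None:
            continue
        gd = seq_mod.time_gap_difference(
            cand, best, day[name].spikes,
            mean_speed_cm_s=mean_speed, mean_lap_duration_s=mean_lap,
            n_shuffles=config.n_gap_shuffles, rng=rng,
            sigma_s=config.rotation_rate_sigma_s)
        out.append({"session": name, "event_start_s": cand.event.start_s,
                    "template": best.trajectory, "gap": gd})
    return out


def run_pipeline(day: dict[str, SessionRecording],
                 config: Optional[PipelineConfig] = None,
                 seed: int = 0,
                 out_dir: Optional[str | Path] = None) -> dict:
    """Chain all stages for one day and return a serializable report."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    logger.info("pipeline seed=%d, config=%s", seed, config.asdict())

    events = detect_day_events(day, config)
    report: dict = {"seed": seed, "config": config.asdict(),
                    "shuffles": {
                        "per_sequence": config.n_sequence_shuffles,
                        "template_sets": config.n_template_sets,
                        "consistency": config.n_consistency_shuffles,
                        "gaps": config.n_gap_shuffles}}
    report["behavior"] = {
        name: vars(entry["behavior"]) for name, entry in events.items()
        if "behavior" in entry}
    report["n_events"] = {
        name: {k: len(v) for k, v in entry.items()
               if isinstance(v, list)} for name, entry in events.items()}

    if "track" not in day or not any(n in day for n in BOX_SESSIONS):
        report["notice"] = ("day lacks a track or box session; "
                            "cross-activation stages skipped")
        logger.warning(report["notice"])
        return report

    cls = classification_stage(day, events, config)
    counts = pd.Series(list(cls["labels"].values())).value_counts()
    report["classification"] = {
        "n_total": cls["n_total"],
        "counts": counts.to_dict(),
        "common_cells": cls["common_cells"]}

    pairing = pairing_stage(cls)
    report["pairings"] = pairing.to_dict(orient="records")

    tuning = tuning_stage(day, events, cls, config, rng)
    cons = [r.z for r in tuning["rotation_consistency"].values()
            if np.isfinite(r.z)]
    report["rotation_consistency"] = {
        "n_cells": len(tuning["rotation_consistency"]),
        "mean_z": float(np.mean(cons)) if cons else None,
        "frac_consistent": float(np.mean(
            [r.significant for r in
             tuning["rotation_consistency"].values()]))
        if tuning["rotation_consistency"] else None}
    pvals = [p for p in tuning["rayleigh_p"].values() if np.isfinite(p)]
    report["rayleigh"] = {
        "n_cells": len(pvals),
        "frac_tuned": float(np.mean(np.asarray(pvals) < 0.05))
        if pvals else None}

    templates = template_stage(tuning, cls, config)
    report["templates"] = {t: list(s.cell_ids)
                           for t, s in templates.items()}

    seq_result = {"candidates": [], "group": None}
    replay_result = {"candidates": [], "group": None}
    gaps = []
    if templates:
        seq_result = sequence_stage(day, events, templates, config, rng)
        replay_result = ripple_stage(day, events, templates, config, rng)
        gaps = gap_stage(day, events, templates, seq_result, config, rng)

    def group_dict(g):
        if g is None:
            return None
        return {"n_candidates": g.n_candidates, "n_matches": g.n_matches,
                "match_rate_pct": g.match_rate_pct, "p_value": g.p_value,
                "p": g.p_label}

    report["sequence_matching"] = group_dict(seq_result.get("group"))
    report["ripple_replay"] = group_dict(replay_result.get("group"))
    report["gap_analysis"] = [
        {"session": g["session"], "event_start_s": g["event_start_s"],
         "template": g["template"],
         "mean_abs_gap_diff": g["gap"].mean_abs_diff, "z": g["gap"].z}
        for g in gaps]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pairing.to_csv(out_dir / "pairings.tsv", sep="\t", index=False)
        from .io import events_to_frame
        frames = []
        for name, entry in events.items():
            for key, val in entry.items():
                if isinstance(val, (list, np.ndarray)) and key != \
                        "laps_by_trajectory":
                    frames.append(events_to_frame(val, label=name))
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / "events.tsv", sep="\t", index=False)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    return str(obj)
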