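"""Delimited-text session format: readers, writers, result tables.

A session directory holds ``meta.json`` (id, condition, geometry, cell
list, LFP rate), ``spikes.tsv`` (cell_id, t_s), ``position.tsv``
(t_s, x_cm, y_cm, hd_deg), optionally ``demo_position.tsv``, ``lfp.tsv``
(one sample per line), and the simulator's ``ground_truth.json`` sidecar.
A day directory holds ``pre_box/``, ``track/``, ``post_box/``
sub-directories. Everything is plain TSV/JSON so fixtures stay diffable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd

from .core import LfpTrace, PositionSeries, SessionRecording

logger = logging.getLogger(__name__)

SESSION_NAMES = ("pre_box", "track", "post_box")


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # tokenizer errors carry the line number
        raise ValueError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1 header row
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line {line}")
        if coerced.isna().any():
            line = int(np.flatnonzero(coerced.isna().to_numpy())[0]) + 2
            raise ValueError(f"{path}: empty value in column {col!r} "
                             f"at line {line}")
        df[col] = coerced
    return df


def write_session(session: SessionRecording, path: str | Path) -> Path:
    """Write one session to a directory of TSV/JSON files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "condition": session.condition,
        "geometry": session.geometry,
        "cell_ids": [int(c) for c in session.cell_ids],
        "lfp_fs_hz": session.lfp.fs if session.lfp is not None else None,
        "lfp_t0_s": session.lfp.t0 if session.lfp is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))

    cids = np.concatenate([
        np.full(t.size, cid, dtype=int)
        for cid, t in session.spikes.items()]) if session.spikes else []
    times = np.concatenate(list(session.spikes.values())) \
        if session.spikes else []
    pd.DataFrame({"cell_id": cids, "t_s": times}).sort_values(
        ["t_s", "cell_id"]).to_csv(path / "spikes.tsv", sep="\t",
                                   index=False, float_format="%.6f")

    def write_pos(pos: PositionSeries, name: str):
        pd.DataFrame({"t_s": pos.t, "x_cm": pos.x, "y_cm": pos.y,
                      "hd_deg": pos.hd_deg}).to_csv(
            path / name, sep="\t", index=False, float_format="%.4f")

    write_pos(session.position, "position.tsv")
    if session.demo_position is not None:
        write_pos(session.demo_position, "demo_position.tsv")
    if session.lfp is not None:
        np.savetxt(path / "lfp.tsv", session.lfp.data, fmt="%.5f")
    if session.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, indent=1))
    return path


def read_session(path: str | Path) -> SessionRecording:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())

    sp = _read_tsv(path / "spikes.tsv", ["cell_id", "t_s"])
    spikes = {int(c): np.sort(g["t_s"].to_numpy())
              for c, g in sp.groupby("cell_id")}
    for cid in meta.get("cell_ids", []):
        spikes.setdefault(int(cid), np.empty(0))

    def read_pos(name: str) -> PositionSeries:
        df = _read_tsv(path / name, ["t_s", "x_cm", "y_cm", "hd_deg"])
        return PositionSeries(t=df["t_s"].to_numpy(),
                              x=df["x_cm"].to_numpy(),
                              y=df["y_cm"].to_numpy(),
                              hd_deg=df["hd_deg"].to_numpy())

    position = read_pos("position.tsv")
    demo = read_pos("demo_position.tsv") \
        if (path / "demo_position.tsv").exists() else None
    lfp = None
    if (path / "lfp.tsv").exists():
        data = np.loadtxt(path / "lfp.tsv")
        lfp = LfpTrace(data=data, fs=float(meta["lfp_fs_hz"]),
                       t0=float(meta.get("lfp_t0_s") or 0.0))
    gt = json.loads((path / "ground_truth.json").read_text()) \
        if (path / "ground_truth.json").exists() else None
    return SessionRecording(
        session_id=meta["session_id"], condition=meta["condition"],
        spikes=spikes, position=position, lfp=lfp, demo_position=demo,
        geometry=meta.get("geometry", {}), ground_truth=gt)


def write_day(day: dict, path: str | Path) -> Path:
    """Write a {pre_box, track, post_box} day produced by ``simulate_day``."""
    path = Path(path)
    for name in SESSION_NAMES:
        if name in day and day[name] is not None:
            write_session(day[name], path / name)
    return path


def read_day(path: str | Path) -> dict[str, SessionRecording]:
    path = Path(path)
    day = {}
    for name in SESSION_NAMES:
        if (path / name / "meta.json").exists():
            day[name] = read_session(path / name)
    if not day:
        raise FileNotFoundError(f"no session sub-directories under {path}")
    return day


def events_to_frame(events, label: str = "") -> pd.DataFrame:
    """Flatten detected events of any type into a TSV-ready table."""
    rows = []
    for ev in events:
        if hasattr(ev, "start_s"):
            row = {"type": type(ev).__name__, "start_s": ev.start_s,
                   "end_s": ev.end_s, "label": label}
            for attr in ("direction", "trajectory", "span_deg", "peak_s",
                         "peak_z"):
                if hasattr(ev, attr):
                    row[attr] = getattr(ev, attr)
        else:
            s, e = ev
            row = {"type": "Interval", "start_s": float(s),
                   "end_s": float(e), "label": label}
        rows.append(row)
    return pd.DataFrame(rows)
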