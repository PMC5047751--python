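"""Core containers for spike, position, and LFP data and detected events.

Conventions used throughout the package: times are seconds since session
start; intervals are half-open ``[start_s, end_s)``; positions are cm; head
direction (HD) is degrees in ``[-180, 180)`` relative to the opening side of
the box (0 deg = facing the opening); positive rotation is counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Controlled vocabulary for box-session conditions.
CONDITIONS = (
    "Trained-demo",
    "Naive-demo",
    "Empty-track",
    "No-track",
    "Toy-car",
    "Blocked-view",
    "Rest",
    "Track",
)

TRAJECTORIES = ("A_to_B", "B_to_A")


def wrap_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles in degrees into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class SpikeTrain:
    """One cell's spike times (s) within a session, with a stable cell id."""

    cell_id: int
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if t.size and np.any(np.diff(t) < 0):
            t = np.sort(t)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class PositionSeries:
    """Head-position tracking samples: time (s), x/y (cm), HD (deg).

    Samples are assumed (approximately) uniformly spaced at ``fs`` Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hd_deg: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.hd_deg = np.asarray(self.hd_deg, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == self.hd_deg.size == n):
            raise ValueError("position arrays must have equal length")
        if n >= 2 and np.any(np.diff(self.t) <= 0):
            raise ValueError("position timestamps must be strictly increasing")

    @property
    def fs(self) -> float:
        if self.t.size < 2:
            return float("nan")
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def hd_unwrapped(self) -> np.ndarray:
        """HD in degrees, unwrapped over time (continuous across +/-180)."""
        return np.degrees(np.unwrap(np.radians(self.hd_deg)))

    def x_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.x)

    def y_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.t, self.y)

    def hd_at(self, times: np.ndarray) -> np.ndarray:
        # interpolate on the unwrapped trace so the wrap point is not crossed
        return wrap_deg(np.interp(times, self.t, self.hd_unwrapped()))

    def speed(self, smooth_s: float = 0.5) -> np.ndarray:
        """Translational speed (cm/s): central difference, boxcar-smoothed."""
        if self.t.size < 3:
            return np.zeros_like(self.t)
        vx = np.gradient(self.x, self.t)
        vy = np.gradient(self.y, self.t)
        sp = np.hypot(vx, vy)
        w = max(1, int(round(smooth_s * self.fs)))
        if w > 1:
            kernel = np.ones(w) / w
            sp = np.convolve(sp, kernel, mode="same")
        return sp


@dataclass
class LfpTrace:
    """One LFP channel sampled at ``fs`` Hz starting at ``t0`` seconds."""

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.size) / self.fs

    @property
    def duration(self) -> float:
        return self.data.size / self.fs


@dataclass(frozen=True)
class RotationEvent:
    start_s: float
    end_s: float
    direction: str  # "CW" or "CCW"
    span_deg: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.direction not in ("CW", "CCW"):
            raise ValueError("direction must be 'CW' or 'CCW'")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class LapEvent:
    trajectory: str  # "A_to_B" or "B_to_A"
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("end_s must exceed start_s")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"trajectory must be one of {TRAJECTORIES}")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class RippleEvent:
    start_s: float
    end_s: float
    peak_s: float
    peak_z: float

    def __post_init__(self):
        if not (self.start_s <= self.peak_s <= self.end_s):
            raise ValueError("peak_s must lie within [start_s, end_s]")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SessionRecording:
    """One recorded session: spike trains, tracking, and optional LFP.

    ``spikes`` maps cell id -> sorted spike-time array (s). ``ground_truth``
    carries the simulator sidecar (labels, event intervals, injected replays)
    when the session is synthetic.
    """

    session_id: str
    condition: str
    spikes: dict[int, np.ndarray]
    position: PositionSeries
    lfp: Optional[LfpTrace] = None
    demo_position: Optional[PositionSeries] = None
    geometry: dict = field(default_factory=lambda: {
        "box_size_cm": 25.0,
        "track_length_cm": 200.0,
        "opening_center_deg": 0.0,
    })
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}")
        self.spikes = {
            int(cid): np.sort(np.asarray(t, dtype=float))
            for cid, t in self.spikes.items()
        }

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def duration(self) -> float:
        return self.position.duration


# ---------------------------------------------------------------------------
# Interval arithmetic: intervals are (n, 2) float arrays of half-open
# [start, end) pairs, sorted and non-overlapping unless stated otherwise.
# ---------------------------------------------------------------------------

def as_intervals(obj) -> np.ndarray:
    """Coerce events / pairs / arrays into an (n, 2) interval array."""
    if obj is None:
        return np.empty((0, 2))
    rows = []
    for item in obj:
        if hasattr(item, "start_s"):
            rows.append((item.start_s, item.end_s))
        elif isinstance(item, dict):
            rows.append((float(item["start_s"]), float(item["end_s"])))
        else:
            s, e = item
            rows.append((float(s), float(e)))
    iv = np.asarray(rows, dtype=float).reshape(-1, 2)
    if iv.size:
        iv = iv[np.argsort(iv[:, 0])]
    return iv


def intervals_total(intervals) -> float:
    iv = as_intervals(intervals)
    return float(np.sum(iv[:, 1] - iv[:, 0])) if iv.size else 0.0


def in_intervals(times: np.ndarray, intervals) -> np.ndarray:
    """Boolean mask: which times fall inside any half-open interval."""
    iv = as_intervals(intervals)
    times = np.asarray(times, dtype=float)
    if not iv.size:
        return np.zeros(times.shape, dtype=bool)
    edges = iv.ravel()
    idx = np.searchsorted(edges, times, side="right")
    return idx % 2 == 1


def intervals_subtract(intervals, holes) -> np.ndarray:
    """Set difference of interval unions (e.g. lap events minus stops)."""
    iv = as_intervals(intervals)
    hv = as_intervals(holes)
    if not iv.size or not hv.size:
        return iv
    out = []
    for s, e in iv:
        pieces = [(s, e)]
        for hs, he in hv:
            nxt = []
            for ps, pe in pieces:
                if he <= ps or hs >= pe:
                    nxt.append((ps, pe))
                    continue
                if hs > ps:
                    nxt.append((ps, hs))
                if he < pe:
                    nxt.append((he, pe))
            pieces = nxt
        out.extend(p for p in pieces if p[1] > p[0])
    return np.asarray(out, dtype=float).reshape(-1, 2)


def intervals_intersect(a, b) -> np.ndarray:
    """Intersection of two interval unions."""
    av, bv = as_intervals(a), as_intervals(b)
    out = []
    for s, e in av:
        for bs, be in bv:
            lo, hi = max(s, bs), min(e, be)
            if hi > lo:
                out.append((lo, hi))
    return as_intervals(out)
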