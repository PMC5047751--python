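"""Segmentation of sessions into rotation, lap, stop, and ripple events.

Rotation events are head turns of at least 180 deg that start and end with
the head inside the +/-45 deg opening zone of the box; lap events are full
end-to-end track traversals; stop periods are >3 s of immobility; ripple
events are 100-250 Hz LFP transients crossing a 4 SD peak threshold with
2.5 SD boundaries. ``lfp_spectra`` and ``behavior_summary`` provide the
spectral and behavioural descriptive statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .core import (
    LapEvent,
    LfpTrace,
    PositionSeries,
    RippleEvent,
    RotationEvent,
    as_intervals,
    in_intervals,
    wrap_deg,
)

logger = logging.getLogger(__name__)

__all__ = [
    "detect_rotation_events",
    "detect_lap_events",
    "detect_stop_periods",
    "detect_ripple_events",
    "lfp_spectra",
    "behavior_summary",
    "BehaviorMetrics",
    "SpectraResult",
]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop index pairs (half-open) of True runs in a boolean mask."""
    if not mask.size:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_rotation_events(
    position: PositionSeries,
    opening_center_deg: float = 0.0,
    *,
    zone_half_width_deg: float = 45.0,
    min_span_deg: float = 180.0,
    min_zone_duration_s: float = 0.15,
    exclude=None,
) -> list[RotationEvent]:
    """Detect full-body rotation events from the head-direction trace.

    An event runs from the last opening-zone sample before the head leaves
    the +/-45 deg zone to the first zone sample after it returns, provided
    the maximum unwrapped excursion in between reaches ``min_span_deg``.
    Direction is CCW for positive (counter-clockwise) net excursion, CW for
    negative. Brief zone grazings shorter than ``min_zone_duration_s`` are
    ignored, which tolerates tracking jitter near the zone edge. Events
    overlapping any ``exclude`` interval (e.g. grooming/rearing flagged by
    the experimenter) are dropped.
    """
    if position.t.size < 3:
        warnings.warn("degenerate position series; no rotation events")
        return []
    hd_rel = wrap_deg(position.hd_deg - opening_center_deg)
    unwrapped = np.degrees(np.unwrap(np.radians(hd_rel)))
    in_zone = np.abs(hd_rel) <= zone_half_width_deg

    min_len = max(1, int(round(min_zone_duration_s * position.fs)))
    visits = [(a, b) for a, b in _runs(in_zone) if b - a >= min_len]
    if len(visits) < 2:
        return []

    events = []
    for (a0, b0), (a1, b1) in zip(visits[:-1], visits[1:]):
        i0, i1 = b0 - 1, a1  # last in-zone sample before, first after
        # span covers the whole turn including its in-zone start/end legs
        # (dwelling in the zone adds nothing unless the head moves)
        win = unwrapped[a0: b1]
        if win.size < 2:
            continue
        span = float(win.max() - win.min())
        if span < min_span_deg:
            continue
        exc = unwrapped[a0: b1] - unwrapped[i0]
        excursion = exc[int(np.argmax(np.abs(exc)))]
        events.append(RotationEvent(
            start_s=float(position.t[i0]),
            end_s=float(position.t[i1]),
            direction="CCW" if excursion > 0 else "CW",
            span_deg=span,
        ))

    if exclude is not None:
        iv = as_intervals(exclude)
        events = [
            ev for ev in events
            if not np.any((iv[:, 0] < ev.end_s) & (iv[:, 1] > ev.start_s))
        ] if iv.size else events
    logger.info("detected %d rotation events (zone +/-%g deg, span >= %g)",
                len(events), zone_half_width_deg, min_span_deg)
    return events


def detect_lap_events(
    position: PositionSeries,
    track_length_cm: float = 200.0,
    end_zone_cm: float = 10.0,
) -> list[LapEvent]:
    """Detect full end-to-end traversals of the linear track.

    A lap runs from the last sample inside the departure end zone to the
    first sample inside the arrival end zone; excursions that turn back
    mid-track produce no lap.
    """
    x = position.x
    zone = np.full(x.size, -1, dtype=np.int8)
    zone[x <= end_zone_cm] = 0  # end A
    zone[x >= track_length_cm - end_zone_cm] = 1  # end B

    laps = []
    prev_end = None  # (which_end, last_index_in_zone)
    for a, b in _runs(zone >= 0):
        which = int(zone[a])
        if prev_end is not None and prev_end[0] != which:
            laps.append(LapEvent(
                trajectory="A_to_B" if which == 1 else "B_to_A",
                start_s=float(position.t[prev_end[1]]),
                end_s=float(position.t[a]),
            ))
        prev_end = (which, b - 1)
    logger.info("detected %d lap events", len(laps))
    return laps


def detect_stop_periods(
    position: PositionSeries,
    speed_thresh_cm_s: float = 2.0,
    min_dur_s: float = 3.0,
) -> np.ndarray:
    """Maximal intervals of immobility (speed < threshold, > min_dur_s).

    Returns an (n, 2) array of [start, end) intervals in seconds. The paper
    protocol defines stops only by ">3 s of immobility"; the 2 cm/s cutoff
    is the conventional rodent immobility threshold.
    """
    sp = position.speed()
    out = []
    for a, b in _runs(sp < speed_thresh_cm_s):
        s, e = float(position.t[a]), float(position.t[min(b, sp.size - 1)])
        if b == sp.size:
            e = float(position.t[-1]) + 1.0 / position.fs
        if e - s > min_dur_s:
            out.append((s, e))
    return as_intervals(out)


def detect_ripple_events(
    lfp: LfpTrace,
    peak_thresh_sd: float = 4.0,
    edge_thresh_sd: float = 2.5,
    band_hz: tuple[float, float] = (100.0, 250.0),
    envelope_smooth_s: float = 0.004,
    merge_gap_s: float = 0.030,
    min_dur_s: float = 0.050,
    max_dur_s: float = 0.400,
) -> list[RippleEvent]:
    """Detect sharp-wave-ripple events in one LFP channel.

    The trace is band-passed 100-250 Hz (4th-order Butterworth, zero
    phase) and the envelope is the rectified signal smoothed with a 4 ms
    Gaussian. Thresholds are expressed in standard deviations of the
    band-passed (filtered) signal over the whole session. Events are
    above-``edge_thresh_sd`` regions containing a >= ``peak_thresh_sd``
    peak; regions closer than ``merge_gap_s`` are merged and events outside
    the 50-400 ms ripple duration range are discarded.
    """
    if lfp.fs < 600:
        raise ValueError("LFP sampling rate must be >= 600 Hz for the "
                         "100-250 Hz ripple band")
    warmup = int(0.5 * lfp.fs)
    if lfp.data.size < warmup:
        raise ValueError("session shorter than the ripple filter warm-up")
    sos = sp_signal.butter(4, list(band_hz), btype="bandpass", fs=lfp.fs,
                           output="sos")
    band = sp_signal.sosfiltfilt(sos, lfp.data)
    env = gaussian_filter1d(np.abs(band), envelope_smooth_s * lfp.fs)
    z = env / band.std()

    regions = _runs(z >= edge_thresh_sd)
    # merge regions separated by less than the merge gap
    merged = []
    gap = merge_gap_s * lfp.fs
    for a, b in regions:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events = []
    for a, b in merged:
        seg = z[a:b]
        pk = int(np.argmax(seg))
        if seg[pk] < peak_thresh_sd:
            continue
        dur = (b - a) / lfp.fs
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        events.append(RippleEvent(
            start_s=lfp.t0 + a / lfp.fs,
            end_s=lfp.t0 + b / lfp.fs,
            peak_s=lfp.t0 + (a + pk) / lfp.fs,
            peak_z=float(seg[pk]),
        ))
    logger.info("detected %d ripple events (peak >= %g SD, edges %g SD)",
                len(events), peak_thresh_sd, edge_thresh_sd)
    return events


@dataclass
class SpectraResult:
    """PSD averaged over intervals plus a 0.5 Hz x 25 ms spectrogram."""

    freqs: np.ndarray  # Hz, 0.5 Hz spacing
    psd: np.ndarray  # average power per frequency within the intervals
    psd_norm: np.ndarray  # psd / total power in the 0.5-400 Hz band
    spec_times: np.ndarray
    spectrogram: np.ndarray  # (freq, time)

    def band_power(self, lo: float, hi: float, normalized: bool = False):
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return float((self.psd_norm if normalized else self.psd)[m].sum())


def lfp_spectra(
    lfp: LfpTrace,
    intervals,
    *,
    freq_res_hz: float = 0.5,
    step_s: float = 0.025,
    window_s: float = 1.0,
    norm_band_hz: tuple[float, float] = (0.5, 400.0),
) -> SpectraResult:
    """Spectrogram and interval-averaged PSD of one LFP channel.

    Power is computed every ``freq_res_hz`` and every ``step_s`` with a
    ``window_s`` window; the PSD averages spectrogram columns whose centre
    falls inside the supplied intervals, and the normalized variant divides
    by the total power within 0.5-400 Hz (so it sums to 1 over that band).
    """
    iv = as_intervals(intervals)
    if iv.size and np.any(iv[:, 1] - iv[:, 0] < window_s):
        raise ValueError("all intervals must be at least one window long")
    nperseg = int(round(window_s * lfp.fs))
    nfft = max(nperseg, int(round(lfp.fs / freq_res_hz)))
    step = max(1, int(round(step_s * lfp.fs)))
    f, t, spec = sp_signal.spectrogram(
        lfp.data, fs=lfp.fs, nperseg=nperseg, noverlap=nperseg - step,
        nfft=nfft, scaling="density", mode="psd")
    t = t + lfp.t0
    if iv.size:
        cols = in_intervals(t, iv)
        if not cols.any():
            raise ValueError("no spectrogram columns inside the intervals")
    else:
        cols = np.ones(t.size, dtype=bool)
    psd = spec[:, cols].mean(axis=1)
    m = (f >= norm_band_hz[0]) & (f <= norm_band_hz[1])
    total = psd[m].sum()
    psd_norm = psd / total if total > 0 else np.zeros_like(psd)
    return SpectraResult(freqs=f, psd=psd, psd_norm=psd_norm,
                         spec_times=t, spectrogram=spec)


@dataclass
class BehaviorMetrics:
    pct_time_facing_opening: float
    n_rotation_events: int
    mean_rotation_duration_s: float
    mean_speed_cm_s: float
    n_laps_per_trajectory: dict[str, int]

    def __post_init__(self):
        if not 0.0 <= self.pct_time_facing_opening <= 100.0:
            raise ValueError("percentage out of [0, 100]")


def behavior_summary(
    position: PositionSeries,
    rotation_events: Sequence[RotationEvent] = (),
    lap_events: Sequence[LapEvent] = (),
    opening_center_deg: float = 0.0,
    zone_half_width_deg: float = 45.0,
) -> BehaviorMetrics:
    """Descriptive behavioural summary of one session."""
    hd_rel = wrap_deg(position.hd_deg - opening_center_deg)
    facing = float(np.mean(np.abs(hd_rel) <= zone_half_width_deg)) * 100.0
    durs = [ev.duration for ev in rotation_events]
    n_laps = {trj: 0 for trj in ("A_to_B", "B_to_A")}
    for lap in lap_events:
        n_laps[lap.trajectory] += 1
    return BehaviorMetrics(
        pct_time_facing_opening=facing,
        n_rotation_events=len(rotation_events),
        mean_rotation_duration_s=float(np.mean(durs)) if durs else float("nan"),
        mean_speed_cm_s=float(np.mean(position.speed())),
        n_laps_per_trajectory=n_laps,
    )
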