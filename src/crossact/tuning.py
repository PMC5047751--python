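"""Firing-rate curves/maps and per-cell tuning statistics.

Binning and smoothing follow the recording protocol: 2 cm spatial bins on
the track with the 10 cm reward zones excluded, 72 five-degree arches for
circular head-direction curves, 1 x 1 cm bins in the box, all smoothed with
a Gaussian kernel of sigma = 2 bins (wrapping circularly for angular
curves, renormalizing at the edges for linear ones). Rates are
smoothed-count / smoothed-occupancy, with raw counts retained so spike
count is conserved before smoothing.

Shuffle-based statistics (rotation-consistency, demonstrator-position
tuning) z-score the observed statistic against curve-rotation or
within-lap circular spike-shift nulls and call z > 1.645 significant
(one-sided p < 0.05 under a normal null).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter

from .core import (
    LapEvent,
    PositionSeries,
    RotationEvent,
    as_intervals,
    in_intervals,
    intervals_subtract,
)

logger = logging.getLogger(__name__)

Z_CRIT = 1.645  # one-sided 5% normal criterion used throughout

__all__ = [
    "RateCurve",
    "CircularRateCurve",
    "RateMap2D",
    "ConsistencyResult",
    "DemoTuningResult",
    "linear_rate_curve",
    "circular_rate_curve",
    "rate_map_2d",
    "rayleigh_hd_test",
    "rotation_consistency",
    "spatial_information",
    "lap_consistency",
    "demo_position_tuning",
    "fisher_lee_correlation",
]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma: float, truncate: float = 3.0) -> np.ndarray:
    radius = max(1, int(math.ceil(truncate * sigma)))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth1d(arr: np.ndarray, sigma_bins: float, circular: bool = False,
             axis: int = -1) -> np.ndarray:
    """Gaussian smoothing (kernel truncated at +/-3 sigma).

    Circular smoothing wraps; linear smoothing renormalizes at the edges so
    a constant input stays constant.
    """
    arr = np.asarray(arr, dtype=float)
    if sigma_bins <= 0:
        return arr.copy()
    k = _gaussian_kernel(sigma_bins)
    if circular:
        return convolve1d(arr, k, axis=axis, mode="wrap")
    sm = convolve1d(arr, k, axis=axis, mode="constant", cval=0.0)
    norm = convolve1d(np.ones(arr.shape[axis]), k, mode="constant", cval=0.0)
    shape = [1] * arr.ndim
    shape[axis] = -1
    return sm / norm.reshape(shape)


# ---------------------------------------------------------------------------
# curve containers
# ---------------------------------------------------------------------------

@dataclass
class RateCurve:
    """Linear-track rate curve on 2 cm bins (reward zones excluded)."""

    bin_centers: np.ndarray  # cm
    rates: np.ndarray  # Hz
    occupancy_s: np.ndarray
    counts: np.ndarray  # raw per-bin spike counts (pre-smoothing)

    @property
    def peak_location_cm(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.rates))])

    @property
    def peak_rate_hz(self) -> float:
        return float(np.max(self.rates))


@dataclass
class CircularRateCurve:
    """Head-direction rate curve on 72 five-degree arches tiling [0, 360)."""

    bin_centers: np.ndarray  # deg
    rates: np.ndarray
    occupancy_s: np.ndarray
    counts: np.ndarray

    @property
    def peak_angle_deg(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.rates))])


@dataclass
class RateMap2D:
    """Firing-rate map on a 1 x 1 cm grid; NaN where occupancy is too low."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    rates: np.ndarray  # (ny, nx), NaN where undefined
    occupancy_s: np.ndarray
    counts: np.ndarray


# ---------------------------------------------------------------------------
# rate estimation
# ---------------------------------------------------------------------------

def _occupancy_hist(position: PositionSeries, intervals, edges,
                    values: np.ndarray) -> np.ndarray:
    mask = in_intervals(position.t, intervals)
    dt = 1.0 / position.fs
    occ, _ = np.histogram(values[mask], bins=edges)
    return occ * dt


def linear_rate_curve(
    spike_times: np.ndarray,
    position: PositionSeries,
    laps: Sequence[LapEvent],
    stops=None,
    *,
    bin_cm: float = 2.0,
    sigma_bins: float = 2.0,
    track_length_cm: float = 200.0,
    reward_zone_cm: float = 10.0,
) -> RateCurve:
    """Trajectory rate curve over the supplied laps, stops excluded."""
    laps = list(laps)
    if not laps:
        raise ValueError("at least one lap event required")
    trajs = {l.trajectory for l in laps}
    if len(trajs) > 1:
        raise ValueError("laps must all lie on one trajectory")
    intervals = intervals_subtract(laps, stops)
    lo, hi = reward_zone_cm, track_length_cm - reward_zone_cm
    edges = np.arange(lo, hi + bin_cm / 2, bin_cm)
    centers = 0.5 * (edges[:-1] + edges[1:])

    occ = _occupancy_hist(position, intervals, edges, position.x)
    if occ.sum() <= 0:
        raise ValueError("zero occupancy over all bins")
    st = np.asarray(spike_times, dtype=float)
    st = st[in_intervals(st, intervals)]
    counts, _ = np.histogram(position.x_at(st), bins=edges)

    sm_occ = smooth1d(occ, sigma_bins)
    sm_cnt = smooth1d(counts.astype(float), sigma_bins)
    rates = np.divide(sm_cnt, sm_occ, out=np.zeros_like(sm_cnt),
                      where=sm_occ > 0)
    return RateCurve(bin_centers=centers, rates=rates, occupancy_s=occ,
                     counts=counts)


def _bin_circular(spike_times, position, events, stops, bin_deg):
    intervals = intervals_subtract(as_intervals(events), stops)
    edges = np.arange(0.0, 360.0 + bin_deg / 2, bin_deg)
    hd = np.mod(position.hd_deg, 360.0)
    occ = _occupancy_hist(position, intervals, edges, hd)
    st = np.asarray(spike_times, dtype=float)
    st = st[in_intervals(st, intervals)]
    spike_hd = np.mod(position.hd_at(st), 360.0)
    counts, _ = np.histogram(spike_hd, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts, occ


def circular_rate_curve(
    spike_times: np.ndarray,
    position: PositionSeries,
    events: Sequence[RotationEvent],
    stops=None,
    *,
    bin_deg: float = 5.0,
    sigma_bins: float = 2.0,
) -> CircularRateCurve:
    """Head-direction rate curve over rotation events (wraps circularly)."""
    if not list(events):
        raise ValueError("at least one rotation event required")
    centers, counts, occ = _bin_circular(spike_times, position, events,
                                         stops, bin_deg)
    sm_occ = smooth1d(occ, sigma_bins, circular=True)
    sm_cnt = smooth1d(counts.astype(float), sigma_bins, circular=True)
    rates = np.divide(sm_cnt, sm_occ, out=np.zeros_like(sm_cnt),
                      where=sm_occ > 0)
    return CircularRateCurve(bin_centers=centers, rates=rates,
                             occupancy_s=occ, counts=counts)


def rate_map_2d(
    spike_times: np.ndarray,
    position: PositionSeries,
    events,
    *,
    bin_cm: float = 1.0,
    box_size_cm: float = 25.0,
    sigma_bins: float = 2.0,
    min_occupancy_s: float = 0.1,
) -> RateMap2D:
    """2-D head-position rate map in the box on a 1 cm grid."""
    intervals = as_intervals(events)
    edges = np.arange(0.0, box_size_cm + bin_cm / 2, bin_cm)
    mask = in_intervals(position.t, intervals)
    dt = 1.0 / position.fs
    occ, _, _ = np.histogram2d(position.y[mask], position.x[mask],
                               bins=[edges, edges])
    occ = occ * dt
    st = np.asarray(spike_times, dtype=float)
    st = st[in_intervals(st, intervals)]
    counts, _, _ = np.histogram2d(position.y_at(st), position.x_at(st),
                                  bins=[edges, edges])
    sm_occ = gaussian_filter(occ, sigma_bins, truncate=3.0, mode="constant")
    sm_cnt = gaussian_filter(counts, sigma_bins, truncate=3.0,
                             mode="constant")
    rates = np.divide(sm_cnt, sm_occ, out=np.zeros_like(sm_cnt),
                      where=sm_occ > 0)
    rates[occ < min_occupancy_s] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RateMap2D(x_centers=centers, y_centers=centers, rates=rates,
                     occupancy_s=occ, counts=counts)


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def rayleigh_hd_test(
    spike_times: np.ndarray,
    position: PositionSeries,
    events,
    min_spikes: int = 10,
) -> float:
    """Rayleigh test p-value for head-direction tuning of spikes in events.

    Returns NaN (with a warning) when the cell fires fewer than
    ``min_spikes`` spikes within the events.
    """
    st = np.asarray(spike_times, dtype=float)
    st = st[in_intervals(st, as_intervals(events))]
    if st.size < min_spikes:
        warnings.warn(
            f"only {st.size} spikes in events (< {min_spikes}); "
            "Rayleigh test undefined")
        return float("nan")
    import pingouin  # established circular-statistics implementation

    alpha = np.radians(position.hd_at(st))
    _, pval = pingouin.circ_rayleigh(alpha)
    return float(pval)


def fisher_lee_correlation(alpha_deg: np.ndarray,
                           beta_deg: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation for paired angle samples."""
    a = np.radians(np.asarray(alpha_deg, dtype=float))
    b = np.radians(np.asarray(beta_deg, dtype=float))
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired angles")
    i, j = np.triu_indices(a.size, k=1)
    num = np.sum(np.sin(a[i] - a[j]) * np.sin(b[i] - b[j]))
    den = math.sqrt(np.sum(np.sin(a[i] - a[j]) ** 2) *
                    np.sum(np.sin(b[i] - b[j]) ** 2))
    return float(num / den) if den > 0 else float("nan")


@dataclass
class ConsistencyResult:
    """z-scored mean cross-event correlation against a rotation null."""

    statistic: float
    shuffle_mean: float
    shuffle_sd: float
    z: float
    significant: bool
    n_events: int
    reason: Optional[str] = None


def _event_curves(spike_times, position, events, bin_deg, sigma_bins):
    """(E, n_bins) smoothed per-event circular rate curves."""
    curves = []
    for ev in events:
        _, counts, occ = _bin_circular(spike_times, position, [ev], None,
                                       bin_deg)
        sm_occ = smooth1d(occ, sigma_bins, circular=True)
        sm_cnt = smooth1d(counts.astype(float), sigma_bins, circular=True)
        curves.append(np.divide(sm_cnt, sm_occ,
                                out=np.zeros_like(sm_cnt), where=sm_occ > 0))
    return np.asarray(curves)


def rotation_consistency(
    spike_times: np.ndarray,
    position: PositionSeries,
    events: Sequence[RotationEvent],
    *,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
    bin_deg: float = 5.0,
    sigma_bins: float = 2.0,
) -> ConsistencyResult:
    """Rotation-consistency: z-scored mean pairwise curve correlation.

    The statistic is the mean, over all unordered pairs of rotation events
    in which the cell fired, of the Pearson correlation between the two
    events' circular rate curves across matched 5-degree bins. The null
    rotates every event's curve independently by a random whole-bin angle
    (the circular geometry lives in the shuffle); z uses the sample SD of
    ``n_shuffles`` such shuffle sets.
    """
    rng = rng or np.random.default_rng()
    events = list(events)
    st = np.asarray(spike_times, dtype=float)
    active = [ev for ev in events
              if np.any((st >= ev.start_s) & (st < ev.end_s))]
    if len(active) < 2:
        return ConsistencyResult(
            statistic=float("nan"), shuffle_mean=float("nan"),
            shuffle_sd=float("nan"), z=float("nan"), significant=False,
            n_events=len(active), reason="cell active in < 2 events")

    curves = _event_curves(st, position, active, bin_deg, sigma_bins)
    sd = curves.std(axis=1)
    curves = curves[sd > 0]
    e, b = curves.shape
    if e < 2:
        return ConsistencyResult(
            statistic=float("nan"), shuffle_mean=float("nan"),
            shuffle_sd=float("nan"), z=float("nan"), significant=False,
            n_events=e, reason="fewer than 2 non-degenerate event curves")

    z_rows = curves - curves.mean(axis=1, keepdims=True)
    z_rows /= np.linalg.norm(z_rows, axis=1, keepdims=True)

    def mean_pairwise(rows):  # rows (..., e, b), unit-norm
        s = rows.sum(axis=-2)
        tot = np.sum(s * s, axis=-1)
        return (tot - e) / (e * (e - 1))

    actual = float(mean_pairwise(z_rows))
    shifts = rng.integers(0, b, size=(n_shuffles, e))
    idx = (np.arange(b)[None, None, :] + shifts[:, :, None]) % b
    shuffled = z_rows[np.arange(e)[None, :, None], idx]
    null = mean_pairwise(shuffled)
    mu, sig = float(null.mean()), float(null.std(ddof=1))
    zval = (actual - mu) / sig if sig > 0 else float("nan")
    return ConsistencyResult(
        statistic=actual, shuffle_mean=mu, shuffle_sd=sig, z=zval,
        significant=bool(zval > Z_CRIT), n_events=e)


# ---------------------------------------------------------------------------
# spatial information and lap consistency
# ---------------------------------------------------------------------------

def spatial_information(
    rates: np.ndarray | RateCurve,
    occupancy_s: Optional[np.ndarray] = None,
    min_occupancy_s: float = 0.1,
) -> float:
    """Skaggs spatial information in bits per spike.

    SI = sum_i p_i (r_i / rbar) log2(r_i / rbar) over occupied bins, with
    p_i the occupancy fraction and rbar the occupancy-weighted mean rate.
    Bins below ``min_occupancy_s`` are excluded.
    """
    if isinstance(rates, RateCurve):
        occupancy_s = rates.occupancy_s
        rates = rates.rates
    r = np.asarray(rates, dtype=float)
    occ = np.asarray(occupancy_s, dtype=float)
    m = occ >= max(min_occupancy_s, np.finfo(float).tiny)
    if not m.any():
        return float("nan")
    r, occ = r[m], occ[m]
    p = occ / occ.sum()
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        return float("nan")
    pos = r > 0
    ratio = r[pos] / rbar
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


def lap_consistency(
    per_lap_curves: Sequence[np.ndarray | RateCurve],
    min_active_laps: int = 2,
) -> float:
    """Mean pairwise Pearson correlation between per-lap rate curves.

    Only laps in which the cell fired (non-zero curve with non-zero
    variance) enter the pairing; NaN if fewer than ``min_active_laps``.
    """
    rows = []
    for c in per_lap_curves:
        r = c.rates if isinstance(c, RateCurve) else np.asarray(c, float)
        if np.any(r != 0) and r.std() > 0:
            rows.append(r)
    if len(rows) < min_active_laps:
        return float("nan")
    rows = np.asarray(rows)
    z = rows - rows.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    e = z.shape[0]
    s = z.sum(axis=0)
    return float((np.dot(s, s) - e) / (e * (e - 1)))


# ---------------------------------------------------------------------------
# demonstrator-position tuning (within-lap circular-shift null)
# ---------------------------------------------------------------------------

@dataclass
class DemoTuningResult:
    """Observer-cell tuning to the demonstrator's track position."""

    spatial_information: float
    lap_consistency: float
    z_spatial_information: float
    z_lap_consistency: float
    n_spikes: int
    null_spatial_information: Optional[np.ndarray] = None
    null_lap_consistency: Optional[np.ndarray] = None

    @property
    def significant_spatial_information(self) -> bool:
        return bool(self.z_spatial_information >= Z_CRIT)

    @property
    def significant_lap_consistency(self) -> bool:
        return bool(self.z_lap_consistency >= Z_CRIT)


def demo_position_tuning(
    spike_times: np.ndarray,
    demo_position: PositionSeries,
    demo_laps: Sequence[LapEvent],
    *,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
    bin_cm: float = 2.0,
    sigma_bins: float = 2.0,
    track_length_cm: float = 200.0,
    reward_zone_cm: float = 10.0,
    min_occupancy_s: float = 0.1,
    compute_lap_consistency: bool = True,
    keep_nulls: bool = False,
) -> DemoTuningResult:
    """Observer spike tuning to demonstrator position, z-scored vs shuffles.

    Spatial information is computed from the observer cell's mean rate
    curve against the demonstrator's position over all laps of one
    trajectory; lap consistency from the per-lap curves. The null shifts
    the cell's spike train circularly within each lap by an independent
    uniform offset, ``n_shuffles`` times, and both statistics are z-scored
    against their shuffle distributions (sample SD). The whole shuffle
    ensemble is evaluated vectorised, so the 1000-shuffle default is cheap.
    """
    rng = rng or np.random.default_rng()
    laps = list(demo_laps)
    if not laps:
        raise ValueError("at least one demonstrator lap required")
    if len({l.trajectory for l in laps}) > 1:
        raise ValueError("demonstrator laps must all lie on one trajectory")
    starts = np.array([l.start_s for l in laps])
    ends = np.array([l.end_s for l in laps])
    durs = ends - starts
    n_laps = len(laps)

    lo, hi = reward_zone_cm, track_length_cm - reward_zone_cm
    edges = np.arange(lo, hi + bin_cm / 2, bin_cm)
    nb = edges.size - 1

    # occupancy (fixed across shuffles)
    dt = 1.0 / demo_position.fs
    occ_lap = np.zeros((n_laps, nb))
    for li, lap in enumerate(laps):
        m = (demo_position.t >= lap.start_s) & (demo_position.t < lap.end_s)
        h, _ = np.histogram(demo_position.x[m], bins=edges)
        occ_lap[li] = h * dt
    occ = occ_lap.sum(axis=0)
    if occ.sum() <= 0:
        raise ValueError("zero demonstrator occupancy")

    st = np.asarray(spike_times, dtype=float)
    lap_idx = np.full(st.size, -1, dtype=int)
    for li in range(n_laps):
        lap_idx[(st >= starts[li]) & (st < ends[li])] = li
    keep = lap_idx >= 0
    st, lap_idx = st[keep], lap_idx[keep]
    rel = st - starts[lap_idx]
    nsp = st.size

    nan = float("nan")
    if nsp == 0:
        return DemoTuningResult(nan, nan, nan, nan, 0)

    sm_occ = smooth1d(occ, sigma_bins)
    sm_occ_lap = smooth1d(occ_lap, sigma_bins, axis=1)
    occ_mask = occ >= min_occupancy_s
    p_occ = np.where(occ_mask, occ, 0.0)
    p_occ = p_occ / p_occ.sum()

    def stats_for_shifts(shifts: np.ndarray):
        """shifts: (S, n_laps) seconds -> (si, lap_cons) arrays of length S."""
        S = shifts.shape[0]
        t_sh = starts[lap_idx] + (rel[None, :] +
                                  shifts[:, lap_idx]) % durs[lap_idx]
        x = np.interp(t_sh.ravel(), demo_position.t,
                      demo_position.x).reshape(S, nsp)
        b = np.floor((x - lo) / bin_cm).astype(int)
        valid = (b >= 0) & (b < nb)
        flat = (np.arange(S)[:, None] * nb + b)[valid]
        counts = np.bincount(flat, minlength=S * nb).reshape(S, nb)
        rates = smooth1d(counts.astype(float), sigma_bins, axis=1) / sm_occ
        rbar = rates @ p_occ
        ratio = rates / np.where(rbar > 0, rbar, 1.0)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(ratio > 0, ratio * np.log2(ratio), 0.0)
        si = term @ p_occ
        si[rbar <= 0] = np.nan

        lap_cons = np.full(S, np.nan)
        if compute_lap_consistency:
            flat_l = (np.arange(S)[:, None] * (n_laps * nb) +
                      lap_idx[None, :] * nb + b)[valid]
            cl = np.bincount(flat_l, minlength=S * n_laps * nb).reshape(
                S, n_laps, nb)
            rl = smooth1d(cl.astype(float), sigma_bins, axis=2) / sm_occ_lap
            active = cl.sum(axis=2) > 0
            mu = rl.mean(axis=2, keepdims=True)
            zr = rl - mu
            norm = np.linalg.norm(zr, axis=2, keepdims=True)
            ok = active & (norm[:, :, 0] > 0)
            zr = np.where(ok[:, :, None], zr / np.where(norm > 0, norm, 1.0),
                          0.0)
            n_act = ok.sum(axis=1).astype(float)
            ssum = zr.sum(axis=1)
            pair_sum = (np.sum(ssum * ssum, axis=1) - n_act) / 2.0
            n_pairs = n_act * (n_act - 1) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                lap_cons = np.where(n_pairs > 0, pair_sum / n_pairs, np.nan)
        return si, lap_cons

    si_act, lc_act = stats_for_shifts(np.zeros((1, n_laps)))
    shifts = rng.uniform(0.0, durs[None, :], size=(n_shuffles, n_laps))
    si_null, lc_null = stats_for_shifts(shifts)

    def zscore(actual, null):
        null = null[np.isfinite(null)]
        if null.size < 2 or not np.isfinite(actual):
            return nan
        sd = null.std(ddof=1)
        return float((actual - null.mean()) / sd) if sd > 0 else nan

    return DemoTuningResult(
        spatial_information=float(si_act[0]),
        lap_consistency=float(lc_act[0]),
        z_spatial_information=zscore(si_act[0], si_null),
        z_lap_consistency=zscore(lc_act[0], lc_null)
        if compute_lap_consistency else nan,
        n_spikes=nsp,
        null_spatial_information=si_null if keep_nulls else None,
        null_lap_consistency=lc_null if keep_nulls else None,
    )
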