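"""Synthetic session generator for the box/track cross-activation analysis.

The generator emulates the statistical structure the analysis assumes, not
the biophysics: a 2-m linear track with directional 1-D Gaussian place
fields, a 25 x 25 cm box in which cells express von-Mises-shaped circular
tuning to head direction during body-rotation events, a configurable
overlap ("cross-activation") between the two populations whose circular
firing order in the box preserves the linear field order on the track,
inhomogeneous Poisson spiking, and a band-limited LFP surrogate (8 Hz theta
during movement, 150 Hz ripple bursts during immobility, pink background).

All randomness flows from ``SimConfig.seed`` through per-component
``numpy.random.Generator`` streams, so identical configs give identical
sessions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .core import (
    LfpTrace,
    PositionSeries,
    SessionRecording,
    TRAJECTORIES,
    wrap_deg,
)

__all__ = [
    "SimConfig",
    "CellPopulation",
    "assign_cell_population",
    "generate_track_session",
    "generate_box_session",
    "generate_lfp",
    "embed_ripple_replay",
    "simulate_day",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic recording day.

    Defaults follow the recorded behaviour where it is quantified (about 19
    laps per trajectory lasting ~5.8 s, about 19 rotation events of ~6.67 s
    per box session, ~0.3 ripples/s during immobility) and conventional
    place/HD-cell numbers elsewhere (10 Hz field peak over a 0.2 Hz floor,
    ~20 cm fields on a 200 cm track, ~45 cells simultaneously recorded).
    """

    n_cells: int = 60
    frac_track_active: float = 0.5
    frac_box_active: float = 0.45
    #: fraction of track-active cells forced to be box-active with
    #: order-preserving circular tuning (the injected cross-activation)
    cross_activation_fraction: float = 0.5
    peak_rate_hz: float = 10.0
    baseline_rate_hz: float = 0.2
    field_width_cm: float = 20.0  # full width at half maximum
    n_laps_per_trajectory: int = 19
    n_rotation_events: int = 19
    rotation_duration_s: float = 6.67
    lap_duration_s: float = 5.8
    position_hz: float = 33.0
    lfp_hz: float = 2000.0
    track_length_cm: float = 200.0
    box_size_cm: float = 25.0
    box_kappa: float = 4.0  # von Mises concentration of box tuning
    ripple_rate_hz: float = 0.3  # ripple bursts per second of immobility
    ripple_amp_sd: float = 6.0  # burst envelope amplitude in background SD
    end_pause_s: float = 1.5  # mean pause at track ends between laps
    immobility_every: int = 4  # insert an immobility epoch every k rotations
    immobility_s: float = 8.0
    designated_trajectory: str = "A_to_B"
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_track_active", "frac_box_active",
                     "cross_activation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.peak_rate_hz > self.baseline_rate_hz >= 0:
            raise ValueError("require peak_rate_hz > baseline_rate_hz >= 0")
        if self.position_hz <= 0 or self.lfp_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.designated_trajectory not in TRAJECTORIES:
            raise ValueError("unknown designated_trajectory")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child RNG stream derived from the master seed."""
        h = zlib.crc32(stream.encode()) % (2 ** 31)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(h,)))


@dataclass
class CellPopulation:
    """Ground-truth tuning for every cell of a synthetic day.

    ``track_center_cm[traj]`` / ``track_peak_hz[traj]`` are NaN for cells
    inactive on that trajectory; ``box_pref_deg`` etc. are NaN for cells
    without box tuning. Labels partition cells into
    {common, track_only, box_only, silent}.
    """

    cell_ids: np.ndarray
    track_center_cm: dict[str, np.ndarray]
    track_peak_hz: dict[str, np.ndarray]
    field_sigma_cm: float
    box_pref_deg: np.ndarray
    box_kappa: np.ndarray
    box_peak_hz: np.ndarray
    labels: np.ndarray  # array of str
    designated_trajectory: str

    def cells_with_label(self, label: str) -> np.ndarray:
        return self.cell_ids[self.labels == label]

    @property
    def common_cells(self) -> np.ndarray:
        return self.cells_with_label("common")

    def track_active(self, trajectory: str) -> np.ndarray:
        return self.cell_ids[np.isfinite(self.track_center_cm[trajectory])]

    @property
    def box_active(self) -> np.ndarray:
        return self.cell_ids[np.isfinite(self.box_pref_deg)]


def assign_cell_population(config: SimConfig) -> CellPopulation:
    """Draw per-cell tuning and ground-truth labels for one synthetic day.

    ``round(n_track * cross_activation_fraction)`` track-active cells are
    forced to be box-active with preferred box angles in the same circular
    order as their field centers on the designated trajectory. With
    ``cross_activation_fraction == 0`` the box-active set is drawn
    independently of the track-active set, so any common cells arise only by
    chance overlap.
    """
    rng = config.rng("population")
    n = config.n_cells
    n_track = int(round(n * config.frac_track_active))
    n_box = int(round(n * config.frac_box_active))
    n_common = int(round(n_track * config.cross_activation_fraction))
    if n_common > n_box:
        raise ValueError(
            "cross_activation_fraction implies more common cells "
            f"({n_common}) than box-active cells ({n_box})")

    ids = np.arange(n)
    track_set = rng.choice(n, size=n_track, replace=False)
    if config.cross_activation_fraction > 0:
        # forced-common cells get order-preserving tuning; the rest of the
        # box set is drawn independently from all remaining cells, so the
        # non-forced overlap stays at its chance level and the expected
        # total overlap grows monotonically with the fraction
        forced_common = rng.choice(track_set, size=n_common, replace=False)
        rest_pool = np.setdiff1d(ids, forced_common)
        n_rest = n_box - n_common
        if n_rest > rest_pool.size:
            raise ValueError("not enough cells for the box set")
        box_set = np.concatenate(
            [forced_common, rng.choice(rest_pool, size=n_rest, replace=False)])
    else:
        forced_common = np.empty(0, dtype=int)
        box_set = rng.choice(n, size=n_box, replace=False)

    is_track = np.isin(ids, track_set)
    is_box = np.isin(ids, box_set)
    labels = np.full(n, "silent", dtype=object)
    labels[is_track & ~is_box] = "track_only"
    labels[~is_track & is_box] = "box_only"
    labels[is_track & is_box] = "common"

    # track tuning: each track-active cell fires on 1 or 2 trajectories;
    # forced-common cells always on the designated trajectory
    lo = 0.075 * config.track_length_cm
    hi = config.track_length_cm - lo
    centers = {trj: np.full(n, np.nan) for trj in TRAJECTORIES}
    peaks = {trj: np.full(n, np.nan) for trj in TRAJECTORIES}
    other_traj = [t for t in TRAJECTORIES
                  if t != config.designated_trajectory][0]
    for cid in track_set:
        on_desig = rng.random() < 0.7
        on_other = rng.random() < 0.7
        if cid in forced_common:
            on_desig = True
        if not (on_desig or on_other):
            on_desig = True
        for trj, on in ((config.designated_trajectory, on_desig),
                        (other_traj, on_other)):
            if on:
                centers[trj][cid] = rng.uniform(lo, hi)
                peaks[trj][cid] = config.peak_rate_hz * rng.uniform(0.7, 1.3)

    # box tuning
    box_pref = np.full(n, np.nan)
    box_kap = np.full(n, np.nan)
    box_peak = np.full(n, np.nan)
    free_box = np.setdiff1d(box_set, forced_common)
    box_pref[free_box] = rng.uniform(0.0, 360.0, size=free_box.size)
    if forced_common.size:
        # map designated-trajectory field centers onto the circle with a
        # shared random offset and a jitter small enough to preserve order
        c = centers[config.designated_trajectory][forced_common]
        base = c / config.track_length_cm * 360.0
        if forced_common.size > 1:
            gaps = np.diff(np.sort(base))
            min_gap = float(gaps.min()) if gaps.size else 360.0
        else:
            min_gap = 360.0
        jitter = min(3.0, min_gap / 3.0)
        offset = rng.uniform(0.0, 360.0)
        box_pref[forced_common] = (
            base + offset + rng.uniform(-jitter, jitter, forced_common.size)
        ) % 360.0
    box_kap[box_set] = config.box_kappa * rng.uniform(0.8, 1.2, box_set.size)
    box_peak[box_set] = config.peak_rate_hz * rng.uniform(0.7, 1.3,
                                                          box_set.size)

    sigma = config.field_width_cm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return CellPopulation(
        cell_ids=ids,
        track_center_cm=centers,
        track_peak_hz=peaks,
        field_sigma_cm=sigma,
        box_pref_deg=box_pref,
        box_kappa=box_kap,
        box_peak_hz=box_peak,
        labels=labels.astype(str),
        designated_trajectory=config.designated_trajectory,
    )


def _poisson_spikes(rate_per_sample: np.ndarray, t: np.ndarray,
                    dt: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spike times from a per-sample intensity (Hz)."""
    counts = rng.poisson(rate_per_sample * dt)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(t[: counts.size], counts)
    return np.sort(starts + rng.uniform(0.0, dt, size=total))


def generate_track_session(pop: CellPopulation, config: SimConfig,
                           session_id: str = "track") -> SessionRecording:
    """Back-and-forth lap running on the linear track with Poisson spiking.

    Position sweeps [0, track_length] once per lap at near-constant speed
    (lap duration jittered +/-10%), pausing at each end between laps.
    Cells fire from their trajectory-specific Gaussian field only while the
    animal moves in that trajectory's direction, plus the uniform baseline.
    Ground truth (lap intervals, end-pause intervals, labels) is stored in
    the session sidecar.
    """
    rng = config.rng("track")
    dt = 1.0 / config.position_hz
    L = config.track_length_cm

    t_chunks, x_chunks = [], []
    laps, pauses = [], []
    t_now = 0.0

    def pause(duration):
        nonlocal t_now
        n = max(1, int(round(duration / dt)))
        t_chunks.append(t_now + np.arange(n) * dt)
        x_chunks.append(np.full(n, x_here))
        pauses.append((t_now, t_now + n * dt))
        t_now += n * dt

    x_here = 0.0
    pause(rng.uniform(0.5, 1.0) * config.end_pause_s * 2)
    for lap in range(config.n_laps_per_trajectory):
        for trj in TRAJECTORIES:
            dur = config.lap_duration_s * rng.uniform(0.9, 1.1)
            n = max(2, int(round(dur / dt)))
            frac = np.arange(n) / n
            # mild sinusoidal speed jitter around constant velocity
            frac = frac + 0.03 * np.sin(2 * np.pi * frac * rng.uniform(1, 3))
            frac = np.clip(frac, 0.0, 1.0)
            xs = frac * L if trj == "A_to_B" else (1.0 - frac) * L
            t_chunks.append(t_now + np.arange(n) * dt)
            x_chunks.append(xs)
            laps.append({"trajectory": trj, "start_s": t_now,
                         "end_s": t_now + n * dt})
            t_now += n * dt
            x_here = L if trj == "A_to_B" else 0.0
            pause(config.end_pause_s * rng.uniform(0.7, 1.3))

    t = np.concatenate(t_chunks)
    x = np.concatenate(x_chunks)
    vx = np.gradient(x, t)
    hd = np.where(vx >= 0, 0.0, -180.0)  # heading along the track
    position = PositionSeries(t=t, x=x, y=np.zeros_like(x), hd_deg=hd)

    sigma = pop.field_sigma_cm
    spikes: dict[int, np.ndarray] = {}
    moving = {"A_to_B": vx > 1.0, "B_to_A": vx < -1.0}
    for cid in pop.cell_ids:
        rate = np.full(t.size, config.baseline_rate_hz)
        for trj in TRAJECTORIES:
            c = pop.track_center_cm[trj][cid]
            if np.isfinite(c):
                rate = rate + moving[trj] * pop.track_peak_hz[trj][cid] * \
                    np.exp(-0.5 * ((x - c) / sigma) ** 2)
        spikes[int(cid)] = _poisson_spikes(rate, t, dt, rng)

    gt = {
        "labels": {int(c): str(l) for c, l in zip(pop.cell_ids, pop.labels)},
        "laps": laps,
        "pauses": [list(p) for p in pauses],
    }
    return SessionRecording(
        session_id=session_id, condition="Track", spikes=spikes,
        position=position,
        geometry={"box_size_cm": config.box_size_cm,
                  "track_length_cm": L, "opening_center_deg": 0.0},
        ground_truth=gt)


def _rotation_hd(config: SimConfig, rng: np.random.Generator,
                 dt: float) -> tuple[np.ndarray, str, float]:
    """Unwrapped HD trace for one full rotation event."""
    direction = "CCW" if rng.random() < 0.5 else "CW"
    sign = 1.0 if direction == "CCW" else -1.0
    start = rng.uniform(-30.0, 30.0)
    total = sign * (360.0 + rng.uniform(-10.0, 10.0))
    dur = config.rotation_duration_s * rng.uniform(0.8, 1.2)
    n = max(2, int(round(dur / dt)))
    frac = np.arange(n + 1) / n
    # constant angular speed with ~20% sinusoidal modulation
    frac = frac + 0.2 / (2 * np.pi) * np.sin(2 * np.pi * frac)
    hd = start + total * frac
    return hd, direction, abs(total)


def generate_box_session(pop: CellPopulation, config: SimConfig,
                         condition: str = "Trained-demo",
                         session_id: str = "box",
                         stream: str = "box") -> SessionRecording:
    """Box session: rotation events interleaved with facing/immobility epochs.

    The HD trace contains ``n_rotation_events`` full rotations (mixed
    CW/CCW) starting and ending within +/-45 deg of the opening, separated
    by irregular low-amplitude facing-opening epochs; every
    ``immobility_every``-th rotation is followed by a frozen immobility
    epoch (for stop detection and ripple placement). Box-active cells spike
    as Poisson from their circular tuning during rotations and at baseline
    otherwise.
    """
    rng = config.rng(stream)
    dt = 1.0 / config.position_hz
    half = config.box_size_cm / 2.0
    r_rot = 0.32 * config.box_size_cm  # head-circle radius during rotation

    t_chunks, hd_chunks, x_chunks, y_chunks = [], [], [], []
    rotations, immobility = [], []
    t_now = 0.0
    hd_now = 0.0

    def facing_epoch(duration):
        nonlocal t_now, hd_now
        n = max(2, int(round(duration / dt)))
        # low-amplitude HD jitter around the opening + small head wander
        steps = rng.normal(0.0, 4.0, n)
        hd = np.clip(np.cumsum(steps) + hd_now, -40.0, 40.0)
        hd = hd - np.linspace(0.0, hd[-1] - rng.uniform(-10, 10), n)
        hd = np.clip(hd, -44.0, 44.0)
        xs = half + np.clip(np.cumsum(rng.normal(0, 0.25, n)), -6, 6)
        ys = half + np.clip(np.cumsum(rng.normal(0, 0.25, n)), -6, 6)
        t_chunks.append(t_now + np.arange(n) * dt)
        hd_chunks.append(hd)
        x_chunks.append(xs)
        y_chunks.append(ys)
        t_now += n * dt
        hd_now = hd[-1]

    def immobile_epoch(duration):
        nonlocal t_now
        n = max(2, int(round(duration / dt)))
        t_chunks.append(t_now + np.arange(n) * dt)
        hd_chunks.append(np.full(n, hd_now))
        x_chunks.append(np.full(n, x_chunks[-1][-1]))
        y_chunks.append(np.full(n, y_chunks[-1][-1]))
        immobility.append((t_now, t_now + n * dt))
        t_now += n * dt

    facing_epoch(rng.uniform(4.0, 8.0))
    for k in range(config.n_rotation_events):
        hd_un, direction, span = _rotation_hd(config, rng, dt)
        hd_un = hd_un + (hd_now - hd_un[0])  # start where we are
        n = hd_un.size
        ang = np.radians(hd_un)
        t_chunks.append(t_now + np.arange(n) * dt)
        hd_chunks.append(wrap_deg(hd_un))
        x_chunks.append(half + r_rot * np.cos(ang))
        y_chunks.append(half + r_rot * np.sin(ang))
        rotations.append({"start_s": t_now, "end_s": t_now + n * dt,
                          "direction": direction, "span_deg": span})
        t_now += n * dt
        hd_now = float(wrap_deg(hd_un[-1]))
        if config.immobility_every and (k + 1) % config.immobility_every == 0:
            immobile_epoch(config.immobility_s * rng.uniform(0.8, 1.4))
        facing_epoch(rng.uniform(3.0, 8.0))

    t = np.concatenate(t_chunks)
    hd = np.concatenate(hd_chunks)
    x = np.clip(np.concatenate(x_chunks), 0.5, config.box_size_cm - 0.5)
    y = np.clip(np.concatenate(y_chunks), 0.5, config.box_size_cm - 0.5)
    position = PositionSeries(t=t, x=x, y=y, hd_deg=hd)

    in_rotation = np.zeros(t.size, dtype=bool)
    for ev in rotations:
        in_rotation |= (t >= ev["start_s"]) & (t < ev["end_s"])

    spikes: dict[int, np.ndarray] = {}
    hd_rad = np.radians(hd)
    for cid in pop.cell_ids:
        rate = np.full(t.size, config.baseline_rate_hz)
        pref = pop.box_pref_deg[cid]
        if np.isfinite(pref):
            kap = pop.box_kappa[cid]
            tuning = np.exp(kap * (np.cos(hd_rad - math.radians(pref)) - 1.0))
            rate = rate + in_rotation * pop.box_peak_hz[cid] * tuning
        spikes[int(cid)] = _poisson_spikes(rate, t, dt, rng)

    gt = {
        "labels": {int(c): str(l) for c, l in zip(pop.cell_ids, pop.labels)},
        "rotation_events": rotations,
        "immobility": [list(p) for p in immobility],
    }
    return SessionRecording(
        session_id=session_id, condition=condition, spikes=spikes,
        position=position,
        geometry={"box_size_cm": config.box_size_cm,
                  "track_length_cm": config.track_length_cm,
                  "opening_center_deg": 0.0},
        ground_truth=gt)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    return pink / pink.std()


def generate_lfp(position: PositionSeries, config: SimConfig,
                 ripple_rate_hz: Optional[float] = None,
                 ripple_amp_sd: Optional[float] = None,
                 stream: str = "lfp") -> tuple[LfpTrace, list[list[float]]]:
    """Band-limited LFP surrogate aligned with a position series.

    During movement (translational speed > 2 cm/s or HD angular speed >
    20 deg/s) an 8 Hz theta sinusoid rides on pink background noise; during
    immobility, 150 Hz ripple bursts (80-120 ms) are inserted as a Poisson
    process at ``ripple_rate_hz``, with burst envelope calibrated to
    ``ripple_amp_sd`` standard deviations of the background ripple-band
    envelope. Returns the trace and the ground-truth burst intervals.
    """
    rng = config.rng(stream)
    if ripple_rate_hz is None:
        ripple_rate_hz = config.ripple_rate_hz
    if ripple_amp_sd is None:
        ripple_amp_sd = config.ripple_amp_sd
    fs = config.lfp_hz
    n = int(round(position.duration * fs))
    tl = position.t[0] + np.arange(n) / fs

    noise = _pink_noise(n, rng)

    # movement mask resampled onto the LFP grid
    sp = position.speed()
    hd_un = position.hd_unwrapped()
    ang_sp = np.abs(np.gradient(hd_un, position.t))
    moving = (sp > 2.0) | (ang_sp > 20.0)
    mov = np.interp(tl, position.t, moving.astype(float)) > 0.5
    ramp = sp_signal.windows.gaussian(int(0.25 * fs) | 1, int(0.05 * fs))
    mov_s = np.convolve(mov.astype(float), ramp / ramp.sum(), mode="same")

    theta = 2.0 * np.sin(2 * np.pi * 8.0 * tl) * mov_s
    data = noise + theta

    # background ripple-band envelope statistics (noise only)
    from scipy.ndimage import gaussian_filter1d
    sos = sp_signal.butter(4, [100, 250], btype="bandpass", fs=fs,
                           output="sos")
    band_noise = sp_signal.sosfiltfilt(sos, noise)
    # amplitudes are expressed in SDs of the band-passed signal, matching
    # the ripple detector's threshold units
    sigma_band = float(band_noise.std())

    bursts: list[list[float]] = []
    if ripple_rate_hz > 0:
        immobile = ~mov
        n_exp = ripple_rate_hz * immobile.sum() / fs
        n_bursts = rng.poisson(n_exp)
        idx_pool = np.flatnonzero(immobile[: max(0, n - int(0.25 * fs))])
        if idx_pool.size and n_bursts > 0:
            starts = np.sort(rng.choice(idx_pool, size=min(
                n_bursts, idx_pool.size), replace=False))
            # drop bursts closer than 250 ms
            keep = np.concatenate([[True], np.diff(starts) > 0.25 * fs])
            amp = ripple_amp_sd * sigma_band / (2.0 / np.pi)  # |A sin| mean
            waves = []
            suppress = np.zeros(n)
            for s0 in starts[keep]:
                dur = rng.uniform(0.08, 0.12)
                m = int(dur * fs)
                # flat-top window: most of the burst stays above the 2.5 SD
                # boundary threshold, as in physiological ripples
                win = sp_signal.windows.tukey(m, alpha=0.4)
                tt = np.arange(m) / fs
                burst = amp * win * np.sin(
                    2 * np.pi * 150.0 * tt + rng.uniform(0, 2 * np.pi))
                waves.append((int(s0), burst[: n - s0]))
                suppress[s0: s0 + m] = np.maximum(
                    suppress[s0: s0 + m], 0.8 * win[: n - s0])
                bursts.append([float(tl[s0]), float(tl[min(s0 + m, n - 1)])])
            # the ripple transient dominates the band locally, so damp the
            # background ripple-band noise inside burst windows (this also
            # removes beating between tone and background)
            data = data - suppress * band_noise
            # iterative per-burst calibration so every achieved envelope
            # peak matches ripple_amp_sd in whole-session SD units
            scales = np.ones(len(waves))
            burst_sig = np.zeros(n)
            for _ in range(2):
                burst_sig[:] = 0.0
                for (s0, w), sc in zip(waves, scales):
                    burst_sig[s0: s0 + w.size] += w * sc
                filt = sp_signal.sosfiltfilt(sos, data + burst_sig)
                env1 = gaussian_filter1d(np.abs(filt), 0.004 * fs)
                unit = float(filt.std())
                for k, (s, e) in enumerate(bursts):
                    i0, i1 = int((s - tl[0]) * fs), int((e - tl[0]) * fs)
                    achieved = float(env1[i0:max(i1, i0 + 1)].max()) / unit
                    if achieved > 0:
                        scales[k] *= ripple_amp_sd / achieved
            burst_sig[:] = 0.0
            for (s0, w), sc in zip(waves, scales):
                burst_sig[s0: s0 + w.size] += w * sc
            data = data + burst_sig

    return LfpTrace(data=data, fs=fs, t0=float(tl[0])), bursts


def embed_ripple_replay(session: SessionRecording, template,
                        n_events: int, config: SimConfig,
                        burst_intervals: Optional[list] = None,
                        stream: str = "replay") -> SessionRecording:
    """Inject template-ordered single-spike replays into ripple bursts.

    In ``n_events`` burst windows, each template cell fires one spike, in
    template order (forward or reversed, chosen per event), compressed into
    the central 80% of the burst. Ground truth is appended to the session
    sidecar. Templates shorter than 5 cells are refused to mirror the
    candidate-event definition.
    """
    cells = list(getattr(template, "cell_ids", template))
    if len(cells) < 5:
        raise ValueError("replay template must have at least 5 cells")
    missing = [c for c in cells if c not in session.spikes]
    if missing:
        raise ValueError(f"template cells absent from session: {missing}")
    rng = config.rng(stream)
    if burst_intervals is None:
        gt = session.ground_truth or {}
        burst_intervals = gt.get("ripple_bursts", [])
    if len(burst_intervals) < n_events:
        raise ValueError(
            f"only {len(burst_intervals)} ripple bursts available, "
            f"{n_events} replays requested")
    chosen = rng.choice(len(burst_intervals), size=n_events, replace=False)

    replays = []
    spikes = {c: list(t) for c, t in session.spikes.items()}
    for bi in chosen:
        s, e = burst_intervals[bi]
        dur = e - s
        lo, hi = s + 0.1 * dur, e - 0.1 * dur
        order = list(cells)
        forward = bool(rng.random() < 0.5)
        if not forward:
            order = order[::-1]
        times = np.linspace(lo, hi, len(order))
        for c, ts in zip(order, times):
            spikes[c].append(float(ts))
        replays.append({"interval": [float(s), float(e)],
                        "cells": [int(c) for c in order],
                        "forward": forward})

    new_spikes = {c: np.sort(np.asarray(t)) for c, t in spikes.items()}
    gt = dict(session.ground_truth or {})
    gt.setdefault("ripple_bursts", list(burst_intervals))
    gt["injected_replays"] = gt.get("injected_replays", []) + replays
    return SessionRecording(
        session_id=session.session_id, condition=session.condition,
        spikes=new_spikes, position=session.position, lfp=session.lfp,
        demo_position=session.demo_position, geometry=session.geometry,
        ground_truth=gt)


def simulate_day(config: SimConfig, with_lfp: bool = False,
                 condition: str = "Trained-demo") -> dict:
    """One full synthetic recording day: Pre-box, Track, Post-box.

    Returns ``{"population", "pre_box", "track", "post_box"}``; box sessions
    carry ground-truth rotation/immobility intervals (and LFP + ripple-burst
    intervals when ``with_lfp``).
    """
    pop = assign_cell_population(config)
    pre = generate_box_session(pop, config, condition=condition,
                               session_id="pre_box", stream="pre_box")
    track = generate_track_session(pop, config)
    post = generate_box_session(pop, config, condition=condition,
                                session_id="post_box", stream="post_box")
    if with_lfp:
        for ses, stream in ((pre, "lfp_pre"), (post, "lfp_post")):
            lfp, bursts = generate_lfp(ses.position, config, stream=stream)
            ses.lfp = lfp
            ses.ground_truth["ripple_bursts"] = bursts
    return {"population": pop, "pre_box": pre, "track": track,
            "post_box": post}
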