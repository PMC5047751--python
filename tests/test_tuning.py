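"""Rate curves, spatial information, and shuffle-statistic calibration."""

import numpy as np
import pytest

import crossact as ca
from crossact.core import LapEvent, PositionSeries, RotationEvent
from crossact.tuning import (
    circular_rate_curve,
    demo_position_tuning,
    lap_consistency,
    linear_rate_curve,
    rate_map_2d,
    rayleigh_hd_test,
    rotation_consistency,
    spatial_information,
)

FS = 33.0


def constant_hd_position(hd_value, dur_s):
    n = int(dur_s * FS)
    t = np.arange(n) / FS
    return PositionSeries(t=t, x=np.zeros(n), y=np.zeros(n),
                          hd_deg=np.full(n, float(hd_value)))


def rotating_position(dur_s, turns=1.0, offset=0.0):
    n = int(dur_s * FS)
    t = np.arange(n) / FS
    hd = (offset + 360.0 * turns * t / dur_s + 180) % 360 - 180
    return PositionSeries(t=t, x=np.zeros(n), y=np.zeros(n), hd_deg=hd)


class TestSpatialInformation:
    def test_closed_forms(self):
        assert spatial_information(np.full(8, 3.0), np.ones(8), 0.0) == \
            pytest.approx(0.0)
        assert spatial_information(np.array([2.0, 0.0]), np.ones(2), 0.0) \
            == pytest.approx(1.0)
        assert spatial_information(np.array([4.0, 0, 0, 0]), np.ones(4),
                                   0.0) == pytest.approx(2.0)

    def test_matches_brute_force_on_random_curves(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            nb = rng.integers(3, 30)
            r = rng.gamma(1.0, 2.0, nb)
            occ = rng.uniform(0.2, 2.0, nb)
            p = occ / occ.sum()
            rbar = np.sum(p * r)
            brute = sum(p[i] * (r[i] / rbar) * np.log2(r[i] / rbar)
                        for i in range(nb) if r[i] > 0)
            assert spatial_information(r, occ, 0.0) == \
                pytest.approx(brute, abs=1e-12)

    def test_zero_rate_curve_is_nan(self):
        assert np.isnan(spatial_information(np.zeros(5), np.ones(5), 0.0))


class TestLinearRateCurve:
    def make_track(self, dur_s=120.0):
        n = int(dur_s * FS)
        t = np.arange(n) / FS
        # simple sawtooth traversals
        period = 12.0
        phase = (t % period) / period
        x = np.where(phase < 0.5, phase * 2, (1 - phase) * 2) * 200.0
        pos = PositionSeries(t=t, x=x, y=np.zeros(n), hd_deg=np.zeros(n))
        laps = ca.detect_lap_events(pos)
        return pos, [l for l in laps if l.trajectory == "A_to_B"]

    def test_zero_spikes_all_zero(self):
        pos, laps = self.make_track()
        curve = linear_rate_curve(np.empty(0), pos, laps)
        assert np.all(curve.rates == 0)

    def test_spike_count_conserved_before_smoothing(self):
        pos, laps = self.make_track()
        rng = np.random.default_rng(1)
        spikes = np.sort(rng.uniform(0, pos.duration, 500))
        curve = linear_rate_curve(spikes, pos, laps)
        from crossact.core import as_intervals, in_intervals
        inside = in_intervals(spikes, as_intervals(laps))
        x = pos.x_at(spikes[inside])
        expected = np.count_nonzero((x >= 10.0) & (x < 190.0))
        assert curve.counts.sum() == expected

    def test_mixed_trajectories_rejected(self):
        pos, _ = self.make_track()
        laps = ca.detect_lap_events(pos)
        with pytest.raises(ValueError):
            linear_rate_curve(np.empty(0), pos, laps)

    def test_zero_occupancy_rejected(self):
        pos, laps = self.make_track()
        bogus = [LapEvent("A_to_B", 1e6, 1e6 + 5)]
        with pytest.raises(ValueError):
            linear_rate_curve(np.empty(0), pos, bogus)


class TestCircularRateCurve:
    def test_all_spikes_at_90_peak_bin(self):
        pos = rotating_position(36.0)
        ev = [RotationEvent(0.0, pos.t[-1] + 1 / FS, "CCW", 360.0)]
        spike_t = pos.t[np.abs(((pos.hd_deg - 90) + 180) % 360 - 180) < 3][:30]
        curve = circular_rate_curve(spike_t, pos, ev)
        assert abs(curve.peak_angle_deg - 90.0) <= 7.5

    def test_equivariance_under_global_rotation(self):
        pos = rotating_position(36.0)
        ev = [RotationEvent(0.0, pos.t[-1] + 1 / FS, "CCW", 360.0)]
        rng = np.random.default_rng(2)
        spikes = np.sort(rng.uniform(0, 30.0, 200))
        c1 = circular_rate_curve(spikes, pos, ev)
        pos2 = PositionSeries(t=pos.t, x=pos.x, y=pos.y,
                              hd_deg=(pos.hd_deg + 90 + 180) % 360 - 180)
        c2 = circular_rate_curve(spikes, pos2, ev)
        shift = 18  # 90 deg / 5 deg bins
        assert np.allclose(np.roll(c1.rates, shift), c2.rates, atol=1e-9)

    def test_uniform_cell_flat_curve(self):
        pos = rotating_position(360.0, turns=10.0)
        ev = [RotationEvent(float(36 * k), float(36 * (k + 1)), "CCW", 360.0)
              for k in range(10)]
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 360.0, 3600))  # 10 Hz homogeneous
        curve = circular_rate_curve(spikes, pos, ev)
        assert curve.rates.std() / curve.rates.mean() < 0.2


class TestRateMap2D:
    def test_masking_and_conservation(self):
        rng = np.random.default_rng(4)
        n = int(600 * FS)
        t = np.arange(n) / FS
        x = np.clip(np.cumsum(rng.normal(0, 0.3, n)) % 50 - 12.5, 0, 25)
        y = np.clip(np.cumsum(rng.normal(0, 0.3, n)) % 50 - 12.5, 0, 25)
        pos = PositionSeries(t=t, x=x, y=y, hd_deg=np.zeros(n))
        spikes = np.sort(rng.uniform(0, t[-1], 400))
        m = rate_map_2d(spikes, pos, [(0.0, float(t[-1]))])
        assert np.nansum(m.rates) >= 0
        assert m.counts.sum() <= 400
        # no-spike map is all zero where defined
        m0 = rate_map_2d(np.empty(0), pos, [(0.0, float(t[-1]))])
        assert np.nansum(m0.rates) == 0


class TestRayleigh:
    def test_concentrated_spikes_tiny_p(self):
        pos = rotating_position(60.0, turns=2.0)
        near = np.abs(((pos.hd_deg - 45) + 180) % 360 - 180) < 4
        spikes = pos.t[near][:40]
        ev = [(0.0, 60.0)]
        assert rayleigh_hd_test(spikes, pos, ev) < 1e-6

    def test_too_few_spikes_is_nan(self):
        pos = rotating_position(60.0)
        with pytest.warns(UserWarning):
            assert np.isnan(rayleigh_hd_test(pos.t[:3], pos, [(0.0, 60.0)]))

    def test_uniform_null_calibration(self):
        """p-values approximately uniform for direction-blind spiking."""
        pos = rotating_position(720.0, turns=20.0)
        ev = [(0.0, 720.0)]
        rng = np.random.default_rng(5)
        pvals = [rayleigh_hd_test(np.sort(rng.uniform(0, 720.0, 60)),
                                  pos, ev) for _ in range(200)]
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.005 <= frac <= 0.12


class TestRotationConsistency:
    def make_session(self, tuned, seed, n_events=10, rate=6.0):
        dur = 8.0
        pos = rotating_position(n_events * dur, turns=float(n_events))
        events = [RotationEvent(k * dur, (k + 1) * dur, "CCW", 360.0)
                  for k in range(n_events)]
        rng = np.random.default_rng(seed)
        dt = 1 / FS
        if tuned:
            lam = 0.2 + rate * np.exp(
                4.0 * (np.cos(np.radians(pos.hd_deg - 120.0)) - 1.0))
        else:
            lam = np.full(pos.t.size, rate / 4)
        counts = rng.poisson(lam * dt)
        spikes = np.repeat(pos.t, counts) + rng.uniform(0, dt, counts.sum())
        return np.sort(spikes), pos, events

    def test_tuned_cell_is_consistent(self):
        spikes, pos, events = self.make_session(True, 6)
        res = rotation_consistency(spikes, pos, events,
                                   rng=np.random.default_rng(0))
        assert res.z > 1.645 and res.significant

    def test_single_active_event_undefined(self):
        spikes, pos, events = self.make_session(True, 6)
        res = rotation_consistency(spikes, pos, events[:1],
                                   rng=np.random.default_rng(0))
        assert not res.significant and res.reason is not None

    def test_statistic_invariant_under_event_relabelling(self):
        spikes, pos, events = self.make_session(True, 7)
        r1 = rotation_consistency(spikes, pos, events,
                                  rng=np.random.default_rng(1))
        r2 = rotation_consistency(spikes, pos, events[::-1],
                                  rng=np.random.default_rng(1))
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_homogeneous_null_calibration(self):
        """A homogeneous Poisson cell is flagged ~5% of the time."""
        flags = []
        rng = np.random.default_rng(8)
        for rep in range(120):
            spikes, pos, events = self.make_session(False, 100 + rep)
            res = rotation_consistency(spikes, pos, events,
                                       n_shuffles=300, rng=rng)
            if np.isfinite(res.z):
                flags.append(res.significant)
        frac = np.mean(flags)
        se = np.sqrt(0.05 * 0.95 / len(flags))
        assert abs(frac - 0.05) <= 3 * se + 0.01


class TestLapConsistency:
    def test_identical_laps_give_one(self):
        curve = np.array([0.0, 1.0, 3.0, 1.0, 0.0])
        assert lap_consistency([curve, curve, curve]) == pytest.approx(1.0)

    def test_anticorrelated_pair_contributes_minus_one(self):
        a = np.array([0.0, 1.0, 2.0, 3.0])
        assert lap_consistency([a, 3.0 - a]) == pytest.approx(-1.0)

    def test_independent_poisson_laps_near_zero(self):
        rng = np.random.default_rng(9)
        vals = [lap_consistency(list(rng.poisson(2.0, (6, 40)).astype(float)))
                for _ in range(200)]
        assert abs(np.nanmean(vals)) < 0.02

    def test_too_few_active_laps_nan(self):
        assert np.isnan(lap_consistency([np.zeros(5), np.ones(5)]))


@pytest.fixture(scope="module")
def demo():
    cfg = ca.SimConfig(seed=7, n_laps_per_trajectory=20)
    pop = ca.assign_cell_population(cfg)
    track = ca.generate_track_session(pop, cfg)
    laps = [LapEvent(**l) for l in track.ground_truth["laps"]
            if l["trajectory"] == "A_to_B"]
    return track.position, laps


class TestDemoTuning:

    def test_coupled_observer_strongly_significant(self, demo):
        pos, laps = demo
        rng = np.random.default_rng(1)
        rate = 0.2 + 8.0 * np.exp(-0.5 * ((pos.x - 100.0) / 8.0) ** 2)
        counts = rng.poisson(rate / FS)
        spikes = np.sort(np.repeat(pos.t, counts))
        res = demo_position_tuning(spikes, pos, laps, n_shuffles=300,
                                   rng=rng)
        assert res.z_spatial_information > 5.0
        assert res.z_lap_consistency > 5.0

    def test_zero_shift_reproduces_actual_statistic(self, demo):
        """A circular shift of 0 is a legal null draw and must reproduce
        the actual statistic exactly."""
        pos, laps = demo

        class ZeroShiftRng:
            def uniform(self, lo, hi, size=None):
                return np.zeros(size)

        rng = np.random.default_rng(2)
        spikes = np.sort(rng.uniform(0, pos.duration,
                                     rng.poisson(pos.duration)))
        res = demo_position_tuning(spikes, pos, laps, n_shuffles=4,
                                   rng=ZeroShiftRng(), keep_nulls=True)
        assert np.allclose(res.null_spatial_information,
                           res.spatial_information)
        assert np.allclose(res.null_lap_consistency, res.lap_consistency,
                           equal_nan=True)

    def test_no_spikes_graceful(self, demo):
        pos, laps = demo
        res = demo_position_tuning(np.empty(0), pos, laps, n_shuffles=5)
        assert res.n_spikes == 0 and np.isnan(res.spatial_information)
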