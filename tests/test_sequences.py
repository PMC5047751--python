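"""Sequence matching: scores, shuffle nulls vs the exhaustive-permutation
oracle, templates, candidates, and time gaps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import crossact as ca
from crossact.core import RippleEvent, RotationEvent
from crossact.sequences import (
    CandidateSequence,
    TemplateSequence,
    build_templates,
    circular_match_score,
    count_matching_sequences,
    extract_ripple_sequence,
    extract_rotation_sequence,
    rank_match_score,
    ripple_match,
    sequence_match_significance,
    time_gap_difference,
)
from crossact.tuning import RateCurve


def template(n, trajectory="A_to_B"):
    return TemplateSequence(trajectory, tuple(range(n)),
                            tuple(np.linspace(10.0, 190.0, n)))


def oracle_score(order, template_order, circular):
    """Independent reference: scipy spearman over explicit shifts."""
    n = len(order)
    rank_t = {c: i for i, c in enumerate(template_order)}
    tvec = [rank_t[c] for c in order]
    best = 0.0
    shifts = range(n) if circular else [0]
    svec = list(range(n))
    for k in shifts:
        shifted = [(s + k) % n for s in svec]
        rho = spearmanr(shifted, tvec).statistic
        if abs(rho) > abs(best):
            best = rho
    return abs(best), best


class TestMatchScores:
    def test_identity_and_reversal(self):
        t = template(5)
        assert circular_match_score(list(t.cell_ids), t) == (1.0, 1.0)
        s, signed = circular_match_score(list(t.cell_ids)[::-1], t)
        assert s == 1.0 and signed == -1.0
        assert rank_match_score(list(t.cell_ids), t) == (1.0, 1.0)
        s, signed = rank_match_score(list(t.cell_ids)[::-1], t)
        assert s == 1.0 and signed == -1.0

    def test_circularly_shifted_sequence_scores_one(self):
        # template 12345; candidate 45123 is a pure circular shift
        t = TemplateSequence("A_to_B", (1, 2, 3, 4, 5),
                             (10.0, 20.0, 30.0, 40.0, 50.0))
        assert circular_match_score([4, 5, 1, 2, 3], t)[0] == 1.0
        assert circular_match_score([5, 1, 2, 3, 4], t)[0] == 1.0

    @settings(max_examples=100, derandomize=True)
    @given(st.permutations(list(range(7))), st.integers(0, 6))
    def test_score_invariant_under_rotation_and_reversal(self, order, k):
        t = template(7)
        s0, _ = circular_match_score(order, t)
        rotated = order[k:] + order[:k]
        assert circular_match_score(rotated, t)[0] == pytest.approx(s0)
        srev, signed_rev = circular_match_score(order[::-1], t)
        assert srev == pytest.approx(s0)

    @settings(max_examples=60, derandomize=True)
    @given(st.permutations(list(range(6))))
    def test_scores_agree_with_scipy_oracle(self, order):
        t = template(6)
        assert circular_match_score(order, t)[0] == pytest.approx(
            oracle_score(order, t.cell_ids, True)[0])
        assert rank_match_score(order, t)[0] == pytest.approx(
            oracle_score(order, t.cell_ids, False)[0])


class TestShuffleVsExhaustiveOracle:
    @pytest.mark.parametrize("n,circular", [(5, True), (5, False),
                                            (6, True), (7, False)])
    def test_null_tail_probability_matches_brute_force(self, n, circular):
        """P(shuffled score < 1) from 1000 identity shuffles agrees with
        the exact probability over all n! permutations within 3 MC SE."""
        t = template(n)
        exact_scores = np.round([oracle_score(list(p), t.cell_ids,
                                              circular)[0]
                                 for p in itertools.permutations(
                                     t.cell_ids)], 9)
        exact_less = np.mean(exact_scores < 1.0)
        res = sequence_match_significance(
            list(t.cell_ids), t, n_shuffles=1000,
            rng=np.random.default_rng(7), circular=circular)
        est_less = np.mean(np.round(res.null_scores, 9) < 1.0)
        se = np.sqrt(exact_less * (1 - exact_less) / 1000)
        assert abs(est_less - exact_less) <= 3 * se
        # and the match decision equals the exact-null decision
        assert res.is_match == (exact_less > 0.95)

    def test_five_cell_circular_identity_cannot_match(self):
        """Rotations/reflections of 5 cells occupy 10/120 > 5% of the
        permutation null, so even a perfect 5-cell circular match is not
        significant under the strict 95% rule."""
        t = template(5)
        res = sequence_match_significance(list(t.cell_ids), t,
                                          rng=np.random.default_rng(0))
        assert res.score == 1.0 and not res.is_match
        # the linear (ripple) score has only 2/120 ties at 1 -> match
        res_lin = ripple_match(list(t.cell_ids), t,
                               rng=np.random.default_rng(0))
        assert res_lin.is_match

    def test_null_calibration_random_sequences(self):
        """Random candidates vs a random template match ~5% of the time
        (linear score; the circular score is conservative by ties)."""
        rng = np.random.default_rng(11)
        t = template(8)
        hits = []
        for _ in range(300):
            order = list(rng.permutation(t.cell_ids))
            res = sequence_match_significance(order, t, n_shuffles=300,
                                              rng=rng, circular=False)
            hits.append(res.is_match)
        frac = np.mean(hits)
        se = np.sqrt(0.05 * 0.95 / len(hits))
        assert frac <= 0.05 + 3 * se  # strict rule is never anticonservative

    def test_shuffle_scope_variants_agree_in_distribution(self):
        t = template(10)
        order = list(np.random.default_rng(3).permutation(t.cell_ids)[:6])
        a = sequence_match_significance(order, t, n_shuffles=2000,
                                        rng=np.random.default_rng(1),
                                        shuffle_scope="candidate")
        b = sequence_match_significance(order, t, n_shuffles=2000,
                                        rng=np.random.default_rng(2),
                                        shuffle_scope="template")
        assert abs(a.null_scores.mean() - b.null_scores.mean()) < 0.05

    def test_reproducible_given_seed(self):
        t = template(7)
        order = [3, 1, 6, 0, 2, 4, 5]
        r1 = sequence_match_significance(order, t,
                                         rng=np.random.default_rng(42))
        r2 = sequence_match_significance(order, t,
                                         rng=np.random.default_rng(42))
        assert np.array_equal(r1.null_scores, r2.null_scores)
        assert r1.is_match == r2.is_match


class TestTemplates:
    def curve(self, peak_loc, peak=8.0, flat=False):
        centers = np.arange(11.0, 190.0, 2.0)
        if flat:
            rates = np.full(centers.size, 2.0)
        else:
            rates = 0.1 + peak * np.exp(-0.5 * ((centers - peak_loc) / 6) ** 2)
        return RateCurve(bin_centers=centers, rates=rates,
                         occupancy_s=np.ones(centers.size),
                         counts=np.zeros(centers.size))

    def test_four_qualifying_cells_no_template(self):
        curves = {"A_to_B": {i: self.curve(20 + 30 * i) for i in range(4)}}
        assert build_templates(curves, range(4)) == {}

    def test_flat_cell_excluded_and_order_by_peak(self):
        curves = {"A_to_B": {i: self.curve(180 - 25 * i) for i in range(6)}}
        curves["A_to_B"][9] = self.curve(0, flat=True)
        tmpl = build_templates(curves, list(range(6)) + [9])
        assert 9 not in tmpl["A_to_B"].cell_ids
        assert list(tmpl["A_to_B"].cell_ids) == [5, 4, 3, 2, 1, 0]

    def test_non_common_cells_excluded(self):
        curves = {"A_to_B": {i: self.curve(20 + 25 * i) for i in range(7)}}
        tmpl = build_templates(curves, common_cells=range(5))
        assert set(tmpl["A_to_B"].cell_ids) <= set(range(5))

    def test_synthetic_template_order_matches_generator(self, day06,
                                                        pipeline_config):
        from crossact.pipeline import template_stage, tuning_stage
        rng = np.random.default_rng(0)
        tun = tuning_stage(day06["day"], day06["events"], day06["cls"],
                           pipeline_config, rng, per_cell_statistics=False)
        templates = template_stage(tun, day06["cls"], pipeline_config)
        pop = day06["day"]["population"]
        trj = "A_to_B"
        assert trj in templates
        tmpl = templates[trj]
        truth_centers = pop.track_center_cm[trj]
        cells = [c for c in tmpl.cell_ids
                 if np.isfinite(truth_centers[c])]
        centers = np.array([truth_centers[c] for c in cells])
        # template order follows the true field-center order; peak
        # estimation (2 cm bins, smoothing) may only swap cells whose
        # true centers nearly coincide
        rho = spearmanr(np.arange(len(cells)), centers).statistic
        assert rho > 0.95
        for i in range(len(cells) - 1):
            if centers[i] > centers[i + 1]:
                assert centers[i] - centers[i + 1] < 6.0


class TestCandidateExtraction:
    def make_rotation(self, angles_by_cell, dur=8.0):
        fs = 33.0
        n = int(dur * fs)
        t = np.arange(n) / fs
        hd = (360.0 * t / dur + 180) % 360 - 180
        pos = ca.PositionSeries(t=t, x=np.zeros(n), y=np.zeros(n), hd_deg=hd)
        ev = RotationEvent(0.0, dur, "CCW", 360.0)
        spikes = {}
        for cid, ang in angles_by_cell.items():
            t_sp = dur * (ang / 360.0)
            spikes[cid] = np.array([t_sp])
        return ev, pos, spikes

    def test_single_spike_cells_ordered_by_angle(self):
        ev, pos, spikes = self.make_rotation(
            {0: 10.0, 1: 50.0, 2: 90.0, 3: 130.0, 4: 170.0})
        cand = extract_rotation_sequence(ev, list(range(5)), spikes, pos)
        assert list(cand.cell_ids) == [0, 1, 2, 3, 4]

    def test_four_active_cells_no_candidate(self):
        ev, pos, spikes = self.make_rotation(
            {0: 10.0, 1: 50.0, 2: 90.0, 3: 130.0})
        assert extract_rotation_sequence(ev, list(range(5)), spikes,
                                         pos) is None

    def test_ripple_sequence_order_is_spike_time_order(self):
        rip = RippleEvent(10.0, 10.2, 10.1, 5.0)
        spikes = {i: np.array([10.02 + 0.03 * i]) for i in range(5)}
        cand = extract_ripple_sequence(rip, list(range(5)), spikes)
        assert list(cand.cell_ids) == [0, 1, 2, 3, 4]
        assert cand.source == "ripple"
        spikes[3] = np.array([])  # only 4 active
        assert extract_ripple_sequence(rip, list(range(5)), spikes) is None


class TestGroupCounting:
    def test_zero_candidates_degenerate(self):
        t = template(6)
        with pytest.warns(UserWarning):
            g = count_matching_sequences([], {"A_to_B": t})
        assert g.n_matches == 0 and g.p_value == 1.0

    def test_injected_matches_significant(self):
        """Candidates that are shifts/reversals of the template produce a
        significant group count; p is reported as <0.005 when no
        randomized set beats it."""
        rng = np.random.default_rng(5)
        t = template(9)
        cands = []
        for k in range(8):
            order = list(t.cell_ids[k % 3:]) + list(t.cell_ids[: k % 3])
            if k % 2:
                order = order[::-1]
            cands.append(CandidateSequence("rotation", None, tuple(order),
                                           tuple(range(9))))
        g = count_matching_sequences(cands, [t], rng=rng)
        assert g.n_matches == 8
        assert g.p_value < 0.05 and g.p_label == "<0.005"

    def test_random_candidates_not_significant(self):
        rng = np.random.default_rng(6)
        t = template(9)
        cands = [CandidateSequence(
            "rotation", None, tuple(rng.permutation(t.cell_ids)),
            tuple(range(9))) for _ in range(20)]
        g = count_matching_sequences(cands, [t],
                                     rng=np.random.default_rng(7))
        assert g.p_value > 0.05


class TestTimeGaps:
    def build_case(self, scale=1.0, jitter=None, seed=0):
        """5 cells, event peak times proportional to track peak spacing."""
        t = TemplateSequence("A_to_B", (0, 1, 2, 3, 4),
                             (20.0, 50.0, 110.0, 140.0, 170.0))
        speed, lap_dur = 40.0, 4.0  # track gaps in scaled time: d/(40*4)
        ev = RotationEvent(100.0, 108.0, "CCW", 360.0)
        locs = np.asarray(t.peak_locations_cm)
        scaled_d = (locs - locs[0]) / (speed * lap_dur)
        peaks = 100.0 + scaled_d * 8.0 * scale + 0.25
        rng = np.random.default_rng(seed)
        if jitter:
            peaks = np.clip(peaks + rng.uniform(-jitter, jitter,
                                                peaks.size),
                            100.05, 107.9)
        spikes = {i: np.array([pk]) for i, pk in enumerate(peaks)}
        cand = CandidateSequence("rotation", ev, (0, 1, 2, 3, 4),
                                 tuple(peaks))
        return cand, t, spikes, speed, lap_dur

    def test_proportional_timing_zero_gap_and_negative_z(self):
        cand, t, spikes, speed, lap_dur = self.build_case()
        gd = time_gap_difference(cand, t, spikes, mean_speed_cm_s=speed,
                                 mean_lap_duration_s=lap_dur,
                                 rng=np.random.default_rng(1))
        assert gd.mean_abs_diff < 0.01
        assert gd.z < 0
        assert np.all((gd.delta_d >= 0) & (gd.delta_d <= 1))
        assert np.all((gd.delta_t >= 0) & (gd.delta_t <= 1))

    def test_order_preserving_random_times_centred_null(self):
        zs = []
        for rep in range(30):
            cand, t, spikes, speed, lap_dur = self.build_case(
                jitter=2.0, seed=rep)
            gd = time_gap_difference(
                cand, t, spikes, mean_speed_cm_s=speed,
                mean_lap_duration_s=lap_dur,
                rng=np.random.default_rng(rep))
            zs.append(gd.z)
        assert abs(np.mean(zs)) < 1.0  # null-like timing: z centred near 0

    def test_single_pair_defined(self):
        t = TemplateSequence("A_to_B", (0, 1, 2, 3, 4),
                             (20.0, 60.0, 100.0, 140.0, 180.0))
        ev = RotationEvent(0.0, 10.0, "CCW", 360.0)
        spikes = {0: np.array([2.0]), 1: np.array([6.0])}
        cand = CandidateSequence("rotation", ev, (0, 1), (2.0, 6.0))
        gd = time_gap_difference(cand, t, spikes, mean_speed_cm_s=40.0,
                                 mean_lap_duration_s=4.0,
                                 rng=np.random.default_rng(0))
        expect = abs(40.0 / 160.0 - 0.4)
        assert gd.mean_abs_diff == pytest.approx(expect, abs=0.01)
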