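"""Template construction, rank-order sequence matching, and time gaps.

A *template sequence* orders a day's common cells by their place-field
peak locations on one track trajectory (cells qualify when their rate
curve peaks at least 3 SD above its mean; templates need >= 5 cells). A
*rotation sequence* orders the template cells active in one box rotation
event by the peak angles of their within-event circular rate curves; a
*ripple sequence* orders active cells by peak firing time within a ripple
event.

Because rotation events are circular, the rotation match score is the
maximum absolute Spearman rank correlation between the template and all
circular shifts of the candidate; ripple sequences use the plain Spearman
correlation. Per-sequence significance shuffles the candidate's cell
identities 1000 times and requires the actual score to exceed 95% of the
shuffled scores (strict inequality, so with discrete nulls a 5-cell
circular sequence can never reach significance — rotations and
reflections of 5 cells already occupy >5% of its permutation null).
Group-level significance recounts matches under 200 independently
randomized template sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import PositionSeries, RippleEvent, RotationEvent
from .tuning import RateCurve, _bin_circular, smooth1d

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSequence",
    "CandidateSequence",
    "MatchResult",
    "GroupMatchResult",
    "GapDifference",
    "build_templates",
    "extract_rotation_sequence",
    "extract_ripple_sequence",
    "circular_match_score",
    "rank_match_score",
    "sequence_match_significance",
    "ripple_match",
    "count_matching_sequences",
    "time_gap_difference",
]

MIN_SEQUENCE_CELLS = 5
MATCH_PERCENTILE = 0.95


@dataclass(frozen=True)
class TemplateSequence:
    """>= 5 common cells ordered by peak firing location on a trajectory."""

    trajectory: str
    cell_ids: tuple[int, ...]
    peak_locations_cm: tuple[float, ...]

    def __post_init__(self):
        if len(self.cell_ids) < MIN_SEQUENCE_CELLS:
            raise ValueError("template needs at least 5 cells")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in template")
        locs = np.asarray(self.peak_locations_cm)
        if np.any(np.diff(locs) < 0):
            raise ValueError("cells must be ordered by peak location")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def ranks_of(self, cells: Sequence[int]) -> np.ndarray:
        """Template order of ``cells``, re-ranked to 0..n-1."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        raw = np.array([pos[c] for c in cells])
        return np.argsort(np.argsort(raw))


@dataclass(frozen=True)
class CandidateSequence:
    """Ordered cells observed in one rotation or ripple event."""

    source: str  # "rotation" | "ripple"
    event: object
    cell_ids: tuple[int, ...]
    order_keys: tuple[float, ...]  # peak angle (deg) or peak time (s)

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class MatchResult:
    score: float  # max |rank correlation|, in [0, 1]
    signed_best: float  # the signed correlation attaining the score
    null_scores: np.ndarray
    is_match: bool
    n_cells: int


@dataclass
class GroupMatchResult:
    n_candidates: int
    n_matches: int
    null_match_counts: np.ndarray
    p_value: float
    p_label: str
    #: which candidates matched the actual templates (same order as input)
    matched: Optional[np.ndarray] = None

    @property
    def match_rate_pct(self) -> float:
        if self.n_candidates == 0:
            return float("nan")
        return 100.0 * self.n_matches / self.n_candidates


@dataclass
class GapDifference:
    pairs: tuple[tuple[int, int], ...]
    delta_d: np.ndarray  # rescaled track time gaps (mean lap length = 1)
    delta_t: np.ndarray  # rescaled event time gaps (event length = 1)
    mean_abs_diff: float
    z: float
    null: np.ndarray


# ---------------------------------------------------------------------------
# templates and candidate extraction
# ---------------------------------------------------------------------------

def build_templates(
    rate_curves_by_trajectory: Mapping[str, Mapping[int, RateCurve]],
    common_cells: Sequence[int],
    *,
    min_cells: int = MIN_SEQUENCE_CELLS,
    peak_sd_criterion: float = 3.0,
) -> dict[str, TemplateSequence]:
    """Build up to one template per trajectory from common-cell curves.

    A cell qualifies when its trajectory rate curve has a prominent peak:
    peak rate >= ``peak_sd_criterion`` standard deviations above the
    curve's mean rate (the highest peak is used when there are several,
    i.e. the global argmax). Trajectories with fewer than ``min_cells``
    qualifying common cells yield no template.
    """
    common = set(int(c) for c in common_cells)
    templates: dict[str, TemplateSequence] = {}
    for trj, curves in rate_curves_by_trajectory.items():
        entries = []
        for cid, curve in curves.items():
            if int(cid) not in common:
                continue
            r = curve.rates
            sd = r.std()
            if r.size == 0 or sd == 0 or \
                    r.max() < r.mean() + peak_sd_criterion * sd:
                continue  # no prominent peak (flat curves never qualify)
            entries.append((curve.peak_location_cm, int(cid)))
        entries.sort()
        if len(entries) >= min_cells:
            templates[trj] = TemplateSequence(
                trajectory=trj,
                cell_ids=tuple(c for _, c in entries),
                peak_locations_cm=tuple(loc for loc, _ in entries),
            )
    logger.info("built %d template(s): %s", len(templates),
                {t: len(s) for t, s in templates.items()})
    return templates


def extract_rotation_sequence(
    event: RotationEvent,
    template_cells: Sequence[int],
    spikes_by_cell: Mapping[int, np.ndarray],
    position: PositionSeries,
    *,
    min_cells: int = MIN_SEQUENCE_CELLS,
    bin_deg: float = 5.0,
    sigma_bins: float = 2.0,
) -> Optional[CandidateSequence]:
    """Rotation sequence: template cells ordered by within-event peak angle.

    Peak angles come from each cell's circular rate curve computed over
    this event alone, taken relative to 0 deg (the opening). Ties in peak
    angle are broken by earlier first spike, then by cell id. Returns None
    when fewer than ``min_cells`` template cells fired in the event.
    """
    entries = []
    for cid in template_cells:
        st = np.asarray(spikes_by_cell.get(cid, ()), dtype=float)
        in_ev = st[(st >= event.start_s) & (st < event.end_s)]
        if in_ev.size == 0:
            continue
        _, counts, occ = _bin_circular(in_ev, position, [event], None,
                                       bin_deg)
        sm_occ = smooth1d(occ, sigma_bins, circular=True)
        sm_cnt = smooth1d(counts.astype(float), sigma_bins, circular=True)
        rates = np.divide(sm_cnt, sm_occ, out=np.zeros_like(sm_cnt),
                          where=sm_occ > 0)
        peak_angle = (np.argmax(rates) + 0.5) * bin_deg
        entries.append((float(peak_angle), float(in_ev[0]), int(cid)))
    if len(entries) < min_cells:
        return None
    entries.sort()
    return CandidateSequence(
        source="rotation", event=event,
        cell_ids=tuple(c for _, _, c in entries),
        order_keys=tuple(a for a, _, _ in entries))


def _peak_firing_time(spikes: np.ndarray, start: float, end: float,
                      sigma_s: float, grid_s: float = 0.001) -> float:
    """Peak of the Gaussian-smoothed instantaneous rate within [start, end)."""
    if spikes.size == 0:
        raise ValueError("cell has no spikes within the event")
    grid = np.arange(start, end, grid_s)
    rate = np.exp(-0.5 * ((grid[:, None] - spikes[None, :]) / sigma_s) ** 2
                  ).sum(axis=1)
    return float(grid[int(np.argmax(rate))])


def extract_ripple_sequence(
    ripple: RippleEvent,
    template_cells: Sequence[int],
    spikes_by_cell: Mapping[int, np.ndarray],
    *,
    min_cells: int = MIN_SEQUENCE_CELLS,
    sigma_s: float = 0.010,
) -> Optional[CandidateSequence]:
    """Ripple sequence: active template cells ordered by peak firing time."""
    entries = []
    for cid in template_cells:
        st = np.asarray(spikes_by_cell.get(cid, ()), dtype=float)
        in_ev = st[(st >= ripple.start_s) & (st < ripple.end_s)]
        if in_ev.size == 0:
            continue
        pk = _peak_firing_time(in_ev, ripple.start_s, ripple.end_s, sigma_s)
        entries.append((pk, int(cid)))
    if len(entries) < min_cells:
        return None
    entries.sort()
    return CandidateSequence(
        source="ripple", event=ripple,
        cell_ids=tuple(c for _, c in entries),
        order_keys=tuple(t for t, _ in entries))


# ---------------------------------------------------------------------------
# match scores
# ---------------------------------------------------------------------------

def _spearman_no_ties(d_sq_sum: np.ndarray, n: int) -> np.ndarray:
    return 1.0 - 6.0 * d_sq_sum / (n * (n * n - 1))


def _circular_scores(cand_ranks: np.ndarray, template_ranks: np.ndarray,
                     circular: bool) -> tuple[float, float]:
    """Max |Spearman| over circular shifts (or the plain value)."""
    n = cand_ranks.size
    shifts = np.arange(n)[:, None] if circular else np.zeros((1, 1), int)
    shifted = (cand_ranks[None, :] + shifts) % n
    d = shifted - template_ranks[None, :]
    rho = _spearman_no_ties(np.sum(d * d, axis=1), n)
    k = int(np.argmax(np.abs(rho)))
    return float(np.abs(rho[k])), float(rho[k])


def _scores_many(cand_ranks: np.ndarray, template_ranks: np.ndarray,
                 circular: bool) -> np.ndarray:
    """Scores of many candidate rank rows (S, n) against one template."""
    S, n = cand_ranks.shape
    if circular:
        shifts = np.arange(n)
        shifted = (cand_ranks[:, None, :] + shifts[None, :, None]) % n
        d = shifted - template_ranks[None, None, :]
        rho = _spearman_no_ties(np.sum(d * d, axis=2), n)
        return np.max(np.abs(rho), axis=1)
    d = cand_ranks - template_ranks[None, :]
    return np.abs(_spearman_no_ties(np.sum(d * d, axis=1), n))


def circular_match_score(
    seq: CandidateSequence | Sequence[int],
    template: TemplateSequence,
) -> tuple[float, float]:
    """Circular match score between a rotation sequence and a template.

    Every circular shift of the candidate order is rank-correlated
    (Spearman) with the template order restricted to the shared cells; the
    score is the maximum absolute correlation and ``signed_best`` its
    signed value (negative when the orders are reversed).
    """
    cells = list(getattr(seq, "cell_ids", seq))
    shared = [c for c in cells if c in template.cell_ids]
    if len(shared) < 2:
        raise ValueError("need >= 2 shared cells to score")
    cand_ranks = np.arange(len(shared))
    return _circular_scores(cand_ranks, template.ranks_of(shared), True)


def rank_match_score(
    seq: CandidateSequence | Sequence[int],
    template: TemplateSequence,
) -> tuple[float, float]:
    """Plain |Spearman| match score (ripple sequences are not circular)."""
    cells = list(getattr(seq, "cell_ids", seq))
    shared = [c for c in cells if c in template.cell_ids]
    if len(shared) < 2:
        raise ValueError("need >= 2 shared cells to score")
    cand_ranks = np.arange(len(shared))
    return _circular_scores(cand_ranks, template.ranks_of(shared), False)


def _null_scores(n: int, n_shuffles: int, rng: np.random.Generator,
                 circular: bool) -> np.ndarray:
    """Identity-shuffle null: scores of random candidate permutations.

    The null distribution depends only on the number of shared cells n —
    a shuffled candidate's ranks are a uniform random permutation whatever
    the template order — so callers may cache it per n.
    """
    perms = rng.permuted(np.tile(np.arange(n), (n_shuffles, 1)), axis=1)
    return _scores_many(perms, np.arange(n), circular)


def _is_match(score: float, null: np.ndarray) -> bool:
    return np.count_nonzero(null < score) > MATCH_PERCENTILE * null.size


def sequence_match_significance(
    seq: CandidateSequence | Sequence[int],
    template: TemplateSequence,
    *,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
    circular: Optional[bool] = None,
    shuffle_scope: str = "candidate",
) -> MatchResult:
    """Per-sequence significance from 1000 cell-identity shuffles.

    ``shuffle_scope="candidate"`` permutes the candidate's own cells;
    ``"template"`` redraws the candidate as a random same-size subset of
    the full template in random order (the two are equivalent in
    distribution — the restricted, re-ranked template order of a random
    subset is a uniform permutation — but both are available). A sequence
    matches when its score strictly exceeds 95% of the shuffled scores.
    """
    rng = rng or np.random.default_rng()
    cells = list(getattr(seq, "cell_ids", seq))
    shared = [c for c in cells if c in template.cell_ids]
    n = len(shared)
    if n < MIN_SEQUENCE_CELLS:
        raise ValueError(
            f"candidate retains {n} template cells (< {MIN_SEQUENCE_CELLS})")
    if circular is None:
        circular = getattr(seq, "source", "rotation") == "rotation"
    t_ranks = template.ranks_of(shared)
    score, signed = _circular_scores(np.arange(n), t_ranks, circular)

    if shuffle_scope == "candidate":
        perms = rng.permuted(np.tile(np.arange(n), (n_shuffles, 1)), axis=1)
        null = _scores_many(perms, t_ranks, circular)
    elif shuffle_scope == "template":
        m = len(template)
        subs = np.array([rng.choice(m, size=n, replace=False)
                         for _ in range(n_shuffles)])
        sub_ranks = np.argsort(np.argsort(subs, axis=1), axis=1)
        null = np.array([
            _circular_scores(np.arange(n), sr, circular)[0]
            for sr in sub_ranks])
    else:
        raise ValueError("shuffle_scope must be 'candidate' or 'template'")

    return MatchResult(score=score, signed_best=signed, null_scores=null,
                       is_match=_is_match(score, null), n_cells=n)


def ripple_match(
    seq: CandidateSequence | Sequence[int],
    template: TemplateSequence,
    *,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> MatchResult:
    """Per-ripple-sequence significance (plain rank correlation, no shifts)."""
    return sequence_match_significance(
        seq, template, n_shuffles=n_shuffles, rng=rng, circular=False)


# ---------------------------------------------------------------------------
# group-level significance
# ---------------------------------------------------------------------------

def count_matching_sequences(
    candidates: Sequence[CandidateSequence],
    templates: Mapping[str, TemplateSequence] | Sequence[TemplateSequence],
    *,
    n_template_sets: int = 200,
    n_shuffles: int = 1000,
    rng: Optional[np.random.Generator] = None,
    min_cells: int = MIN_SEQUENCE_CELLS,
) -> GroupMatchResult:
    """Matching-sequence count with 200-template-set randomization.

    A candidate is a matching sequence when it significantly matches at
    least one template (per-sequence 1000-shuffle rule). The null recounts
    matches after permuting every template's cell identities, fresh per
    set; p is the fraction of randomized sets with strictly more matches
    than observed (reported as "<1/n_sets" when zero). The per-sequence
    shuffle null is cached per shared-cell count n, which is exact in
    distribution (see :func:`_null_scores`).
    """
    rng = rng or np.random.default_rng()
    tmpl_list = list(templates.values()) if isinstance(templates, Mapping) \
        else list(templates)
    if not tmpl_list:
        raise ValueError("at least one template required")
    if not candidates:
        warnings.warn("no candidate sequences; p = 1 by convention")
        return GroupMatchResult(0, 0, np.zeros(n_template_sets, dtype=int),
                                1.0, "1", matched=np.zeros(0, dtype=bool))

    null_cache: dict[tuple[int, bool], np.ndarray] = {}

    def null_for(n: int, circular: bool) -> np.ndarray:
        key = (n, circular)
        if key not in null_cache:
            null_cache[key] = np.sort(
                _null_scores(n, n_shuffles, rng, circular))
        return null_cache[key]

    # pre-compute, per (candidate, template): candidate cells' positions in
    # the template and the cached null
    pairings = []  # (cand_idx, tmpl_idx, idx_in_template, circular)
    for ci, cand in enumerate(candidates):
        circ = cand.source == "rotation"
        for ti, tmpl in enumerate(tmpl_list):
            pos = {c: i for i, c in enumerate(tmpl.cell_ids)}
            idx = np.array([pos[c] for c in cand.cell_ids if c in pos])
            if idx.size >= min_cells:
                pairings.append((ci, ti, idx, circ))

    def count_matches(perm_by_template) -> np.ndarray:
        matched = np.zeros(len(candidates), dtype=bool)
        for ci, ti, idx, circ in pairings:
            if matched[ci]:
                continue
            raw = idx if perm_by_template is None \
                else perm_by_template[ti][idx]
            t_ranks = np.argsort(np.argsort(raw))
            n = idx.size
            score, _ = _circular_scores(np.arange(n), t_ranks, circ)
            null = null_for(n, circ)
            if np.searchsorted(null, score, side="left") > \
                    MATCH_PERCENTILE * null.size:
                matched[ci] = True
        return matched

    matched_actual = count_matches(None)
    n_matches = int(matched_actual.sum())
    null_counts = np.empty(n_template_sets, dtype=int)
    for k in range(n_template_sets):
        perms = [rng.permutation(len(t)) for t in tmpl_list]
        null_counts[k] = int(count_matches(perms).sum())

    p = float(np.mean(null_counts > n_matches))
    label = f"<{1.0 / n_template_sets:g}" if p == 0 else f"{p:g}"
    logger.info("matching sequences: %d/%d actual, null median %g, p=%s",
                n_matches, len(candidates), float(np.median(null_counts)),
                label)
    return GroupMatchResult(
        n_candidates=len(candidates), n_matches=n_matches,
        null_match_counts=null_counts, p_value=p, p_label=label,
        matched=matched_actual)


# ---------------------------------------------------------------------------
# time gaps
# ---------------------------------------------------------------------------

def time_gap_difference(
    seq: CandidateSequence,
    template: TemplateSequence,
    spikes_by_cell: Mapping[int, np.ndarray],
    *,
    mean_speed_cm_s: float,
    mean_lap_duration_s: float,
    n_shuffles: int = 200,
    rng: Optional[np.random.Generator] = None,
    sigma_s: float = 0.100,
) -> GapDifference:
    """Are relative firing times in a matching sequence track-like?

    For cells with neighbouring peaks on the track (consecutive in
    template order, restricted to the sequence's cells), the track time
    gap is peak-location distance / mean running speed, rescaled so the
    mean lap length is 1; the event time gap is the interval between the
    cells' peak firing times (100 ms Gaussian-smoothed rate) with the
    event rescaled to length 1. The statistic is the mean absolute gap
    difference |delta_d - delta_t| over pairs, z-scored against
    ``n_shuffles`` order-preserving randomizations of the event peak
    times (sorted uniform draws assigned in the observed firing order).
    """
    rng = rng or np.random.default_rng()
    ev = seq.event
    start, end = ev.start_s, ev.end_s
    dur = end - start

    # order the sequence's cells by track peak location
    loc = {c: l for c, l in zip(template.cell_ids,
                                template.peak_locations_cm)}
    cells = [c for c in seq.cell_ids if c in loc]
    if len(cells) < 2:
        raise ValueError("need >= 2 cells present in the template")
    track_order = sorted(cells, key=lambda c: loc[c])
    pairs = tuple(zip(track_order[:-1], track_order[1:]))

    delta_d = np.array([
        abs(loc[b] - loc[a]) / mean_speed_cm_s / mean_lap_duration_s
        for a, b in pairs])

    peak_t = {}
    for c in cells:
        st = np.asarray(spikes_by_cell[c], dtype=float)
        st = st[(st >= start) & (st < end)]
        peak_t[c] = (_peak_firing_time(st, start, end, sigma_s) - start) / dur
    delta_t = np.array([abs(peak_t[b] - peak_t[a]) for a, b in pairs])
    actual = float(np.mean(np.abs(delta_d - delta_t)))

    # order-preserving null: random scaled peak times, observed order kept
    obs_order = np.argsort([peak_t[c] for c in cells])  # cells by peak time
    n = len(cells)
    u = np.sort(rng.uniform(0.0, 1.0, size=(n_shuffles, n)), axis=1)
    # cell at observed-order position j gets the j-th sorted uniform
    cell_index = {c: i for i, c in enumerate(cells)}
    pos_in_order = np.empty(n, dtype=int)
    pos_in_order[obs_order] = np.arange(n)
    shuffled_peaks = u[:, pos_in_order]  # (S, n) keyed by cells list order
    ia = np.array([cell_index[a] for a, _ in pairs])
    ib = np.array([cell_index[b] for _, b in pairs])
    null_dt = np.abs(shuffled_peaks[:, ib] - shuffled_peaks[:, ia])
    null = np.mean(np.abs(delta_d[None, :] - null_dt), axis=1)
    sd = null.std(ddof=1)
    z = float((actual - null.mean()) / sd) if sd > 0 else float("nan")
    return GapDifference(pairs=pairs, delta_d=delta_d, delta_t=delta_t,
                         mean_abs_diff=actual, z=z, null=null)
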