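"""Common-cell accounting: active-cell classification, chance proportion,
and the proportion difference index (PDI).

A putative pyramidal cell counts as *active* in an environment when its
mean firing rate inside that environment's events (rotation events in the
box, lap-running events on a track trajectory), with stopping periods
excluded, lies in [0.5, 6] Hz; rates above 6 Hz mark putative
interneurons. Cells active in both environments are *common cells*.

Under the null hypothesis that the box and a track trajectory recruit two
independent random subsets of the N recorded cells, the expected
proportion of common cells is (n_t/N) * (n_b/N); the PDI
(P_act - P_chance)/(P_act + P_chance) in [-1, 1] measures how far the
observed overlap exceeds it. Note that only the population-denominator
form of the actual proportion, n_common/N, is comparable to that chance
formula under independence; the trajectory-denominator form n_common/n_t
is the day-level bookkeeping behind statements like "51% of running-active
cells were common". Both are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import as_intervals, in_intervals, intervals_subtract, \
    intervals_total

logger = logging.getLogger(__name__)

ACTIVE_RATE_RANGE_HZ = (0.5, 6.0)

__all__ = [
    "PairingCounts",
    "PDIResult",
    "mean_rate_in_events",
    "classify_active_cells",
    "chance_proportion",
    "actual_proportion",
    "proportion_difference_index",
    "pairing_analysis",
    "percentage",
]


@dataclass(frozen=True)
class PairingCounts:
    """Cell counts for one box-session x track-trajectory pairing."""

    n_total: int  # putative pyramidal cells recorded that day (N)
    n_track: int  # cells active on the trajectory (n_t)
    n_box: int  # cells active in the box session (n_b)
    n_common: int  # cells active in both

    def __post_init__(self):
        if not (0 <= self.n_common <= min(self.n_track, self.n_box)
                <= max(self.n_track, self.n_box) <= self.n_total):
            raise ValueError(
                "require 0 <= n_common <= min(n_t, n_b) <= N; got "
                f"{self}")


@dataclass(frozen=True)
class PDIResult:
    p_act: float
    p_chance: float
    pdi: float


def percentage(part: int | float, whole: int | float) -> float:
    """Simple percentage helper used by the bookkeeping reports."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return 100.0 * part / whole


def mean_rate_in_events(spike_times: np.ndarray, events, stops=None) -> float:
    """Mean firing rate (Hz) within events, stop periods excluded."""
    intervals = intervals_subtract(as_intervals(events), stops)
    total = intervals_total(intervals)
    if total <= 0:
        return float("nan")
    st = np.asarray(spike_times, dtype=float)
    return float(np.count_nonzero(in_intervals(st, intervals)) / total)


def classify_active_cells(
    spikes_by_cell: Mapping[int, np.ndarray],
    rotation_events=None,
    lap_events_by_trajectory: Optional[Mapping[int | str, Sequence]] = None,
    box_stops=None,
    track_stops=None,
    rate_range_hz: tuple[float, float] = ACTIVE_RATE_RANGE_HZ,
) -> pd.DataFrame:
    """Per-cell activity rates and day-level classification.

    Returns a DataFrame indexed by cell id with the mean rate in rotation
    events (``box_rate``), per-trajectory lap rates, per-environment active
    flags (rate within ``rate_range_hz``), and a ``label`` column in
    {common, rotation_only, running_only, inactive}. A cell above 6 Hz in
    one environment is excluded from that environment's active set only.
    """
    lo, hi = rate_range_hz
    lap_events_by_trajectory = lap_events_by_trajectory or {}
    rows = {}
    for cid, st in spikes_by_cell.items():
        row = {}
        box_rate = (mean_rate_in_events(st, rotation_events, box_stops)
                    if rotation_events else float("nan"))
        row["box_rate"] = box_rate
        row["box_active"] = bool(np.isfinite(box_rate) and
                                 lo <= box_rate <= hi)
        track_active = False
        for trj, laps in lap_events_by_trajectory.items():
            r = (mean_rate_in_events(st, laps, track_stops)
                 if laps else float("nan"))
            row[f"rate_{trj}"] = r
            act = bool(np.isfinite(r) and lo <= r <= hi)
            row[f"active_{trj}"] = act
            track_active |= act
        row["track_active"] = track_active
        if row["box_active"] and track_active:
            row["label"] = "common"
        elif row["box_active"]:
            row["label"] = "rotation_only"
        elif track_active:
            row["label"] = "running_only"
        else:
            row["label"] = "inactive"
        rows[int(cid)] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    logger.info("classified %d cells: %s", len(df),
                df["label"].value_counts().to_dict() if len(df) else {})
    return df


def chance_proportion(counts: PairingCounts) -> float:
    """Expected common-cell proportion under independent random activation:
    (n_t / N) * (n_b / N)."""
    if counts.n_total <= 0:
        raise ValueError("N must be positive")
    return (counts.n_track / counts.n_total) * \
        (counts.n_box / counts.n_total)


def actual_proportion(counts: PairingCounts,
                      denominator: str = "track") -> float:
    """Observed common-cell proportion.

    ``denominator="track"`` gives n_common / n_t (proportion of
    trajectory-active cells that are common; the day-level bookkeeping
    form). ``denominator="population"`` gives n_common / N, the form
    directly comparable with :func:`chance_proportion` under independence
    and the one used in the pairing/PDI analysis.
    """
    if denominator == "track":
        if counts.n_track <= 0:
            raise ValueError("n_track must be positive for the "
                             "track-denominator form")
        return counts.n_common / counts.n_track
    if denominator == "population":
        return counts.n_common / counts.n_total
    raise ValueError("denominator must be 'track' or 'population'")


def proportion_difference_index(p_act: float, p_chance: float) -> float:
    """PDI = (P_act - P_chance) / (P_act + P_chance), in [-1, 1].

    NaN when both proportions are zero (undefined).
    """
    if p_act < 0 or p_chance < 0:
        raise ValueError("proportions must be non-negative")
    denom = p_act + p_chance
    if denom <= 0:
        return float("nan")
    return (p_act - p_chance) / denom


def pairing_analysis(
    track_active_by_trajectory: Mapping[str, set],
    box_active_by_session: Mapping[str, set],
    n_total: int,
    day: str = "",
) -> pd.DataFrame:
    """PDI table over all box-session x track-trajectory pairings.

    ``track_active_by_trajectory`` maps trajectory label -> set of active
    cell ids; ``box_active_by_session`` maps box-session label (e.g.
    pre_box/post_box) -> set of cell ids active in that session's rotation
    events (the per-pairing n_b uses the single session, while day-level
    common-cell classification pools Pre+Post elsewhere). One row per
    pairing — up to 4 per day — with both actual-proportion variants and
    the PDI from the population-denominator form.
    """
    rows = []
    for ses, box_set in box_active_by_session.items():
        for trj, trk_set in track_active_by_trajectory.items():
            common = set(box_set) & set(trk_set)
            counts = PairingCounts(n_total=n_total, n_track=len(trk_set),
                                   n_box=len(box_set), n_common=len(common))
            p_chance = chance_proportion(counts)
            p_act = actual_proportion(counts, denominator="population")
            p_act_track = (actual_proportion(counts, denominator="track")
                           if counts.n_track else float("nan"))
            rows.append({
                "day": day, "session": ses, "trajectory": trj,
                "N": counts.n_total, "n_t": counts.n_track,
                "n_b": counts.n_box, "n_common": counts.n_common,
                "p_act": p_act, "p_act_track": p_act_track,
                "p_chance": p_chance,
                "pdi": proportion_difference_index(p_act, p_chance),
            })
    return pd.DataFrame(rows)
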