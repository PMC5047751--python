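"""Pipeline configuration with defaults matching the recording protocol.

Every tunable of the analysis lives here so that a single YAML file (or a
``PipelineConfig(...)`` call) reproduces or overrides the protocol: 2 cm
track bins and 5-degree arches smoothed with sigma = 2 bins, the 0.5-6 Hz
active-cell band, the z > 1.645 significance criterion, the 3 SD template
peak rule with >= 5 cells, 1000 per-sequence / 200 template-set shuffles,
the 4 / 2.5 SD ripple thresholds in the 100-250 Hz band, >3 s stops, the
+/-45 degree opening zone with 180 degree minimum rotation span, and the
10 cm reward-zone exclusion.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # geometry
    track_length_cm: float = 200.0
    box_size_cm: float = 25.0
    opening_center_deg: float = 0.0
    reward_zone_cm: float = 10.0
    # binning & smoothing
    bin_cm: float = 2.0
    bin_deg: float = 5.0
    map_bin_cm: float = 1.0
    sigma_bins: float = 2.0
    min_occupancy_s: float = 0.1
    # behavioural events
    opening_zone_half_deg: float = 45.0
    min_rotation_span_deg: float = 180.0
    end_zone_cm: float = 10.0
    stop_speed_cm_s: float = 2.0
    stop_min_dur_s: float = 3.0
    # cell classification & significance
    active_rate_min_hz: float = 0.5
    active_rate_max_hz: float = 6.0
    z_criterion: float = 1.645
    rayleigh_min_spikes: int = 10
    # sequences
    template_peak_sd: float = 3.0
    min_sequence_cells: int = 5
    n_sequence_shuffles: int = 1000
    n_template_sets: int = 200
    n_consistency_shuffles: int = 1000
    n_demo_shuffles: int = 1000
    n_gap_shuffles: int = 200
    rotation_rate_sigma_s: float = 0.100
    ripple_rate_sigma_s: float = 0.010
    # ripple detection
    ripple_band_low_hz: float = 100.0
    ripple_band_high_hz: float = 250.0
    ripple_peak_sd: float = 4.0
    ripple_edge_sd: float = 2.5
    ripple_envelope_smooth_s: float = 0.004
    ripple_merge_gap_s: float = 0.030
    ripple_min_dur_s: float = 0.050
    ripple_max_dur_s: float = 0.400

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        defaults = cls()
        overrides = {k: v for k, v in raw.items()
                     if getattr(defaults, k) != v}
        if overrides:
            logger.info("config overrides from %s: %s", path, overrides)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
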