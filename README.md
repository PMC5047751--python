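# crossact

Analysis of **cross-environment activation** of hippocampal place-cell
patterns: do the firing sequences a rat's CA1 cells express while running
laps on a linear track also appear while the same rat merely sits in a
small box nearby, watching another rat run?

The package re-implements the full analysis chain for paired box/track
recording sessions as a tested Python library with a thin CLI:

- **Event detection** — body-rotation events in the box (head turns
  ≥ 180° starting and ending within ±45° of the box opening), lap-running
  events on the track, stop periods (> 3 s of immobility), and
  sharp-wave-ripple events in the LFP (100–250 Hz band, 4 SD peak /
  2.5 SD boundary thresholds), plus LFP power spectra and behavioural
  summaries.
- **Tuning statistics** — linear rate curves (2 cm bins, reward zones
  excluded), circular head-direction rate curves (72 × 5° arches), 2-D
  rate maps (1 cm grid), all smoothed with a σ = 2-bin Gaussian; Skaggs
  spatial information (bits/spike), Rayleigh head-direction tests,
  lap consistency, *rotation-consistency* (z-scored mean cross-event
  curve correlation against a curve-rotation shuffle null), and
  demonstrator-position tuning z-scored against within-lap circular
  spike-train shifts.
- **Common-cell accounting** — cells active (mean rate 0.5–6 Hz) both in
  box rotation events and in track lap-running are *common cells*. For
  each box-session × trajectory pairing the observed common-cell
  proportion `P_act` is compared with the chance proportion under
  independent random activation, `P_chance = (n_t/N)(n_b/N)`, through the
  proportion difference index
  `PDI = (P_act − P_chance)/(P_act + P_chance) ∈ [−1, 1]`.
- **Sequence matching** — ≥ 5 common cells ordered by place-field peak
  (peak ≥ 3 SD above the curve mean) form a per-trajectory *template*;
  rotation events are scored by the maximum |Spearman rank correlation|
  over all circular shifts of the within-event firing order, ripples by
  the plain rank correlation. Per-sequence significance uses 1000
  cell-identity shuffles (match ⇔ score > 95% of shuffles); group-level
  significance recounts matches under 200 randomized template sets.
  Time-gap analysis asks whether relative firing times inside matching
  sequences are proportional to track field spacing.
- **Synthetic sessions** — a seeded generator producing the whole study
  structure (directional Gaussian place fields on a 2 m track, von-Mises
  HD tuning in a 25 × 25 cm box, a configurable order-preserving overlap
  between the two populations, Poisson spiking, theta/ripple LFP
  surrogates, injectable replay) so every stage is testable without real
  recordings.

## Worked example

```python
import numpy as np
import crossact as ca
from crossact.pipeline import run_pipeline

day = ca.simulate_day(ca.SimConfig(seed=2, cross_activation_fraction=0.6))
report = run_pipeline(day, seed=3)

print(report["classification"]["counts"])
print([round(p["pdi"], 3) for p in report["pairings"]])
print(report["sequence_matching"])
```

prints (exactly, for these seeds):

```
{'inactive': 24, 'common': 21, 'running_only': 9, 'rotation_only': 6}
[0.217, 0.285, 0.206, 0.263]
{'n_candidates': 38, 'n_matches': 32, 'match_rate_pct': 84.2105...,
 'p_value': 0.0, 'p': '<0.005'}
```

With 60% of track-active cells forced to share order-preserved tuning in
the box, 21 of 60 cells come out as common, every pairing's PDI is
positive, and 32 of 38 rotation sequences match a same-day track template
— far more than any of the 200 randomized template sets produce
(p < 0.005). Re-running with `cross_activation_fraction=0` gives PDIs
scattered around 0 and a non-significant match count.

The same chain is available from a shell:

```bash
crossact simulate --out day1 --seed 2
crossact report --day day1 --out day1_results --seed 3
```

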