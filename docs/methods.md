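# Methods

## The analysis in brief

A recording day pairs sessions in which a rat sits in a small open-sided
box (Pre-box, Post-box) with a session in which it runs a 2 m linear
track. The question is whether track-running firing structure is
expressed in the box. The chain is: segment behaviour into events;
classify cells as active per environment; compare the observed overlap
of the two active populations with its chance level; and test whether
multi-cell firing *order* is preserved between track laps and box
rotation events (and, separately, within sharp-wave ripples).

All intervals are half-open `[start, end)` seconds, positions cm, head
direction (HD) degrees in [−180, 180) relative to the box opening
(0° = facing the opening), with counter-clockwise positive.

## Event detection

**Rotation events.** The HD trace is unwrapped; an event runs from the
last sample inside the ±45° opening zone before the head leaves it to
the first zone sample after it returns, and is kept when the maximal
unwrapped excursion reaches 180°. Direction is the sign of that
excursion. Because the criterion uses the net unwrapped excursion, brief
counter-rotations from tracking jitter do not split an event; zone
grazings shorter than 0.15 s are ignored for the same reason. An
exclusion mask (grooming/rearing intervals supplied by the experimenter
or the simulator) removes overlapping events — irregular behaviour is
not inferred from the data.

**Laps.** A lap runs between the 10 cm end zones of the track (the
reward sites); an excursion that turns back mid-track yields no lap.

**Stops.** Speed is the centrally-differenced head position smoothed
over 0.5 s; stops are maximal intervals with speed < 2 cm/s lasting
> 3 s. The 3 s minimum is the protocol value; the 2 cm/s cutoff is the
conventional rodent immobility threshold and is configurable (the
protocol does not state one).

**Ripples.** The LFP is band-passed 100–250 Hz (4th-order Butterworth,
zero-phase); the envelope is the rectified signal smoothed with a 4 ms
Gaussian. Thresholds are expressed in standard deviations *of the
band-passed signal* over the whole session — the protocol states its
thresholds in "stds of the filtered LFPs" — which also keeps the
background envelope (mean ≈ 0.8 SD) far from the 4 SD peak criterion.
Events are above-2.5 SD regions containing a ≥ 4 SD peak, merged across
gaps < 30 ms, restricted to the 50–400 ms ripple duration range.
Envelope smoothing, merge gap, and the duration clamp are this package's
choices (the protocol states only the thresholds); all are configurable
and echoed in the logs.

**Spectra.** Spectrograms use 1 s windows every 25 ms with power at
0.5 Hz spacing; the PSD averages columns inside the supplied intervals
and the normalized variant divides by total 0.5–400 Hz power.

## Tuning statistics

Rates are smoothed-count / smoothed-occupancy with a Gaussian kernel of
σ = 2 bins truncated at ±3σ — wrapping circularly for the 72 × 5° HD
arches, renormalizing at the edges for the 2 cm linear bins (90 bins
between the excluded 10 cm reward zones) and the 1 cm box grid. Raw
counts are kept alongside, so spike count is conserved before
smoothing. Bins with under 0.1 s occupancy are excluded from spatial
information and correlations.

**Spatial information** (bits/spike): `SI = Σ p_i (r_i/r̄) log2(r_i/r̄)`
with `p_i` occupancy fractions and `r̄` the occupancy-weighted mean rate.

**Rotation-consistency.** The statistic is the mean Pearson correlation,
across matched 5° bins, between a cell's per-event circular rate curves,
over all unordered pairs of events in which the cell fired. The null
independently rotates every event's curve by a uniform whole-bin angle;
1000 such shuffle sets give the mean and sample SD for the z-score, and
z > 1.645 (one-sided 5%) is called consistent. Implementing the
"circular correlation" as bin-matched Pearson is a deliberate choice:
the shuffle rotates whole curves, which is only meaningful for a
bin-matched statistic. A Fisher–Lee circular–circular correlation is
exported for paired angle samples (`tuning.fisher_lee_correlation`), but
it applies to angle pairs, not bin-matched curves, so it is not an
alternative statistic inside rotation-consistency.

**Demonstrator-position tuning.** An observer cell's spikes are related
to the *demonstrator's* track position: spatial information from the
all-laps mean curve, lap consistency as the mean pairwise Pearson
correlation of per-lap curves (cells active in ≥ 2 laps). The null
circularly shifts the spike train within each lap by an independent
uniform offset, 1000 times; both statistics are z-scored against their
shuffle distributions and z ≥ 1.645 is significant. The whole shuffle
ensemble is evaluated vectorised (one `bincount`/convolution per
ensemble), which keeps 500 cells × 1000 shuffles under a minute. Because
the statistic of an untuned cell is exchangeable with its shuffles, the
test's false-positive rate should sit at the nominal 5% — the
calibration the acceptance script measures. (The z-score criterion is
not an exact percentile rule; skew in the null can move the realised
rate a point or two, which the simulation quantifies.)

**Rayleigh test.** Head-direction significance of spike-time HDs within
rotation events uses `pingouin.circ_rayleigh`, with a configurable
minimum of 10 spikes.

## Common cells, chance proportion, PDI

A putative pyramidal cell is *active* in an environment when its mean
rate inside that environment's events (stops excluded) lies in
[0.5, 6] Hz; above 6 Hz it is treated as a putative interneuron and
excluded from that environment's active set only. Common cells are
active in both environments (box classification pools Pre- and Post-box
rotation events at day level; each pairing uses the single box session's
events — both variants appear in the pairing table).

For a pairing of a box session with a track trajectory, with `N`
recorded cells, `n_t` trajectory-active, `n_b` box-active and `n_common`
common, the chance proportion under independent random activation is
`(n_t/N)(n_b/N)`. Two observed-proportion conventions exist:
`n_common/n_t` (share of trajectory-active cells that are common — the
day-level bookkeeping behind statements like "51% of running-active
cells were common") and `n_common/N`. Only the population-denominator
form has expectation equal to the chance formula under independence
(E[n_common] = n_t·n_b/N), so the PDI analysis uses `P_act = n_common/N`;
the other form is reported alongside. `PDI = (P_act − P_chance) /
(P_act + P_chance)`. Note that PDI is a concave function of `P_act`, so
its null mean carries a small negative finite-count bias even though
`P_act − P_chance` itself is centred on zero; both quantities are
checked in the tests.

## Sequence matching

**Templates.** Per trajectory, common cells whose rate curve peaks
≥ 3 SD above its mean (highest peak if several) are ordered by peak
location; ≥ 5 cells make a template (≤ 2 per day).

**Candidates.** A rotation event with ≥ 5 active template cells yields a
rotation sequence ordered by within-event circular-curve peak angle
(ties: earlier first spike, then cell id). A ripple event with ≥ 5
active cells yields a ripple sequence ordered by peak firing time
(spike trains smoothed with a 10 ms Gaussian inside ripples, 100 ms
inside rotation events — the protocol does not state these widths; both
are configurable).

**Scores.** Rotation sequences: maximum |Spearman| between the template
order and every circular shift of the candidate order (rank correlations
computed on shared cells re-ranked 0..n−1; candidates must retain ≥ 5
template cells). Ripple sequences: plain |Spearman|. Perfect forward and
reversed orders both score 1 (signed +1 / −1).

**Per-sequence significance.** 1000 shuffles of the candidate's cell
identities; a sequence matches when its score strictly exceeds 95% of
shuffled scores. With discrete nulls this strict rule is conservative:
for 5 cells the 10 rotations/reflections already occupy 1/12 of the
circular permutation null, so a perfect 5-cell circular match can never
be significant — an intrinsic property of the method, reproduced by the
exhaustive-permutation oracle in the tests. An alternative shuffle scope
(redrawing candidates from the full template) is provided; it is
equivalent in distribution.

**Group significance.** The number of matching sequences (matching ≥ 1
same-day template) is compared with the counts obtained from 200 sets of
identity-permuted templates; p is the fraction of sets with strictly
more matches, reported as "< 0.005" when zero. Because the
identity-shuffle null depends only on the shared-cell count n, the group
routine caches one 1000-shuffle null per n and reuses it across
candidates and template sets — exact in distribution and verified
against honest per-sequence shuffles. Sharing thresholds correlates
decisions slightly across candidates within one call; the per-sequence
API draws fresh nulls.

**Time gaps.** For a matching sequence, consecutive cells in track-peak
order give a track gap (peak distance / mean lap running speed, scaled
so the mean lap duration is 1) and an event gap (peak-time difference
with the event scaled to length 1); the statistic is the mean |Δd − Δt|
over pairs, z-scored against 200 order-preserving randomizations of the
event peak times (sorted uniform draws assigned in the observed firing
order).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis
assumes, not hippocampal biophysics. Defaults are the quantified
behavioural values — 19 laps per trajectory of ~5.8 s, 19 rotation
events of ~6.67 s per box session, ~0.3 ripple bursts per second of
immobility — and conventional cell parameters where the protocol gives
none: 60 cells per day, half track-active and 45% box-active (matching
the recorded ~49%/43% active fractions), 10 Hz field peaks over a 0.2 Hz
baseline, 20 cm (FWHM) Gaussian fields with per-cell directionality, von
Mises HD tuning with κ ≈ 4 in the box. The `cross_activation_fraction`
forces that share of track-active cells to be box-active with preferred
angles mapped from their field centres (shared random offset, jitter
bounded below half the minimal angular gap, so circular order is
preserved exactly); the remaining box cells are drawn independently, so
the fraction 0 reduces to independent random activation and the expected
overlap grows monotonically with the fraction.

The LFP surrogate is pink noise plus an 8 Hz theta sinusoid during
movement and 150 Hz flat-top bursts during immobility; background
ripple-band noise is damped inside burst windows (the transient
dominates the band, and this removes tone/noise beating) and burst
amplitudes are iteratively calibrated so each achieved envelope peak
matches the requested SD level. Injected replays place one spike per
template cell, forward or reversed, inside a burst.

Not emulated: theta-phase structure (precession), realistic spike
waveforms or sorting errors, rate remapping dynamics within sessions,
overdispersion beyond Poisson, behavioural idiosyncrasies (grooming,
rearing), or volume-conducted LFP structure. Passing tests therefore
demonstrate that the *pipeline* recovers the structure it is designed to
detect at realistic rates and sample sizes — not that real recordings
would behave this way.

All stochastic components draw from named child streams of one master
seed (`SimConfig.seed`), so identical configs give identical sessions;
analysis-side shuffles take explicit `numpy.random.Generator`s and every
report records its seed and shuffle counts.

## Numerical choices and degenerate inputs

- z-scores use the sample SD (ddof = 1) of the shuffle distribution;
  shuffle counts are 1000 (per-sequence, consistency, demonstrator
  tuning) and 200 (template sets, time gaps).
- Cells active in < 2 events/laps give undefined consistency (reported
  as not-significant with a reason, or NaN), not an error; zero-spike
  inputs propagate NaN statistics.
- Zero occupancy over all bins, mixed-trajectory lap lists, LFP below
  600 Hz, and sessions shorter than the filter warm-up raise errors.
- Pearson correlations drop constant curves; lap consistency requires
  ≥ 2 active laps.
- Test and acceptance problem sizes (20 replicate days per condition,
  200–500 simulated cells per calibration, 300–1000 shuffles in module
  tests) were chosen as the smallest sizes whose Monte-Carlo error is
  well inside the asserted tolerances.

## Known limitations

- The strict "> 95% of shuffles" rule makes 5-cell circular candidates
  unmatchable (see above); the effective minimum for rotation sequences
  is 6 cells, which the match-rate bookkeeping inherits.
- The chance-proportion model treats cells as exchangeable; systematic
  rate differences between environments (violating the 0.5–6 Hz band
  symmetry) would bias PDI in real data.
- Demonstrator-tuning z-scores inherit null skew from the smoothed-curve
  statistics; the realised false-positive rate is calibrated by
  simulation rather than assumed.
- The CLI analyses one day at a time; multi-day aggregation is a thin
  concatenation left to the user (condition labels are carried through
  the tables).
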