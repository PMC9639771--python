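# Methods

This note documents the models and numerical choices behind `neuromech`: what
the synthetic experiment generator emulates, how each analysis stage is
defined, which parameters matter and why their defaults were chosen, and what
the passing tests do and do not establish about real recordings.

## The measurement chain being modelled

During an isometric contraction, fluctuations in the common synaptic drive to
a motoneuron pool appear successively in three observable signals: the pooled
motor-unit firing activity (cumulative spike train, CST), the shortening of
muscle fascicles imaged in the same region, and finally the torque measured
at the dynamometer. The pipeline quantifies the band-limited coupling between
these signals and the latencies separating them, and expresses motor-unit
recruitment/de-recruitment thresholds in both the torque and the
fascicle-length coordinate systems.

## Synthetic trials (`simdata`)

**Motoneuron pool.** Seven units (the typical decomposition yield with
32-channel ultrasound-transparent grids) with recruitment thresholds on an
exponential ladder, `t_i = t_min · R^((i−1)/(n−1))`, range `R = 30` and
`t_min = 0.5 %MVC` so the whole pool is recruited below a 20 %MVC target.
Rate coding is linear above threshold: 8 Hz at recruitment, gain
0.5 Hz/%MVC, saturating at 35 Hz. The gain was set so the pooled mean rate on
a 20 %MVC plateau is ≈15 Hz, matching the discharge rates the emulated
recordings typically show. Discharges are a renewal process: each interval is
`1/rate(E(t))` scaled by `max(0.1, 1 + 0.15·z)` with standard-normal `z`
(multiplicative jitter, CV 0.15; the 0.1 floor forbids non-physiological
short intervals). A unit's first discharge falls exactly at its threshold
crossing.

**Protocols.** Ramp-hold: 10 %MVC/s ramps, 30-s plateau at 20 or 40 %MVC,
2048-Hz sampling, 80-fps imaging. Sinusoidal mode replaces the plateau with a
0.5-Hz, ±2.5 %MVC modulation. Excitation is open loop (drive proportional to
the torque target): real subjects close the loop visually, but open-loop
drive preserves the statistical structure the analysis consumes while keeping
every trial exactly reproducible.

**Mechanics.** The drive `s(t)` is the CST smoothed with a zero-phase 400-ms
unit-area Hann kernel (wide enough to suppress individual firings, narrow
enough to pass the 0.75–2 Hz analysis band) and normalized so its plateau
mean equals the target level. Then

    shortening(t) = k_f · s(t − Δf)        torque(t) = s(t − Δf − Δt)

with `Δf = Δt = 75 ms` by default, injected as **pure integer-sample shifts**
so the ground-truth lags are exact (at 2048 Hz, 75 ms quantizes to
75.195 ms, the value stored as truth). `k_f` is calibrated per trial so a
20 %MVC plateau shortens the fascicle by the configured amount (7.5 mm for
the short-muscle preset, rest length 60.2 mm; a long-muscle preset with
74.5 mm rest length is included). Pennation is affine in shortening
(15.2°→19.2° over 7.5 mm for the short preset), with no curvature. A
`causal-kernel` mode replaces the shifts with a critically damped kernel
`(t/τ²)e^(−t/τ)` for realism; its effective band-limited group delay must
then be measured, not assumed, so all delay-recovery tests use pure-shift
mode.

**Noise.** Torque noise (0.25 %MVC) and per-frame fascicle noise (0.15 mm,
typical tracking precision) are the study conditions. Torque noise is
band-limited (white noise lowpassed at 5 Hz): white sensor noise at 2048 Hz
carries almost no power in the 0.75–2 Hz band and would make the correlation
analysis trivially clean.

**EMG.** Each unit has a random 32-channel MUAP template (Gaussian-windowed,
slightly skewed oscillation; amplitude decays with grid distance from a
random centre; onset lag and phase drift across the grid mimic propagation
and tissue filtering and make independently seeded units mutually
dissimilar). The recording is the linear superposition of templates at the
discharge times plus white noise.

**Ultrasound.** A speckle background with the fascicle (plus faint parallel
neighbours) and the central aponeurosis drawn at rest geometry is rendered
once; frame *k* warps it with the affine that fixes the aponeurosis line
pointwise and maps the rest fascicle endpoint to the commanded one, so every
frame encodes length and pennation exactly and the optical flow has a
recoverable affine ground truth. The synthetic field of view (100 × 40 mm at
0.25 mm/px) is wider than a 60-mm probe so the full fascicle stays visible;
real probes see only ~80 % of a fascicle, which the renderer does not
emulate. One rising trigger edge per frame is written into a 2048-Hz binary
channel.

**Seeding.** A master seed fans out into named sub-streams (ISI jitter, EMG
noise, torque noise, fascicle noise, speckle, templates); identical
configuration and seed give a bit-identical trial.

## Analysis

**Cleaning (`spiketools`).** Discharges closer than 20 ms are collapsed onto
the first of the cluster (deterministic replacement for manual editing);
intervals above 250 ms are flagged as missing-pulse gaps but never imputed,
since re-estimating pulses requires the decomposition internals. Mean rate
uses `(n−1)/span` over the window rather than `n/window`, which is unbiased
for sparse trains; smoothed rate traces use a unit-area 400-ms Hann kernel
(the 0.5-Hz sinusoidal modulation is still resolved).

**SIL.** The silhouette score is reimplemented from its operational
definition — relative height of the claimed source peaks over the baseline
peaks: squared amplitudes of claimed peaks and of all other positive local
maxima are pooled, split by two-class 1-D k-means (centroids initialised at
min/max), and the score is `(d_between − d_within)/max(d_between, d_within)`
with summed squared distances of the claimed peaks to the low/high centroid.
Exact agreement with any particular decomposition package's internal variant
is not claimed. Acceptance gate 0.86 by default (32-channel grids warrant a
less conservative gate than the usual 0.90); it is a configuration value.

**MUAP tracking.** Spike-triggered averages over a ±25-ms window; matching
maximizes the zero-mean normalized correlation of the channel-concatenated
templates over global shifts within ±10 ms, with the 0.80 match gate. A
shifted copy scores ≈1 (only the truncated window tail, a few 1e-3 of the
energy, is lost).

**Conditioning and lags (`xcorrlag`).** "4th-order zero-phase Butterworth"
is read as a 4th-order design applied forward-backward (effective 8th-order
magnitude). The windowed estimator computes, per fully contained 5-s window,
the per-lag Pearson correlation over the overlapping samples — identical by
construction to a brute-force per-lag `corrcoef` oracle, which the tests
enforce. Peak = signed maximum; ties resolve to the smallest |lag|; no
sub-sample interpolation (0.49-ms resolution is far below the delays of
interest); search range ±1 s. The CST enters conditioning as the raw summed
binary train — the 2-Hz lowpass is the smoothing. Signed window lags are
averaged (not lags of |peak|).

A caveat established while validating the zero-phase contract: the
raw-vs-conditioned correlation peak is only well posed when the raw signal
has in-band structure. For broadband inputs the peak is nearly flat
(relative curvature ~1e-5 per sample) and any finite-sample estimator
scatters its location by a few samples through magnitude reweighting; this
is a gain effect, not a group delay, and it has zero mean. Tests therefore
assert exact 0 lag for in-band tones and a ≤5-ms, zero-mean bound for
broadband noise.

**Segmentation and thresholds (`thresholds`).** Onset/offset: torque above
2 %MVC sustained for 100 ms. Plateau: longest run with the 500-ms-smoothed
torque within ±25 % of target (a band that also contains the sinusoidal
modulation, so one code path serves both protocols), trimmed while the
smoothed slope exceeds 2 %MVC/s and then widened by the known half-kernel
corner blur. These boundary criteria are declared, not derived from any
particular dataset. Thresholds are read at the discharge sample itself, with
flags for tonic units and units recruited after the ramp.

**Cohort pipeline (`study`).** Subjects are simulation seeds with ±10 %
uniform jitter on rest length, delays and MVC torque so group dispersion is
nonzero; n = 10 by default. Marginal effects collapse the other factors
within subject and take a paired t contrast with a 95 % CI; Bonferroni
adjustment is applied per contrast family. With a single subject row set
(e.g. a table of printed condition means) only the collapsed mean difference
is defined and CI/p are NaN — this is how the worked-example arithmetic on
the embedded reference tables is computed. An omnibus repeated-measures
ANOVA is deliberately not part of the surface; contrasts with CIs are.

**Tracking (`fastrack`).** Forward-additive Gauss–Newton on the six affine
parameters, 3-level Gaussian pyramid, bilinear sampling, convergence when
the ROI-corner displacement update falls below 1e-3 px (max 50 iterations
per level). The ROI is the fascicle bounding box dilated by 20 px.
Frame-to-frame transforms are composed with no key-frame re-anchoring;
drift is accepted and measured against synthetic truth (≈0.3 mm RMSE over
an 880-frame ramp-hold sequence). Rest length defaults to the frame-0
value, with an explicit override for a rest-window average. Pennation can be
taken from the tracked geometry per frame or recomputed from a re-digitized
geometry; both entry points exist. Resampling to the EMG clock positions
each frame value at its trigger-edge sample and evaluates a cubic spline at
every sample in between.

## Problem sizes used by the test suite and acceptance script

Delay recovery and threshold statistics use ten 38-s trials; the
render-and-track check uses an 11-s ramp-hold (880 frames at 80 fps,
400 × 160 px) with a 6-s plateau; Monte-Carlo checks (ISI CV, SIL
monotonicity, CI coverage, template dissimilarity) use 5–1000 replicates as
noted in each test. These sizes were chosen as the smallest at which the
quantities of interest are statistically stable.

## Known limitations

- The plant is linear, open loop and delay-pure: no force–length/velocity
  dependence, no tendon elasticity, no feedback tracking error, no fatigue.
- Because torque is a right-shifted copy of the drive, the torque read at a
  unit's recruitment (rising drive) is systematically *below* its drive
  threshold and the read at de-recruitment is above it: the simulated
  recruitment-minus-de-recruitment difference in %MVC is ≈ −2·(ramp
  rate)·(total delay), i.e. negative. Empirically the opposite sign is
  observed in humans; that direction is attributed to motoneuron
  de-recruitment hysteresis (persistent inward currents) and passive
  fascicle re-lengthening during relaxation, none of which this plant
  includes — by design, so that delay ground truth stays exact. The
  corresponding acceptance test records this as an open discrepancy rather
  than hiding it; what the model does reproduce is the coordinate
  dependence itself: the torque-coordinate gap grows linearly with the
  transmission delay while the fascicle-length gap is independent of it.
- Fascicle-coordinate threshold symmetry holds only up to the drive→fascicle
  delay times the local shortening rate (~0.6 mm under the default
  conditions) plus discharge-timing quantization.
- The renderer warps one static speckle pattern; real ultrasound decorrelates
  speckle under out-of-plane motion, so tracking performance on these
  sequences is an upper bound on real-data performance.
- Synthetic EMG is an additive template model with white noise; it is not a
  volume-conductor simulation and is not meant to be decomposed.
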