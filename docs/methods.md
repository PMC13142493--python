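# Methods

This note documents the models and numerical choices behind `scgate`: what
the synthetic-data generator simulates and why, how each analysis stage is
defined, and what the test suite's recoveries do and do not establish.

## Generative model

### Spiking

Each neuron is an inhomogeneous Poisson process. Around every stimulus
onset the rate is

    r(t) = r0 + a_phase · K_vis(t)

where `r0` is the baseline (default 10 spikes/s, typical of visually
responsive SC neurons and well above the 1 spike/s inclusion floor) and
`K_vis` is a fixed response kernel: the sum of two log-normal-shaped bumps
peaking at 50 ms and 90 ms (weight 0.35 for the second), essentially zero
before 30 ms. The kernel is normalized so that its mean over the 30–130 ms
response window equals 1; the amplitude `a` therefore *is* the neuron's
expected evoked ΔFR in spikes/s, which makes ground truth directly
comparable to the pipeline's estimate. Saccade-locked firing uses a
raised-cosine burst kernel peaking 10 ms before saccade onset (half-width
30 ms), normalized the same way over the −50…+25 ms window. Spikes are
drawn per 1 ms bin (Poisson counts, uniform jitter within the bin), so the
expected count in any window equals the integral of the rate — the
conservation property the tests check at 1% with 10⁴ trials.

### Population structure

Between-neuron evoked amplitudes are truncated normals. The truncation
floor for visually responsive classes defaults to 12 spikes/s rather than
zero: a neuron enters the "visual" or "visual-movement" pool only after
functional classification, which requires a clearly detectable visual
response, and a power calculation (Poisson rates, 150 trials/phase,
rank-sum at 0.05/115) puts per-neuron detection power at ≈0.99 for a
12 spikes/s response but ≈0.17 at 5 spikes/s. A zero-floor population would
contain members that classification could never have admitted. The parent
location of the truncated normal is re-solved numerically so the realized
population mean equals the configured mean.

Inactivation acts multiplicatively: each neuron's During amplitude is its
Before amplitude times a shared class gain (the ratio of configured
During/Before class means). This reproduces both the population means and
the per-neuron Before-vs-During correlation structure; independent
per-phase draws would destroy the latter. Motor amplitudes are drawn once
per neuron and used identically in every phase — the scenario contract is
that inactivating the visual relay spares motor drive.

Scenario presets encode the study conditions: the LGN scenario uses class
means 48.8 → 1.0 (visual) and 22.8 → 0.4 spikes/s (visual-movement) with 90
+ 25 visually responsive and 7 movement neurons; the dual-inactivation
scenario adds a third phase with the same visual gain (no rescue) and slows
saccades into the inactivated field by a factor 0.75; the V1 scenario sets
the During gain to one minus a per-session suppression fraction. For the
pooled V1 population the full-overlap session uses 0.95 and one partial
session 0.78 (both published); the two remaining partial sessions are not
individually published and default to 0.40 and 0.31 so that, with session
neuron counts (14, 14, 14, 13), the neuron-weighted ground-truth mean
equals the published population mean of 61.5%.

### Behavior and eye movements

Guided-saccade outcomes are Bernoulli draws from the ground-truth scotoma —
a rotated Gaussian failure surface evaluated at the target (During) or a
flat floor (Before; 13% for the LGN preset, 10.4% for V1, matching the
session averages they emulate). The default scotoma has amplitude 0.85 and
offset 0.05, so the failure probability at the RF-center target is exactly
0.90. Successful trials plant a saccade to the target (endpoint jitter
0.3°/axis) 150–350 ms after the go cue; failed trials leave the eye at
fixation, the behavioral signature of an unseen target. Outcomes stored in
the trial table are produced by running the actual detector and scoring
rule on the generated trace, not copied from the Bernoulli draw, so the
behavioral chain is exercised end to end.

Eye traces are sampled at 1 kHz. Fixational noise is band-limited (white
noise smoothed over ~20 ms, rescaled to the configured 0.05° SD) — white
position noise at 1 kHz would imply implausible velocity noise and defeat
any threshold detector. Planted saccades follow a raised-cosine velocity
profile with main-sequence duration `D = 2.2·amplitude + 21 ms`, giving
peak velocity `2A/D` that grows with amplitude; every planted saccade of
≥ 1° exceeds the 30°/s threshold and ≥ 2° exceeds the 8000°/s² criterion,
so planted events are recoverable by construction.

### Laminar MUA

Threshold crossings are generated per channel once at the −3 SD level and
*thinned* for deeper thresholds — physically, a −5 SD crossing is also a
−3 SD crossing — so per-channel event counts are exactly non-increasing in
|θ|. Survival follows `exp(−(|θ|−3)/λ)` (λ = 1 for noise and genuine MUA)
with two finite-amplitude cutoffs that shape the threshold sweep:

- channels **above** the true surface carry a weak volume-conducted copy of
  the evoked response (15 crossings/s at −3 SD, decaying over 150 µm and
  with λ = 0.8) whose waveforms never exceed 4.8 SD of the channel noise —
  lenient thresholds therefore bias the estimated surface dorsally, while
  −5 SD and beyond exclude the conducted signal entirely;
- genuine multiunit waveforms peak between 5 and 6 SD (uniform per
  channel), so the deepest thresholds (−5.5, −6) lose channels
  heterogeneously and break the run-of-three rule unpredictably.

Between these two failure modes the cross-session correspondence between
MUA-derived and single-unit-derived surface estimates peaks at −5 SD,
which is what the threshold-selection procedure is designed to find. Driven
channels span the surface down to ~600 µm at full strength, tapering to
zero by ~1.1 mm, mirroring the depth profile of visual drive in SC.

## Analysis choices

- **Windows** (ms, half-open, relative to the event): visual 30–130 vs
  −100–0; saccadic −50–+25 vs −300–−200; early MUA 30–80. Half-open
  `[start, end)` avoids double-counting boundary spikes.
- **Differentiation**: 5-sample boxcar on position (edge-padded), central
  difference for velocity, central difference of speed for acceleration.
  Detected onsets/offsets are refined from the threshold crossing back to
  the local speed minimum (floored at a third of the velocity threshold),
  which removes the few-ms lag of threshold crossing behind movement onset.
- **Candidate merging**: above-threshold intervals separated by < 10 ms are
  merged before the duration test, so a single saccade is not split by a
  one-sample dip at its velocity trough.
- **Acceptance window**: the 3° square endpoint window is interpreted as
  side length 3° (half-width 1.5°), configurable.
- **Scotoma fit**: plain least squares over non-missing bins, predictions
  not clipped to [0,1] (clipping applies only when simulating outcomes);
  multi-start initialization (center at the max-failure bin and at the
  weighted centroid, σ ∈ {2°, 6°}, φ ∈ {0, π/4}) guards against the
  rotation/width local minima of rotated Gaussians; the result is
  canonicalized to σx ≥ σy with φ wrapped to [0, π). Bins are unweighted
  regardless of trial count.
- **Overlap**: both shapes polygonized with ≥ 512 vertices and clipped
  exactly (shapely); agreement with a 10⁶-point rejection-sampling oracle
  is within 0.01.
- **Rank tests**: exact Wilcoxon enumeration below n = 25 without ties,
  normal approximation otherwise; all-zero difference vectors return p = 1.
  The Bonferroni family for per-neuron tests is the set of neurons tested
  within the same inactivation condition. The population signed-rank is
  two-sided by default (configurable); the residual and band tests are
  one-sided as their hypotheses dictate.
- **FDR**: Benjamini–Hochberg at q = 0.05 across the 32 probe channels.
- **Threshold-selection tie-break**: smaller |θ| wins (more events, more
  stable estimates).
- **Regression weights**: per-condition neuron counts, since conditions
  summarize unequal numbers of neurons; CIs by bootstrap over conditions.
- **Alignment**: ignore-missing population means over depth; channels
  shifted beyond the probe extent are missing.

## Replication runs and problem sizes

`scgate.study` rebuilds each headline comparison at its published size
(115, 25, 15, and 55 neurons; 150 trials/phase; 8 behavioral sessions of 40
RF-center trials/phase; 12 overlap conditions with 8-point condition
noise). Cohort-level statistics are reported as the mean over eight
replicate simulated cohorts of the prescribed size: the replicate average
estimates the expected value of the cohort statistic with ~√8 less
Monte-Carlo error while leaving the cohort design untouched. Sweeps use 50
seeds (motor sparing) and 200 seeds (overlap correlation); calibration
suites use 1000 seeds. These sizes keep the full suite around a minute on
one core.

## What the synthetic recoveries show — and what they do not

Passing tests establish that the pipeline is *internally correct*: it
recovers known ground truth at realistic effect sizes, its statistics are
calibrated under null generators, and its geometry agrees with independent
oracles. The generator does not emulate several properties of real
recordings: spike-sorting errors and drift, non-Poisson firing (burstiness,
refractoriness), correlated noise across neurons and channels, eye-tracker
artifacts beyond a validity mask, stimulus-identity effects (stimulus type
is a categorical label only), or biophysical mechanisms of muscimol spread.
Recovery on synthetic sessions therefore validates the analysis code, not
the biological claims; with real data the same entry points consume the
documented CSV formats.

Known limitations: percent reduction is undefined (NaN) for neurons whose
measured Before ΔFR is non-positive, as in the source analyses, and such
neurons drop out of cohort means; the scotoma fit is unconstrained, so
amplitude + offset may exceed 1 on noisy maps; the dual-inactivation
velocity check uses spontaneous in-RF saccades as a proxy for saccades into
the inactivated field.
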