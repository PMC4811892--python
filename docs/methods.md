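# Methods

This note documents the models and procedures the package implements, the
choices made where the experimental literature leaves the design open, and
what the synthetic-data tests do and do not establish.

## Acoustic CI simulation (vocoder)

The degraded-speech condition is produced by an eight-channel sinewave
vocoder over 100 Hz–10 kHz. Channel edges are equally spaced along the
basilar membrane using Greenwood's frequency–position map
`F(x) = A(10^{ax} − k)`; the constants are the conventional human
parameterisation `A = 165.4 Hz`, `a = 2.1` (with `x` the proportion of
cochlear length), `k = 0.88`, exposed in `GreenwoodMap`. Per channel, the
amplitude envelope is extracted by half-wave rectification followed by a
4th-order Butterworth low-pass at 300 Hz with unit DC gain, and the output
is the sum of sinusoids at the channel centre frequencies modulated by
those envelopes.

Open choices, fixed as follows:

* **Band-split filters.** The envelope filter's order is part of the design;
  the band-split filters' is not. We use 4th-order Butterworth band-passes
  applied forward–backward (`sosfiltfilt`), i.e. zero phase, so that splice
  timing is never shifted by group delay. Order and phase mode are
  configurable (`VocoderConfig.band_order`, `zero_phase`).
* **Centre frequencies.** The Greenwood midpoint of each band (midpoint in
  cochlear position mapped back to Hz), consistent with place-based
  spacing; geometric and arithmetic means are available as options.
* **Carrier phase.** 0 at signal start — deterministic, seedless.
* **Sampling.** Inputs whose rate is below `2·f_hi` are rejected rather
  than silently resampled; resampling would alter the sample count that
  carries the durational cue.

Invariants enforced by tests: output length equals input length for every
input; edge positions are equally spaced in cochlear place to 1e−9; the
envelope of a stationary unit sine has DC `1/π` within 2%; vocoded noise
shows the eight carrier peaks; re-vocoding keeps the same carrier set.

## Stimulus construction

Critical items pair a polysyllabic target with a monosyllabic competitor
embedded in its first syllable. Cross-splicing combines the first part of
one token (up to its marked boundary) with the second part of another (from
its own boundary): Condition 1 (target-matching duration cues) splices two
recordings of the polysyllabic sentence; Condition 2 (target-mismatching)
puts the longer monosyllabic first part before the same polysyllabic
second part. Concatenation is sample-exact — no resampling or windowing —
so the duration difference between conditions is carried unchanged through
vocoding (length conservation above). Cut points are optionally snapped to
the nearest zero crossing within 5 ms to avoid clicks; this is an
engineering convenience, not part of the original procedure.

The synthetic inventory reproduces the materials' structure: 26 critical
pairs plus 40 fillers (7 polysyllabic / 33 monosyllabic; 20 without
competitor, 10 with initial and 10 with final embedding). The
mono-minus-poly first-syllable duration difference is drawn from
`20 + 100·Beta(2.25, 2.75)` ms: support [20, 120] ms and mean exactly
65 ms, matching the reported range and mean (a uniform draw would force a
mean of 70 ms). Tokens for listening are harmonic complexes with a
speech-like 3–5 Hz amplitude contour — stand-ins that carry the boundary
and duration structure, not natural speech.

## Ocular preprocessing

Traces are 250-Hz samples of gaze and pupil area with a validity flag;
blinks appear as runs of invalid/zero-pupil samples. Rules:

* Blinks **shorter than 300 ms** are linearly interpolated between the
  medians of the 25 valid samples before and after the gap (gaze x/y are
  repaired the same way so AOI labelling sees no hole).
* Trials with a blink of **300 ms or longer**, or with an incorrect click,
  are excluded. The verbal rule ("shorter than" interpolated, "longer
  than" excluded) leaves exactly 300 ms unassigned; we exclude it —
  conservative — and the threshold is configurable.
* Participants whose excluded trials reach **50%** of the session are
  dropped.

%ERPD = (observation − baseline)/baseline × 100. Baseline 1 is the mean
pupil area in the 200 ms before the target word, per trial; baseline 2 is
the mean over the 200 ms immediately preceding the first sentence of the
session, per participant (the anchor "very beginning of the experiment" is
otherwise unspecified). All windows are half-open `[start, end)` with
0-based sample indexing; the 200–2000 ms analysis window at 250 Hz is
exactly 450 samples. Fixation counting uses a minimum dwell of 80 ms
(unspecified in the source; a common fixation-duration floor). The
fixation growth-curve window is 200–1800 ms while the general analysis
window is 200–2000 ms; both are parameters with those defaults.

## Fixation analysis

The display splits the screen 3×3; pictures sit centred in the four corner
quadrants and are treated as their whole quadrant (matching the
quadrant-centred layout); the centre cell holds the fixation cross, edge
cells carry no AOI. Proportion-of-fixation curves are per-time-sample
means over trials, grouped by condition × presentation; 95% CIs are a
normal approximation over participant mean curves (the CI construction is
not specified in the source; a participant bootstrap is available behind
`ci_method="bootstrap"`).

The crossover time — when the target curve overtakes the competitor's — is
the first time with target strictly above competitor that persists for at
least 100 ms (default). A persistence criterion makes the reading
well-defined on noisy curves; identical curves have no crossover. The
display smoother is locally weighted linear regression (tricube weights,
span 0.5); it reproduces constants and straight lines and is used for
figures only, never for statistics.

## Growth-curve analysis

Time courses are modelled on an orthonormal polynomial basis built by QR
orthogonalisation of raw powers over the observed grid (times are first
affinely mapped to [−1, 1], so fits are invariant to affine rescaling of
the time axis). Terms: intercept, slope, rise-and-fall around the
inflection, tail curvature, plus a quartic for the fixation model (order 4
logistic); %ERPD uses order 3 with an identity link. Fixed effects are the
basis terms and their interactions with Condition and Presentation
(centred treatment contrasts); every participant gets random coefficients
on all basis terms with diagonal covariance.

Estimation contract:

* identity link with random effects — `statsmodels` `MixedLM` by maximum
  likelihood (not REML, so fixed-effect likelihood-ratio tests are valid);
* logistic link with random effects — an in-package **Laplace
  approximation** to the marginal likelihood (per-participant Newton inner
  loop, L-BFGS-B outer loop over fixed effects and log-SDs; convergence at
  1e−6 relative log-likelihood change, at most 200 iterations). This is
  the same approximation lme4's `glmer` uses by default, and the test
  suite verifies agreement with `glmer` on a fixture as well as exact
  reduction to ordinary least squares / plain logistic regression when the
  random part is removed;
* the fixation response is the per-sample binary fixation indicator
  aggregated to binomial counts per participant × condition × time (an
  equivalent likelihood); an empirical-logit linear mode is offered as the
  faster alternative.

Model comparison follows a sequential ladder: starting from the basis-only
model, each basis term's factor-interaction block is added in term order
and evaluated with a likelihood ratio test (χ² with df equal to the number
of added columns). The ladder is configurable; printed χ² values from the
original human data are not reproduction targets — they depend on
recordings that are not available.

## Synthetic sessions and ground truth

A session is 62 trials, 26 critical (13 target-matching / 13
target-mismatching, interleaved at random) and 36 fillers sampled without
replacement from the 40-item inventory (reconciling the 66-item inventory
with the 62-trial session). Each trial is 3.5 s: sentence onset, target
word at +1000 ms, 2.5 s tail; the session opens with a 1-s lead-in whose
final 200 ms anchor baseline 2. Clicks are correct with probability 0.95.

**Gaze.** A Markov dwell process: switch events arrive at rate `1/τ`
(τ = 300 ms, calibrated so the 200–2000 ms window contains on average
three counted fixations); the state drawn at a switch at time `s` follows
`q(s) = p(s) + τ·p′(s)` (clipped and renormalised), which solves
`dp/dt = (q − p)/τ` — the occupancy probability at every instant therefore
equals the generating curve exactly, not a lagged version of it. Pooled
proportions over 2000 trials per condition match the generating curves
within 0.03 in tests. Target curves rise logistically to an asymptote;
competitor curves rise early and decay after disambiguation; the
target-mismatching condition is a rigid time shift of the target-matching
curves by the preset's crossover offset — 120 ms for the natural-speech
preset, 220 ms (with shallower, slower curves) for the degraded preset,
encoding the qualitative findings as generator presets, not as claims of
reproduction.

**Pupil.** Pupil area = baseline × (1 + template/100), so %ERPD recovers
the stored template exactly on noiseless traces. The natural-speech
template is gamma-shaped, `(t/t_p)^κ e^{κ(1−t/t_p)}`, peaking at
t_p = 1000 ms after word onset (the slow effort response peaks only after
900 ms) with amplitudes 5 / 6.5 / 3.5% for matching / mismatching /
filler; the degraded preset is elevated ~6% already before word onset and
much flatter (κ = 1.2, peak 1300 ms, amplitudes 1.2–2%). On top: AR(1)
noise (ρ = 0.97 at 250 Hz, stationary SD 6 device units), a slow
random-walk drift (SD 8), and Poisson blinks (0.15/trial) with log-normal
durations straddling 300 ms (short mix median 150 ms, long mix median
420 ms, 20% long). No variance figures exist for the original traces; all
noise parameters are free configuration with these defaults.

**End-to-end recovery.** `end_to_end_check` runs simulate → screening/blink
repair → epoching → AOI labelling → pooled proportion curves → crossover
detection. It reports the per-condition crossover (read with persistence
spanning the rest of the window — "target ahead for good") and recovers
the condition offset by least-squares time-alignment of the two
conditions' target-minus-competitor difference curves, which uses the
whole curve rather than a single crossing and is unbiased because the
generating curves are exactly rigid shifts. Sessions for this check are
critical-trials-only (fillers carry no crossover information); several
hundred sessions put the offset SE near 10 ms, sized a priori from the
binomial pointwise SE and the curve slope at the crossing.

## What the synthetic tests do not show

The generator emulates the statistical structure the analyses rely on —
condition-dependent fixation curves, slow dilation templates, blinks,
AR(1) noise — not natural speech, oculomotor main sequences, picture
saliency, or item-level variability (item random effects are out of scope;
the models include participant random effects only, as in the original
analysis). Passing tests establish that the pipeline recovers known ground
truth under these conditions; they do not reproduce the original
participant statistics, which depend on undeposited human data.

## Numerical conventions

Half-open windows, 0-based indexing throughout. Filter warm-up is guarded:
signals shorter than the zero-phase padding raise an explicit error.
Blink repair touches only gap samples and conserves sample count.
Degenerate inputs (empty epochs, truncated trials, baseline windows
overlapping unrepaired gaps) raise rather than pad. All generator
randomness flows from one root seed (`numpy` `default_rng`); two runs with
the same configuration are bit-identical, and pipeline outputs embed the
configuration hash and seed.
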