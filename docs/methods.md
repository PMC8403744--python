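# Methods

This note documents the models, calibrations, and numerical choices behind
`saccadapt`. The package is a *simulator plus analysis pipeline*: every
analysis result it produces is computed from synthetic data generated by
its own observer model, so the analysis code can be validated by parameter
recovery against known ground truth.

## Stimulus model

Displays are modelled in degrees of visual angle with the origin at screen
center and an exact tangent mapping to pixels (51.5 × 29 cm panel at
1920 × 1080 px viewed from 60 cm; black/grey/white luminances 0.21 / 58.33 /
105.70 cd/m²). The canonical representation of a grating display is a 1-D
luminance profile

    L(x) = L_grey · (1 + c · w(2πx/λ + φ)),

with Michelson contrast c and waveform w either a sinusoid (default) or a
square wave. The source material for this paradigm describes "luminance
gratings" without fixing the waveform; both are implemented because the
phase and correlation arithmetic — the part that matters — is identical,
and the waveform is a config field. The grey separator bar and the test
slices are generalised-Gaussian windows exp(−(|y−y₀|/α)^β) acting on
contrast (α = 2.1°, β = 3 inverted for the separator; β = 5 non-inverted
for slices); an inverted window leaves pure grey at its center.

The noise mask is white noise shaped in the frequency domain by a radial
Gaussian amplitude envelope centered at 0.18 cyc/° with width 0.02 cyc/°,
then normalised to Michelson contrast 0.7 around grey. Only the mask's
average spatial frequency and contrast are constrained by the design; the
specific band-pass interpretation here makes the amplitude spectrum peak at
the stated frequency and puts the spectral centroid inside the stated
0.18 ± 0.02 band, which the tests verify by discrete Fourier analysis.

## Experiment designs

Factor levels are fixed to the five study designs (see `design.py`): Δc
levels ±0.28 in 0.04 steps (experiments 1 and 4), a single −0.07
(experiment 2), −0.3…0.2 in 0.05 steps (experiment 3), and a 13-level
asymmetric set (experiment 5). Full crossings with the stated repetitions
give 480, 384, 528, 120-per-block, and 832 trials respectively. For
experiment 3 the printed total (528) implies that grating position and
F_anti are counterbalanced *within* the 8 measurements of each
Δc × blank cell, so the crossing is 11 × 6 × 2 × 2 × 2. Saccade direction
is counterbalanced everywhere; it enters as an explicit design factor only
in experiment 2, where it is needed to reach the printed 384 trials.

Gaze-contingent timing uses a rolling saccade-latency predictor (median of
up to the last 20 realized latencies, initialised at 190 ms). In the
build-up experiment the adaptation-stimulus onset is scheduled so that
`adaptation_onset − target_onset = predicted_latency − intended_duration`,
with the earlier of the two events 1.2 s after trial start; in the decay
experiment adaptation onset is delayed by the predicted latency and the
target appears at 1.5 s, clamping realized adaptation durations near 1.5 s.

## Generative observer

The observer's PSE (in Δc units) as a function of adaptation duration
t_adapt and postsaccadic blank t_blank is

    pse(t_adapt, t_blank) = (1 − e^{−t_adapt/τ}) · P(t_blank),
    P(0) = pse_max,   P(t ≥ 0.1 s) = A·ln(t) + B  (clamped ≤ 0),

with linear interpolation between the anchor and the 0.1 s point. The form
is the simplest pair of monotone curves consistent with the observed
phenomenology (rapidly emerging, log-persistent adaptation); the defaults
are calibrated against the printed group-level magnitudes of the study
this package simulates:

| parameter | default | calibration constraint |
|---|---|---|
| `pse_max` | −0.14 | group PSE after ~1.7 s adaptation, no blank |
| `tau_build_s` | 0.18 s | response proportion 0.39 at probe −0.07 for adaptation ≤ 100 ms |
| `decay_A`, `decay_B` | 0.0198, −0.0693 (ln-seconds) | P(0.1 s) = −0.115, P(1.6 s) = −0.06 |
| `jnd` | 0.077 | group mean JND |
| `lapse_rate` | 0.02 | asymptotes visibly off 0/1 in real fits |
| latency shift/shape/scale | 80 ms / 8 / 13.5 ms | cohort medians 160–235 ms; `latency_scale_for_median` solves the scale for a given cohort median |
| `landing_error_sd_deg` | 0.75° | mid-point of the typical 0.5–1° landing error for ~11° saccades |
| `fixation_jitter_sd_deg` | 0.1° | stable fixation well under the 0.5° exclusion SD |
| `blink_prob` | 0.03 | total exclusion fractions land in the observed 7–9% range |

Responses are Bernoulli draws from the lapse-bounded cumulative Gaussian.
Adaptation is frozen at saccade onset (no further build-up during the
saccade or blank), matching the operational definition of adaptation
duration as adaptation-stimulus onset to saccade onset.

Gaze is synthesised at 1 kHz: fixation jitter is Gaussian-filtered white
noise (20 ms kernel) rescaled to the target SD — smooth enough that its
velocities stay far below detection thresholds; the saccade follows the
displacement profile u − sin(2πu)/(2π) with main-sequence duration
2.2 ms/° + 21 ms and Gaussian landing error; blinks (one per affected
trial, 100–250 ms) freeze the reported position and set the blink flag.
The simulator records ground truth, defining the true saccade onset as the
first millisecond at which the *noise-free* profile exceeds either
detection threshold (22 °/s velocity or 3800 °/s² acceleration, whichever
crossing is earlier — for ~11° saccades the acceleration criterion leads).

What the generator does **not** emulate: inter-individual parameter
variability (all simulated participants share one parameter set unless a
list is supplied, so between-subject SDs of fitted PSEs are much smaller
than in real cohorts and t statistics against zero are correspondingly
larger), visual-field asymmetries (upper vs. lower, central vs.
peripheral — experiment 4's two slice conditions run but produce equal
PSEs), contrast-dependence of adaptation (experiment 5's smaller effect at
high test contrast is not generated), microsaccades/drift, corrective
saccades, and tracker noise beyond the jitter model. Passing recovery
tests therefore demonstrates that the *analysis* pipeline is unbiased
under realistic oculomotor statistics, not that the generator reproduces
every property of human data.

## Saccade detection and exclusions

Offline detection thresholds velocity and acceleration (22 °/s, 3800 °/s²)
on a 5-sample boxcar-smoothed trace; suprathreshold runs merged across
gaps < 20 ms, runs < 4 ms discarded, and event edges refined to the
unsmoothed threshold crossings (the smoothing kernel otherwise lags the
onset by 2–3 ms). These auxiliary constants are exposed as parameters; the
thresholds themselves are the standard tracker settings. Blink-flagged
samples (and their smoothing neighbourhood) never contribute.

The amplitude rule computes F_corr = |amplitude| / λ_corr against the
nearest non-negative integer; trials with distance ≥ 0.25 are excluded
(0.5 is the worst case: the saccade swapped the roles of the gratings).
The unsigned ratio is used, so undershoots of leftward and rightward
targets are treated symmetrically. The remaining rules follow the study
protocol: any blink before mask onset; display switch not inside the
detected saccade; presaccadic horizontal gaze SD > 0.5°; latency > 600 ms
(experiments 1/4/5); adaptation duration off 1.5 s by > 100 ms
(experiment 3). All violated rules are reported, not just the first.

## Analysis

The psychometric fit maximises the Bernoulli likelihood over (μ, ln σ, λ)
with L-BFGS-B, bounds μ within the level range ± its span, σ in
[span/100, 3·span], λ in [0, 0.1], from 10 restarts (first start from a
moment estimate, the rest jittered by a fixed RNG stream), making fits
deterministic. All-identical responses raise a degenerate-fit error.
Optional percentile bootstrap CIs resample trials.

The build-up running average uses the exact bin scheme of the protocol:
bins anchored at 0 ms growing from 150 to 300 ms width, then 300 ms bins
sliding in 1 ms steps to 1400 ms, then bins anchored at 1400 ms shrinking
back to 150 ms. Bins are closed intervals; empty bins are omitted rather
than interpolated, and group curves average participants pointwise over
emitted bins.

The decay fit y = A·ln(x) + B is ordinary least squares on blanks
≥ 100 ms; the model is undefined at x = 0, so the no-blank PSE is reported
separately as an anchor rather than entering the fit. t tests (one-sample,
paired, pooled two-sample) delegate to `scipy.stats`; no multiple-testing
correction is applied (α = 0.05, raw p values).

## Problem sizes and determinism

The test suite simulates single participants (480–528 trials) for unit
checks and 16 participants for the group-recovery check; the acceptance
script runs 16 participants of experiment 1, three 7-participant cohorts
of experiment 2 (the short-adaptation proportion rests on only ~100 trials
per cohort, so cohorts are pooled to shrink its binomial error), and
7 participants of experiment 3. All randomness flows from a single master
seed through spawned `numpy` generator streams: one per participant, so
datasets are reproducible and byte-identical across runs, and reports hash
identically for identical configs.

## Known limitations

- The exponential/logarithmic adaptation dynamics are a phenomenological
  stand-in, not a mechanistic model; only their calibrated magnitudes and
  monotonicity are meaningful.
- PSE is a single scalar per trial; effects specific to visual field,
  slice location, or test contrast are not generated (see above).
- The latency predictor uses all trials with a detected saccade, valid or
  not; the protocol's "previous 20 trials available" is ambiguous on this
  point.
- Square-wave gratings share the sinusoid's phase arithmetic but their
  harmonics are not band-limited; the noise mask's band-pass definition is
  one of several consistent with "Gaussian-filtered" noise.
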