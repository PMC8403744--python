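"""Generative observer: adaptation dynamics, 2AFC responses, and gaze traces.

The observer's state of luminance adaptation sets the point of subjective
equality (PSE) of its contrast judgments. The PSE builds up with
presaccadic adaptation duration as an exponential saturation toward a
maximal shift ``pse_max`` (negative: the correlated grating must be given
extra contrast to look equal), and decays during a postsaccadic blank
following a logarithmic time course anchored at the no-blank value:

    pse(t_adapt, t_blank) = (1 - exp(-t_adapt / tau)) * P(t_blank)
    P(0) = pse_max,  P(t) = decay_A * ln(t) + decay_B  for t >= 0.1 s

Defaults are calibrated so a ~1.7 s adaptation with no blank yields a PSE
of about -0.14 contrast-difference units and a 1.5 s adaptation followed by
a 1.6 s blank about -0.06, the group-level magnitudes of the study design
this package simulates.

Responses are Bernoulli draws from a cumulative-Gaussian psychometric
function with standard deviation ``jnd`` and a symmetric lapse rate.
Gaze is synthesised at 1 kHz: low-pass-filtered fixation jitter, a
shifted-gamma saccade latency, a smooth minimum-jerk-like saccade whose
duration follows the main sequence, Gaussian landing error, and optional
blinks. The simulator records ground truth (latency, saccade onset defined
as the first millisecond at which the noise-free velocity exceeds the
22 deg/s detection threshold) so offline detection can be validated
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import gaze as gz
from .design import (ExperimentSpec, LatencyPredictor, TrialDesign,
                     TEST_DURATION_MS, MASK_DURATION_MS,
                     build_schedule, schedule_onsets_exp2, schedule_onsets_exp3)

_VEL_THRESHOLD = gz.VELOCITY_THRESHOLD


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant."""

    pse_max: float = -0.14            # asymptotic PSE shift (delta-c units)
    tau_build_s: float = 0.18         # build-up time constant
    decay_A: float = 0.019837         # log-decay slope (delta-c per ln-second)
    decay_B: float = -0.069324        # log-decay intercept (delta-c)
    decay_floor_s: float = 0.1        # below this blank, interpolate to the anchor
    jnd: float = 0.077                # cumulative-Gaussian SD (delta-c units)
    lapse_rate: float = 0.02
    latency_shift_ms: float = 80.0    # shifted-gamma latency distribution
    latency_shape: float = 8.0
    latency_scale_ms: float = 13.5
    landing_error_sd_deg: float = 0.75
    fixation_jitter_sd_deg: float = 0.1
    blink_prob: float = 0.03          # per-trial probability of one blink

    def __post_init__(self) -> None:
        if self.jnd <= 0:
            raise ValueError("jnd must be positive")
        if self.pse_max > 0:
            raise ValueError("an adapting observer has pse_max <= 0")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse rate must lie in [0, 0.1]")

    @property
    def latency_median_ms(self) -> float:
        from scipy.stats import gamma
        return self.latency_shift_ms + float(
            gamma.median(self.latency_shape, scale=self.latency_scale_ms))


def latency_scale_for_median(target_median_ms: float, shift_ms: float = 80.0,
                             shape: float = 8.0) -> float:
    """Gamma scale putting the shifted-gamma latency median at a target value.

    Group median latencies differ between cohorts (the study's groups ranged
    roughly 160-235 ms); this solves for the scale parameter of the default
    latency distribution that reproduces a given cohort median.
    """
    from scipy.stats import gamma
    if target_median_ms <= shift_ms:
        raise ValueError("target median must exceed the distribution shift")
    return (target_median_ms - shift_ms) / float(gamma.median(shape))


def true_pse(t_adapt_s: float, t_blank_s: float, params: ObserverParams) -> float:
    """Generating PSE for a given adaptation duration and postsaccadic blank.

    Monotone non-increasing in ``t_adapt`` (more adaptation, more negative
    PSE) with magnitude monotone non-increasing in ``t_blank`` (longer
    blank, weaker effect). The logarithmic decay would diverge at zero
    blank, so the no-blank PSE anchors the curve and blanks below
    ``decay_floor_s`` interpolate linearly to it. The decayed PSE never
    crosses zero.
    """
    if t_adapt_s < 0 or t_blank_s < 0:
        raise ValueError("durations must be non-negative")
    build = 1.0 - np.exp(-t_adapt_s / params.tau_build_s)
    if t_blank_s == 0.0:
        plateau = params.pse_max
    else:
        t = max(t_blank_s, params.decay_floor_s)
        decayed = params.decay_A * np.log(t) + params.decay_B
        decayed = min(decayed, 0.0)
        if t_blank_s < params.decay_floor_s:
            frac = t_blank_s / params.decay_floor_s
            plateau = params.pse_max + frac * (decayed - params.pse_max)
        else:
            plateau = decayed
    return float(build * plateau)


def response_probability(delta_c: float, realized_pse: float,
                         params: ObserverParams) -> float:
    """P("anticorrelated grating looked higher in contrast") at one delta-c."""
    lam = params.lapse_rate
    return lam / 2.0 + (1.0 - lam) * norm.cdf((delta_c - realized_pse) / params.jnd)


def simulate_response(trial: TrialDesign, realized_pse: float,
                      params: ObserverParams, rng: np.random.Generator) -> int:
    """Bernoulli 2AFC judgment: 1 = anticorrelated-higher, 0 = correlated-higher."""
    return int(rng.random() < response_probability(trial.delta_c, realized_pse, params))


# --------------------------------------------------------------------------
# gaze synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GazeGroundTruth:
    """What the simulator actually did, for validating offline analysis."""

    latency_ms: float            # threshold-crossing onset minus target onset
    saccade_onset_ms: float      # first ms with noise-free speed > 22 deg/s
    saccade_offset_ms: float
    movement_start_ms: float     # kinematic start of the saccade profile
    amplitude_deg: float
    landing_x_deg: float
    trigger_time_ms: float       # online switch: first ms with eccentricity > 2 deg
    test_onset_ms: float
    mask_onset_ms: float
    adaptation_duration_ms: float


def _main_sequence_duration_ms(amplitude_deg: float) -> float:
    """Saccade duration from the main sequence: ~2.2 ms/deg + 21 ms."""
    return 2.2 * abs(amplitude_deg) + 21.0


def _smooth_step(u: np.ndarray) -> np.ndarray:
    """Unit displacement profile with zero edge velocity: u - sin(2 pi u)/(2 pi)."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _filtered_jitter(n: int, sd_deg: float, rng: np.random.Generator,
                     kernel_sd_ms: float = 20.0) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to the requested positional SD.

    The 20 ms temporal kernel keeps jitter velocities far below the 22 deg/s
    detection threshold at realistic SDs.
    """
    if sd_deg == 0.0 or n == 0:
        return np.zeros(n)
    width = int(6 * kernel_sd_ms) | 1
    t = np.arange(width) - width // 2
    kernel = np.exp(-t ** 2 / (2.0 * kernel_sd_ms ** 2))
    kernel /= kernel.sum()
    raw = rng.standard_normal(n + width)
    smooth = np.convolve(raw, kernel, mode="same")[width // 2: width // 2 + n]
    std = smooth.std()
    return smooth * (sd_deg / std) if std > 0 else smooth


def simulate_gaze(trial: TrialDesign, params: ObserverParams,
                  rng: np.random.Generator) -> tuple[gz.GazeTrace, GazeGroundTruth]:
    """Synthesise one trial's 1 kHz gaze trace and its ground truth.

    The trace covers trial initiation through mask offset. The
    gaze-contingent timeline is resolved internally: the display switch
    (adaptation -> blank/test) happens when the synthetic gaze crosses the
    2 deg online trigger radius, the test stimulus appears after the
    trial's blank duration, and the mask 400 ms later.
    """
    latency = params.latency_shift_ms + rng.gamma(params.latency_shape,
                                                  params.latency_scale_ms)
    landing_x = trial.target_eccentricity_deg + rng.normal(0.0, params.landing_error_sd_deg)
    amplitude = landing_x  # saccade starts at the (jittered-around-zero) center
    dur = _main_sequence_duration_ms(amplitude)
    move_start = trial.target_onset_ms + latency

    # ground-truth detection onset: first ms at which the noise-free profile
    # exceeds either detection threshold. Speed is
    # |A| / D * (1 - cos(2 pi u)) * 1000 deg/s and its derivative
    # |A| * 2 pi * 1e6 * sin(2 pi u) / D^2 deg/s^2; the earlier continuous
    # crossing defines the event edge.
    peak_speed = 2.0 * abs(amplitude) / dur * 1000.0
    if peak_speed <= _VEL_THRESHOLD:
        u_vel = 1.0
    else:
        u_vel = np.arccos(1.0 - _VEL_THRESHOLD * dur / (abs(amplitude) * 1000.0)) / (2.0 * np.pi)
    peak_accel = abs(amplitude) * 2.0 * np.pi * 1e6 / dur ** 2
    if peak_accel <= gz.ACCELERATION_THRESHOLD:
        u_acc = 1.0
    else:
        u_acc = np.arcsin(gz.ACCELERATION_THRESHOLD / peak_accel) / (2.0 * np.pi)
    u_cross = min(u_vel, u_acc)
    onset_true = np.ceil(move_start + u_cross * dur)
    offset_true = np.floor(move_start + (1.0 - u_cross) * dur)

    # online trigger: noise-free crossing of the 2 deg radius
    s_cross = 2.0 / abs(amplitude) if abs(amplitude) > 2.0 else 1.0
    u_grid = np.linspace(0.0, 1.0, 2001)
    u_trig = float(u_grid[np.searchsorted(_smooth_step(u_grid), s_cross)])
    trigger = np.ceil(move_start + u_trig * dur)

    test_onset = trigger + trial.blank_duration_ms
    mask_onset = test_onset + TEST_DURATION_MS
    n = int(np.ceil(mask_onset + MASK_DURATION_MS + 60.0))

    t = np.arange(n, dtype=float)
    x = _filtered_jitter(n, params.fixation_jitter_sd_deg, rng)
    y = _filtered_jitter(n, params.fixation_jitter_sd_deg, rng)
    u = (t - move_start) / dur
    x = x + amplitude * _smooth_step(u)

    blink = np.zeros(n, dtype=bool)
    if rng.random() < params.blink_prob:
        b_start = int(rng.uniform(0.0, mask_onset))
        b_dur = int(rng.uniform(100.0, 250.0))
        b_end = min(n, b_start + b_dur)
        blink[b_start:b_end] = True
        if b_start > 0:  # tracker holds last good position during the blink
            x[b_start:b_end] = x[b_start - 1]
            y[b_start:b_end] = y[b_start - 1]

    truth = GazeGroundTruth(
        latency_ms=float(onset_true - trial.target_onset_ms),
        saccade_onset_ms=float(onset_true),
        saccade_offset_ms=float(offset_true),
        movement_start_ms=float(move_start),
        amplitude_deg=float(amplitude),
        landing_x_deg=float(landing_x),
        trigger_time_ms=float(trigger),
        test_onset_ms=float(test_onset),
        mask_onset_ms=float(mask_onset),
        adaptation_duration_ms=float(onset_true - trial.adaptation_onset_ms),
    )
    return gz.GazeTrace(x=x, y=y, blink=blink), truth


def gaze_trace_frame(trace: gz.GazeTrace) -> pd.DataFrame:
    """Per-trial gaze CSV layout: t (ms), x, y (deg), blink flag."""
    return pd.DataFrame({"t_ms": trace.t_ms.astype(int), "x_deg": trace.x,
                         "y_deg": trace.y, "blink": trace.blink.astype(int)})


# --------------------------------------------------------------------------
# dataset generation
# --------------------------------------------------------------------------

def observer_params_from_dict(overrides: dict | None,
                              base: ObserverParams | None = None) -> ObserverParams:
    base = base or ObserverParams()
    if not overrides:
        return base
    valid = {f.name for f in fields(ObserverParams)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown observer parameters: {sorted(unknown)}")
    return replace(base, **overrides)


def simulate_trial(trial: TrialDesign, spec: ExperimentSpec, params: ObserverParams,
                   predictor: LatencyPredictor, rng: np.random.Generator) -> dict:
    """Run one trial end to end: timing, gaze, measures, validity, response."""
    if spec.experiment == 2:
        a_on, t_on = schedule_onsets_exp2(trial.intended_adaptation_duration_ms,
                                          predictor.predict())
        trial.adaptation_onset_ms, trial.target_onset_ms = a_on, t_on
    elif spec.experiment == 3:
        a_on, t_on = schedule_onsets_exp3(predictor.predict(),
                                          spec.target_onset_fixed_ms)
        trial.adaptation_onset_ms, trial.target_onset_ms = a_on, t_on
    # experiments 1/4/5: onsets already fixed by the schedule

    trace, truth = simulate_gaze(trial, params, rng)
    measures = gz.compute_trial_measures(trace, trial.adaptation_onset_ms,
                                         trial.target_onset_ms, truth.mask_onset_ms)
    status = gz.validate_trial(measures, spec.experiment, trial.lambda_corr_deg)
    if measures.saccade_found:
        predictor.observe(measures.saccade_latency_ms)

    pse = true_pse(max(0.0, truth.adaptation_duration_ms) / 1000.0,
                   trial.blank_duration_ms / 1000.0, params)
    response = simulate_response(trial, pse, params, rng)

    row = {f.name: getattr(trial, f.name) for f in fields(TrialDesign)}
    row.update({f.name: getattr(measures, f.name) for f in fields(gz.TrialMeasures)})
    row.update({
        "valid": status.valid,
        "exclusion_reasons": ";".join(sorted(status.reasons)),
        "f_corr": status.f_corr,
        "integer_distance": status.integer_distance,
        "response_anti_higher": response,
        "truth_pse": pse,
        "truth_latency_ms": truth.latency_ms,
        "truth_saccade_onset_ms": truth.saccade_onset_ms,
        "truth_adaptation_duration_ms": truth.adaptation_duration_ms,
        "mask_onset_ms": truth.mask_onset_ms,
    })
    return row


def generate_dataset(spec: ExperimentSpec, n_participants: int,
                     params: ObserverParams | Sequence[ObserverParams],
                     master_seed: int) -> pd.DataFrame:
    """Simulate a full experiment: one trial record per scheduled trial.

    Each participant gets an independent RNG stream spawned from the master
    seed, so the output is reproducible and participants are statistically
    independent. Columns cover the trial design, gaze-derived measures,
    validity status with reason codes, the 2AFC response, and the
    simulator's ground truth (columns prefixed ``truth_``).
    """
    if isinstance(params, ObserverParams):
        params = [params] * n_participants
    if len(params) != n_participants:
        raise ValueError("need one ObserverParams per participant")

    rows = []
    seeds = np.random.SeedSequence(master_seed).spawn(n_participants)
    for p, (pp, ss) in enumerate(zip(params, seeds)):
        rng = np.random.default_rng(ss)
        schedule = build_schedule(spec, rng)
        predictor = LatencyPredictor()
        for trial in schedule:
            row = simulate_trial(trial, spec, pp, predictor, rng)
            row["participant"] = p
            rows.append(row)
    frame = pd.DataFrame(rows)
    cols = ["participant"] + [c for c in frame.columns if c != "participant"]
    return frame[cols]
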