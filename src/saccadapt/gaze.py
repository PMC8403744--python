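"""Offline saccade detection, per-trial eye-movement measures, and trial exclusions.

Saccades are detected from 1 kHz gaze traces with velocity/acceleration
thresholds of 22 deg/s and 3800 deg/s^2 (the standard EyeLink parser
settings). Because the parser's internals are proprietary, the remaining
machinery is fixed here and exposed as parameters: velocities are estimated
by central differences on a 5-sample boxcar-smoothed trace, suprathreshold
runs shorter than 4 ms are discarded, runs separated by less than 20 ms are
merged, and event onsets/offsets are refined to the unsmoothed threshold
crossings.

Trial validity implements the exclusion rules of the study design: blinks
before mask onset, display switches not completed within the saccade,
unstable presaccadic fixation (horizontal SD > 0.5 deg), saccade amplitudes
landing near the worst-case half-cycle offset (integer distance of the
amplitude/wavelength ratio >= 0.25), over-long latencies (> 600 ms;
experiments 1, 4, 5 only) and adaptation durations deviating more than
100 ms from the intended 1.5 s (experiment 3 only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ONLINE_TRIGGER_DEG

VELOCITY_THRESHOLD = 22.0       # deg/s
ACCELERATION_THRESHOLD = 3800.0  # deg/s^2
SMOOTH_WINDOW = 5                # samples (1 ms each)
MIN_EVENT_MS = 4
MERGE_GAP_MS = 20

FIXATION_SD_LIMIT_DEG = 0.5
AMPLITUDE_BOUNDARY = 0.25
MAX_LATENCY_MS = 600.0
ADAPTATION_TOLERANCE_MS = 100.0
INTENDED_ADAPTATION_EXP3_MS = 1500.0


@dataclass
class GazeTrace:
    """Uniform 1 kHz gaze recording: horizontal/vertical position in degrees.

    ``t_ms[i] == i``; blink samples are flagged and their positions are not
    trustworthy (the simulator holds the last pre-blink position, real
    trackers report garbage).
    """

    x: np.ndarray
    y: np.ndarray
    blink: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.blink = np.asarray(self.blink, dtype=bool)
        if not (self.x.shape == self.y.shape == self.blink.shape):
            raise ValueError("x, y, blink must have identical length")

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.x.size, dtype=float)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: int
    offset_ms: int
    peak_velocity: float   # deg/s
    amplitude_deg: float   # horizontal, signed

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")


@dataclass
class TrialMeasures:
    saccade_latency_ms: float = np.nan
    saccade_amplitude_deg: float = np.nan
    presaccadic_fixation_deg: float = np.nan
    postsaccadic_fixation_deg: float = np.nan
    adaptation_duration_ms: float = np.nan
    fixation_sd_horizontal_deg: float = np.nan
    saccade_onset_ms: float = np.nan
    saccade_offset_ms: float = np.nan
    trigger_time_ms: float = np.nan
    switch_within_saccade: bool = False
    blink_in_window: bool = False
    saccade_found: bool = False


EXCLUSION_REASONS = (
    "blink",
    "switch_outside_saccade",
    "fixation_unstable",
    "amplitude_invalid",
    "latency_too_long",
    "adaptation_duration_deviant",
)


@dataclass
class ValidityStatus:
    valid: bool
    reasons: frozenset[str] = field(default_factory=frozenset)
    f_corr: float = np.nan
    integer_distance: float = np.nan

    def __post_init__(self) -> None:
        self.reasons = frozenset(self.reasons)
        if self.valid != (not self.reasons):
            raise ValueError("valid flag inconsistent with reason codes")


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: x.size]


def _velocity(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference 2-D speed (deg/s) and its derivative (deg/s^2) at 1 kHz."""
    vx = np.gradient(x) * 1000.0
    vy = np.gradient(y) * 1000.0
    speed = np.hypot(vx, vy)
    accel = np.abs(np.gradient(speed)) * 1000.0
    return speed, accel


def detect_saccades(trace: GazeTrace,
                    velocity_threshold: float = VELOCITY_THRESHOLD,
                    acceleration_threshold: float = ACCELERATION_THRESHOLD,
                    smooth_window: int = SMOOTH_WINDOW,
                    min_event_ms: int = MIN_EVENT_MS,
                    merge_gap_ms: int = MERGE_GAP_MS) -> list[SaccadeEvent]:
    """Detect saccades as suprathreshold velocity/acceleration runs.

    Candidate runs are found on the smoothed speed trace, merged across
    short gaps, duration-filtered, and finally the onset (offset) is walked
    back (forward) to the first (last) sample whose *raw* speed still
    exceeds the velocity threshold, which removes the lag the smoothing
    kernel introduces at the event edges. Blink samples never contribute.
    """
    n = len(trace)
    if n < smooth_window + 2:
        return []
    xs = _smooth(trace.x, smooth_window)
    ys = _smooth(trace.y, smooth_window)
    speed_s, accel_s = _velocity(xs, ys)
    speed_raw, accel_raw = _velocity(trace.x, trace.y)

    usable = ~trace.blink
    # the smoothing kernel smears blink samples into their neighbourhood
    if trace.blink.any():
        usable &= ~(_smooth(trace.blink.astype(float), smooth_window) > 1e-9)

    above = usable & ((speed_s > velocity_threshold) | (accel_s > acceleration_threshold))
    if not above.any():
        return []

    # contiguous runs
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))

    # merge runs separated by short gaps
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    events: list[SaccadeEvent] = []
    for s, e in merged:
        if e - s + 1 < min_event_ms:
            continue
        # refine edges on the unsmoothed trace to undo the kernel's edge lag
        raw_above = (speed_raw > velocity_threshold) | (accel_raw > acceleration_threshold)
        while s > 0 and usable[s - 1] and raw_above[s - 1]:
            s -= 1
        while e < n - 1 and usable[e + 1] and raw_above[e + 1]:
            e += 1
        events.append(SaccadeEvent(
            onset_ms=s, offset_ms=e,
            peak_velocity=float(np.max(speed_raw[s:e + 1])),
            amplitude_deg=float(trace.x[e] - trace.x[s]),
        ))
    return events


def online_trigger_time(trace: GazeTrace,
                        threshold_deg: float = ONLINE_TRIGGER_DEG) -> float | None:
    """First sample at which radial gaze eccentricity exceeds the trigger radius.

    This reproduces the online gaze-contingent rule that swapped the
    adaptation display for the test display; returns ``None`` if gaze never
    leaves the central region (no switch).
    """
    ecc = np.hypot(trace.x, trace.y)
    above = (ecc > threshold_deg) & ~trace.blink
    hits = np.flatnonzero(above)
    return float(hits[0]) if hits.size else None


# --------------------------------------------------------------------------
# per-trial measures
# --------------------------------------------------------------------------

def first_saccade_after(events: list[SaccadeEvent], t_ms: float) -> SaccadeEvent | None:
    for ev in events:
        if ev.onset_ms >= t_ms:
            return ev
    return None


def compute_trial_measures(trace: GazeTrace, adaptation_onset_ms: float,
                           target_onset_ms: float, mask_onset_ms: float,
                           events: list[SaccadeEvent] | None = None) -> TrialMeasures:
    """Latency, amplitude, fixation positions/stability, adaptation duration.

    The presaccadic fixation position is the mean horizontal gaze between
    adaptation-stimulus onset and saccade onset; the postsaccadic fixation
    position the mean between saccade offset and mask onset; the saccade
    amplitude is their difference. Latency is saccade onset minus target
    onset at 1 ms resolution.
    """
    m = TrialMeasures()
    m.blink_in_window = bool(trace.blink[: int(mask_onset_ms) + 1].any())
    trig = online_trigger_time(trace)
    m.trigger_time_ms = np.nan if trig is None else trig

    if events is None:
        events = detect_saccades(trace)
    ev = first_saccade_after(events, target_onset_ms)
    if ev is None:
        return m

    m.saccade_found = True
    m.saccade_onset_ms = float(ev.onset_ms)
    m.saccade_offset_ms = float(ev.offset_ms)
    m.saccade_latency_ms = float(ev.onset_ms - target_onset_ms)
    m.adaptation_duration_ms = float(ev.onset_ms - adaptation_onset_ms)

    pre = slice(int(adaptation_onset_ms), ev.onset_ms + 1)
    post = slice(ev.offset_ms, int(mask_onset_ms) + 1)
    pre_x = trace.x[pre][~trace.blink[pre]]
    post_x = trace.x[post][~trace.blink[post]]
    if pre_x.size:
        m.presaccadic_fixation_deg = float(np.mean(pre_x))
        m.fixation_sd_horizontal_deg = float(np.std(pre_x))
    if post_x.size:
        m.postsaccadic_fixation_deg = float(np.mean(post_x))
    m.saccade_amplitude_deg = m.postsaccadic_fixation_deg - m.presaccadic_fixation_deg
    m.switch_within_saccade = (trig is not None
                               and ev.onset_ms <= trig <= ev.offset_ms)
    return m


# --------------------------------------------------------------------------
# exclusion rules
# --------------------------------------------------------------------------

def amplitude_validity(amplitude_deg: float, lambda_corr_deg: float,
                       boundary: float = AMPLITUDE_BOUNDARY) -> tuple[float, float, bool]:
    """Amplitude/wavelength ratio, its distance to the nearest integer, validity.

    ``f_corr = |amplitude| / lambda_corr``; an integer ratio means the
    saccade preserved the correlated/anticorrelated assignment perfectly, a
    half-integer ratio (distance 0.5) means it inverted it — the worst
    case. Trials at or beyond the midpoint boundary (0.25) are invalid.
    """
    if lambda_corr_deg <= 0:
        raise ValueError(f"wavelength must be positive, got {lambda_corr_deg}")
    f_corr = abs(amplitude_deg) / lambda_corr_deg
    integer_distance = abs(f_corr - round(f_corr))
    return f_corr, integer_distance, bool(integer_distance < boundary)


def validate_trial(measures: TrialMeasures, experiment: int,
                   lambda_corr_deg: float) -> ValidityStatus:
    """Apply every exclusion rule applicable to the experiment; report all violations."""
    reasons: set[str] = set()
    if measures.blink_in_window:
        reasons.add("blink")
    if not (measures.saccade_found and measures.switch_within_saccade):
        reasons.add("switch_outside_saccade")
    if not (measures.fixation_sd_horizontal_deg <= FIXATION_SD_LIMIT_DEG):
        reasons.add("fixation_unstable")

    f_corr = integer_distance = np.nan
    if measures.saccade_found and np.isfinite(measures.saccade_amplitude_deg):
        f_corr, integer_distance, amp_ok = amplitude_validity(
            measures.saccade_amplitude_deg, lambda_corr_deg)
        if not amp_ok:
            reasons.add("amplitude_invalid")
    else:
        reasons.add("amplitude_invalid")

    if (experiment in (1, 4, 5) and measures.saccade_found
            and measures.saccade_latency_ms > MAX_LATENCY_MS):
        reasons.add("latency_too_long")
    if experiment == 3 and measures.saccade_found:
        dev = abs(measures.adaptation_duration_ms - INTENDED_ADAPTATION_EXP3_MS)
        if dev > ADAPTATION_TOLERANCE_MS:
            reasons.add("adaptation_duration_deviant")

    return ValidityStatus(valid=not reasons, reasons=frozenset(reasons),
                          f_corr=float(f_corr), integer_distance=float(integer_distance))
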