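"""Counterbalanced trial schedules and gaze-contingent timing rules.

Five experiment designs are supported:

1. Main adaptation measurement: 15 contrast-difference levels from -0.28 to
   +0.28 in steps of 0.04, 8 repetitions per factor combination (480 trials),
   overlap paradigm, saccade-target onset jittered 1.4-1.6 s after trial start.
2. Build-up of adaptation: a single contrast difference (-0.07), intended
   adaptation durations 100-1200 ms in 100 ms steps, adaptive scheduling of
   the adaptation-stimulus onset from a rolling saccade-latency prediction
   (384 trials).
3. Decay of adaptation: contrast differences -0.3 to +0.2 in 0.05 steps,
   postsaccadic blank durations {0, 100, 200, 400, 800, 1600} ms, adaptation
   onset delayed by the predicted latency so realized adaptation durations
   cluster at 1.5 s (528 trials).
4. Visual-field contribution: as experiment 1 but two blocked slice
   conditions (test slice at the saccade-target location vs. at the
   presaccadic fixation location), 2 repetitions (120 trials per block).
5. High-contrast test: 13 contrast-difference levels, adaptation contrast
   jittered in [0.3, 0.7] per trial, test mean contrast equal to it.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, fields
from typing import Literal, Sequence

import numpy as np
import pandas as pd

WAVELENGTH_RANGE_DEG = (5.0, 6.25)       # correlated-grating wavelength jitter
PHASE_RANGE_RAD = (-0.5 * np.pi, 0.5 * np.pi)
F_ANTI_LEVELS = (1.5, 2.5)
F_CORR = 2.0                             # saccade spans 2 correlated cycles
ADAPTATION_CONTRAST = 0.5
TEST_MEAN_CONTRAST = 0.15
TEST_DURATION_MS = 400.0
MASK_DURATION_MS = 300.0
FIXATION_OVERLAP_MS = 200.0
ONLINE_TRIGGER_DEG = 2.0                 # gaze eccentricity triggering the display switch


def _levels(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class ExperimentSpec:
    """Factor levels and timing constants for one experiment."""

    experiment: int
    delta_c_levels: tuple[float, ...]
    repetitions: int
    f_anti_levels: tuple[float, ...] = F_ANTI_LEVELS
    positions: tuple[str, ...] = ("upper", "lower")
    adaptation_durations_ms: tuple[float, ...] = ()   # experiment 2
    blank_durations_ms: tuple[float, ...] = ()        # experiment 3
    slice_conditions: tuple[str, ...] = ()            # experiment 4 blocks
    adaptation_contrast_range: tuple[float, float] | None = None  # experiment 5
    direction_as_factor: bool = False
    overlap: bool = True
    target_onset_range_s: tuple[float, float] | None = (1.4, 1.6)
    target_onset_fixed_ms: float | None = None
    mean_test_contrast: float = TEST_MEAN_CONTRAST
    has_mask: bool = True

    @property
    def n_trials(self) -> int:
        n = len(self.delta_c_levels) * len(self.positions) * len(self.f_anti_levels) * self.repetitions
        for extra in (self.adaptation_durations_ms, self.blank_durations_ms):
            if extra:
                n *= len(extra)
        if self.direction_as_factor:
            n *= 2
        return n

    @property
    def n_trials_per_block(self) -> int:
        return self.n_trials

    @property
    def n_blocks(self) -> int:
        return max(1, len(self.slice_conditions))


def experiment_spec(experiment: int) -> ExperimentSpec:
    """Build the printed design for experiments 1-5."""
    if experiment == 1:
        return ExperimentSpec(1, _levels(-0.28, 0.28, 0.04), repetitions=8)
    if experiment == 2:
        return ExperimentSpec(
            2, (-0.07,), repetitions=4,
            adaptation_durations_ms=tuple(float(d) for d in range(100, 1300, 100)),
            direction_as_factor=True, overlap=False,
            target_onset_range_s=None, target_onset_fixed_ms=1200.0,
        )
    if experiment == 3:
        return ExperimentSpec(
            3, _levels(-0.3, 0.2, 0.05), repetitions=2,
            blank_durations_ms=(0.0, 100.0, 200.0, 400.0, 800.0, 1600.0),
            overlap=False, target_onset_range_s=None, target_onset_fixed_ms=1500.0,
        )
    if experiment == 4:
        return ExperimentSpec(
            4, _levels(-0.28, 0.28, 0.04), repetitions=2,
            slice_conditions=("center", "periphery"),
        )
    if experiment == 5:
        return ExperimentSpec(
            5, (-0.4, -0.3, -0.2, -0.15, -0.1, -0.05, 0.0,
                0.05, 0.1, 0.15, 0.2, 0.3, 0.4),
            repetitions=8, adaptation_contrast_range=(0.3, 0.7), has_mask=False,
        )
    raise ValueError(f"unknown experiment id {experiment!r}")


@dataclass
class TrialDesign:
    """Complete stimulus/timing specification for one trial."""

    experiment: int
    trial_index: int
    block: str = ""
    delta_c: float = 0.0
    f_anti: float = 1.5
    correlated_position: Literal["upper", "lower"] = "upper"
    saccade_direction: Literal["left", "right"] = "right"
    lambda_corr_deg: float = 5.5
    common_phase_rad: float = 0.0
    target_eccentricity_deg: float = 11.0
    fixation_to_target_interval_s: float = 1.5
    intended_adaptation_duration_ms: float = np.nan   # experiment 2
    blank_duration_ms: float = 0.0                    # experiment 3
    slice_condition: str = ""                         # experiment 4
    adaptation_contrast: float = ADAPTATION_CONTRAST  # jittered in experiment 5
    mean_test_contrast: float = TEST_MEAN_CONTRAST
    adaptation_onset_ms: float = 0.0                  # filled by the timing engine
    target_onset_ms: float = np.nan

    @property
    def lambda_anti_deg(self) -> float:
        from .stimulus import anticorrelated_wavelength
        return anticorrelated_wavelength(self.lambda_corr_deg, self.f_anti)


def build_schedule(spec: ExperimentSpec, seed: int | np.random.Generator) -> list[TrialDesign]:
    """Full factor crossing x repetitions, shuffled; one schedule per participant.

    Saccade direction is counterbalanced: either as an explicit design
    factor (experiment 2) or by splitting the repetitions of every factor
    combination evenly between leftward and rightward targets.

    Experiment 4 returns two equal blocks (center, periphery), each shuffled
    within itself.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    conditions: list[dict] = [{}]
    if spec.adaptation_durations_ms:
        conditions = [{"intended_adaptation_duration_ms": d} for d in spec.adaptation_durations_ms]
    elif spec.blank_durations_ms:
        conditions = [{"blank_duration_ms": b} for b in spec.blank_durations_ms]

    blocks = spec.slice_conditions or ("",)
    trials: list[TrialDesign] = []
    for block in blocks:
        block_trials: list[TrialDesign] = []
        for cond in conditions:
            for delta_c in spec.delta_c_levels:
                for pos in spec.positions:
                    for f_anti in spec.f_anti_levels:
                        if spec.direction_as_factor:
                            reps = [(r, d) for r in range(spec.repetitions)
                                    for d in ("left", "right")]
                        else:
                            reps = [(r, ("left", "right")[r % 2]) for r in range(spec.repetitions)]
                        for _, direction in reps:
                            block_trials.append(TrialDesign(
                                experiment=spec.experiment, trial_index=-1, block=block,
                                delta_c=delta_c, f_anti=f_anti, correlated_position=pos,
                                saccade_direction=direction, slice_condition=block,
                                mean_test_contrast=spec.mean_test_contrast, **cond,
                            ))
        rng.shuffle(block_trials)
        trials.extend(block_trials)

    for i, t in enumerate(trials):
        t.trial_index = i
        t.lambda_corr_deg = float(rng.uniform(*WAVELENGTH_RANGE_DEG))
        t.common_phase_rad = float(rng.uniform(*PHASE_RANGE_RAD))
        sign = 1.0 if t.saccade_direction == "right" else -1.0
        t.target_eccentricity_deg = sign * F_CORR * t.lambda_corr_deg
        if spec.target_onset_range_s is not None:
            t.fixation_to_target_interval_s = float(rng.uniform(*spec.target_onset_range_s))
            t.target_onset_ms = t.fixation_to_target_interval_s * 1000.0
            t.adaptation_onset_ms = 0.0
        else:
            t.fixation_to_target_interval_s = spec.target_onset_fixed_ms / 1000.0
        if spec.adaptation_contrast_range is not None:
            t.adaptation_contrast = float(rng.uniform(*spec.adaptation_contrast_range))
            t.mean_test_contrast = t.adaptation_contrast
    return trials


def schedule_to_frame(trials: Sequence[TrialDesign]) -> pd.DataFrame:
    """One row per trial; the CSV export format of a schedule."""
    return pd.DataFrame([{f.name: getattr(t, f.name) for f in fields(TrialDesign)}
                         for t in trials])


def schedule_from_frame(frame: pd.DataFrame) -> list[TrialDesign]:
    cols = {f.name for f in fields(TrialDesign)}
    return [TrialDesign(**{k: v for k, v in row.items() if k in cols})
            for row in frame.to_dict("records")]


# --------------------------------------------------------------------------
# adaptive saccade-latency prediction and onset scheduling
# --------------------------------------------------------------------------

@dataclass
class LatencyPredictor:
    """Rolling-median saccade-latency estimate used for gaze-contingent timing.

    The estimate is the median of up to the last ``window`` realized
    latencies; before any latency has been observed it is the fixed
    ``initial_ms`` value (190 ms).
    """

    window: int = 20
    initial_ms: float = 190.0
    history: list[float] = field(default_factory=list)

    def predict(self) -> float:
        if not self.history:
            return self.initial_ms
        return float(statistics.median(self.history[-self.window:]))

    def observe(self, latency_ms: float) -> None:
        self.history.append(float(latency_ms))


def schedule_onsets_exp2(intended_adaptation_ms: float, predicted_latency_ms: float,
                         baseline_ms: float = 1200.0) -> tuple[float, float]:
    """Adaptation and saccade-target onsets for the build-up experiment.

    The adaptation stimulus is timed so that, if the saccade starts at the
    predicted latency after target onset, the realized adaptation duration
    equals the intended one: ``adaptation_onset - target_onset =
    predicted_latency - intended_adaptation``. The earlier of the two events
    occurs ``baseline_ms`` after trial initiation.
    """
    if intended_adaptation_ms <= 0 or predicted_latency_ms <= 0:
        raise ValueError("durations must be positive")
    diff = predicted_latency_ms - intended_adaptation_ms
    if diff >= 0:
        return baseline_ms + diff, baseline_ms
    return baseline_ms, baseline_ms - diff


def schedule_onsets_exp3(predicted_latency_ms: float,
                         target_onset_ms: float = 1500.0) -> tuple[float, float]:
    """Adaptation and target onsets for the decay experiment.

    The adaptation onset is delayed by the predicted latency so the realized
    adaptation duration (adaptation onset to saccade onset) is close to
    ``target_onset_ms`` (1.5 s) whenever the prediction is accurate.
    """
    if predicted_latency_ms < 0:
        raise ValueError("predicted latency must be non-negative")
    return float(predicted_latency_ms), float(target_onset_ms)
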