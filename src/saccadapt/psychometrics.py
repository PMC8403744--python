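"""Response-data analysis: psychometric fits, running averages, decay fits, t tests.

The psychometric model is a cumulative Gaussian with a single symmetric
lapse parameter,

    P(anticorrelated-higher | delta_c) =
        lambda/2 + (1 - lambda) * Phi((delta_c - mu) / sigma),

fitted by maximum likelihood. The point of subjective equality (PSE) is
``mu`` — the contrast difference at which both gratings are judged equal
(50% point) — and the just-noticeable difference (JND) is ``sigma``, the
standard deviation of the cumulative Gaussian. The lapse is bounded in
[0, 0.1], which keeps the asymptotes off 0/1 as real data show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

LAPSE_MAX = 0.1
_N_RESTARTS = 10


class DegenerateFitError(RuntimeError):
    """Raised when the data cannot constrain a psychometric or statistical fit."""


@dataclass
class PsychometricFit:
    pse: float
    jnd: float
    lapse: float
    log_likelihood: float
    n_trials: int
    ci_pse: tuple[float, float] | None = None
    ci_jnd: tuple[float, float] | None = None

    def predict(self, delta_c) -> np.ndarray:
        return expected_proportion(np.asarray(delta_c, dtype=float),
                                   self.pse, self.jnd, self.lapse)


def expected_proportion(delta_c, pse: float, jnd: float, lapse: float = 0.0):
    """Model proportion of anticorrelated-higher responses at ``delta_c``."""
    if jnd <= 0:
        raise ValueError("jnd must be positive")
    return lapse / 2.0 + (1.0 - lapse) * stats.norm.cdf(
        (np.asarray(delta_c, dtype=float) - pse) / jnd)


def _negative_log_likelihood(theta: np.ndarray, x: np.ndarray, k: np.ndarray,
                             n: np.ndarray) -> float:
    mu, log_sigma, lapse = theta
    p = expected_proportion(x, mu, np.exp(log_sigma), lapse)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log(1.0 - p)))


def fit_psychometric(delta_c, responses, n_bootstrap: int = 0,
                     seed: int = 0) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to binary 2AFC responses.

    ``delta_c`` and ``responses`` are per-trial arrays (responses coded 1 =
    anticorrelated-higher). The optimizer is bounded L-BFGS-B on
    (mu, log sigma, lapse) restarted from 10 jittered starting points drawn
    from a fixed RNG stream, so the fit is deterministic for given data.
    Optional percentile bootstrap CIs resample trials.
    """
    x = np.asarray(delta_c, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("delta_c and responses must be matching 1-D arrays")
    if np.unique(x).size < 2:
        raise DegenerateFitError("need >= 2 distinct contrast-difference levels")
    if np.all(y == y[0]):
        raise DegenerateFitError(
            f"all responses identical ({int(y[0])}); psychometric location unidentifiable")

    # aggregate to (level, successes, count) for the likelihood
    levels, inv = np.unique(x, return_inverse=True)
    k = np.bincount(inv, weights=y, minlength=levels.size)
    n = np.bincount(inv, minlength=levels.size).astype(float)

    span = levels.max() - levels.min()
    bounds = [(levels.min() - span, levels.max() + span),
              (np.log(span / 100.0), np.log(span * 3.0)),
              (0.0, LAPSE_MAX)]

    # crude moment start: interpolate the 50% crossing of observed proportions
    props = k / n
    mu0 = float(np.interp(0.5, np.clip(props, 0.01, 0.99), levels,
                          left=levels[0], right=levels[-1]))
    theta0 = np.array([mu0, np.log(max(span / 4.0, 1e-3)), 0.02])

    rng = np.random.default_rng(seed)
    best = None
    for i in range(_N_RESTARTS):
        start = theta0 if i == 0 else np.array([
            rng.uniform(bounds[0][0], bounds[0][1]),
            rng.uniform(bounds[1][0], bounds[1][1]),
            rng.uniform(0.0, LAPSE_MAX),
        ])
        res = optimize.minimize(_negative_log_likelihood, start,
                                args=(levels, k, n), method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma, lapse = best.x

    ci_pse = ci_jnd = None
    if n_bootstrap > 0:
        boot_rng = np.random.default_rng(seed + 1)
        pses, jnds = [], []
        for _ in range(n_bootstrap):
            idx = boot_rng.integers(0, x.size, x.size)
            try:
                f = fit_psychometric(x[idx], y[idx], n_bootstrap=0, seed=seed)
            except DegenerateFitError:
                continue
            pses.append(f.pse)
            jnds.append(f.jnd)
        if len(pses) >= 10:
            ci_pse = tuple(np.percentile(pses, [2.5, 97.5]))
            ci_jnd = tuple(np.percentile(jnds, [2.5, 97.5]))

    return PsychometricFit(pse=float(mu), jnd=float(np.exp(log_sigma)),
                           lapse=float(lapse), log_likelihood=float(-best.fun),
                           n_trials=int(x.size), ci_pse=ci_pse, ci_jnd=ci_jnd)


# --------------------------------------------------------------------------
# running average over adaptation duration (build-up time course)
# --------------------------------------------------------------------------

@dataclass
class RunningAverageCurve:
    bin_centers_ms: np.ndarray
    proportions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers_ms = np.asarray(self.bin_centers_ms, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)


def running_average_bins(t_min: float = 0.0, t_max: float = 1400.0,
                         bin_ms: float = 300.0,
                         step_ms: float = 1.0) -> list[tuple[float, float]]:
    """The (start, end) bin sequence of the build-up running average.

    Bins grow from half width anchored at the range start (0-150, 0-151,
    ..., 0-300 ms), then slide at full width in 1 ms steps (1-301, ...,
    1100-1400), then shrink anchored at the range end (1101-1400, ...,
    1250-1400 ms).
    """
    half = bin_ms / 2.0
    bins = [(t_min, t_min + half + i * step_ms)
            for i in range(int(round(half / step_ms)) + 1)]
    start = t_min + step_ms
    while start + bin_ms <= t_max:
        bins.append((start, start + bin_ms))
        start += step_ms
    while start <= t_max - half:
        bins.append((start, t_max))
        start += step_ms
    return bins


def running_average(durations_ms, responses, t_min: float = 0.0,
                    t_max: float = 1400.0, bin_ms: float = 300.0) -> RunningAverageCurve:
    """Proportion of anticorrelated-higher responses over adaptation duration.

    Each bin's proportion is assigned to the bin midpoint; bins are closed
    intervals and empty bins are omitted.
    """
    t = np.asarray(durations_ms, dtype=float)
    y = np.asarray(responses, dtype=float)
    centers, props, counts = [], [], []
    for lo, hi in running_average_bins(t_min, t_max, bin_ms):
        mask = (t >= lo) & (t <= hi)
        c = int(mask.sum())
        if c == 0:
            continue
        centers.append((lo + hi) / 2.0)
        props.append(float(y[mask].mean()))
        counts.append(c)
    return RunningAverageCurve(np.array(centers), np.array(props), np.array(counts))


# --------------------------------------------------------------------------
# logarithmic decay fit (persistence over blank duration)
# --------------------------------------------------------------------------

@dataclass
class DecayFit:
    A: float
    B: float
    domain_ms: tuple[float, float]
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, blank_ms) -> np.ndarray:
        return self.A * np.log(np.asarray(blank_ms, dtype=float)) + self.B


def fit_log_decay(blank_ms, pse, min_blank_ms: float = 100.0) -> DecayFit:
    """Least-squares fit of ``pse = A * ln(blank) + B`` over blanks >= 100 ms.

    The natural-log model is undefined at zero blank, so the zero-blank PSE
    is excluded from the fit domain and reported separately by callers.
    """
    x = np.asarray(blank_ms, dtype=float)
    y = np.asarray(pse, dtype=float)
    keep = x >= min_blank_ms
    x, y = x[keep], y[keep]
    if np.unique(x).size < 2:
        raise DegenerateFitError("need >= 2 distinct blank durations >= min_blank_ms")
    design = np.column_stack([np.log(x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return DecayFit(A=float(coef[0]), B=float(coef[1]),
                    domain_ms=(float(x.min()), float(x.max())), residuals=resid)


# --------------------------------------------------------------------------
# t tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def t_test(a, b=None, mode: str = "one-sample", tail: str = "two-sided",
           popmean: float = 0.0) -> TTestResult:
    """Student t test: one-sample (against ``popmean``), paired, or pooled two-sample.

    ``tail`` is 'two-sided', 'less' or 'greater'. The two-sample test uses
    the equal-variance pooled formula (df = n1 + n2 - 2).
    """
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("need n >= 2 per sample")
    if mode == "one-sample":
        if np.ptp(a) == 0:
            raise DegenerateFitError("zero variance: t statistic undefined")
        res = stats.ttest_1samp(a, popmean, alternative=tail)
        df = a.size - 1
    elif mode == "paired":
        b = np.asarray(b, dtype=float)
        if np.ptp(a - b) == 0:
            raise DegenerateFitError("zero variance of differences")
        res = stats.ttest_rel(a, b, alternative=tail)
        df = a.size - 1
    elif mode == "two-sample":
        b = np.asarray(b, dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise DegenerateFitError("zero variance in both samples")
        res = stats.ttest_ind(a, b, equal_var=True, alternative=tail)
        df = a.size + b.size - 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


# --------------------------------------------------------------------------
# subset fits
# --------------------------------------------------------------------------

def subset_fits(records: pd.DataFrame, split_by: str,
                delta_col: str = "delta_c", response_col: str = "response_anti_higher",
                **fit_kwargs) -> dict:
    """One psychometric fit per level of a splitting factor.

    Fit failures for a level are returned as the exception object under
    that level's key rather than aborting the other levels.
    """
    if split_by not in records.columns:
        raise KeyError(f"no column {split_by!r} in records")
    out: dict = {}
    for level, sub in records.groupby(split_by, sort=True):
        try:
            out[level] = fit_psychometric(sub[delta_col].to_numpy(),
                                          sub[response_col].to_numpy(), **fit_kwargs)
        except DegenerateFitError as err:
            out[level] = err
    return out
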