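"""Psychometric fitting, running averages, decay fits, and t tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from saccadapt.psychometrics import (DegenerateFitError, expected_proportion,
                                     fit_log_decay, fit_psychometric,
                                     running_average, running_average_bins,
                                     subset_fits, t_test)

EXP1_LEVELS = np.round(np.arange(-0.28, 0.2801, 0.04), 10)


def _simulate_2afc(pse, jnd, lapse, levels, reps, seed):
    rng = np.random.default_rng(seed)
    x = np.repeat(levels, reps)
    p = lapse / 2 + (1 - lapse) * norm.cdf((x - pse) / jnd)
    return x, (rng.random(x.size) < p).astype(float)


class TestFitPsychometric:
    def test_parameter_recovery_main_design(self):
        """480-trial datasets at the main design's levels recover the
        generating PSE within 0.02 and JND within 25%; averaging over
        several independent datasets checks the estimator is unbiased
        rather than one lucky draw."""
        fits = [fit_psychometric(*_simulate_2afc(-0.14, 0.077, 0.02,
                                                 EXP1_LEVELS, 32, seed=s))
                for s in range(6)]
        assert np.mean([f.pse for f in fits]) == pytest.approx(-0.14, abs=0.02)
        assert np.mean([f.jnd for f in fits]) == pytest.approx(0.077, rel=0.25)

    def test_symmetric_responses_give_zero_pse(self):
        x, y = _simulate_2afc(0.0, 0.08, 0.0, EXP1_LEVELS, 40, seed=1)
        assert fit_psychometric(x, y).pse == pytest.approx(0.0, abs=0.015)

    def test_fit_proportion_at_pse_is_half(self):
        x, y = _simulate_2afc(-0.1, 0.07, 0.0, EXP1_LEVELS, 40, seed=2)
        fit = fit_psychometric(x, y)
        no_lapse = (fit.predict(fit.pse) - fit.lapse / 2) / (1 - fit.lapse)
        assert no_lapse == pytest.approx(0.5, abs=1e-9)

    def test_likelihood_at_optimum_beats_generating_parameters(self):
        from saccadapt.psychometrics import _negative_log_likelihood
        x, y = _simulate_2afc(-0.14, 0.077, 0.02, EXP1_LEVELS, 32, seed=3)
        fit = fit_psychometric(x, y)
        levels, inv = np.unique(x, return_inverse=True)
        k = np.bincount(inv, weights=y)
        n = np.bincount(inv).astype(float)
        nll_fit = _negative_log_likelihood(
            np.array([fit.pse, np.log(fit.jnd), fit.lapse]), levels, k, n)
        nll_gen = _negative_log_likelihood(
            np.array([-0.14, np.log(0.077), 0.02]), levels, k, n)
        assert nll_fit <= nll_gen + 1e-6

    def test_deterministic(self):
        x, y = _simulate_2afc(-0.1, 0.08, 0.02, EXP1_LEVELS, 16, seed=4)
        a, b = fit_psychometric(x, y), fit_psychometric(x, y)
        assert (a.pse, a.jnd, a.lapse) == (b.pse, b.jnd, b.lapse)

    def test_bootstrap_ci_brackets_estimate(self):
        x, y = _simulate_2afc(-0.14, 0.077, 0.02, EXP1_LEVELS, 16, seed=5)
        fit = fit_psychometric(x, y, n_bootstrap=60)
        assert fit.ci_pse[0] <= fit.pse <= fit.ci_pse[1]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_psychometric(np.array([-0.1, -0.1, -0.1]), np.array([0.0, 1.0, 0.0]))
        with pytest.raises(DegenerateFitError):
            fit_psychometric(EXP1_LEVELS, np.ones(EXP1_LEVELS.size))


class TestExpectedProportion:
    def test_half_at_pse(self):
        assert expected_proportion(-0.14, -0.14, 0.077, 0.0) == pytest.approx(0.5)

    def test_baseline_closed_form(self):
        """Probe at -0.07 with no adaptation: ~0.18 anticorrelated-higher."""
        assert expected_proportion(-0.07, 0.0, 0.077, 0.0) == pytest.approx(
            norm.cdf(-0.07 / 0.077))
        assert expected_proportion(-0.07, 0.0, 0.077, 0.0) == pytest.approx(0.18, abs=0.01)

    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_monotone_in_delta_c(self, a, b):
        lo, hi = sorted((a, b))
        assert expected_proportion(lo, -0.1, 0.077, 0.05) <= expected_proportion(
            hi, -0.1, 0.077, 0.05)

    def test_invalid_jnd(self):
        with pytest.raises(ValueError):
            expected_proportion(0.0, 0.0, -1.0)


def _oracle_bins():
    """Independent enumeration of the quoted bin scheme: bins grow anchored at
    0 ms from half width 150 to 300, slide at width 300 in 1 ms steps, then
    shrink anchored at 1400 ms back to width 150."""
    bins = [(0, e) for e in range(150, 301)]
    bins += [(s, s + 300) for s in range(1, 1101)]
    bins += [(s, 1400) for s in range(1101, 1251)]
    return bins


class TestRunningAverage:
    def test_bin_scheme_matches_oracle(self):
        assert running_average_bins() == [(float(a), float(b)) for a, b in _oracle_bins()]

    def test_constant_responses_give_constant_curve(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(16, 1384, 200)
        curve = running_average(t, np.ones(200))
        assert np.all(curve.proportions == 1.0)

    def test_single_early_trial(self):
        """A lone trial at 50 ms populates exactly the bins containing 50 ms,
        each with proportion 1."""
        curve = running_average(np.array([50.0]), np.array([1.0]))
        oracle = [(a + b) / 2 for a, b in _oracle_bins() if a <= 50 <= b]
        np.testing.assert_allclose(curve.bin_centers_ms, oracle)
        assert np.all(curve.proportions == 1.0)

    @settings(max_examples=20)
    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_trials(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        t = rng.uniform(0, 1400, n)
        y = rng.integers(0, 2, n).astype(float)
        curve = running_average(t, y)
        centers, props = [], []
        for a, b in _oracle_bins():
            inside = (t >= a) & (t <= b)
            if inside.any():
                centers.append((a + b) / 2)
                props.append(y[inside].mean())
        np.testing.assert_allclose(curve.bin_centers_ms, centers)
        np.testing.assert_allclose(curve.proportions, props)

    def test_bin_centers_strictly_increasing(self):
        rng = np.random.default_rng(3)
        curve = running_average(rng.uniform(0, 1400, 500), rng.integers(0, 2, 500))
        assert np.all(np.diff(curve.bin_centers_ms) > 0)


class TestLogDecayFit:
    def test_exact_recovery(self):
        blanks = np.array([100.0, 200.0, 400.0, 800.0, 1600.0])
        y = 0.02 * np.log(blanks) - 0.20
        fit = fit_log_decay(blanks, y)
        assert fit.A == pytest.approx(0.02, abs=1e-12)
        assert fit.B == pytest.approx(-0.20, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_two_points_match_algebraic_solution(self):
        x = np.array([100.0, 1600.0])
        y = np.array([-0.11, -0.06])
        fit = fit_log_decay(x, y)
        a = (y[1] - y[0]) / (np.log(x[1]) - np.log(x[0]))
        b = y[0] - a * np.log(x[0])
        assert fit.A == pytest.approx(a)
        assert fit.B == pytest.approx(b)

    def test_zero_blank_excluded_from_domain(self):
        blanks = np.array([0.0, 100.0, 400.0, 1600.0])
        fit = fit_log_decay(blanks, 0.02 * np.log(np.maximum(blanks, 1)) - 0.2)
        assert fit.domain_ms[0] == 100.0

    def test_magnitude_decreasing_when_A_positive(self):
        fit = fit_log_decay(np.array([100.0, 1600.0]), np.array([-0.11, -0.06]))
        x = np.linspace(100, 1600, 50)
        assert np.all(np.diff(np.abs(fit.predict(x))) < 0)

    def test_rank_deficient(self):
        with pytest.raises(DegenerateFitError):
            fit_log_decay(np.array([400.0, 400.0]), np.array([-0.1, -0.09]))


class TestTTests:
    def test_one_sample_closed_form(self):
        a = np.array([-1.2, -0.8, -1.5, -0.9, -1.1])
        res = t_test(a, mode="one-sample", tail="two-sided")
        expected_t = a.mean() / (a.std(ddof=1) / np.sqrt(a.size))
        assert res.t == pytest.approx(expected_t, abs=1e-10)
        assert res.df == 4

    def test_two_sample_pooled_df(self):
        """Pooled two-sample t with n1=16, n2=7 has 21 degrees of freedom."""
        rng = np.random.default_rng(0)
        res = t_test(rng.normal(0.39, 0.09, 16), rng.normal(0.17, 0.07, 7),
                     mode="two-sample")
        assert res.df == 21

    def test_paired_equals_one_sample_on_differences(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        paired = t_test(a, b, mode="paired")
        one = t_test(a - b, mode="one-sample")
        assert paired.t == pytest.approx(one.t, abs=1e-10)
        assert paired.p == pytest.approx(one.p, abs=1e-10)

    def test_one_sided_direction(self):
        a = np.array([-0.14, -0.12, -0.16, -0.13])
        res = t_test(a, mode="one-sample", tail="less")
        assert res.t < 0 and res.p < 0.01

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateFitError):
            t_test(np.array([-1.0, -1.0, -1.0, -1.0]), mode="one-sample")


class TestSubsetFits:
    def test_homogeneous_split_levels_agree(self, exp1_small_records):
        valid = exp1_small_records[exp1_small_records["valid"]]
        fits = subset_fits(valid, "f_anti")
        pooled = fit_psychometric(valid["delta_c"].to_numpy(),
                                  valid["response_anti_higher"].to_numpy())
        pses = [f.pse for f in fits.values()]
        assert len(pses) == 2
        for pse in pses:
            assert pse == pytest.approx(pooled.pse, abs=0.03)

    def test_level_counts_partition_total(self, exp1_small_records):
        valid = exp1_small_records[exp1_small_records["valid"]]
        fits = subset_fits(valid, "correlated_position")
        assert sum(f.n_trials for f in fits.values()) == len(valid)

    def test_fit_errors_propagate_per_level(self, exp1_small_records):
        df = exp1_small_records.copy()
        # poison one level: constant responses make its fit degenerate
        df.loc[df["f_anti"] == 1.5, "response_anti_higher"] = 1
        fits = subset_fits(df, "f_anti")
        assert isinstance(fits[1.5], DegenerateFitError)
        assert not isinstance(fits[2.5], DegenerateFitError)

    def test_missing_column(self, exp1_small_records):
        with pytest.raises(KeyError):
            subset_fits(exp1_small_records, "no_such_factor")
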