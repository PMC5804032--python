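"""Patient-level tests: correlation, risk, spectral, dip, goodness of fit."""

import numpy as np
import pytest
from scipy import stats

from moodcourse.data import SurveySeries
from moodcourse.errors import InsufficientDataError
from moodcourse.model import (AffectiveMarginalParams,
                              LinearMeanRevertingParams, sample_stationary,
                              sample_transition)
from moodcourse.patient import (dip_test, frequency_grid, gof_density_test,
                                gof_transition_test, harmonic_f_test,
                                kendall_correlation, mania_risk)


def _series(instrument, scores, spacing=61.0):
    scores = np.asarray(scores, dtype=float)
    return SurveySeries("p", instrument, spacing * np.arange(len(scores)),
                        scores)


class TestKendall:
    @pytest.mark.parametrize("dep,man,tau", [
        ([1, 2, 3], [3, 2, 1], -1.0),          # perfect anti-monotone
        ([1, 2, 3], [1, 3, 2], 1 / 3),         # 2 concordant, 1 discordant
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
    ])
    def test_exact_values(self, dep, man, tau):
        r = kendall_correlation(_series("PHQ9", dep), _series("ASRM", man))
        assert r.statistic == pytest.approx(tau)

    def test_constant_series_is_ill_defined(self):
        r = kendall_correlation(_series("PHQ9", [4, 4, 4, 4]),
                                _series("ASRM", [1, 2, 3, 4]))
        assert r.statistic is None and r.p_value is None
        assert r.detail["reason"] == "constant_series"

    def test_antisymmetric_under_order_reversal(self, rng):
        dep = rng.integers(0, 27, 30)
        man = rng.integers(0, 20, 30)
        r1 = kendall_correlation(_series("PHQ9", dep), _series("ASRM", man))
        r2 = kendall_correlation(_series("PHQ9", dep),
                                 _series("ASRM", 20 - man))
        assert r1.statistic == pytest.approx(-r2.statistic)

    def test_missing_pairs_dropped(self):
        r = kendall_correlation(_series("PHQ9", [1, np.nan, 2, 3]),
                                _series("ASRM", [3, 5, 2, 1]))
        assert r.n_used == 3 and r.statistic == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            kendall_correlation(_series("PHQ9", [1, np.nan]),
                                _series("ASRM", [2, 3]))


class TestManiaRisk:
    def test_toy_counts(self):
        # 4 depressed surveys of which 2 manic; 6 not depressed, 1 manic
        phq = _series("PHQ9", [12, 15, 11, 10, 3, 4, 5, 2, 1, 0])
        asr = _series("ASRM", [7, 8, 2, 3, 6, 1, 2, 3, 0, 1])
        r = mania_risk(asr, phq)
        assert r.risk_depressed == pytest.approx(0.5)
        assert r.risk_not_depressed == pytest.approx(1 / 6)
        assert r.n_depressed + r.n_not_depressed == 10

    def test_never_depressed_is_undefined_on_that_side(self):
        r = mania_risk(_series("ASRM", [7, 2, 8]), _series("PHQ9", [3, 4, 5]))
        assert r.risk_depressed is None
        assert r.risk_not_depressed == pytest.approx(2 / 3)

    def test_always_manic(self):
        r = mania_risk(_series("ASRM", [7, 8, 9, 10]),
                       _series("PHQ9", [12, 3, 15, 2]))
        assert r.risk_depressed == 1.0 and r.risk_not_depressed == 1.0

    def test_custom_cutoffs(self):
        r = mania_risk(_series("ASRM", [5, 5, 1]), _series("PHQ9", [9, 2, 9]),
                       mania_cut=5, dep_cut=9)
        assert r.risk_depressed == pytest.approx(0.5)


class TestFrequencyGrid:
    def test_bimonthly_grid_in_cycles_per_year(self):
        g = frequency_grid(1 / 61.0) * 365.25
        assert len(g) == 30
        assert g[0] == pytest.approx(0.25, rel=0.01)
        assert g[-1] == pytest.approx(3.0, rel=0.01)

    def test_weekly_grid_in_cycles_per_week(self):
        g = frequency_grid(1 / 7.0) * 7.0
        assert g[0] == pytest.approx(1 / 24)
        assert g[-1] == pytest.approx(1 / 2)

    def test_even_spacing(self):
        g = frequency_grid(0.123)
        assert np.allclose(np.diff(g), np.diff(g)[0])

    def test_invalid_sampling_frequency(self):
        with pytest.raises(ValueError):
            frequency_grid(0.0)


class TestHarmonicFTest:
    def test_injected_sinusoid_detected_at_its_frequency(self, rng):
        t = 7.0 * np.arange(120)
        grid = frequency_grid(1 / 7.0)
        f0 = grid[10]
        x = np.clip(np.rint(8 + 5 * np.sin(2 * np.pi * f0 * t)
                            + rng.normal(0, 1, 120)), 0, 52)
        sr = harmonic_f_test(_series("SIGHD", x, spacing=7.0))
        assert np.argmin(sr.p_values) == 10
        assert sr.p_values[10] < 1e-3

    def test_invariant_to_adding_a_constant(self, rng):
        x = np.clip(rng.integers(2, 15, 60).astype(float), 0, 52)
        s1 = harmonic_f_test(_series("SIGHD", x, spacing=7.0))
        s2 = harmonic_f_test(_series("SIGHD", x + 10, spacing=7.0))
        np.testing.assert_allclose(s1.f_statistics, s2.f_statistics,
                                   atol=1e-9)

    def test_null_pvalues_approximately_uniform(self, rng):
        # white noise calibration at a few interior grid frequencies
        reps = 300
        pvals = np.empty((reps, 30))
        for r in range(reps):
            x = rng.normal(10, 2, 52)
            sr = harmonic_f_test(_series("SIGHD", np.clip(np.rint(x), 0, 52),
                                         spacing=7.0))
            pvals[r] = sr.p_values
        for k in (5, 14, 25):
            assert stats.kstest(pvals[:, k], "uniform").pvalue > 0.01

    def test_constant_series_degenerate(self):
        sr = harmonic_f_test(_series("SIGHD", [7] * 30, spacing=7.0))
        assert np.all(sr.p_values == 1.0)
        assert sr.detail["degenerate"]

    def test_missing_values_interpolated(self, rng):
        x = rng.integers(2, 15, 52).astype(float)
        x[[3, 17, 30]] = np.nan
        sr = harmonic_f_test(_series("SIGHD", x, spacing=7.0))
        assert np.all(np.isfinite(sr.p_values))

    def test_too_short_series(self):
        with pytest.raises(InsufficientDataError):
            harmonic_f_test(_series("SIGHD", np.arange(10.0), spacing=7.0))


class TestDipTest:
    def test_unimodal_calibration(self):
        # rounded Gaussians should rarely be flagged
        rng = np.random.default_rng(0)
        n_ok = 0
        for seed in range(40):
            z = np.clip(np.rint(rng.normal(12, 2, 200)), 0, 27)
            n_ok += int(dip_test(z, seed=seed).p_value > 0.05)
        assert n_ok >= 36  # >= 90% of seeds

    def test_bimodal_power(self):
        rng = np.random.default_rng(1)
        n_rej = 0
        for seed in range(40):
            z = np.concatenate([rng.normal(2, 0.5, 100),
                                rng.normal(15, 0.5, 100)])
            z = np.clip(np.rint(z), 0, 27)
            n_rej += int(dip_test(z, seed=seed).p_value < 0.05)
        assert n_rej >= 38  # >= 95% of seeds

    def test_identical_scores_jitter_to_uniform(self):
        r = dip_test([5] * 50, seed=0)
        assert r.p_value > 0.3  # uniform on one unit interval is unimodal

    def test_too_few_scores(self):
        with pytest.raises(InsufficientDataError):
            dip_test([1, 2, 3], seed=0)

    def test_seed_controls_jitter(self):
        z = np.rint(np.random.default_rng(3).normal(10, 3, 60))
        r1, r2 = dip_test(z, seed=1), dip_test(z, seed=1)
        assert r1.statistic == r2.statistic
        r3 = dip_test(z, seed=2)
        assert r3.statistic != r1.statistic


def _affective_series(n, dt, params, inst, seed, clip_hi):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = sample_stationary("affective", params, None, rng)
    for i in range(n - 1):
        x[i + 1] = sample_transition("affective", params, x[i], dt, rng)
    z = np.clip(np.rint(params.s * x), 0, clip_hi)
    return _series(inst, z, spacing=dt)


class TestGoodnessOfFit:
    def test_self_consistency_pvalues_not_extreme(self):
        # data from the model itself: bootstrap p-values should span the
        # unit interval rather than concentrate near 0
        params = AffectiveMarginalParams(0.002, 5.0, s=5.8)
        pvals = [gof_density_test(
            _affective_series(25, 61.0, params, "PHQ9", 100 + k, 27),
            n_boot=30, seed=k).p_value for k in range(8)]
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.25
        assert 0.2 <= np.mean(pvals) <= 0.8

    def test_density_test_rejects_mismatched_gaussian_data(self):
        # mean-reverting Gaussian data with negative excursions shifted
        # into range: symmetric around the mean, unlike the skewed
        # stationary law of the affective model at small b
        ou = LinearMeanRevertingParams(kappa=0.05, theta=3.0, sigma=2.2)
        pvals = []
        for k in range(5):
            rng = np.random.default_rng(k)
            x = np.empty(60)
            x[0] = sample_stationary("ou", ou, None, rng)
            for i in range(59):
                x[i + 1] = sample_transition("ou", ou, x[i], 61.0, rng)
            z = np.clip(np.rint(x), 0, 27)
            s = _series("PHQ9", z)
            pvals.append(gof_density_test(s, "affective", n_boot=30,
                                          seed=k).p_value)
        assert np.median(pvals) < 0.05

    def test_transition_self_consistency(self):
        params = AffectiveMarginalParams(0.003, 5.0, s=2.0)
        pvals = [gof_transition_test(
            _affective_series(52, 7.0, params, "YMRS", 200 + k, 60),
            n_boot=30, seed=k).p_value for k in range(6)]
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.34
        assert np.mean(pvals) > 0.2

    def test_empty_bootstrap_is_an_error(self):
        s = _affective_series(25, 61.0, AffectiveMarginalParams(0.002, 5.0, 5.8),
                              "PHQ9", 7, 27)
        with pytest.raises(ValueError):
            gof_density_test(s, n_boot=0, seed=0)

    def test_pvalue_counts_replicates_at_least_as_discrepant(self):
        s = _affective_series(30, 61.0, AffectiveMarginalParams(0.002, 5.0, 5.8),
                              "PHQ9", 8, 27)
        r = gof_density_test(s, n_boot=25, seed=3)
        assert 0.0 <= r.p_value <= 1.0
        assert r.detail["n_boot"] + r.detail["n_failed"] == 25
        assert r.detail["fit_quantile_pct"] == pytest.approx(100 * r.p_value)
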