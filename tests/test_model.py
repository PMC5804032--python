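"""Core diffusion model: drift, simulation, closed forms, likelihood, fitting."""

import numpy as np
import pytest
from scipy import integrate, stats

from moodcourse.errors import (DegenerateDataError, DomainError,
                               InsufficientDataError,
                               UnsupportedConfigurationError)
from moodcourse.model import (AffectiveMarginalParams, AffectiveParams,
                              DEFAULT_AFFECTIVE, LinearMeanRevertingParams,
                              SquareRootDiffusionParams, MoodPath,
                              SimulationConfig, affective_drift, fit_mle,
                              log_likelihood, sample_stationary,
                              sample_transition, simulate, stationary_cdf,
                              stationary_density, transition_cdf,
                              transition_density)

FIG_PARAMS = DEFAULT_AFFECTIVE  # a_d=0.002, a_m=0.003, b=5, rho=0
MARG = AffectiveMarginalParams(a=0.003, b=5.0)


class TestParams:
    @pytest.mark.parametrize("bad", [
        dict(a_d=0.0), dict(b_m=-1.0), dict(rho=1.5), dict(s_d=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(a_d=0.002, a_m=0.003, b_d=5.0, b_m=5.0)
        kw.update(bad)
        with pytest.raises(DomainError):
            AffectiveParams(**kw)

    def test_json_round_trip(self):
        p = AffectiveParams(0.002, 0.003, 5, 5, rho=-0.2, s_d=3, s_m=1.5)
        assert AffectiveParams.from_json(p.to_json()) == p


class TestDrift:
    def test_zero_exactly_at_stable_point(self):
        dd, dm = affective_drift(np.sqrt(5), np.sqrt(5), FIG_PARAMS)
        assert dd == 0.0 and dm == 0.0

    def test_direct_substitution(self):
        dd, _ = affective_drift(1.0, 1.0, FIG_PARAMS)
        assert dd == pytest.approx(0.002 * (5 / 1 - 1))  # 0.008/day

    def test_divergence_near_zero_keeps_positivity(self):
        dd, _ = affective_drift(1e-9, 1.0, FIG_PARAMS)
        assert dd > 1e5

    def test_domain_error_on_nonpositive_state(self):
        with pytest.raises(DomainError):
            affective_drift(0.0, 1.0, FIG_PARAMS)

    def test_noise_free_flow_monotone_toward_fixed_point(self):
        cfg_lo = SimulationConfig(dt=0.5, seed=0, noise=False, init_d=0.2,
                                  init_m=0.2)
        path = simulate("affective", FIG_PARAMS, 2000, cfg_lo)
        assert np.all(np.diff(path.d_values) >= -1e-12)
        cfg_hi = SimulationConfig(dt=0.5, seed=0, noise=False, init_d=9.0,
                                  init_m=9.0)
        path = simulate("affective", FIG_PARAMS, 2000, cfg_hi)
        assert np.all(np.diff(path.d_values) <= 1e-12)


class TestSimulate:
    def test_noise_free_convergence_to_sqrt_b(self):
        cfg = SimulationConfig(dt=0.1, seed=0, noise=False, init_d=0.5,
                               init_m=7.0)
        path = simulate("affective", FIG_PARAMS, 5000, cfg)
        assert path.d_values[-1] == pytest.approx(np.sqrt(5), abs=1e-3)
        assert path.m_values[-1] == pytest.approx(np.sqrt(5), abs=1e-3)

    def test_reproducible_and_seed_sensitive(self):
        cfg = SimulationConfig(dt=0.1, seed=3)
        p1 = simulate("affective", FIG_PARAMS, 500, cfg)
        p2 = simulate("affective", FIG_PARAMS, 500, cfg)
        assert np.array_equal(p1.d_values, p2.d_values)
        p3 = simulate("affective", FIG_PARAMS, 500,
                      SimulationConfig(dt=0.1, seed=4))
        assert not np.array_equal(p1.d_values, p3.d_values)

    def test_paths_stay_strictly_positive(self):
        # start near zero where the 1/X drift must rescue the path
        cfg = SimulationConfig(dt=0.1, seed=1, init_d=0.01, init_m=0.01)
        path = simulate("affective", FIG_PARAMS, 20000, cfg)
        assert np.all(path.d_values > 0) and np.all(path.m_values > 0)
        cir = SquareRootDiffusionParams(kappa=0.5, theta=0.2, sigma=1.0)
        path = simulate("cir", cir, 2000, SimulationConfig(dt=0.1, seed=1,
                                                           init_d=0.05))
        assert np.all(path.d_values > 0)

    def test_exact_marginal_requires_independent_noise(self):
        p = AffectiveParams(0.002, 0.003, 5, 5, rho=0.4)
        with pytest.raises(UnsupportedConfigurationError):
            simulate("affective", p, 100,
                     SimulationConfig(scheme="exact_marginal"))

    def test_step_noise_correlation_matches_rho(self):
        for rho, tol in ((0.0, 0.05), (0.6, 0.05)):
            p = AffectiveParams(0.02, 0.02, 5, 5, rho=rho)
            cfg = SimulationConfig(dt=1.0, seed=5)
            path = simulate("affective", p, 4000, cfg)
            # recover the driving increments from the Euler update
            d, m = path.d_values, path.m_values
            zd = np.diff(d) - p.a_d * (p.b_d / d[:-1] - d[:-1])
            zm = np.diff(m) - p.a_m * (p.b_m / m[:-1] - m[:-1])
            r = np.corrcoef(zd, zm)[0, 1]
            assert r == pytest.approx(rho, abs=tol)

    def test_time_rescaling_of_a_is_exact_pathwise(self):
        # (c*a, b) at step dt equals (a, b) at step c*dt with the same noise
        c = 4.0
        base = AffectiveParams(0.002, 0.003, 5, 5)
        fast = AffectiveParams(c * 0.002, c * 0.003, 5, 5)
        p_fast = simulate("affective", fast, 1000,
                          SimulationConfig(dt=0.1, seed=9))
        p_slow = simulate("affective", base, 1000 * c,
                          SimulationConfig(dt=0.1 * c, seed=9))
        np.testing.assert_allclose(p_fast.d_values, p_slow.d_values)
        np.testing.assert_allclose(p_fast.m_values, p_slow.m_values)

    def test_long_run_mean_of_squared_coordinate(self):
        # stationary E[M^2] = b + 1; ~600 effective samples => tol ~3 SE
        cfg = SimulationConfig(dt=0.25, seed=11)
        path = simulate("affective", FIG_PARAMS, 2e5, cfg)
        m2 = path.m_values[::40] ** 2
        se = np.sqrt(2 * 12 * (1 / (2 * FIG_PARAMS.a_m)) / 2e5)
        assert m2.mean() == pytest.approx(6.0, abs=3 * se)

    def test_exact_marginal_matches_stationary_law(self):
        cfg = SimulationConfig(dt=500.0, seed=2, scheme="exact_marginal",
                               init_d=2.0, init_m=2.0)
        path = simulate("affective", FIG_PARAMS, 500.0 * 800, cfg)
        res = stats.kstest(path.m_values ** 2, stats.chi2(df=6).cdf)
        assert res.pvalue > 0.01

    def test_mood_path_csv_export(self, tmp_path):
        cfg = SimulationConfig(dt=1.0, seed=0)
        path = simulate("affective", FIG_PARAMS, 10, cfg)
        f = tmp_path / "path.csv"
        path.to_csv(f)
        assert f.read_text().splitlines()[0] == "time_days,d,m"


class TestStationaryDensity:
    def test_rayleigh_special_case(self):
        # b = 1: chi with 2 df, density x exp(-x^2/2)
        p = AffectiveMarginalParams(a=0.002, b=1.0)
        assert stationary_density("affective", p, 1.0) == pytest.approx(
            np.exp(-0.5), abs=1e-12)

    @pytest.mark.parametrize("b", [0.5, 2.0, 5.0])
    def test_mode_at_sqrt_b(self, b):
        p = AffectiveMarginalParams(a=0.002, b=b)
        xs = np.linspace(0.01, 6, 2000)
        dens = stationary_density("affective", p, xs)
        assert xs[np.argmax(dens)] == pytest.approx(np.sqrt(b), abs=0.01)

    @pytest.mark.parametrize("model_id,params", [
        ("affective", AffectiveMarginalParams(0.002, 5.0)),
        ("ou", LinearMeanRevertingParams(0.05, 10.0, 1.5)),
        ("cir", SquareRootDiffusionParams(0.05, 8.0, 0.8)),
    ])
    def test_normalisation(self, model_id, params):
        lo = -np.inf if model_id == "ou" else 1e-9
        val, _ = integrate.quad(
            lambda x: stationary_density(model_id, params, x), lo, np.inf,
            limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_numerical_fokker_planck(self):
        # stationary FP: 0 = -(mu f)' + (D f)'' with mu = a(b/x - x), D = a.
        # Integrating once (zero flux): f'/f = mu/D  =>  f ~ exp(int mu/a).
        p = AffectiveMarginalParams(a=0.004, b=3.0)
        xs = np.linspace(0.05, 8, 400)
        logf = np.array([integrate.quad(
            lambda u: (p.b / u - u), 0.05, x)[0] for x in xs])
        f = np.exp(logf)
        f /= np.trapezoid(f, xs)
        dens = stationary_density("affective", p, xs)
        dens /= np.trapezoid(dens, xs)
        np.testing.assert_allclose(f, dens, rtol=1e-3, atol=1e-6)

    def test_domain_error_outside_state_space(self):
        with pytest.raises(DomainError):
            stationary_density("affective", MARG, -1.0)


class TestTransitionDensity:
    def test_ergodic_limit_is_stationary(self):
        xs = np.linspace(0.1, 6, 60)
        td = transition_density("affective", MARG, 2.0, xs, 1e6)
        sd = stationary_density("affective", MARG, xs)
        assert np.max(np.abs(td - sd)) < 1e-8

    @pytest.mark.parametrize("model_id,params,x0", [
        ("affective", MARG, 2.0),
        ("ou", LinearMeanRevertingParams(0.05, 10.0, 1.5), 8.0),
        ("cir", SquareRootDiffusionParams(0.05, 8.0, 0.8), 5.0),
    ])
    def test_normalisation_in_x1(self, model_id, params, x0):
        lo = -np.inf if model_id == "ou" else 1e-9
        val, _ = integrate.quad(
            lambda x1: transition_density(model_id, params, x0, x1, 61.0),
            lo, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_chapman_kolmogorov(self):
        # two half-steps compose into one full step
        x0, dt = 1.8, 30.0
        xs = np.linspace(1e-3, 8, 1500)
        half = transition_density("affective", MARG, x0, xs, dt / 2)
        full = transition_density("affective", MARG, x0, 2.3, dt)
        half2 = transition_density("affective", MARG, xs, 2.3, dt / 2)
        composed = np.trapezoid(half * half2, xs)
        assert composed == pytest.approx(full, rel=1e-6)

    def test_monte_carlo_histogram_oracle(self):
        # exact one-step samples vs the closed-form density, binomial error
        rng = np.random.default_rng(0)
        n = 100_000
        samp = sample_transition("affective", MARG,
                                 np.full(n, 2.0), 61.0, rng)
        edges = np.linspace(0.5, 4.5, 33)
        hist, _ = np.histogram(samp, bins=edges)
        mids = 0.5 * (edges[1:] + edges[:-1])
        probs = (transition_cdf("affective", MARG, 2.0, edges[1:], 61.0)
                 - transition_cdf("affective", MARG, 2.0, edges[:-1], 61.0))
        exp = n * probs
        sd = np.sqrt(n * probs * (1 - probs))
        assert np.all(np.abs(hist - exp) < 5 * sd + 1)

    def test_invalid_delta_t(self):
        with pytest.raises(DomainError):
            transition_density("affective", MARG, 1.0, 1.0, 0.0)

    def test_transition_cdf_consistent_with_density(self):
        val, _ = integrate.quad(
            lambda x1: transition_density("affective", MARG, 2.0, x1, 20.0),
            1e-9, 2.5)
        assert val == pytest.approx(
            transition_cdf("affective", MARG, 2.0, 2.5, 20.0), abs=1e-7)


class TestLogLikelihood:
    def test_single_pair_matches_gaussian_closed_form(self):
        p = LinearMeanRevertingParams(0.05, 10.0, 1.2)
        ll = log_likelihood("ou", p, [8, 11], [0.0, 7.0])
        ee = np.exp(-0.05 * 7)
        mean = 10 + (8.5 - 10) * ee
        sd = np.sqrt(1.2**2 * (1 - ee**2) / (2 * 0.05))
        assert ll == pytest.approx(stats.norm.logpdf(11.5, mean, sd))

    def test_identity_scale_equals_sum_of_transition_logs(self):
        p = AffectiveMarginalParams(0.003, 5.0, s=1.0)
        scores = np.array([2, 3, 2, 4])
        times = np.array([0.0, 7.0, 21.0, 28.0])
        expected = sum(
            np.log(transition_density("affective", p, scores[i] + 0.5,
                                      scores[i + 1] + 0.5,
                                      times[i + 1] - times[i]))
            for i in range(3))
        assert log_likelihood("affective", p, scores, times) == \
            pytest.approx(expected)

    def test_gap_structure_matters(self):
        p = AffectiveMarginalParams(0.003, 5.0)
        scores = [2, 5, 3, 4]
        equal = log_likelihood("affective", p, scores, [0, 7, 14, 21])
        uneven = log_likelihood("affective", p, scores, [0, 7, 35, 42])
        assert equal != pytest.approx(uneven)
        # missing values only lengthen the gap
        with_gap = log_likelihood("affective", p, [2, np.nan, 5, 3, 4],
                                  [0, 3.5, 7, 35, 42])
        assert with_gap == pytest.approx(uneven)

    def test_all_missing_raises(self):
        with pytest.raises(InsufficientDataError):
            log_likelihood("affective", MARG, [np.nan, np.nan], [0, 7])


class TestFitMLE:
    def test_gaussian_fit_matches_ar1_regression_oracle(self, rng):
        # equally spaced OU observations are an AR(1); conditional least
        # squares gives closed-form estimates the MLE must reproduce
        true = LinearMeanRevertingParams(0.04, 12.0, 1.5)
        n, dt = 800, 7.0
        x = np.empty(n)
        x[0] = sample_stationary("ou", true, None, rng)
        for i in range(n - 1):
            x[i + 1] = sample_transition("ou", true, x[i], dt, rng)
        scores = x - 0.5  # offset restores x exactly
        fit = fit_mle("ou", scores, dt * np.arange(n), seed=0)
        y, z = x[1:], x[:-1]
        phi = np.polyfit(z, y, 1)
        kappa_cls = -np.log(phi[0]) / dt
        theta_cls = phi[1] / (1 - phi[0])
        resid = y - np.polyval(phi, z)
        sigma_cls = np.sqrt(np.var(resid) * 2 * kappa_cls
                            / (1 - phi[0] ** 2))
        assert fit.converged
        assert fit.params.kappa == pytest.approx(kappa_cls, rel=0.02)
        assert fit.params.theta == pytest.approx(theta_cls, rel=0.02)
        assert fit.params.sigma == pytest.approx(sigma_cls, rel=0.02)

    def test_affective_recovery_single_series(self, rng):
        true = AffectiveMarginalParams(a=0.003, b=5.0, s=2.0)
        n = 1500
        x = np.empty(n)
        x[0] = sample_stationary("affective", true, None, rng)
        for i in range(n - 1):
            x[i + 1] = sample_transition("affective", true, x[i], 7.0, rng)
        scores = true.s * x - 0.5
        fit = fit_mle("affective", scores, 7.0 * np.arange(n), seed=1)
        assert fit.converged
        assert fit.log_likelihood >= log_likelihood(
            "affective", true, scores, 7.0 * np.arange(n))
        assert fit.params.b == pytest.approx(5.0, rel=0.5)

    def test_constant_series_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_mle("affective", [4] * 20, 7.0 * np.arange(20))

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_mle("affective", [1, 2, 3], [0, 7, 14])

    def test_deterministic_given_seed(self, rng):
        x = np.abs(rng.normal(5, 2, 60)) + 1
        t = 7.0 * np.arange(60)
        f1 = fit_mle("cir", x, t, seed=5)
        f2 = fit_mle("cir", x, t, seed=5)
        assert f1.params == f2.params
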