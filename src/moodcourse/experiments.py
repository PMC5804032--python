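"""Reproducible validation experiments over the package's own machinery.

Each function runs a self-contained, seeded experiment — simulation
oracle checks, estimator calibration, regime-specific power — and
returns a plain dict of computed quantities.  The analysis drivers, the
test suite and the acceptance script all call these functions, so the
numbers they report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cohort import CohortSpec, generate_cohort, regime_oracle_check
from .model import (AffectiveMarginalParams, AffectiveParams,
                    DEFAULT_AFFECTIVE, SimulationConfig,
                    _euler_affective_paths, fit_mle, sample_stationary,
                    sample_transition, simulate)
from .patient import frequency_grid
from .population import mean_p_aggregate
from .study import run_parametric_study

__all__ = [
    "grid_summary", "aggregation_examples", "noise_free_convergence",
    "stationary_law_check", "parameter_recovery", "mean_p_type_i_error",
    "regime_power_suite", "study_monotonicity",
]


def grid_summary() -> dict:
    """Endpoints (in natural units) of the two standard frequency grids."""
    g_bi = frequency_grid(1.0 / 61.0)       # bimonthly, cycles/day
    g_wk = frequency_grid(1.0 / 7.0)        # weekly
    return {
        "n_frequencies": len(g_bi),
        "bimonthly_low_cyc_per_year": float(g_bi[0] * 365.25),
        "bimonthly_high_cyc_per_year": float(g_bi[-1] * 365.25),
        "weekly_low_cyc_per_week": float(g_wk[0] * 7.0),
        "weekly_high_cyc_per_week": float(g_wk[-1] * 7.0),
    }


def aggregation_examples() -> dict:
    """The canonical mean-p worked example: one vs one hundred p = 0.2."""
    one = mean_p_aggregate([0.2])
    hundred = mean_p_aggregate([0.2] * 100)
    return {
        "single_p02_aggregate": one.aggregate_p,
        "single_p02_rejected": one.rejected,
        "hundred_p02_aggregate": hundred.aggregate_p,
        "hundred_p02_rejected": hundred.rejected,
    }


def noise_free_convergence(duration: float = 5000.0) -> dict:
    """Distance of the noise-free flow from (sqrt(b_d), sqrt(b_m))."""
    p = DEFAULT_AFFECTIVE
    cfg = SimulationConfig(dt=0.1, seed=0, noise=False, init_d=0.3, init_m=9.0)
    path = simulate("affective", p, duration, cfg)
    err_d = abs(path.d_values[-1] - np.sqrt(p.b_d))
    err_m = abs(path.m_values[-1] - np.sqrt(p.b_m))
    return {"max_error": float(max(err_d, err_m)), "duration_days": duration}


def stationary_law_check(n_seeds: int = 20, duration_days: float = 3e5,
                         dt: float = 0.1, thin_days: float = 1250.0,
                         alpha: float = 0.01, seed: int = 0) -> dict:
    """KS comparison of simulated X^2 against its Gamma stationary law.

    Simulates ``n_seeds`` long Euler paths of the manic coordinate
    (a = 0.003/day, b = 5) in one vectorised sweep, thins each to
    weakly dependent samples (spacing ``thin_days`` ~ 7.5 mixing
    times), and tests X^2 against the chi-squared law with b + 1
    degrees of freedom at level ``alpha``.
    """
    p = DEFAULT_AFFECTIVE
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_days / dt))
    record_every = int(round(thin_days / dt))
    _, out_m = _euler_affective_paths(p, n_steps, dt, rng,
                                      init_d=np.sqrt(p.b_d),
                                      init_m=np.sqrt(p.b_m),
                                      n_paths=n_seeds,
                                      record_every=record_every)
    passed = 0
    pvals = []
    for i in range(n_seeds):
        y = out_m[:, i] ** 2
        res = stats.kstest(y, stats.chi2(df=p.b_m + 1.0).cdf)
        pvals.append(res.pvalue)
        passed += int(res.pvalue > alpha)
    return {"pass_fraction": passed / n_seeds, "n_seeds": n_seeds,
            "n_samples_per_seed": int(out_m.shape[0]),
            "ks_pvalues": pvals}


def parameter_recovery(n_reps: int = 50, n_obs: int = 2000,
                       dt_days: float = 7.0, a: float = 0.003, b: float = 5.0,
                       s: float = 2.0, rel_tol: float = 0.25,
                       seed: int = 0) -> dict:
    """Recovery of (a, b, s) from long weekly series of the affective model.

    Observations are continuous-valued (``score = s X - 1/2`` so the
    fitting offset reconstructs ``s X`` exactly); integer rounding at
    this scale would add quantisation noise comparable to the weekly
    innovation and bias the rate upward (see the methods note).
    """
    true = AffectiveMarginalParams(a=a, b=b, s=s)
    rng = np.random.default_rng(seed)
    x = np.empty((n_reps, n_obs))
    x[:, 0] = sample_stationary("affective", true, n_reps, rng)
    for i in range(n_obs - 1):
        x[:, i + 1] = sample_transition("affective", true, x[:, i],
                                        dt_days, rng)
    times = dt_days * np.arange(n_obs)
    scores = s * x - 0.5
    n_ok = 0
    errors = np.empty((n_reps, 3))
    for r in range(n_reps):
        fit = fit_mle("affective", scores[r], times, seed=seed + r)
        p = fit.params
        errors[r] = [abs(p.a - a) / a, abs(p.b - b) / b, abs(p.s - s) / s]
        n_ok += int(np.all(errors[r] <= rel_tol))
    return {"success_rate": n_ok / n_reps, "n_reps": n_reps,
            "median_rel_errors": np.median(errors, axis=0).tolist(),
            "rel_tol": rel_tol}


def mean_p_type_i_error(n_trials: int = 10_000, ns: tuple = (5, 15, 178),
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the mean-p aggregate under the uniform null."""
    from .population import EXACT_N_MAX
    rng = np.random.default_rng(seed)
    rates = {}
    for n in ns:
        means = rng.random((n_trials, n)).mean(axis=1)
        if n <= EXACT_N_MAX:  # same switch as mean_p_aggregate, vectorised
            aggp = stats.irwinhall(n).cdf(means * n)
        else:
            aggp = stats.norm.cdf(means, loc=0.5,
                                  scale=np.sqrt(1.0 / (12.0 * n)))
        rates[int(n)] = float(np.mean(aggp < alpha))
    return {"rates": rates, "n_trials": n_trials, "alpha": alpha}


def regime_power_suite(seed: int = 0, n_patients: int = 20,
                       n_affective: int = 15, gof_boot: int = 40) -> dict:
    """Power/retention of each test on the regime that targets it.

    Rhythmic, multistable and one-dimensional cohorts should be flagged
    by their matching tests; an affective cohort should retain the
    unimodality null and show roughly nominal goodness-of-fit
    rejection rates.
    """
    out = {}
    for k, (regime, n) in enumerate((
            ("rhythmic", n_patients), ("multistable", n_patients),
            ("one_dimensional", n_patients), ("affective", n_affective))):
        spec = CohortSpec(n_patients=n, regime=regime, cadence="bimonthly",
                          seed=seed + 101 * (k + 1))
        cohort = generate_cohort(spec)
        out[regime] = regime_oracle_check(regime, cohort, seed=seed,
                                          gof_boot=gof_boot)
    return out


def study_monotonicity(years: float = 50.0, warmup_years: float = 5.0,
                       seeds: tuple = (0, 1),
                       b_d_levels: tuple = (5.0, 8.0),
                       a_d_levels: tuple = (0.002, 0.008)) -> dict:
    """Effect of b_d on time depressed and of a_d on episode length.

    Scaled-down runs (tens of years) average over a couple of seeds;
    higher b_d should increase percent time depressed, higher a_d
    should shorten the mean depressive episode.
    """
    base = DEFAULT_AFFECTIVE

    def summarize(params, seed):
        cfg = SimulationConfig(dt=0.1, seed=seed, init_d=0.1, init_m=0.1)
        return run_parametric_study(params, total_years=years,
                                    warmup_years=warmup_years, config=cfg)

    pct_dep = {}
    for b_d in b_d_levels:
        p = AffectiveParams(base.a_d, base.a_m, b_d, base.b_m, base.rho)
        vals = [summarize(p, s).percent_time["depression"] for s in seeds]
        pct_dep[b_d] = float(np.mean(vals))
    mean_dur = {}
    for a_d in a_d_levels:
        p = AffectiveParams(a_d, base.a_m, base.b_d, base.b_m, base.rho)
        durs = []
        for s in seeds:
            d = summarize(p, s).mean_durations["depression"]
            if d is not None:
                durs.append(d)
        mean_dur[a_d] = float(np.mean(durs)) if durs else None
    return {"percent_depression_by_b_d": pct_dep,
            "mean_dep_episode_days_by_a_d": mean_dur,
            "years": years, "seeds": list(seeds)}
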