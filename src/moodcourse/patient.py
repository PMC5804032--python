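"""Patient-level statistical tests of mood-course hypotheses.

Four procedures, each applied to one patient's survey series:

* one-dimensionality — Kendall rank correlation between concurrent
  depressive and manic scores, plus the risk of mania while depressed
  versus while not depressed;
* rhythmicity — Thomson's multitaper harmonic F test over a 30-point
  frequency grid;
* multistability — Hartigan's dip test on jittered integer scores;
* model adequacy — two parametric-bootstrap goodness-of-fit tests
  (stationary density and one-step transition distribution) against
  the affective-instability model or the OU/CIR comparison models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal.windows import dpss

from . import model as mc_model
from .data import INSTRUMENTS, SurveySeries
from .dip import dip_monte_carlo_null, dip_statistic
from .errors import InsufficientDataError
from .model import SCORE_OFFSET, fit_mle, sample_stationary, sample_transition

__all__ = [
    "TestResult", "SpectralResult", "ManiaRisk",
    "kendall_correlation", "mania_risk", "frequency_grid",
    "harmonic_f_test", "dip_test", "gof_density_test", "gof_transition_test",
]

N_FREQUENCIES = 30
N_TAPERS = 7
TIME_BANDWIDTH = 4.0


@dataclass
class TestResult:
    """A patient-level statistic with its p-value.

    ``p_value`` (and sometimes ``statistic``) is ``None`` when the test
    is ill-defined for this patient (constant scores, empty risk
    denominator); such results are excluded from population aggregation.
    """

    test: str
    statistic: float | None
    p_value: float | None
    n_used: int
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "p_value": self.p_value, "n_used": self.n_used,
                "detail": self.detail}


@dataclass
class SpectralResult:
    """Per-frequency harmonic F statistics and p-values (30 frequencies)."""

    frequencies: np.ndarray
    f_statistics: np.ndarray
    p_values: np.ndarray
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.frequencies) == len(self.f_statistics)
                == len(self.p_values)):
            raise ValueError("spectral arrays must have equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class ManiaRisk:
    """Risk of concurrent mania, conditioned on depression status."""

    risk_depressed: float | None
    risk_not_depressed: float | None
    n_depressed: int
    n_not_depressed: int


def _paired(a: SurveySeries, b: SurveySeries) -> tuple[np.ndarray, np.ndarray]:
    """Complete concurrent pairs (a_scores, b_scores) on the shared grid."""
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if len(common) == 0:
        raise InsufficientDataError("series share no time points")
    sa, sb = a.scores[ia], b.scores[ib]
    keep = ~(np.isnan(sa) | np.isnan(sb))
    return sa[keep], sb[keep]


def kendall_correlation(dep: SurveySeries, man: SurveySeries) -> TestResult:
    """Kendall tau-b between concurrent depressive and manic scores.

    The tie-corrected tau-b variant is used because integer surveys are
    heavily tied.  Patients whose scores are constant across the paired
    surveys have no defined rank correlation and are marked undefined.
    """
    x, y = _paired(dep, man)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("kendall", None, None, len(x),
                          {"reason": "constant_series"})
    tau, p = stats.kendalltau(x, y)
    return TestResult("kendall", float(tau), float(p), len(x))


def mania_risk(asrm: SurveySeries, phq9: SurveySeries,
               mania_cut: int = 6, dep_cut: int = 10) -> ManiaRisk:
    """Fraction of concurrent surveys with mania, split by depression status.

    Mania is ASRM >= ``mania_cut``; depression is PHQ9 >= ``dep_cut``.
    A patient never depressed (or never not depressed) has an undefined
    risk on that side, reported as ``None``.
    """
    man, dep = _paired(asrm, phq9)
    if len(man) == 0:
        raise InsufficientDataError("no complete concurrent pairs")
    depressed = dep >= dep_cut
    manic = man >= mania_cut
    n_dep = int(depressed.sum())
    n_not = int((~depressed).sum())
    r_dep = float(manic[depressed].mean()) if n_dep else None
    r_not = float(manic[~depressed].mean()) if n_not else None
    return ManiaRisk(r_dep, r_not, n_dep, n_not)


def frequency_grid(sampling_freq: float, n: int = N_FREQUENCIES) -> np.ndarray:
    """``n`` frequencies equally spaced on [fs/24, fs/2] inclusive."""
    if not sampling_freq > 0:
        raise ValueError("sampling frequency must be positive")
    return np.linspace(sampling_freq / 24.0, sampling_freq / 2.0, n)


def _interpolate_missing(series: SurveySeries) -> np.ndarray:
    """Linear interpolation of missing scores on the scheduled grid."""
    t_obs, z_obs = series.observed()
    if len(z_obs) == 0:
        raise InsufficientDataError("all observations missing")
    return np.interp(series.times, t_obs, z_obs)


def harmonic_f_test(series: SurveySeries,
                    grid: np.ndarray | None = None) -> SpectralResult:
    """Thomson's multitaper harmonic F test for periodic line components.

    Uses K = 7 Slepian tapers with time-bandwidth 4.  At each grid
    frequency the taper eigencoefficients are regressed on the taper DC
    responses; the resulting F statistic has an F(2, 2K-2) null for a
    white locally-flat background.  The series mean is removed via the
    Slepian-taper mean estimate, and missing values are filled by linear
    interpolation beforehand (the spectral machinery needs contiguous
    data; the other tests drop missing values instead).
    """
    x = _interpolate_missing(series)
    t = series.times
    n = len(x)
    if n < 24:
        raise InsufficientDataError("harmonic F test needs >= 24 surveys")
    fs = 1.0 / float(np.median(np.diff(t)))
    if grid is None:
        grid = frequency_grid(fs)
    tapers = dpss(n, TIME_BANDWIDTH, N_TAPERS)  # (K, n), unit energy
    h0 = tapers.sum(axis=1)                     # taper DC responses
    if np.ptp(x) == 0:
        return SpectralResult(np.asarray(grid), np.zeros(len(grid)),
                              np.ones(len(grid)), {"degenerate": True})
    # mean removal via the Slepian tapers (weighted DC regression)
    y0 = tapers @ x
    mu = (y0 @ h0) / (h0 @ h0)
    x = x - mu
    phase = np.exp(-2j * np.pi * np.outer(np.asarray(grid), t))  # (F, n)
    y = phase @ (tapers * x).T                                   # (F, K)
    h0sq = h0 @ h0
    mu_f = (y @ h0) / h0sq
    resid = y - np.outer(mu_f, h0)
    num = (N_TAPERS - 1) * np.abs(mu_f) ** 2 * h0sq
    den = np.sum(np.abs(resid) ** 2, axis=1)
    fstat = np.where(den > 0, num / np.maximum(den, 1e-300), np.inf)
    pvals = stats.f.sf(fstat, 2, 2 * N_TAPERS - 2)
    return SpectralResult(np.asarray(grid), fstat, pvals, {"fs": fs, "mu": mu})


def dip_test(scores, seed: int = 0, n_reps: int = 2000) -> TestResult:
    """Hartigan dip test of unimodality on jittered integer scores.

    Each score receives uniform(-1/2, 1/2) jitter (symmetric
    de-rounding) so the sample is continuous; the p-value comes from a
    seeded Monte-Carlo null of uniform samples at the observed n (the
    dip's null distribution is the same for every continuous unimodal
    reference in the large-n sense; the uniform is the standard,
    conservative calibration choice).
    """
    z = np.asarray(scores, dtype=float)
    z = z[~np.isnan(z)]
    if len(z) < 10:
        raise InsufficientDataError("dip test needs >= 10 scores")
    rng = np.random.default_rng(seed)
    jittered = z + rng.uniform(-0.5, 0.5, size=len(z))
    d = dip_statistic(jittered)
    null = dip_monte_carlo_null(len(z), n_reps=n_reps)
    p = (1.0 + np.sum(null >= d)) / (len(null) + 1.0)
    return TestResult("dip", float(d), float(p), len(z))


# ---------------------------------------------------------------------------
# parametric-bootstrap goodness of fit
# ---------------------------------------------------------------------------


def _latent_scale(model_id: str, params) -> float:
    return params.s if model_id == "affective" else 1.0


def _density_statistic(model_id: str, params, z: np.ndarray) -> float:
    """KS distance between observed scores and the fitted stationary law."""
    x = (z + SCORE_OFFSET) / _latent_scale(model_id, params)
    u = mc_model.stationary_cdf(model_id, params, x)
    return float(stats.kstest(u, "uniform").statistic)


def _transition_statistic(model_id: str, params, z: np.ndarray,
                          t: np.ndarray) -> float:
    """KS distance of one-step probability integral transforms from uniform."""
    x = (z + SCORE_OFFSET) / _latent_scale(model_id, params)
    dts = np.diff(t)
    u = np.array([
        mc_model.transition_cdf(model_id, params, x[i], x[i + 1], dts[i])
        for i in range(len(x) - 1)
    ], dtype=float)
    return float(stats.kstest(u, "uniform").statistic)


def _simulate_replicate_scores(model_id: str, params, inst, times: np.ndarray,
                               n_reps: int, rng) -> np.ndarray:
    """(n_reps, len(times)) integer score replicates at the observed times."""
    scale = _latent_scale(model_id, params)
    x = sample_stationary(model_id, params, n_reps, rng)
    out = np.empty((n_reps, len(times)))
    out[:, 0] = x
    for i, dt in enumerate(np.diff(times)):
        x = sample_transition(model_id, params, x, dt, rng)
        out[:, i + 1] = x
    scores = np.rint(out * scale)  # observation model: score = round(s*x)
    return np.clip(scores, inst.score_min, inst.score_max)


def _gof_test(series: SurveySeries, model_id: str, n_boot: int, seed: int,
              statistic, test_name: str, refit_restarts: int) -> TestResult:
    if n_boot <= 0:
        raise ValueError("the parametric bootstrap needs at least 1 replicate")
    t, z = series.observed()
    fit = fit_mle(model_id, z, t, seed=seed)
    obs = statistic(model_id, fit.params, z, t)
    inst = INSTRUMENTS[series.instrument]
    rng = np.random.default_rng(seed)
    reps = _simulate_replicate_scores(model_id, fit.params, inst, t,
                                      n_boot, rng)
    null = []
    n_failed = 0
    for r in range(n_boot):
        try:
            rf = fit_mle(model_id, reps[r], t, seed=seed + 1 + r,
                         n_restarts=refit_restarts)
            null.append(statistic(model_id, rf.params, reps[r], t))
        except (InsufficientDataError, ValueError):
            n_failed += 1
    if not null:
        raise InsufficientDataError("all bootstrap replicates failed to fit")
    null = np.asarray(null)
    p = float(np.mean(null >= obs))
    return TestResult(test_name, obs, p, len(z),
                      {"model_id": model_id, "n_boot": len(null),
                       "n_failed": n_failed,
                       "fit_quantile_pct": 100.0 * float(np.mean(null >= obs)),
                       "log_likelihood": fit.log_likelihood,
                       "converged": fit.converged})


def gof_density_test(series: SurveySeries, model_id: str = "affective",
                     n_boot: int = 200, seed: int = 0,
                     refit_restarts: int = 2) -> TestResult:
    """Does the fitted stationary density explain the scores as well as
    data simulated from the fitted model itself?

    The statistic is the KS distance between the observed scores and the
    fitted stationary CDF; the p-value is the fraction of ``n_boot``
    model-simulated datasets (same cadence and length, each re-fitted)
    with at least as large a discrepancy.  The ``fit_quantile_pct``
    detail is the "fits as well as q% of sampled data" reading.
    """
    def stat(mid, params, z, t):
        return _density_statistic(mid, params, z)
    return _gof_test(series, model_id, n_boot, seed, stat,
                     "gof_density", refit_restarts)


def gof_transition_test(series: SurveySeries, model_id: str = "affective",
                        n_boot: int = 200, seed: int = 0,
                        refit_restarts: int = 2) -> TestResult:
    """Parametric-bootstrap test of the fitted one-step transition law.

    Intended for the weekly cadence, which samples mood often enough to
    inform transition parameters.  The statistic is the KS distance of
    the one-step probability integral transforms from uniformity.
    """
    return _gof_test(series, model_id, n_boot, seed, _transition_statistic,
                     "gof_transition", refit_restarts)
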