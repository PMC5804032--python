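"""Affective-instability diffusion model and comparison diffusions.

Mood is modelled as a two-dimensional positive diffusion: a depressive
coordinate ``D_t`` and a manic coordinate ``M_t`` that each mean-revert
toward a baseline while being pushed away from zero,

    dD = a_d (b_d / D - D) dt + sqrt(2 a_d) (sqrt(1 - rho^2) dV + rho dW)
    dM = a_m (b_m / M - M) dt + sqrt(2 a_m) dW

with ``V`` and ``W`` independent Wiener processes.  In the absence of
noise the flow has a single asymptotically stable point at
``(sqrt(b_d), sqrt(b_m))``; ``a`` sets the speed of fluctuation (1/day)
and ``b`` the overall symptom level.  Observed integer survey scores are
scaled latent values, ``score ~ s * X``.

The squared coordinate ``Y = X**2`` satisfies (Ito)

    dY = 2 a (b + 1 - Y) dt + sqrt(8 a Y) dW,

a square-root (CIR-type) diffusion with kappa = 2a, theta = b + 1 and
sigma^2 = 8a.  Its stationary law is Gamma((b+1)/2, rate 1/2) — i.e.
chi-squared with b + 1 degrees of freedom — and its transition law is a
scaled noncentral chi-squared.  All closed forms for X follow by the
change of variables ``x -> x**2`` (Jacobian ``2x``).

Two standard one-dimensional comparison models are provided under the
same interface: a linear mean-reverting Gaussian diffusion
(Ornstein-Uhlenbeck) and a general square-root diffusion
(Cox-Ingersoll-Ross).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
    UnsupportedConfigurationError,
)

__all__ = [
    "AffectiveParams",
    "AffectiveMarginalParams",
    "LinearMeanRevertingParams",
    "SquareRootDiffusionParams",
    "MoodPath",
    "SimulationConfig",
    "ModelFit",
    "affective_drift",
    "simulate",
    "stationary_density",
    "stationary_cdf",
    "transition_density",
    "transition_cdf",
    "sample_stationary",
    "sample_transition",
    "log_likelihood",
    "fit_mle",
    "SCORE_OFFSET",
]

#: Observed integer scores are treated as continuous values ``score + 0.5``
#: (half the score resolution), so that a score of 0 maps into the strictly
#: positive state space of the affective and square-root models.
SCORE_OFFSET = 0.5

_EULER_FLOOR = 1e-4


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AffectiveParams:
    """Parameters of the two-dimensional affective-instability model.

    Rates ``a_d``/``a_m`` are in 1/day; ``b_d``/``b_m`` are dimensionless
    baseline levels; ``rho`` is the correlation of the driving noises
    (0 = independent symptoms); ``s_d``/``s_m`` translate latent mood into
    survey-score units.
    """

    a_d: float
    a_m: float
    b_d: float
    b_m: float
    rho: float = 0.0
    s_d: float = 1.0
    s_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a_d", "a_m", "b_d", "b_m", "s_d", "s_m"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if not -1.0 <= self.rho <= 1.0:
            raise DomainError(f"rho must lie in [-1, 1], got {self.rho}")

    def marginal(self, axis: str) -> "AffectiveMarginalParams":
        """One-coordinate parameters for ``axis`` in {'depression', 'mania'}."""
        if axis == "depression":
            return AffectiveMarginalParams(self.a_d, self.b_d, self.s_d)
        if axis == "mania":
            return AffectiveMarginalParams(self.a_m, self.b_m, self.s_m)
        raise ValueError(f"unknown axis {axis!r}")

    def to_dict(self) -> dict:
        return {
            "a_d": self.a_d, "a_m": self.a_m, "b_d": self.b_d, "b_m": self.b_m,
            "rho": self.rho, "s_d": self.s_d, "s_m": self.s_m,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "AffectiveParams":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, text: str) -> "AffectiveParams":
        return cls.from_dict(json.loads(text))


#: Fig-style reference parameterisation: slow depressive fluctuation
#: (a_d = 2 per 1000 days), slightly faster manic fluctuation
#: (a_m = 3 per 1000 days), equal baselines b = 5, independent noise.
DEFAULT_AFFECTIVE = AffectiveParams(a_d=0.002, a_m=0.003, b_d=5.0, b_m=5.0, rho=0.0)


@dataclass(frozen=True)
class AffectiveMarginalParams:
    """One coordinate of the affective model plus its observation scale."""

    a: float
    b: float
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "s"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class LinearMeanRevertingParams:
    """Ornstein-Uhlenbeck parameters: dX = kappa (theta - X) dt + sigma dW."""

    kappa: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise DomainError(f"kappa must be positive, got {self.kappa}")
        if not self.sigma > 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class SquareRootDiffusionParams:
    """CIR parameters: dX = kappa (theta - X) dt + sigma sqrt(X) dW."""

    kappa: float
    theta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise DomainError(f"kappa must be positive, got {self.kappa}")
        if not self.theta > 0:
            raise DomainError(f"theta must be positive, got {self.theta}")
        if not self.sigma > 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class MoodPath:
    """A latent mood trajectory on a time grid (days).

    ``m_values`` is ``None`` for the one-dimensional comparison models.
    """

    times: np.ndarray
    d_values: np.ndarray
    m_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "d_values", np.asarray(self.d_values, dtype=float))
        if self.m_values is not None:
            object.__setattr__(self, "m_values", np.asarray(self.m_values, dtype=float))
            if len(self.m_values) != len(self.times):
                raise ValueError("m_values length must match times")
        if len(self.d_values) != len(self.times):
            raise ValueError("d_values length must match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        m = self.m_values if self.m_values is not None else np.full_like(self.d_values, np.nan)
        return pd.DataFrame({"time_days": self.times, "d": self.d_values, "m": m})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SimulationConfig:
    """Plumbing for path simulation.

    ``scheme`` is ``euler_reflected`` (Euler-Maruyama with a reflecting
    floor, any rho) or ``exact_marginal`` (per-coordinate noncentral
    chi-squared transition sampling, rho = 0 only).  ``noise=False`` runs
    the deterministic drift flow, used for fixed-point diagnostics.
    """

    dt: float = 0.1
    seed: int = 0
    scheme: str = "euler_reflected"
    init_d: float = 1.0
    init_m: float = 1.0
    noise: bool = True

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.scheme not in ("euler_reflected", "exact_marginal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class ModelFit:
    """Result of a maximum-likelihood fit."""

    model_id: str
    params: object
    log_likelihood: float
    converged: bool
    n_obs: int
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# drift and simulation
# ---------------------------------------------------------------------------


def affective_drift(d: float, m: float, params: AffectiveParams) -> tuple[float, float]:
    """Deterministic drift (dD/dt, dM/dt) of the affective model, 1/day.

    Zero exactly at the stable point ``(sqrt(b_d), sqrt(b_m))``; diverges
    to +inf as either coordinate approaches zero, which is what keeps the
    process positive.
    """
    if not (np.all(np.asarray(d) > 0) and np.all(np.asarray(m) > 0)):
        raise DomainError("drift requires strictly positive d and m")
    dd = params.a_d * (params.b_d / d - d)
    dm = params.a_m * (params.b_m / m - m)
    return dd, dm


def _euler_affective_paths(
    params: AffectiveParams,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    init_d: float,
    init_m: float,
    n_paths: int = 1,
    noise: bool = True,
    record_every: int = 1,
    floor: float = _EULER_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama paths of (D, M); returns arrays (n_recorded, n_paths).

    The reflecting floor takes |x| then clips at ``floor`` so paths stay
    strictly positive.  Noise entering D is sqrt(1-rho^2) dV + rho dW and
    M is driven by dW alone, giving step-noise correlation rho.
    """
    a_d, a_m, b_d, b_m, rho = params.a_d, params.a_m, params.b_d, params.b_m, params.rho
    sig_d = math.sqrt(2.0 * a_d * dt)
    sig_m = math.sqrt(2.0 * a_m * dt)
    c1 = math.sqrt(max(0.0, 1.0 - rho * rho))
    d = np.full(n_paths, float(init_d))
    m = np.full(n_paths, float(init_m))
    n_rec = n_steps // record_every
    out_d = np.empty((n_rec, n_paths))
    out_m = np.empty((n_rec, n_paths))
    block = 8192
    k = 0  # records written
    step = 0
    while step < n_steps:
        nb = min(block, n_steps - step)
        if noise:
            z = rng.standard_normal((2, nb, n_paths))
        for i in range(nb):
            d = d + a_d * (b_d / d - d) * dt
            m = m + a_m * (b_m / m - m) * dt
            if noise:
                zw = z[0, i]
                d = d + sig_d * (c1 * z[1, i] + rho * zw)
                m = m + sig_m * zw
            np.abs(d, out=d)
            np.abs(m, out=m)
            np.maximum(d, floor, out=d)
            np.maximum(m, floor, out=m)
            step += 1
            if step % record_every == 0:
                out_d[k] = d
                out_m[k] = m
                k += 1
    return out_d, out_m


def _euler_1d(kind: str, params, n_steps: int, dt: float, rng, init: float,
              noise: bool = True, floor: float = _EULER_FLOOR) -> np.ndarray:
    """Euler path for the OU / CIR comparison models (single path)."""
    x = float(init)
    out = np.empty(n_steps)
    z = rng.standard_normal(n_steps) if noise else np.zeros(n_steps)
    k, th, sg = params.kappa, params.theta, params.sigma
    sdt = math.sqrt(dt)
    for i in range(n_steps):
        if kind == "ou":
            x = x + k * (th - x) * dt + (sg * sdt * z[i] if noise else 0.0)
        else:  # cir
            x = x + k * (th - x) * dt + sg * math.sqrt(max(x, 0.0)) * sdt * z[i]
            x = max(abs(x), floor)
        out[i] = x
    return out


def simulate(model_id: str, params, duration: float, config: SimulationConfig) -> MoodPath:
    """Simulate a path of the requested model over ``duration`` days.

    ``affective`` returns a two-coordinate :class:`MoodPath`; ``ou`` and
    ``cir`` return a path in ``d_values`` with ``m_values`` left None.
    ``exact_marginal`` uses the noncentral chi-squared transition of the
    squared coordinate and is only available for rho = 0 (the coupled
    transition has no closed form).
    """
    if duration < config.dt:
        raise ValueError("duration must be at least one time step")
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(duration / config.dt))
    times = config.dt * np.arange(1, n_steps + 1)

    if model_id == "affective":
        if config.scheme == "exact_marginal":
            if params.rho != 0.0:
                raise UnsupportedConfigurationError(
                    "exact_marginal sampling requires rho = 0"
                )
            if not config.noise:
                raise UnsupportedConfigurationError(
                    "exact_marginal has no noise-free variant"
                )
            d = _exact_affective_path(params.a_d, params.b_d, config.init_d,
                                      n_steps, config.dt, rng)
            m = _exact_affective_path(params.a_m, params.b_m, config.init_m,
                                      n_steps, config.dt, rng)
            return MoodPath(times, d, m)
        out_d, out_m = _euler_affective_paths(
            params, n_steps, config.dt, rng, config.init_d, config.init_m,
            n_paths=1, noise=config.noise,
        )
        return MoodPath(times, out_d[:, 0], out_m[:, 0])

    if model_id in ("ou", "cir"):
        if config.scheme == "exact_marginal":
            x = np.empty(n_steps)
            cur = np.array([config.init_d])
            for i in range(n_steps):
                cur = sample_transition(model_id, params, cur, config.dt, rng)
                x[i] = cur[0]
            return MoodPath(times, x, None)
        x = _euler_1d(model_id, params, n_steps, config.dt, rng,
                      config.init_d, noise=config.noise)
        return MoodPath(times, x, None)

    raise ValueError(f"unknown model_id {model_id!r}")


def _exact_affective_path(a: float, b: float, init: float, n_steps: int,
                          dt: float, rng) -> np.ndarray:
    """Exact path of one affective coordinate via Y = X^2 transitions."""
    y = init * init
    ee = math.exp(-2.0 * a * dt)
    c = 1.0 / (2.0 * (1.0 - ee))
    df = b + 1.0
    out = np.empty(n_steps)
    for i in range(n_steps):
        nc = 2.0 * c * y * ee
        y = rng.noncentral_chisquare(df, nc) / (2.0 * c)
        out[i] = math.sqrt(y)
    return out


# ---------------------------------------------------------------------------
# closed-form densities
# ---------------------------------------------------------------------------


def _check_positive_state(x, model_id: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if model_id in ("affective", "cir") and np.any(x <= 0):
        raise DomainError(f"{model_id} state space is x > 0")
    return x


def stationary_density(model_id: str, params, x) -> np.ndarray:
    """Stationary probability density of the model at ``x`` (latent scale).

    The affective marginal is the chi distribution with ``b + 1`` degrees
    of freedom (mode at sqrt(b)); OU is Gaussian; CIR is Gamma.
    """
    x = _check_positive_state(x, model_id)
    if model_id == "affective":
        return stats.chi.pdf(x, df=params.b + 1.0)
    if model_id == "ou":
        sd = params.sigma / math.sqrt(2.0 * params.kappa)
        return stats.norm.pdf(x, loc=params.theta, scale=sd)
    if model_id == "cir":
        shape = 2.0 * params.kappa * params.theta / params.sigma**2
        rate = 2.0 * params.kappa / params.sigma**2
        return stats.gamma.pdf(x, a=shape, scale=1.0 / rate)
    raise ValueError(f"unknown model_id {model_id!r}")


def stationary_cdf(model_id: str, params, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if model_id == "affective":
        return stats.chi.cdf(x, df=params.b + 1.0)
    if model_id == "ou":
        sd = params.sigma / math.sqrt(2.0 * params.kappa)
        return stats.norm.cdf(x, loc=params.theta, scale=sd)
    if model_id == "cir":
        shape = 2.0 * params.kappa * params.theta / params.sigma**2
        rate = 2.0 * params.kappa / params.sigma**2
        return stats.gamma.cdf(x, a=shape, scale=1.0 / rate)
    raise ValueError(f"unknown model_id {model_id!r}")


def _cir_transition_constants(kappa, theta, sigma, delta_t):
    ee = math.exp(-kappa * delta_t)
    c = 2.0 * kappa / (sigma**2 * (1.0 - ee))
    df = 4.0 * kappa * theta / sigma**2
    return c, df, ee


def transition_density(model_id: str, params, x0, x1, delta_t: float) -> np.ndarray:
    """Conditional density of X(t + delta_t) = x1 given X(t) = x0.

    Affective: the squared coordinate is CIR with kappa = 2a, theta = b+1,
    sigma^2 = 8a, so 2c X1^2 | x0 is noncentral chi-squared with b+1 df
    and noncentrality 2c x0^2 e^(-2a dt), c = 1/(2(1 - e^(-2a dt)));
    the density in x1 carries the Jacobian 2 x1.
    """
    if not delta_t > 0:
        raise DomainError("delta_t must be positive")
    x1 = _check_positive_state(x1, model_id)
    x0 = _check_positive_state(x0, model_id)
    if model_id == "affective":
        c, df, ee = _cir_transition_constants(2.0 * params.a, params.b + 1.0,
                                              math.sqrt(8.0 * params.a), delta_t)
        nc = 2.0 * c * np.asarray(x0) ** 2 * ee
        return 2.0 * c * 2.0 * x1 * stats.ncx2.pdf(2.0 * c * x1**2, df, nc)
    if model_id == "ou":
        mean, sd = _ou_transition_moments(params, x0, delta_t)
        return stats.norm.pdf(x1, loc=mean, scale=sd)
    if model_id == "cir":
        c, df, ee = _cir_transition_constants(params.kappa, params.theta,
                                              params.sigma, delta_t)
        nc = 2.0 * c * np.asarray(x0) * ee
        return 2.0 * c * stats.ncx2.pdf(2.0 * c * x1, df, nc)
    raise ValueError(f"unknown model_id {model_id!r}")


def _ou_transition_moments(params, x0, delta_t):
    ee = np.exp(-params.kappa * delta_t)
    mean = params.theta + (np.asarray(x0, dtype=float) - params.theta) * ee
    var = params.sigma**2 * (1.0 - ee**2) / (2.0 * params.kappa)
    return mean, np.sqrt(var)


def transition_cdf(model_id: str, params, x0, x1, delta_t: float) -> np.ndarray:
    """Conditional CDF P(X(t + delta_t) <= x1 | X(t) = x0)."""
    if not delta_t > 0:
        raise DomainError("delta_t must be positive")
    x1 = np.asarray(x1, dtype=float)
    if model_id == "affective":
        c, df, ee = _cir_transition_constants(2.0 * params.a, params.b + 1.0,
                                              math.sqrt(8.0 * params.a), delta_t)
        nc = 2.0 * c * np.asarray(x0) ** 2 * ee
        return stats.ncx2.cdf(2.0 * c * np.maximum(x1, 0.0) ** 2, df, nc)
    if model_id == "ou":
        mean, sd = _ou_transition_moments(params, x0, delta_t)
        return stats.norm.cdf(x1, loc=mean, scale=sd)
    if model_id == "cir":
        c, df, ee = _cir_transition_constants(params.kappa, params.theta,
                                              params.sigma, delta_t)
        nc = 2.0 * c * np.asarray(x0) * ee
        return stats.ncx2.cdf(2.0 * c * np.maximum(x1, 0.0), df, nc)
    raise ValueError(f"unknown model_id {model_id!r}")


def sample_stationary(model_id: str, params, size, rng: np.random.Generator):
    """Draw from the stationary law (latent scale)."""
    if model_id == "affective":
        return np.sqrt(rng.chisquare(params.b + 1.0, size=size))
    if model_id == "ou":
        sd = params.sigma / math.sqrt(2.0 * params.kappa)
        return rng.normal(params.theta, sd, size=size)
    if model_id == "cir":
        shape = 2.0 * params.kappa * params.theta / params.sigma**2
        rate = 2.0 * params.kappa / params.sigma**2
        return rng.gamma(shape, 1.0 / rate, size=size)
    raise ValueError(f"unknown model_id {model_id!r}")


def sample_transition(model_id: str, params, x0, delta_t: float,
                      rng: np.random.Generator):
    """Draw X(t + delta_t) given X(t) = x0, exactly; vectorised over x0."""
    x0 = np.asarray(x0, dtype=float)
    if model_id == "affective":
        c, df, ee = _cir_transition_constants(2.0 * params.a, params.b + 1.0,
                                              math.sqrt(8.0 * params.a), delta_t)
        nc = 2.0 * c * x0**2 * ee
        y = rng.noncentral_chisquare(df, nc) / (2.0 * c)
        return np.sqrt(y)
    if model_id == "ou":
        mean, sd = _ou_transition_moments(params, x0, delta_t)
        return rng.normal(mean, sd)
    if model_id == "cir":
        c, df, ee = _cir_transition_constants(params.kappa, params.theta,
                                              params.sigma, delta_t)
        nc = 2.0 * c * x0 * ee
        return rng.noncentral_chisquare(df, nc) / (2.0 * c)
    raise ValueError(f"unknown model_id {model_id!r}")


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------


def _observed_to_continuous(scores, times):
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    keep = ~np.isnan(scores)
    z = scores[keep] + SCORE_OFFSET
    t = times[keep]
    if len(z) == 0:
        raise InsufficientDataError("all observations are missing")
    return z, t


def _log_transition_density(model_id: str, params, x0: np.ndarray,
                            x1: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """Vectorised log transition density over consecutive pairs."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if model_id == "affective":
            ee = np.exp(-2.0 * params.a * dts)
            c = 1.0 / (2.0 * (1.0 - ee))
            df = params.b + 1.0
            nc = 2.0 * c * x0**2 * ee
            return (np.log(2.0 * c) + np.log(2.0 * x1)
                    + stats.ncx2.logpdf(2.0 * c * x1**2, df, nc))
        if model_id == "ou":
            ee = np.exp(-params.kappa * dts)
            mean = params.theta + (x0 - params.theta) * ee
            var = params.sigma**2 * (1.0 - ee**2) / (2.0 * params.kappa)
            return stats.norm.logpdf(x1, loc=mean, scale=np.sqrt(var))
        if model_id == "cir":
            ee = np.exp(-params.kappa * dts)
            c = 2.0 * params.kappa / (params.sigma**2 * (1.0 - ee))
            df = 4.0 * params.kappa * params.theta / params.sigma**2
            nc = 2.0 * c * x0 * ee
            return np.log(2.0 * c) + stats.ncx2.logpdf(2.0 * c * x1, df, nc)
    raise ValueError(f"unknown model_id {model_id!r}")


def log_likelihood(model_id: str, params, scores: Sequence, times: Sequence) -> float:
    """Markov log-likelihood of integer survey scores under a model.

    Scores are offset by +0.5 and, for the affective model, divided by the
    observation scale ``s`` (with the log-Jacobian ``-log s`` per
    transition).  Missing observations simply lengthen the time gap; the
    likelihood is the sum of log transition densities over consecutive
    observed pairs (conditional on the first observation).
    """
    z, t = _observed_to_continuous(scores, times)
    if len(z) < 2:
        raise InsufficientDataError("need at least 2 non-missing observations")
    if model_id == "affective":
        x = z / params.s
        jac = -math.log(params.s)
    elif model_id in ("ou", "cir"):
        x = z
        jac = 0.0
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    if model_id in ("affective", "cir") and np.any(x <= 0):
        return -np.inf
    dts = np.diff(t)
    logd = _log_transition_density(model_id, params, x[:-1], x[1:], dts)
    if not np.all(np.isfinite(logd)):
        return -np.inf
    return float(np.sum(logd) + jac * (len(x) - 1))


def _moment_init(model_id: str, z: np.ndarray, t: np.ndarray):
    """Crude moment/autocorrelation starting values on the observed scale."""
    dt_med = float(np.median(np.diff(t)))
    mean = float(np.mean(z))
    var = max(float(np.var(z)), 1e-8)
    # lag-1 autocorrelation on near-median gaps
    zc = z - mean
    num = float(np.sum(zc[:-1] * zc[1:]))
    den = float(np.sum(zc * zc))
    r = min(max(num / den if den > 0 else 0.3, 0.05), 0.95)
    if model_id == "ou":
        kappa = -math.log(r) / dt_med
        sigma = math.sqrt(2.0 * kappa * var)
        return LinearMeanRevertingParams(kappa, mean, sigma)
    if model_id == "cir":
        kappa = -math.log(r) / dt_med
        theta = max(mean, 1e-3)
        sigma = math.sqrt(max(2.0 * kappa * var / theta, 1e-8))
        return SquareRootDiffusionParams(kappa, theta, sigma)
    if model_id == "affective":
        # z ~ s X, X^2 ~ chi2(b+1): E z^2 = s^2 (b+1), Var z^2 = s^4 2(b+1)
        m2 = float(np.mean(z**2))
        v2 = max(float(np.var(z**2)), 1e-8)
        s2 = v2 / (2.0 * m2)
        b = max(m2 / s2 - 1.0, 0.2)
        # autocorr of z^2 decays like e^(-2 a dt)
        y = z**2
        yc = y - np.mean(y)
        dy = float(np.sum(yc * yc))
        ry = min(max(float(np.sum(yc[:-1] * yc[1:])) / dy if dy > 0 else 0.3,
                     0.05), 0.95)
        a = -math.log(ry) / (2.0 * dt_med)
        return AffectiveMarginalParams(a, b, math.sqrt(s2))
    raise ValueError(f"unknown model_id {model_id!r}")


_FIT_SPECS = {
    # (to unconstrained vector, from vector)
    "affective": (
        lambda p: np.log([p.a, p.b, p.s]),
        lambda v: AffectiveMarginalParams(*np.exp(v)),
    ),
    "ou": (
        lambda p: np.array([math.log(p.kappa), p.theta, math.log(p.sigma)]),
        lambda v: LinearMeanRevertingParams(math.exp(v[0]), v[1], math.exp(v[2])),
    ),
    "cir": (
        lambda p: np.log([p.kappa, p.theta, p.sigma]),
        lambda v: SquareRootDiffusionParams(*np.exp(v)),
    ),
}


def fit_mle(model_id: str, scores: Sequence, times: Sequence,
            init_strategy: str = "moment", seed: int = 0,
            n_restarts: int = 5) -> ModelFit:
    """Maximum-likelihood fit of a model to one observed score series.

    Optimises the Markov transition likelihood over log-transformed
    positive parameters (theta of the Gaussian model is unconstrained)
    with a moment-based start plus seeded random restarts; ties are broken
    by likelihood, then by smaller parameter norm.
    """
    z, t = _observed_to_continuous(scores, times)
    if len(z) < 10:
        raise InsufficientDataError("need at least 10 non-missing observations")
    if np.ptp(z) == 0:
        raise DegenerateDataError("series is constant; parameters are not identifiable")
    to_vec, from_vec = _FIT_SPECS[model_id]
    if init_strategy == "moment":
        p0 = _moment_init(model_id, z, t)
    else:
        raise ValueError(f"unknown init_strategy {init_strategy!r}")
    v0 = to_vec(p0)

    full_scores = z - SCORE_OFFSET  # re-offset inside objective
    def nll(v):
        try:
            with np.errstate(over="ignore"):
                p = from_vec(v)
            vals = (p.a, p.b, p.s) if hasattr(p, "a") else \
                (p.kappa, p.theta, p.sigma)
            if not np.all(np.isfinite(vals)):
                return np.inf
        except (DomainError, OverflowError):
            return np.inf
        ll = log_likelihood(model_id, p, full_scores, t)
        return -ll if np.isfinite(ll) else np.inf

    rng = np.random.default_rng(seed)
    starts = [v0] + [v0 + rng.normal(0.0, 0.5, size=len(v0))
                     for _ in range(max(0, n_restarts - 1))]
    best = None
    any_success = False
    for v in starts:
        res = optimize.minimize(nll, v, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxiter": 2000})
        if not np.isfinite(res.fun):
            continue
        key = (-res.fun, -float(np.linalg.norm(res.x)))
        if best is None or key > best[0]:
            best = (key, res)
        any_success = any_success or bool(res.success)
    if best is None:
        return ModelFit(model_id, p0, -np.inf, False, len(z),
                        {"message": "all starts failed"})
    res = best[1]
    params = from_vec(res.x)
    return ModelFit(model_id, params, -float(res.fun), any_success, len(z),
                    {"n_starts": len(starts), "message": str(res.message)})
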