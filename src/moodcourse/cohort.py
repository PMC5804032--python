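"""Synthetic survey cohorts with the structure each hypothesis assumes.

Four generative regimes produce paired mania/depression survey series:

* ``affective`` — the affective-instability diffusion, observed as
  ``round(s * X)`` at the survey times;
* ``rhythmic`` — a sinusoidal mood cycle plus noise (the periodic
  hypothesis);
* ``multistable`` — a semi-Markov switcher between euthymic, depressive
  and manic states with well-separated Gaussian score emissions (the
  multiple-stable-states hypothesis);
* ``one_dimensional`` — a single mean-reverting latent mood whose
  positive part drives mania scores and negative part depression
  scores (the bipolar "spectrum" hypothesis).

Cohort geometry and missingness emulate a longitudinal bipolar study:
bimonthly self-report surveys (ASRM/PHQ9, 61-day spacing, default 25
surveys ~ 4 years, missingness 0.55%/3.5%) and weekly interviewer
ratings (YMRS/SIGHD, default 52 surveys, missingness 9.7%/9.2%).
Missingness is completely at random, independent of the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import Cohort, INSTRUMENTS, Instrument, SurveySeries
from .errors import DomainError
from .model import (AffectiveParams, DEFAULT_AFFECTIVE,
                    LinearMeanRevertingParams, sample_stationary,
                    sample_transition, simulate, SimulationConfig)

__all__ = ["CohortSpec", "CADENCES", "generate_cohort", "latent_to_scores",
           "regime_oracle_check", "RhythmicParams", "MultistableParams",
           "OneDimensionalParams"]


#: cadence -> (spacing days, default number of surveys,
#:             mania instrument, depression instrument,
#:             default per-instrument missingness)
CADENCES = {
    "bimonthly": (61.0, 25, "ASRM", "PHQ9", {"ASRM": 0.0055, "PHQ9": 0.035}),
    "weekly": (7.0, 52, "YMRS", "SIGHD", {"YMRS": 0.097, "SIGHD": 0.092}),
}


@dataclass(frozen=True)
class RhythmicParams:
    """Sinusoidal mood cycle; frequency in cycles/day, phase random/patient."""

    frequency: float = 1.0 / 365.25
    amplitude_dep: float = 6.0
    amplitude_man: float = 4.0
    baseline_dep: float = 8.0
    baseline_man: float = 5.0
    noise_sd: float = 2.0
    antiphase: bool = True  # mania peaks when depression troughs

    def validate(self, spacing: float) -> None:
        if not 0 < self.frequency < 0.5 / spacing:
            raise DomainError("rhythm frequency must lie in (0, cadence/2)")
        if self.noise_sd <= 0 or self.amplitude_dep <= 0 or self.amplitude_man <= 0:
            raise DomainError("amplitudes and noise sd must be positive")


@dataclass(frozen=True)
class MultistableParams:
    """Semi-Markov switcher between euthymia, depression and mania.

    Dwell times are exponential with state-specific means (days);
    emissions are Gaussian around state-specific score means.  This is a
    test fixture embodying the multistable hypothesis, not a claim
    about bipolar disorder.
    """

    mean_dwell: dict = field(default_factory=lambda: {
        "euthymia": 150.0, "depression": 150.0, "mania": 120.0})
    dep_means: dict = field(default_factory=lambda: {
        "euthymia": 2.0, "depression": 16.0, "mania": 3.0})
    man_means: dict = field(default_factory=lambda: {
        "euthymia": 1.0, "depression": 2.0, "mania": 12.0})
    emission_sd: float = 1.0

    def validate(self, spacing: float) -> None:
        if self.emission_sd <= 0:
            raise DomainError("emission sd must be positive")
        if any(v <= 0 for v in self.mean_dwell.values()):
            raise DomainError("dwell means must be positive")


#: transition kernel of the switcher (row state -> column state)
_MS_STATES = ("euthymia", "depression", "mania")
_MS_KERNEL = {
    "euthymia": (("depression", 0.5), ("mania", 0.5)),
    "depression": (("euthymia", 0.8), ("mania", 0.2)),
    "mania": (("euthymia", 0.8), ("depression", 0.2)),
}


@dataclass(frozen=True)
class OneDimensionalParams:
    """One latent mean-reverting mood; sign splits the two poles.

    Positive latent values produce mania scores, negative values
    depression scores, so high scores on one axis force zero on the
    other (the strict two-poles structure).
    """

    ou: LinearMeanRevertingParams = LinearMeanRevertingParams(
        kappa=0.02, theta=0.0, sigma=0.3)
    scale: float = 8.0

    def validate(self, spacing: float) -> None:
        if self.scale <= 0:
            raise DomainError("scale must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort (fully seeded, reproducible)."""

    n_patients: int
    regime: str = "affective"
    cadence: str = "bimonthly"
    n_surveys: int | None = None
    missingness: dict | None = None
    regime_params: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("affective", "rhythmic", "multistable",
                               "one_dimensional"):
            raise DomainError(f"unknown regime {self.regime!r}")
        if self.cadence not in CADENCES:
            raise DomainError(f"unknown cadence {self.cadence!r}")
        if self.n_patients < 1:
            raise DomainError("need at least one patient")
        miss = self.resolved_missingness()
        if any(not 0 <= v < 1 for v in miss.values()):
            raise DomainError("missingness fractions must lie in [0, 1)")
        spacing, n_default, *_ = CADENCES[self.cadence]
        n = self.n_surveys or n_default
        if self.cadence == "weekly" and n < 24:
            raise DomainError("weekly cohorts need at least 24 surveys")
        if self.cadence == "bimonthly" and n * spacing < 4 * 365.25:
            raise DomainError("bimonthly cohorts span at least 4 years")

    def resolved_missingness(self) -> dict:
        return dict(CADENCES[self.cadence][4] if self.missingness is None
                    else self.missingness)

    def resolved_regime_params(self):
        spacing = CADENCES[self.cadence][0]
        if self.regime_params is not None:
            p = self.regime_params
        elif self.regime == "affective":
            # scale so the median latent level maps to instrument mid-range,
            # which gives realistic spread across the integer score grid
            from scipy.stats import chi
            _, _, man_name, dep_name, _ = CADENCES[self.cadence]
            base = DEFAULT_AFFECTIVE
            s_d = (0.5 * INSTRUMENTS[dep_name].score_max
                   / chi.ppf(0.5, base.b_d + 1.0))
            s_m = (0.5 * INSTRUMENTS[man_name].score_max
                   / chi.ppf(0.5, base.b_m + 1.0))
            p = AffectiveParams(base.a_d, base.a_m, base.b_d, base.b_m,
                                base.rho, s_d=round(s_d, 3), s_m=round(s_m, 3))
        elif self.regime == "rhythmic":
            p = RhythmicParams()
        elif self.regime == "multistable":
            p = MultistableParams()
        else:
            p = OneDimensionalParams()
        if hasattr(p, "validate"):
            p.validate(spacing)
        return p

    def to_dict(self) -> dict:
        rp = self.resolved_regime_params()
        rp_dict = rp.to_dict() if hasattr(rp, "to_dict") else asdict(rp) \
            if not isinstance(rp, dict) else rp
        return {"n_patients": self.n_patients, "regime": self.regime,
                "cadence": self.cadence, "n_surveys": self.n_surveys,
                "missingness": self.resolved_missingness(),
                "regime_params": rp_dict, "seed": self.seed}


def latent_to_scores(latent, scale: float, instrument: Instrument):
    """Observation model: integer score = round(scale * latent), clipped."""
    if scale <= 0:
        raise DomainError("scale must be positive")
    latent = np.asarray(latent, dtype=float)
    return np.clip(np.rint(latent * scale), instrument.score_min,
                   instrument.score_max)


def _affective_latents(params: AffectiveParams, times, rng):
    """Latent (D, M) at the survey times, exact when rho = 0."""
    if params.rho == 0.0:
        d = _exact_series(params.a_d, params.b_d, times, rng)
        m = _exact_series(params.a_m, params.b_m, times, rng)
        return d, m
    cfg = SimulationConfig(dt=0.1, seed=int(rng.integers(2**31)),
                           init_d=np.sqrt(params.b_d),
                           init_m=np.sqrt(params.b_m))
    path = simulate("affective", params, times[-1] + cfg.dt, cfg)
    idx = np.searchsorted(path.times, times)
    idx = np.clip(idx, 0, len(path.times) - 1)
    return path.d_values[idx], path.m_values[idx]


def _exact_series(a: float, b: float, times, rng):
    from .model import AffectiveMarginalParams
    p = AffectiveMarginalParams(a, b)
    x = sample_stationary("affective", p, None, rng)
    out = np.empty(len(times))
    out[0] = x
    for i, dt in enumerate(np.diff(times)):
        x = sample_transition("affective", p, x, dt, rng)
        out[i + 1] = float(x)
    return out


def _generate_patient(spec: CohortSpec, params, times, man_inst, dep_inst, rng):
    """(dep_scores, man_scores) for one patient, before missingness."""
    if spec.regime == "affective":
        d, m = _affective_latents(params, times, rng)
        dep = latent_to_scores(d, params.s_d, dep_inst)
        man = latent_to_scores(m, params.s_m, man_inst)
    elif spec.regime == "rhythmic":
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * params.frequency * times + phase)
        wave_m = -wave if params.antiphase else wave
        dep = params.baseline_dep + params.amplitude_dep * wave \
            + rng.normal(0, params.noise_sd, len(times))
        man = params.baseline_man + params.amplitude_man * wave_m \
            + rng.normal(0, params.noise_sd, len(times))
        dep = np.clip(np.rint(dep), dep_inst.score_min, dep_inst.score_max)
        man = np.clip(np.rint(man), man_inst.score_min, man_inst.score_max)
    elif spec.regime == "multistable":
        states = _semi_markov_states(params, times, rng)
        dep = np.array([params.dep_means[s] for s in states])
        man = np.array([params.man_means[s] for s in states])
        dep = dep + rng.normal(0, params.emission_sd, len(times))
        man = man + rng.normal(0, params.emission_sd, len(times))
        dep = np.clip(np.rint(dep), dep_inst.score_min, dep_inst.score_max)
        man = np.clip(np.rint(man), man_inst.score_min, man_inst.score_max)
    else:  # one_dimensional
        lat = _ou_series(params.ou, times, rng)
        dep = latent_to_scores(np.maximum(-lat, 0.0), params.scale, dep_inst)
        man = latent_to_scores(np.maximum(lat, 0.0), params.scale, man_inst)
    return dep, man


def _semi_markov_states(params: MultistableParams, times, rng) -> list[str]:
    state = "euthymia"
    t_next = rng.exponential(params.mean_dwell[state])
    out = []
    t_prev = 0.0
    for t in times:
        # advance the switcher to time t
        elapsed = t - t_prev
        while elapsed >= t_next:
            elapsed -= t_next
            targets, probs = zip(*_MS_KERNEL[state])
            state = targets[rng.choice(len(targets), p=np.array(probs))]
            t_next = rng.exponential(params.mean_dwell[state])
        t_next -= elapsed
        t_prev = t
        out.append(state)
    return out


def _ou_series(p: LinearMeanRevertingParams, times, rng):
    x = sample_stationary("ou", p, None, rng)
    out = np.empty(len(times))
    out[0] = x
    for i, dt in enumerate(np.diff(times)):
        x = float(sample_transition("ou", p, x, dt, rng))
        out[i + 1] = x
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the paired series of a synthetic cohort.

    Fully deterministic given ``spec.seed``: the same spec yields a
    byte-identical cohort.
    """
    params = spec.resolved_regime_params()  # validates before sampling
    spacing, n_default, man_name, dep_name, _ = CADENCES[spec.cadence]
    n_surveys = spec.n_surveys or n_default
    times = spacing * np.arange(n_surveys)
    man_inst, dep_inst = INSTRUMENTS[man_name], INSTRUMENTS[dep_name]
    miss = spec.resolved_missingness()
    rng = np.random.default_rng(spec.seed)
    series: list[SurveySeries] = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        dep, man = _generate_patient(spec, params, times, man_inst,
                                     dep_inst, rng)
        for name, scores in ((dep_name, dep), (man_name, man)):
            scores = scores.astype(float)
            rate = miss.get(name, 0.0)
            if rate > 0:
                scores[rng.random(n_surveys) < rate] = np.nan
            series.append(SurveySeries(pid, name, times.copy(), scores))
    return Cohort(series, meta={"spec": spec.to_dict()})


def regime_oracle_check(regime: str, cohort: Cohort, seed: int = 0,
                        gof_boot: int = 50) -> dict:
    """Run the test matching a regime over a cohort; report rejections.

    Closes the generator-test loop: a rhythmic cohort should be flagged
    by the rhythmicity aggregate, a well-separated multistable cohort
    by the dip aggregate, a one-dimensional cohort by strongly negative
    rank correlation with near-zero mania-while-depressed risk, and an
    affective cohort should *retain* the unimodality null.
    """
    from . import patient as pt
    from .population import mean_p_aggregate, min_p_aggregate

    report: dict = {"regime": regime, "n_patients": 0}
    if regime == "rhythmic":
        rows = []
        for _, dep, man in cohort.patients():
            for s in (dep, man):
                rows.append(pt.harmonic_f_test(s).p_values)
        agg = min_p_aggregate(np.array(rows), mc_reps=20_000, seed=seed)
        report.update(aggregate_p=agg.aggregate_p, rejected=agg.rejected,
                      n_patients=len(rows) // 2)
    elif regime == "multistable":
        pvals = []
        for k, (_, dep, man) in enumerate(cohort.patients()):
            for s in (dep, man):
                _, z = s.observed()
                pvals.append(pt.dip_test(z, seed=seed + k).p_value)
        agg = mean_p_aggregate(pvals)
        report.update(aggregate_p=agg.aggregate_p, rejected=agg.rejected,
                      n_patients=len(pvals) // 2)
    elif regime == "one_dimensional":
        taus, risks = [], []
        for _, dep, man in cohort.patients():
            r = pt.kendall_correlation(dep, man)
            if r.statistic is not None:
                taus.append(r.statistic)
            mr = pt.mania_risk(man, dep)
            if mr.risk_depressed is not None:
                risks.append(mr.risk_depressed)
        report.update(mean_tau=float(np.mean(taus)) if taus else None,
                      mean_risk_depressed=(float(np.mean(risks))
                                           if risks else None),
                      n_patients=len(taus))
    elif regime == "affective":
        dip_p, gof_p = [], []
        for k, (_, dep, man) in enumerate(cohort.patients()):
            for s in (dep, man):
                _, z = s.observed()
                dip_p.append(pt.dip_test(z, seed=seed + k).p_value)
            gof_p.append(pt.gof_density_test(dep, "affective",
                                             n_boot=gof_boot,
                                             seed=seed + k).p_value)
        dip_agg = mean_p_aggregate(dip_p)
        report.update(dip_aggregate_p=dip_agg.aggregate_p,
                      dip_rejected=dip_agg.rejected,
                      gof_rejection_rate=float(np.mean(
                          np.asarray(gof_p) < 0.05)),
                      n_patients=len(gof_p))
    else:
        raise DomainError(f"unknown regime {regime!r}")
    return report
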