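"""Long-run parametric study of the affective-instability model.

Simulates the model for many life-years, classifies daily mood samples
into euthymia / mania / depression / mixed states by a fixed threshold,
detects DSM-style episodes (state runs of at least a week), and
summarizes percent time per state, episode counts and mean durations.
Mood is dimensionless, so the threshold gains meaning only relative to
the parameters; the conventional value is 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AffectiveParams, MoodPath, SimulationConfig, _euler_affective_paths

__all__ = ["StateSequence", "Episode", "CourseSummary", "classify_states",
           "detect_episodes", "run_parametric_study", "PERSONAS",
           "EUTHYMIA", "MANIA", "DEPRESSION", "MIXED", "STATE_NAMES"]

EUTHYMIA, MANIA, DEPRESSION, MIXED = 0, 1, 2, 3
STATE_NAMES = {EUTHYMIA: "euthymia", MANIA: "mania",
               DEPRESSION: "depression", MIXED: "mixed"}
MOOD_STATES = (MANIA, DEPRESSION, MIXED)

DEFAULT_THRESHOLD = 3.0
MIN_EPISODE_DAYS = 7


@dataclass
class StateSequence:
    """Daily state labels derived from a mood path and a threshold."""

    times: np.ndarray
    labels: np.ndarray  # integer codes, see STATE_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels must have equal length")


@dataclass
class Episode:
    """A maximal mood-state (or euthymic) period on the daily grid."""

    state: int
    start_day: float
    duration_days: float
    censored: bool = False  # truncated by the stored-window boundary


@dataclass
class CourseSummary:
    """Percent time, episode counts and mean episode durations per state."""

    percent_time: dict[str, float]
    episode_counts: dict[str, int]
    mean_durations: dict[str, float | None]
    detail: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in STATE_NAMES.values():
            rows.append((s, self.percent_time[s], self.episode_counts[s],
                         self.mean_durations[s]))
        return pd.DataFrame(rows, columns=["state", "percent_time",
                                           "episode_count",
                                           "mean_duration_days"])

    def to_dict(self) -> dict:
        return {"percent_time": self.percent_time,
                "episode_counts": self.episode_counts,
                "mean_durations": self.mean_durations,
                "detail": self.detail}


def classify_states(path: MoodPath, threshold: float = DEFAULT_THRESHOLD) -> StateSequence:
    """Quadrant classification of a mood path.

    A variable strictly above the threshold counts as elevated; values
    exactly at the threshold count as below, making the partition of a
    continuous path exhaustive.  Classification is invariant to jointly
    rescaling mood values and the threshold.
    """
    d = path.d_values
    m = path.m_values
    if m is None:
        raise ValueError("state classification needs a two-coordinate path")
    dm = d > threshold
    mm = m > threshold
    labels = np.where(dm & mm, MIXED,
                      np.where(dm, DEPRESSION, np.where(mm, MANIA, EUTHYMIA)))
    return StateSequence(path.times, labels)


def _runs(labels: np.ndarray):
    """Run-length encoding: yields (state, start_index, length)."""
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        yield int(labels[i]), i, j - i
        i = j


def detect_episodes(states: StateSequence,
                    min_days: int = MIN_EPISODE_DAYS) -> list[Episode]:
    """Episodes from daily state labels.

    Maximal runs of mania / depression / mixed lasting at least
    ``min_days`` become mood episodes; shorter mood runs are absorbed
    into the surrounding euthymic period.  Euthymic episodes are the
    periods in between mood episodes (including window edges).  Episodes
    touching the first or last stored day are flagged as censored and
    counted with their observed duration.
    """
    labels = states.labels
    n = len(labels)
    if n == 0:
        return []
    spacing = float(np.median(np.diff(states.times))) if n > 1 else 1.0
    episodes: list[Episode] = []
    cursor = 0  # start index of the current euthymic stretch
    for state, start, length in _runs(labels):
        if state in MOOD_STATES and length * spacing >= min_days:
            if start > cursor:
                episodes.append(Episode(
                    EUTHYMIA, states.times[cursor],
                    (start - cursor) * spacing,
                    censored=(cursor == 0)))
            episodes.append(Episode(
                state, states.times[start], length * spacing,
                censored=(start == 0 or start + length == n)))
            cursor = start + length
    if cursor < n:
        episodes.append(Episode(EUTHYMIA, states.times[cursor],
                                (n - cursor) * spacing,
                                censored=True))
    return episodes


def summarize(states: StateSequence, episodes: list[Episode]) -> CourseSummary:
    labels = states.labels
    n = len(labels)
    pct = {name: 100.0 * float(np.mean(labels == code))
           for code, name in STATE_NAMES.items()}
    counts = {name: 0 for name in STATE_NAMES.values()}
    durs: dict[str, list[float]] = {name: [] for name in STATE_NAMES.values()}
    n_censored = 0
    for ep in episodes:
        name = STATE_NAMES[ep.state]
        counts[name] += 1
        durs[name].append(ep.duration_days)
        n_censored += int(ep.censored)
    means = {name: (float(np.mean(v)) if v else None)
             for name, v in durs.items()}
    return CourseSummary(pct, counts, means,
                         {"n_days": n, "n_censored_episodes": n_censored})


def run_parametric_study(params: AffectiveParams,
                         total_years: float = 1100.0,
                         warmup_years: float = 100.0,
                         config: SimulationConfig | None = None,
                         threshold: float = DEFAULT_THRESHOLD,
                         min_days: int = MIN_EPISODE_DAYS) -> CourseSummary:
    """Simulate, discard warm-up, classify daily samples, summarize.

    Defaults follow the standard long-run protocol: 1100 simulated
    years starting from mood values (0.1, 0.1), with the first 100
    years discarded as burn-in and daily samples stored for the
    remaining 1000 years.
    """
    if warmup_years >= total_years:
        raise ValueError("warm-up must be shorter than the total run")
    if config is None:
        config = SimulationConfig(dt=0.1, seed=0, init_d=0.1, init_m=0.1)
    rng = np.random.default_rng(config.seed)
    steps_per_day = int(round(1.0 / config.dt))
    n_days = int(round(total_years * 365.25))
    out_d, out_m = _euler_affective_paths(
        params, n_days * steps_per_day, config.dt, rng,
        config.init_d, config.init_m, n_paths=1, noise=config.noise,
        record_every=steps_per_day)
    keep = int(round(warmup_years * 365.25))
    days = np.arange(keep + 1, n_days + 1, dtype=float)
    path = MoodPath(days, out_d[keep:, 0], out_m[keep:, 0])
    states = classify_states(path, threshold)
    episodes = detect_episodes(states, min_days)
    summary = summarize(states, episodes)
    summary.detail.update({"total_years": total_years,
                           "warmup_years": warmup_years,
                           "seed": config.seed, "dt": config.dt,
                           "threshold": threshold})
    return summary


#: Caricature parameterisations illustrating qualitatively distinct
#: clinical courses.  These are illustrations of the parameter space,
#: not claims of diagnostic validity.
PERSONAS: dict[str, AffectiveParams] = {
    "bipolar_like": AffectiveParams(a_d=0.002, a_m=0.003, b_d=5.0, b_m=5.0),
    "bipolar_ii_like": AffectiveParams(a_d=0.002, a_m=0.003, b_d=6.0, b_m=2.0),
    "rapid_cycling": AffectiveParams(a_d=0.02, a_m=0.03, b_d=5.0, b_m=5.0),
    "mdd_like": AffectiveParams(a_d=0.002, a_m=0.003, b_d=7.0, b_m=0.5),
    "healthy": AffectiveParams(a_d=0.002, a_m=0.003, b_d=1.0, b_m=1.0),
}
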