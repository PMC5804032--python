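"""Survey instruments, per-patient series, and long-format cohort I/O.

The canonical exchange format is a long CSV with header
``patient_id,time_days,instrument,score``; an empty score field marks a
missing survey.  Times are integer days since each patient's first
scheduled survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["Instrument", "INSTRUMENTS", "SurveySeries", "Cohort",
           "read_cohort_csv", "write_cohort_csv"]


@dataclass(frozen=True)
class Instrument:
    """A mood survey instrument with its score range and episode cutoff.

    ``episode_threshold`` is the conventional cutoff for a clinically
    significant state (mania for ASRM >= 6, depression for PHQ9 >= 10);
    the weekly interviewer-rated instruments are used without a cutoff
    here.
    """

    name: str
    score_min: int
    score_max: int
    axis: str  # "mania" or "depression"
    episode_threshold: int | None = None

    def __post_init__(self) -> None:
        if self.score_min >= self.score_max:
            raise DomainError("score_min must be below score_max")
        if self.axis not in ("mania", "depression"):
            raise DomainError(f"unknown axis {self.axis!r}")


#: The four instruments of the bimonthly (self-report) and weekly
#: (interviewer-rated) datasets.
INSTRUMENTS: dict[str, Instrument] = {
    "ASRM": Instrument("ASRM", 0, 20, "mania", episode_threshold=6),
    "PHQ9": Instrument("PHQ9", 0, 27, "depression", episode_threshold=10),
    "YMRS": Instrument("YMRS", 0, 60, "mania"),
    "SIGHD": Instrument("SIGHD", 0, 52, "depression"),
}


@dataclass
class SurveySeries:
    """One patient x one instrument series; NaN scores mark missing surveys."""

    patient_id: str
    instrument: str
    times: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.times) != len(self.scores):
            raise ValueError("times and scores must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        inst = INSTRUMENTS.get(self.instrument)
        if inst is not None:
            obs = self.scores[~np.isnan(self.scores)]
            if len(obs) and (obs.min() < inst.score_min or obs.max() > inst.score_max):
                raise ValueError(
                    f"scores outside {self.instrument} range "
                    f"[{inst.score_min}, {inst.score_max}]"
                )

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.scores)))

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, scores) with missing entries dropped."""
        keep = ~np.isnan(self.scores)
        return self.times[keep], self.scores[keep]


@dataclass
class Cohort:
    """A collection of paired series; two series (one per axis) per patient."""

    series: list[SurveySeries]
    meta: dict = field(default_factory=dict)

    def patients(self) -> Iterator[tuple[str, SurveySeries, SurveySeries]]:
        """Yield (patient_id, depression_series, mania_series)."""
        by_pid: dict[str, dict[str, SurveySeries]] = {}
        order: list[str] = []
        for s in self.series:
            if s.patient_id not in by_pid:
                by_pid[s.patient_id] = {}
                order.append(s.patient_id)
            axis = INSTRUMENTS[s.instrument].axis
            by_pid[s.patient_id][axis] = s
        for pid in order:
            d = by_pid[pid]
            if "depression" in d and "mania" in d:
                yield pid, d["depression"], d["mania"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for t, sc in zip(s.times, s.scores):
                rows.append((s.patient_id, t, s.instrument,
                             "" if np.isnan(sc) else int(sc)))
        return pd.DataFrame(rows, columns=["patient_id", "time_days",
                                           "instrument", "score"])


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    """Read a long-format cohort CSV; malformed rows are dropped with a note."""
    df = pd.read_csv(path, dtype={"patient_id": str, "instrument": str})
    required = {"patient_id", "time_days", "instrument", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort CSV must have columns {sorted(required)}")
    bad = ~df["instrument"].isin(INSTRUMENTS)
    n_bad = int(bad.sum())
    df = df[~bad]
    series = []
    for (pid, inst), grp in df.groupby(["patient_id", "instrument"], sort=False):
        grp = grp.sort_values("time_days")
        series.append(SurveySeries(pid, inst,
                                   grp["time_days"].to_numpy(dtype=float),
                                   pd.to_numeric(grp["score"], errors="coerce")
                                   .to_numpy(dtype=float)))
    return Cohort(series, meta={"n_dropped_rows": n_bad})
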