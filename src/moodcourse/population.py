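"""Population-level aggregation of patient p-values.

Patient-level tests are combined by comparing the mean p-value across
patients to the distribution of the mean of N independent uniform(0, 1)
variables (Irwin-Hall, exact for N <= 50; Gaussian with mean 1/2 and
variance 1/(12N) above).  A single p-value of 0.2 is thus not rejected,
while one hundred p-values of 0.2 are overwhelming evidence.

For the rhythmicity test, where 30 frequencies are tested per patient
and patients may oscillate at different frequencies, the per-patient
minimum p-value over the grid is averaged instead and compared to the
mean of N independent minima of 30 uniforms (Beta(1, 30)), evaluated by
seeded Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["AggregateResult", "mean_p_aggregate", "min_p_aggregate",
           "EXACT_N_MAX", "N_FREQ"]

EXACT_N_MAX = 50   # Irwin-Hall below/at, Gaussian approximation above
N_FREQ = 30
DEFAULT_ALPHA = 0.05


@dataclass
class AggregateResult:
    """A population-level aggregated test."""

    variant: str                 # "mean_p" or "min_p_over_frequencies"
    mean_statistic: float
    n_patients: int
    aggregate_p: float
    alpha: float = DEFAULT_ALPHA
    detail: dict = field(default_factory=dict)

    @property
    def rejected(self) -> bool:
        return self.aggregate_p < self.alpha

    def to_dict(self) -> dict:
        return {"variant": self.variant,
                "mean_statistic": self.mean_statistic,
                "n_patients": self.n_patients,
                "aggregate_p": self.aggregate_p,
                "alpha": self.alpha,
                "rejected": self.rejected}


def mean_uniform_cdf(mean: float, n: int) -> float:
    """P(mean of n iid uniforms <= mean): exact Irwin-Hall or CLT."""
    if n <= EXACT_N_MAX:
        return float(stats.irwinhall(n).cdf(mean * n))
    return float(stats.norm.cdf(mean, loc=0.5,
                                scale=np.sqrt(1.0 / (12.0 * n))))


def mean_p_aggregate(pvals, alpha: float = DEFAULT_ALPHA) -> AggregateResult:
    """Aggregate patient p-values by their mean against the uniform null.

    Undefined patient-level results must be excluded by the caller
    before aggregation (patients with ill-defined statistics carry no
    evidence either way).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("cannot aggregate an empty p-value list")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    mean = float(p.mean())
    agg = mean_uniform_cdf(mean, p.size)
    return AggregateResult("mean_p", mean, int(p.size), agg, alpha,
                           {"method": "irwin_hall" if p.size <= EXACT_N_MAX
                            else "gaussian"})


def min_p_aggregate(pval_matrix, mc_reps: int = 100_000, seed: int = 0,
                    alpha: float = DEFAULT_ALPHA) -> AggregateResult:
    """Aggregate the per-patient minimum over 30 frequency p-values.

    The observed statistic is the mean over patients of each patient's
    minimum p-value across the 30-frequency grid.  Under the null all
    p-values are independent uniforms, so each minimum is Beta(1, 30);
    the aggregate p-value is the seeded Monte-Carlo probability that the
    mean of N such minima falls at or below the observed statistic.
    """
    pm = np.atleast_2d(np.asarray(pval_matrix, dtype=float))
    if pm.shape[1] != N_FREQ:
        raise ValueError(f"expected {N_FREQ} frequency columns, "
                         f"got {pm.shape[1]}")
    if np.any(np.isnan(pm)) or np.any((pm < 0) | (pm > 1)):
        raise ValueError("p-values must lie in [0, 1] with no NaN")
    n = pm.shape[0]
    stat = float(pm.min(axis=1).mean())
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(mc_reps, 2_000_000 // max(n, 1)))
    done = 0
    while done < mc_reps:
        m = min(chunk, mc_reps - done)
        sims = rng.beta(1.0, N_FREQ, size=(m, n)).mean(axis=1)
        count += int(np.sum(sims <= stat))
        done += m
    agg = count / mc_reps
    return AggregateResult("min_p_over_frequencies", stat, n, agg, alpha,
                           {"mc_reps": mc_reps, "seed": seed})
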