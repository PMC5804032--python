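"""End-to-end orchestration: cohort -> patient tests -> aggregates.

`run_pipeline` ties the stages together: it loads (or generates) a
cohort, runs the requested patient-level tests, excludes ill-defined
results, aggregates p-values at the population level, and writes a
reproducible result bundle (JSON records plus CSV summaries and a run
log with seeds and exclusion counts).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import patient as pt
from .cohort import CohortSpec, generate_cohort
from .data import Cohort, read_cohort_csv
from .population import mean_p_aggregate, min_p_aggregate

__all__ = ["PipelineConfig", "run_pipeline", "ALL_TESTS"]

ALL_TESTS = ("one_dimensional", "rhythmic", "multistable",
             "gof_density", "gof_transition")


@dataclass
class PipelineConfig:
    """What to run, on which cohort, and where to write results."""

    input_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    tests: tuple = ("one_dimensional", "rhythmic", "multistable")
    alpha: float = 0.05
    gof_boot: int = 200
    gof_model: str = "affective"
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests {sorted(unknown)}")
        if self.input_csv is None and self.cohort_spec is None:
            raise ValueError("either input_csv or cohort_spec is required")


def _load(config: PipelineConfig) -> Cohort:
    if config.input_csv is not None:
        cohort = read_cohort_csv(config.input_csv)
    else:
        cohort = generate_cohort(config.cohort_spec)
    if not any(True for _ in cohort.patients()):
        raise ValueError("cohort contains no patient with both axes")
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured tests; return (and optionally write) the bundle.

    The bundle maps test names to per-patient records and aggregate
    records; the run log records seeds, the package version, and the
    number of ill-defined patient results excluded from aggregation.
    """
    cohort = _load(config)
    bundle: dict = {"patients": [], "aggregates": [],
                    "log": {"seed": config.seed, "alpha": config.alpha,
                            "version": __version__,
                            "python": platform.python_version(),
                            "excluded": {}, "cohort_meta": cohort.meta}}
    patients = list(cohort.patients())

    if "one_dimensional" in config.tests:
        _run_one_dimensional(patients, config, bundle)
    if "rhythmic" in config.tests:
        _run_rhythmic(patients, config, bundle)
    if "multistable" in config.tests:
        _run_multistable(patients, config, bundle)
    if "gof_density" in config.tests:
        _run_gof(patients, config, bundle, transition=False)
    if "gof_transition" in config.tests:
        _run_gof(patients, config, bundle, transition=True)

    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _record(bundle, pid, axis, result: pt.TestResult):
    rec = {"patient_id": pid, "axis": axis, **result.to_dict()}
    bundle["patients"].append(rec)
    return rec


def _aggregate(bundle, name, axis, pvals, excluded, config, extra=None):
    bundle["log"]["excluded"][f"{name}/{axis}"] = excluded
    if not pvals:
        bundle["aggregates"].append({"test": name, "axis": axis,
                                     "n_patients": 0, "aggregate_p": None,
                                     "note": "no defined patient results"})
        return
    agg = mean_p_aggregate(pvals, alpha=config.alpha)
    rec = {"test": name, "axis": axis, **agg.to_dict()}
    if extra:
        rec.update(extra)
    bundle["aggregates"].append(rec)


def _run_one_dimensional(patients, config, bundle):
    taus, tau_p, risks_dep, risks_not = [], [], [], []
    excluded = 0
    for pid, dep, man in patients:
        r = pt.kendall_correlation(dep, man)
        _record(bundle, pid, "joint", r)
        if r.statistic is None:
            excluded += 1
        else:
            taus.append(r.statistic)
            tau_p.append(r.p_value)
        mr = pt.mania_risk(man, dep)
        if mr.risk_depressed is not None:
            risks_dep.append(mr.risk_depressed)
        if mr.risk_not_depressed is not None:
            risks_not.append(mr.risk_not_depressed)
        bundle["patients"].append({
            "patient_id": pid, "axis": "joint", "test": "mania_risk",
            "statistic": None, "p_value": None,
            "n_used": mr.n_depressed + mr.n_not_depressed,
            "detail": {"risk_depressed": mr.risk_depressed,
                       "risk_not_depressed": mr.risk_not_depressed}})
    bundle["aggregates"].append({
        "test": "kendall_mean_tau", "axis": "joint",
        "mean_statistic": float(np.mean(taus)) if taus else None,
        "min": float(np.min(taus)) if taus else None,
        "max": float(np.max(taus)) if taus else None,
        "n_patients": len(taus)})
    bundle["aggregates"].append({
        "test": "mania_risk_mean", "axis": "joint",
        "mean_risk_depressed": (float(np.mean(risks_dep))
                                if risks_dep else None),
        "mean_risk_not_depressed": (float(np.mean(risks_not))
                                    if risks_not else None),
        "n_patients_depressed": len(risks_dep),
        "n_patients_not_depressed": len(risks_not)})
    bundle["log"]["excluded"]["kendall/joint"] = excluded


def _run_rhythmic(patients, config, bundle):
    for axis_idx, axis in ((1, "depression"), (2, "mania")):
        pmat = []
        for rec in patients:
            s = rec[axis_idx]
            sr = pt.harmonic_f_test(s)
            pmat.append(sr.p_values)
            bundle["patients"].append({
                "patient_id": rec[0], "axis": axis, "test": "harmonic_f",
                "statistic": float(np.max(sr.f_statistics)),
                "p_value": float(np.min(sr.p_values)),
                "n_used": len(s.times),
                "detail": {"frequencies": sr.frequencies.tolist(),
                           "p_values": sr.p_values.tolist()}})
        pmat = np.array(pmat)
        # mean p per frequency, each against the mean-of-uniforms null
        per_freq = [mean_p_aggregate(pmat[:, k], alpha=config.alpha)
                    for k in range(pmat.shape[1])]
        bundle["aggregates"].append({
            "test": "rhythmic_mean_p", "axis": axis,
            "n_patients": pmat.shape[0],
            "per_frequency_aggregate_p": [a.aggregate_p for a in per_freq],
            "any_rejected": bool(any(a.rejected for a in per_freq))})
        agg = min_p_aggregate(pmat, seed=config.seed, alpha=config.alpha)
        bundle["aggregates"].append({"test": "rhythmic_min_p", "axis": axis,
                                     **agg.to_dict()})


def _run_multistable(patients, config, bundle):
    for axis_idx, axis in ((1, "depression"), (2, "mania")):
        pvals, excluded = [], 0
        for k, rec in enumerate(patients):
            s = rec[axis_idx]
            _, z = s.observed()
            r = pt.dip_test(z, seed=config.seed + k)
            _record(bundle, rec[0], axis, r)
            if r.p_value is None:
                excluded += 1
            else:
                pvals.append(r.p_value)
        _aggregate(bundle, "multistable", axis, pvals, excluded, config)


def _run_gof(patients, config, bundle, transition: bool):
    test = pt.gof_transition_test if transition else pt.gof_density_test
    name = "gof_transition" if transition else "gof_density"
    for axis_idx, axis in ((1, "depression"), (2, "mania")):
        pvals, quantiles, excluded = [], [], 0
        for k, rec in enumerate(patients):
            s = rec[axis_idx]
            try:
                r = test(s, config.gof_model, n_boot=config.gof_boot,
                         seed=config.seed + k)
            except Exception as exc:  # fit failures are excluded, logged
                excluded += 1
                bundle["patients"].append({
                    "patient_id": rec[0], "axis": axis, "test": name,
                    "statistic": None, "p_value": None, "n_used": 0,
                    "detail": {"error": str(exc)}})
                continue
            _record(bundle, rec[0], axis, r)
            pvals.append(r.p_value)
            quantiles.append(r.detail["fit_quantile_pct"])
        extra = {"mean_fit_quantile_pct": (float(np.mean(quantiles))
                                           if quantiles else None),
                 "model_id": config.gof_model}
        _aggregate(bundle, name, axis, pvals, excluded, config, extra)


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    pd.DataFrame([{k: v for k, v in rec.items() if k != "detail"}
                  for rec in bundle["patients"]]).to_csv(
        outdir / "patient_tests.csv", index=False)
    pd.json_normalize(bundle["aggregates"]).to_csv(
        outdir / "aggregates.csv", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
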