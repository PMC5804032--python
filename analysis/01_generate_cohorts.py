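"""Generate the four synthetic regime cohorts used by the analyses.

Writes one long-format CSV per regime under results/cohorts/ plus a
manifest of the specs.  The affective cohort is the stand-in for a
longitudinal bipolar survey study (bimonthly self reports); a weekly
affective cohort supports the transition goodness-of-fit analysis.
"""

import json
from pathlib import Path

from moodcourse.cohort import CohortSpec, generate_cohort
from moodcourse.data import write_cohort_csv

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)

SPECS = {
    "affective_bimonthly": CohortSpec(n_patients=24, regime="affective",
                                      cadence="bimonthly", seed=11),
    "affective_weekly": CohortSpec(n_patients=15, regime="affective",
                                   cadence="weekly", seed=12),
    "rhythmic_bimonthly": CohortSpec(n_patients=40, regime="rhythmic",
                                     cadence="bimonthly", seed=13),
    "multistable_bimonthly": CohortSpec(n_patients=40, regime="multistable",
                                        cadence="bimonthly", seed=14),
    "one_dimensional_bimonthly": CohortSpec(n_patients=40,
                                            regime="one_dimensional",
                                            cadence="bimonthly", seed=15),
}


def main() -> None:
    manifest = {}
    for name, spec in SPECS.items():
        cohort = generate_cohort(spec)
        path = OUT / f"{name}.csv"
        write_cohort_csv(cohort, path)
        manifest[name] = spec.to_dict()
        n_missing = sum(int((s.scores != s.scores).sum())
                        for s in cohort.series)
        print(f"{name}: {spec.n_patients} patients, "
              f"{len(cohort.series)} series, {n_missing} missing entries "
              f"-> {path.name}")
    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


if __name__ == "__main__":
    main()
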