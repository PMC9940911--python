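"""Generate the synthetic study cohorts.

Simulates an 18-subject patient cohort tested ON and OFF stimulation and
an 18-subject control (HC) cohort through the two-armed reversal task
(three 40-trial sessions, 80%:20% arms reversing after trial 60), using
hierarchically sampled RLDDM parameters whose group locations encode the
study conditions: lower drift-rate scaling ON than OFF, and lower still
in controls.

Writes results/trials_patients.csv, results/trials_hc.csv and the
generating subject parameters.
"""

import sys
from pathlib import Path

import numpy as np

from rlddm.io import write_manifest, write_trials
from rlddm.task import (CohortSpec, DEFAULT_GROUP_MEANS, generate_cohort_data,
                        make_schedule, sample_cohort)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def write_params(cohort, path):
    import pandas as pd

    rows = []
    for i, subj in enumerate(cohort):
        for cond, p in subj.items():
            rows.append({"subject": f"s{i + 1:02d}", "condition": cond,
                         "a": p.a, "t": p.t, "z": p.z, "m": p.m,
                         "alpha_pos_raw": p.alpha_pos_raw,
                         "alpha_neg_raw": p.alpha_neg_raw})
    pd.DataFrame(rows).to_csv(path, index=False)


def main():
    rng = np.random.default_rng(SEED)
    schedule = make_schedule()

    patients_spec = CohortSpec(n_subjects=18)
    patients = sample_cohort(patients_spec, rng)
    patient_data = generate_cohort_data(patients, schedule, rng=rng)
    write_trials(patient_data, OUT / "trials_patients.csv")
    write_params(patients, OUT / "params_patients.csv")

    hc_spec = CohortSpec(n_subjects=18,
                         group_means={"HC": dict(DEFAULT_GROUP_MEANS["HC"])})
    hc = sample_cohort(hc_spec, rng)
    hc_data = generate_cohort_data(hc, schedule, rng=rng)
    write_trials(hc_data, OUT / "trials_hc.csv")
    write_params(hc, OUT / "params_hc.csv")

    n_om = [ds.n_omissions for ds in patient_data]
    print(f"patients: {len(patient_data)} datasets x {schedule.n_trials} trials, "
          f"omissions {min(n_om)}-{max(n_om)} (mean {np.mean(n_om):.1f})")
    print(f"controls: {len(hc_data)} datasets")
    write_manifest(OUT / "simulate_manifest.json", "simulate", SEED,
                   outputs=["trials_patients.csv", "trials_hc.csv"],
                   parameters={"n_subjects": 18})


if __name__ == "__main__":
    main()
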