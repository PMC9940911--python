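"""Model validation: posterior-predictive checks, parameter recovery and the
exploration parameter map.

Uses the whole-task dual-rate fit from 03_fit_rlddm.py to (i) regenerate
50 synthetic experiments and check the observed learning curves sit
inside the 95% replication band, (ii) refit five model-generated cohorts
and correlate generating with recovered subject-level parameters, and
(iii) map P(Explore) over a grid of (positive learning rate, drift-rate
scaling, boundary separation) centred on the OFF-state group means with
20 simulated datasets per cell.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rlddm.inference import load_posterior
from rlddm.io import read_trials
from rlddm.learning import AgentParams
from rlddm.task import CohortSpec, make_schedule, sample_cohort
from rlddm.validation import (parameter_recovery, pexplore_parameter_map,
                              posterior_predictive)

OUT = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240


def main():
    rng = np.random.default_rng(SEED)
    schedule = make_schedule()
    data = read_trials(OUT / "trials_patients.csv")
    post = load_posterior(SCRATCH / "posterior_whole.npz")

    # --- posterior-predictive check -----------------------------------
    ppc = posterior_predictive(post, data, schedule, n_sims=50, rng=rng)
    rows = []
    for c in ppc.conditions:
        cov = ppc.coverage(c)
        print(f"PPC {c}: observed learning curve inside the 95% band at "
              f"{100 * cov:.1f}% of trials")
        lo, hi = ppc.band[c]
        for i in range(schedule.n_trials):
            rows.append({"condition": c, "trial": i + 1,
                         "observed": ppc.observed_curve[c][i],
                         "band_lo": lo[i], "band_hi": hi[i]})
    pd.DataFrame(rows).to_csv(OUT / "ppc_learning_curves.csv", index=False)
    g = ppc.sim_stats.groupby("condition")["p_explore"].mean()
    print("simulated P(Explore) by condition:",
          {c: round(v, 3) for c, v in g.items()})

    # --- parameter recovery -------------------------------------------
    cohort = sample_cohort(CohortSpec(n_subjects=18), rng)
    rec = parameter_recovery(cohort, schedule, n_sets=5, rng=rng,
                             chains=2, burn=1000, draws=1000)
    rec.pairs.to_csv(OUT / "recovery_pairs.csv", index=False)
    for p, (r, pv) in rec.correlations.items():
        print(f"recovery {p}: r = {r:.3f} (p = {pv:.1e})")

    # --- exploration parameter map ------------------------------------
    centre = AgentParams(a=1.96, t=0.45, z=0.5, m=4.51, alpha_pos_raw=-0.85,
                         alpha_neg_raw=-2.97, condition="OFF")
    grid = {"alpha_pos_raw": np.array([-1.85, -0.85, 0.15]),
            "m": np.array([0.0, 1.5, 3.0, 4.5, 6.0]),
            "a": np.array([1.5, 1.96, 2.4])}
    surf = pexplore_parameter_map(centre, grid, schedule, sims_per_cell=20,
                                  rng=rng)
    cells = []
    for idx in np.ndindex(*surf.mean.shape):
        cells.append({"alpha_pos_raw": grid["alpha_pos_raw"][idx[0]],
                      "m": grid["m"][idx[1]], "a": grid["a"][idx[2]],
                      "p_explore": surf.mean[idx], "se": surf.se[idx]})
    pd.DataFrame(cells).to_csv(OUT / "pexplore_map.csv", index=False)
    prof = surf.profile("m")
    print("P(Explore) profile along m", dict(zip(grid["m"], np.round(prof, 3))))


if __name__ == "__main__":
    main()
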