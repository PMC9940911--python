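"""Behavioural summaries of the synthetic cohorts.

Computes, per subject and condition: omission counts, per-session rewards
and P(Explore), twelve 10-trial-bin P(Explore)/P(Reward) series, and the
per-subject DBS-induced exploration change (max-session and whole-task
definitions).  Exploratory choices are classified against the generating
value trajectories written by 01_simulate_cohort.py.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from rlddm.io import read_trials
from rlddm.learning import AgentParams, compute_q_trajectory
from rlddm.summaries import binned_stats, delta_pexplore, session_summary

OUT = Path(__file__).resolve().parents[1] / "results"


def load_params(path):
    df = pd.read_csv(path)
    return {(r["subject"], r["condition"]): AgentParams(
        a=r["a"], t=r["t"], z=r["z"], m=r["m"],
        alpha_pos_raw=r["alpha_pos_raw"], alpha_neg_raw=r["alpha_neg_raw"],
        condition=r["condition"]) for _, r in df.iterrows()}


def main():
    sess_rows, bin_rows = [], []
    for tag in ("patients", "hc"):
        datasets = read_trials(OUT / f"trials_{tag}.csv")
        params = load_params(OUT / f"params_{tag}.csv")
        for ds in datasets:
            traj = compute_q_trajectory(ds, params[(ds.subject, ds.condition)])
            sess_rows.append(session_summary(ds, traj))
            bin_rows.append(binned_stats(ds, traj))
    sessions = pd.concat(sess_rows, ignore_index=True)
    bins = pd.concat(bin_rows, ignore_index=True)
    sessions.to_csv(OUT / "behaviour_sessions.csv", index=False)
    bins.to_csv(OUT / "behaviour_bins.csv", index=False)

    group = sessions.groupby("condition")["p_explore"].mean()
    print("mean session P(Explore):",
          {c: round(v, 3) for c, v in group.items()})
    pr = bins.groupby("condition")["p_reward"].mean()
    print("mean bin P(Reward):", {c: round(v, 3) for c, v in pr.items()})

    # per-subject stimulation-induced exploration change
    rows = []
    pat = sessions[sessions.condition.isin(["ON", "OFF"])]
    for subj, grp in pat.groupby("subject"):
        on = grp[grp.condition == "ON"]
        off = grp[grp.condition == "OFF"]
        rows.append({"subject": subj,
                     "max_session": delta_pexplore(on, off, "max_session"),
                     "whole_task": delta_pexplore(on, off, "whole_task")})
    delta = pd.DataFrame(rows)
    delta.to_csv(OUT / "delta_pexplore.csv", index=False)
    print(f"max-session delta P(Explore): mean {delta.max_session.mean():.3f}, "
          f"range {delta.max_session.min():.2f} to {delta.max_session.max():.2f}")


if __name__ == "__main__":
    main()
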