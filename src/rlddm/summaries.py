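"""Behavioural statistics: omission filtering, session and binned summaries.

P(Explore) is the fraction of responded choices in a window that picked
the option with the strictly lower expected value; P(Reward) is rewards
divided by responses.  Bins are anchored to the absolute trial grid, so
with the default design the reversal boundary falls exactly between bins
6 and 7; omissions shrink denominators but never shift bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import SubjectDataset
from .learning import QTrajectory, classify_exploratory


def filter_omissions(dataset: SubjectDataset):
    """Drop omitted trials, keeping original trial indices (gaps allowed).

    Returns ``(cleaned dataset, omission count)``.
    """
    mask = dataset.responded
    count = int((~mask).sum())
    if not mask.any():
        warnings.warn(f"all trials of {dataset.subject}/{dataset.condition} are omissions")
    cleaned = SubjectDataset(
        subject=dataset.subject, condition=dataset.condition,
        session=dataset.session[mask], trial=dataset.trial[mask],
        choice=dataset.choice[mask], outcome=dataset.outcome[mask],
        dt=dataset.dt[mask])
    return cleaned, count


def pexplore(dataset: SubjectDataset, traj: QTrajectory,
             mask: np.ndarray | None = None) -> float:
    """Exploratory choices / responded choices within an optional mask."""
    flags = classify_exploratory(dataset, traj)
    responded = dataset.responded
    if mask is not None:
        flags = flags & mask
        responded = responded & mask
    n = int(responded.sum())
    return float(flags.sum()) / n if n else np.nan


def session_summary(dataset: SubjectDataset, traj: QTrajectory) -> pd.DataFrame:
    """Per-session rewards won, mean decision time and P(Explore)."""
    if len(traj) != dataset.n_trials:
        raise ValueError("trajectory is not aligned with the dataset")
    flags = classify_exploratory(dataset, traj)
    rows = []
    for sess in np.unique(dataset.session):
        m = dataset.session == sess
        resp = m & dataset.responded
        n_resp = int(resp.sum())
        rows.append({
            "subject": dataset.subject,
            "condition": dataset.condition,
            "session": int(sess),
            "n_responses": n_resp,
            "rewards": float(np.nansum(dataset.outcome[resp])) if n_resp else 0.0,
            "mean_dt": float(np.nanmean(dataset.dt[resp])) if n_resp else np.nan,
            "p_explore": float(flags[m].sum()) / n_resp if n_resp else np.nan,
        })
    return pd.DataFrame(rows)


def binned_stats(dataset: SubjectDataset, traj: QTrajectory,
                 bin_width: int = 10, n_trials: int | None = None) -> pd.DataFrame:
    """P(Explore) and P(Reward) in fixed-width bins on the trial grid.

    Bins with no responses carry nan ratios (missing, never zero).
    """
    if n_trials is None:
        n_trials = int(dataset.trial.max())
    if n_trials % bin_width:
        raise ValueError(f"bin width {bin_width} does not divide {n_trials} trials")
    flags = classify_exploratory(dataset, traj)
    bin_ix = (dataset.trial - 1) // bin_width + 1
    rows = []
    for b in range(1, n_trials // bin_width + 1):
        m = bin_ix == b
        resp = m & dataset.responded
        n_resp = int(resp.sum())
        rows.append({
            "subject": dataset.subject,
            "condition": dataset.condition,
            "bin": b,
            "n_responses": n_resp,
            "p_explore": float(flags[m].sum()) / n_resp if n_resp else np.nan,
            "p_reward": float(np.nansum(dataset.outcome[resp])) / n_resp if n_resp else np.nan,
        })
    return pd.DataFrame(rows)


def delta_pexplore(on_summaries: pd.DataFrame, off_summaries: pd.DataFrame,
                   mode: str = "max_session") -> float:
    """DBS-induced change in exploration for one subject.

    ``max_session``: largest per-session increase (ON minus OFF);
    ``whole_task``: response-weighted task-level difference.
    """
    on = on_summaries.set_index("session")
    off = off_summaries.set_index("session")
    common = on.index.intersection(off.index)
    if len(common) == 0:
        raise KeyError("no common sessions between conditions")
    diffs = on.loc[common, "p_explore"] - off.loc[common, "p_explore"]
    if mode == "max_session":
        return float(diffs.max())
    if mode == "whole_task":
        def task_level(df):
            w = df.loc[common, "n_responses"]
            return float((df.loc[common, "p_explore"] * w).sum() / w.sum())
        return task_level(on) - task_level(off)
    raise ValueError(f"unknown mode {mode!r}")
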