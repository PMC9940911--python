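"""Model validation: posterior-predictive checks, parameter recovery, and
parameter-space mapping of exploration.

Posterior-predictive simulation regenerates whole synthetic experiments
from the posterior-mean subject parameters (full-posterior simulation is
available via ``point="draws"``) and compares learning curves, decision
times and exploration statistics with the observed data.  Parameter
recovery refits model-generated cohorts and correlates generating with
re-estimated subject-level values.  The parameter map simulates a grid of
agents around a centre point (20 synthetic datasets per cell by
convention) to show how exploration depends on each parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import SubjectDataset
from .inference import (ModelSpec, PosteriorDraws, RL_PARAMS,
                        agent_params_from_posterior, build_model, run_mcmc)
from .learning import AgentParams, compute_q_trajectory
from .summaries import pexplore, session_summary
from .task import (DEFAULT_OMISSION_RATE, TaskSchedule, generate_agent_dataset,
                   generate_cohort_data)


def learning_curve(datasets, schedule: TaskSchedule) -> np.ndarray:
    """Per-trial probability of choosing the objectively better option,
    pooled over datasets (responded trials only)."""
    better = schedule.better_option()
    hits = np.zeros(schedule.n_trials)
    n = np.zeros(schedule.n_trials)
    for ds in datasets:
        ix = ds.trial - 1
        resp = ds.responded
        hits[ix[resp]] += (ds.choice[resp] == better[ix[resp]])
        n[ix[resp]] += 1
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, hits / n, np.nan)


@dataclass
class PPCResult:
    """Posterior-predictive replications and their summary bands."""

    conditions: list
    observed_curve: dict            # condition -> (T,) observed learning curve
    sim_curves: dict                # condition -> (n_sims, T)
    band: dict                      # condition -> (2, T) 2.5/97.5 percentiles
    sim_stats: pd.DataFrame         # per sim x condition x session P(Explore)/rewards
    observed_dts: dict              # condition -> signed decision times
    sim_dts: dict                   # condition -> signed decision times, pooled sims

    def coverage(self, condition: str) -> float:
        """Fraction of trials at which the observed curve lies in the band."""
        obs = self.observed_curve[condition]
        lo, hi = self.band[condition]
        ok = (obs >= lo) & (obs <= hi)
        valid = ~np.isnan(obs)
        return float(ok[valid].mean())


def _signed_dts(datasets) -> np.ndarray:
    """Decision times, negated for choices of the initially lower-valued
    (i.e. lower-boundary) option — the conventional plotting device."""
    out = []
    for ds in datasets:
        resp = ds.responded
        sign = np.where(ds.choice[resp] == 0, 1.0, -1.0)
        out.append(sign * ds.dt[resp])
    return np.concatenate(out) if out else np.empty(0)


def posterior_predictive(fit: PosteriorDraws, datasets, schedule: TaskSchedule,
                         n_sims: int = 50, rng: np.random.Generator | None = None,
                         omission_rate: float = DEFAULT_OMISSION_RATE,
                         q0: float = 0.5) -> PPCResult:
    """Generate ``n_sims`` full synthetic replications from the fit.

    Each replication simulates every subject x condition through the task
    from that subject's posterior-mean parameters and summarises the same
    statistics computed on the observed data.
    """
    if rng is None:
        rng = np.random.default_rng()
    cohort = agent_params_from_posterior(fit)
    conds = fit.conditions
    by_cond = {c: [ds for ds in datasets if ds.condition == c] for c in conds}
    observed = {c: learning_curve(by_cond[c], schedule) for c in conds}
    obs_dts = {c: _signed_dts(by_cond[c]) for c in conds}

    sim_curves = {c: np.empty((n_sims, schedule.n_trials)) for c in conds}
    sim_dts = {c: [] for c in conds}
    stat_rows = []
    for k in range(n_sims):
        sim = generate_cohort_data(cohort, schedule, omission_rate, rng, q0=(q0, q0))
        for c in conds:
            sub = [ds for ds in sim if ds.condition == c]
            sim_curves[c][k] = learning_curve(sub, schedule)
            sim_dts[c].append(_signed_dts(sub))
            for i, ds in enumerate(sub):
                params = cohort[i][c]
                traj = compute_q_trajectory(ds, params, q0=(q0, q0))
                summ = session_summary(ds, traj)
                for _, row in summ.iterrows():
                    stat_rows.append({"sim": k, "condition": c,
                                      "session": row["session"],
                                      "p_explore": row["p_explore"],
                                      "rewards": row["rewards"]})
    band = {c: np.nanpercentile(sim_curves[c], [2.5, 97.5], axis=0) for c in conds}
    return PPCResult(conditions=list(conds), observed_curve=observed,
                     sim_curves=sim_curves, band=band,
                     sim_stats=pd.DataFrame(stat_rows),
                     observed_dts=obs_dts,
                     sim_dts={c: np.concatenate(v) for c, v in sim_dts.items()})


@dataclass
class RecoveryResult:
    """Generating vs re-estimated parameter pairs and their correlations."""

    pairs: pd.DataFrame             # set, subject, condition, parameter, true, recovered
    correlations: dict              # parameter -> (pearson r, two-sided p)
    n_failed: int = 0

    def all_positive(self, threshold: float = 0.0) -> bool:
        return all(r > threshold for r, _ in self.correlations.values())


def parameter_recovery(cohort, schedule: TaskSchedule, n_sets: int = 5,
                       rng: np.random.Generator | None = None,
                       omission_rate: float = DEFAULT_OMISSION_RATE,
                       chains: int = 2, burn: int = 1000, draws: int = 1000,
                       spec: ModelSpec | None = None) -> RecoveryResult:
    """Simulate ``n_sets`` cohorts from known parameters and refit each.

    ``cohort`` is a list of ``{condition: AgentParams}`` (the generating
    truth).  Failed refits are excluded with a count.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    spec = spec or ModelSpec()
    rows = []
    n_failed = 0
    for k in range(n_sets):
        data = generate_cohort_data(cohort, schedule, omission_rate, rng)
        try:
            model = build_model(data, spec)
            post = run_mcmc(model, chains=chains, burn=burn, draws=draws,
                            seed=int(rng.integers(0, 2 ** 31 - 1)))
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        point = post.subject_point_estimates()
        for si, sid in enumerate(post.subjects):
            subj_ix = int(sid[1:]) - 1  # ids are s01, s02, ...
            for cond in post.conditions:
                truth = cohort[subj_ix][cond]
                for p in RL_PARAMS:
                    rows.append({
                        "set": k, "subject": sid, "condition": cond,
                        "parameter": p,
                        "true": getattr(truth, p),
                        "recovered": point[si, post.param_names.index(f"{p}[{cond}]")],
                    })
    pairs = pd.DataFrame(rows)
    corrs = {}
    for p in RL_PARAMS:
        sub = pairs[pairs.parameter == p]
        r, pval = stats.pearsonr(sub["true"], sub["recovered"])
        corrs[p] = (float(r), float(pval))
    return RecoveryResult(pairs=pairs, correlations=corrs, n_failed=n_failed)


@dataclass
class PExploreMap:
    """Mean simulated P(Explore) over a parameter grid, with Monte-Carlo SE."""

    axes: dict                      # parameter -> grid values
    mean: np.ndarray                # shape = tuple(len(v) for v in axes.values())
    se: np.ndarray

    def profile(self, param: str) -> np.ndarray:
        """Mean P(Explore) along one axis, averaged over the others."""
        names = list(self.axes)
        other = tuple(i for i, n in enumerate(names) if n != param)
        return self.mean.mean(axis=other)


def pexplore_parameter_map(center: AgentParams, grid: dict,
                           schedule: TaskSchedule, sims_per_cell: int = 20,
                           rng: np.random.Generator | None = None,
                           omission_rate: float = 0.0,
                           q0: float = 0.5) -> PExploreMap:
    """Map exploration over a grid of parameter combinations.

    ``grid`` maps parameter names (any of AgentParams' fields) to value
    arrays; all other parameters stay at ``center``.  Each cell simulates
    ``sims_per_cell`` synthetic datasets and records the mean task-level
    P(Explore), classified against the generating value trajectory.
    """
    if rng is None:
        rng = np.random.default_rng()
    names = list(grid)
    shapes = tuple(len(grid[n]) for n in names)
    mean = np.empty(shapes)
    se = np.empty(shapes)
    for idx in np.ndindex(*shapes):
        kw = {n: float(grid[n][i]) for n, i in zip(names, idx)}
        params = AgentParams(**{**_params_dict(center), **kw})
        vals = np.empty(sims_per_cell)
        for k in range(sims_per_cell):
            ds = generate_agent_dataset(params, schedule, omission_rate, rng,
                                        q0=(q0, q0))
            traj = compute_q_trajectory(ds, params, q0=(q0, q0))
            vals[k] = pexplore(ds, traj)
        mean[idx] = np.nanmean(vals)
        se[idx] = np.nanstd(vals, ddof=1) / np.sqrt(sims_per_cell)
    return PExploreMap(axes={n: np.asarray(grid[n], dtype=float) for n in names},
                       mean=mean, se=se)


def _params_dict(p: AgentParams) -> dict:
    return {"a": p.a, "t": p.t, "z": p.z, "m": p.m,
            "alpha_pos_raw": p.alpha_pos_raw, "alpha_neg_raw": p.alpha_neg_raw,
            "condition": p.condition}
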