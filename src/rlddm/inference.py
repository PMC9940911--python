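"""Hierarchical Bayesian estimation of the RLDDM with condition contrasts.

Model structure: every subject contributes one dataset per condition.
Boundary separation, drift-rate scaling and the two learning rates are
condition dependent (separate group-level normals per condition); the
non-decision time and start point are subject traits assumed unaffected
by condition.  The per-trial likelihood is the WFPT density evaluated at
the drift implied by the subject's running value difference; omitted
trials contribute nothing.

The paper-scale budget is four chains with 7,000 burn-in and 15,000
retained draws; tests and desk-scale replications use a reduced budget
(``run_mcmc`` accepts any).  Convergence is summarised by the
Gelman--Rubin statistic of the group-level nodes, computed with arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .data import OMITTED, SubjectDataset
from .sampler import _run_chain, total_loglik
from .wfpt import SERIES_EPS

RL_PARAMS = ("a", "m", "alpha_pos_raw", "alpha_neg_raw")
SHARED_PARAMS = ("t", "z")

#: weakly-informative priors on the estimation scale:
#: (group-mean location, group-mean scale, half-normal scale of group SD)
DEFAULT_PRIORS = {
    "a": (1.5, 1.0, 0.5),
    "m": (0.0, 5.0, 3.0),
    "alpha_pos_raw": (0.0, 2.0, 1.5),
    "alpha_neg_raw": (0.0, 2.0, 1.5),
    "t": (0.4, 0.5, 0.3),
    "z": (0.5, 0.2, 0.15),
}

# hard support bounds for subject-level proposals
_BOUNDS = {
    "a": (0.05, 10.0),
    "m": (-30.0, 30.0),
    "alpha_pos_raw": (-10.0, 10.0),
    "alpha_neg_raw": (-10.0, 10.0),
    "t": (1e-3, 3.0),
    "z": (0.02, 0.98),
}

_INIT_SCALES = {
    "a": 0.15, "m": 0.6, "alpha_pos_raw": 0.5, "alpha_neg_raw": 0.5,
    "t": 0.03, "z": 0.04,
}

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit and over which trial window.

    variant : 'dual_rate' (separate learning rates for positive and
        negative prediction errors) or 'single_rate'.
    window : 'whole', 'pre_reversal' (trials 1..reversal) or
        'post_reversal' (trials reversal+1..end).
    """

    variant: str = "dual_rate"
    window: str = "whole"
    reversal_trial: int = 60
    q0: float = 0.5
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in ("dual_rate", "single_rate"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.window not in ("whole", "pre_reversal", "post_reversal"):
            raise ValueError(f"unknown window {self.window!r}")


class RLDDMModel:
    """Packed data + graph metadata for one hierarchical fit."""

    def __init__(self, datasets, spec: ModelSpec):
        self.spec = spec
        self.subjects = sorted({ds.subject for ds in datasets})
        self.conditions = sorted({ds.condition for ds in datasets})
        S, C = len(self.subjects), len(self.conditions)
        self.S, self.C = S, C
        self.P = 4 * C + 2
        self.param_names = []
        for c, cond in enumerate(self.conditions):
            for p in RL_PARAMS:
                self.param_names.append(f"{p}[{cond}]")
        self.param_names += list(SHARED_PARAMS)

        subj_ix = {s: i for i, s in enumerate(self.subjects)}
        cond_ix = {c: i for i, c in enumerate(self.conditions)}

        chs, outs, rts, offs = [], [], [], [0]
        ds_subj, ds_cond = [], []
        for ds in datasets:
            mask = ds.responded.copy()
            if spec.window == "pre_reversal":
                mask &= ds.trial <= spec.reversal_trial
            elif spec.window == "post_reversal":
                mask &= ds.trial > spec.reversal_trial
            n = int(mask.sum())
            if n == 0:
                raise ValueError(
                    f"subject {ds.subject}/{ds.condition} has no responded "
                    f"trials in window {spec.window!r}")
            chs.append(ds.choice[mask])
            outs.append(ds.outcome[mask])
            rts.append(ds.dt[mask])
            offs.append(offs[-1] + n)
            ds_subj.append(subj_ix[ds.subject])
            ds_cond.append(cond_ix[ds.condition])
        self.choices = np.concatenate(chs).astype(np.int64)
        self.outcomes = np.concatenate(outs).astype(np.float64)
        self.dts = np.concatenate(rts).astype(np.float64)
        self.offs = np.asarray(offs, dtype=np.int64)
        self.ds_subj = np.asarray(ds_subj, dtype=np.int64)
        self.ds_cond = np.asarray(ds_cond, dtype=np.int64)

        # subject -> dataset index lists (CSR layout)
        order = np.argsort(self.ds_subj, kind="stable")
        self.subj_ds_idx = order.astype(np.int64)
        counts = np.bincount(self.ds_subj, minlength=S)
        self.subj_ds_off = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

        # per-subject minimum decision time (caps the non-decision time)
        self.min_dt = np.full(S, np.inf)
        for d in range(len(self.ds_subj)):
            s = self.ds_subj[d]
            lo, hi = self.offs[d], self.offs[d + 1]
            self.min_dt[s] = min(self.min_dt[s], self.dts[lo:hi].min())

        priors = dict(DEFAULT_PRIORS)
        priors.update(spec.priors)
        self.pmu_loc = np.empty(self.P)
        self.pmu_scale = np.empty(self.P)
        self.psd_scale = np.empty(self.P)
        self.bounds_lo = np.empty(self.P)
        self.bounds_hi = np.empty(self.P)
        self.init_scale_row = np.empty(self.P)
        for j, name in enumerate(self.param_names):
            base = name.split("[")[0]
            self.pmu_loc[j], self.pmu_scale[j], self.psd_scale[j] = priors[base]
            self.bounds_lo[j], self.bounds_hi[j] = _BOUNDS[base]
            self.init_scale_row[j] = _INIT_SCALES[base]

    def col(self, param: str, condition: str | None = None) -> int:
        """Column index of a parameter node (condition needed for RL params)."""
        if param in SHARED_PARAMS:
            return self.param_names.index(param)
        name = f"{param}[{condition}]"
        if name not in self.param_names:
            raise KeyError(f"unknown parameter node {name}")
        return self.param_names.index(name)

    def loglik(self, theta: np.ndarray) -> float:
        """Total log likelihood at subject-level point ``theta`` (S, P)."""
        return float(total_loglik(self.choices, self.outcomes, self.dts,
                                  self.offs, self.ds_subj, self.ds_cond,
                                  np.asarray(theta, dtype=float), self.C,
                                  self.spec.q0, SERIES_EPS))

    def _init_theta(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.empty((self.S, self.P))
        for j, name in enumerate(self.param_names):
            base = name.split("[")[0]
            if base == "a":
                theta[:, j] = rng.normal(1.5, 0.2, self.S)
            elif base == "m":
                theta[:, j] = rng.normal(2.0, 0.8, self.S)
            elif base in ("alpha_pos_raw", "alpha_neg_raw"):
                theta[:, j] = rng.normal(-1.0, 0.5, self.S)
            elif base == "t":
                theta[:, j] = np.minimum(0.6 * self.min_dt, 0.5) * rng.uniform(0.8, 1.0, self.S)
            else:  # z
                theta[:, j] = rng.normal(0.5, 0.02, self.S)
            theta[:, j] = np.clip(theta[:, j], self.bounds_lo[j] + 1e-6,
                                  self.bounds_hi[j] - 1e-6)
        return theta


def build_model(datasets, spec: ModelSpec | None = None) -> RLDDMModel:
    """Assemble the hierarchical model graph over a list of datasets."""
    return RLDDMModel(list(datasets), spec or ModelSpec())


@dataclass
class PosteriorDraws:
    """MCMC output: (chain, draw, ...) arrays plus diagnostics."""

    subject: np.ndarray       # (chains, draws, S, P)
    group_mu: np.ndarray      # (chains, draws, P)
    group_sd: np.ndarray      # (chains, draws, P)
    deviance: np.ndarray      # (chains, draws)
    param_names: list
    subjects: list
    conditions: list
    rhat: dict
    accept_rate: float

    @property
    def n_chains(self) -> int:
        return self.subject.shape[0]

    @property
    def n_draws(self) -> int:
        return self.subject.shape[1]

    def col(self, param: str, condition: str | None = None) -> int:
        if param in SHARED_PARAMS:
            return self.param_names.index(param)
        return self.param_names.index(f"{param}[{condition}]")

    def subject_point_estimates(self) -> np.ndarray:
        """Posterior-mean subject-level parameters, shape (S, P)."""
        return self.subject.mean(axis=(0, 1))

    def group_mu_flat(self, param: str, condition: str | None = None) -> np.ndarray:
        return self.group_mu[:, :, self.col(param, condition)].reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.param_names):
            draws = self.group_mu[:, :, j].reshape(-1)
            lo, hi = hdi(draws, 0.95)
            rows.append({"parameter": name, "mean": draws.mean(),
                         "hdi95_lo": lo, "hdi95_hi": hi,
                         "rhat": self.rhat.get(name, np.nan)})
        return pd.DataFrame(rows)


def hdi(samples: np.ndarray, prob: float) -> tuple:
    """Highest density interval of a 1-D sample (narrowest interval)."""
    lo, hi = az.hdi(np.asarray(samples, dtype=float).reshape(-1), hdi_prob=prob)
    return float(lo), float(hi)


def run_mcmc(model: RLDDMModel, chains: int = 4, burn: int = 7000,
             draws: int = 15000, seed: int | None = None) -> PosteriorDraws:
    """Sample the hierarchical posterior; deterministic under ``seed``.

    Emits a warning (not a failure) if any group-level Gelman--Rubin
    statistic reaches 1.1.
    """
    rng = np.random.default_rng(seed)
    single = model.spec.variant == "single_rate"
    subj, gmu, gsd, dev = [], [], [], []
    acc = 0.0
    for ch in range(chains):
        chain_seed = int(rng.integers(0, 2 ** 31 - 1))
        init = model._init_theta(np.random.default_rng(chain_seed))
        scales = np.tile(model.init_scale_row, (model.S, 1))
        o_th, o_mu, o_sd, o_dev, o_acc = _run_chain(
            model.choices, model.outcomes, model.dts, model.offs,
            model.ds_subj, model.ds_cond,
            model.subj_ds_idx, model.subj_ds_off,
            model.S, model.C, single,
            model.pmu_loc, model.pmu_scale, model.psd_scale,
            model.bounds_lo, model.bounds_hi,
            init, scales, int(burn), int(draws), chain_seed,
            model.spec.q0, SERIES_EPS)
        if not np.all(np.isfinite(o_dev)):
            bad = int(np.sum(~np.isfinite(o_dev)))
            raise RuntimeError(f"{bad} non-finite deviance draws in chain {ch}")
        subj.append(o_th)
        gmu.append(o_mu)
        gsd.append(o_sd)
        dev.append(o_dev)
        acc += o_acc
    gmu = np.stack(gmu)
    gsd = np.stack(gsd)
    subj = np.stack(subj)
    dev = np.stack(dev)
    if single:
        # mirror the tied learning-rate nodes for reporting
        for c in range(model.C):
            gmu[:, :, 4 * c + 3] = gmu[:, :, 4 * c + 2]
            gsd[:, :, 4 * c + 3] = gsd[:, :, 4 * c + 2]

    rhat = {}
    if chains >= 2:
        for j, name in enumerate(model.param_names):
            if single and j % 4 == 3 and j < 4 * model.C:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat[name] = float(az.rhat(az.convert_to_dataset(
                    gmu[:, :, j][:, :, None]))["x"].values[0])
        worst = max(rhat.values())
        if worst >= RHAT_THRESHOLD:
            warnings.warn(f"max group-level R-hat = {worst:.3f} >= {RHAT_THRESHOLD}",
                          RuntimeWarning)
    return PosteriorDraws(subject=subj, group_mu=gmu, group_sd=gsd,
                          deviance=dev, param_names=list(model.param_names),
                          subjects=list(model.subjects),
                          conditions=list(model.conditions),
                          rhat=rhat, accept_rate=acc / chains)


def compute_dic(posterior: PosteriorDraws, model: RLDDMModel) -> float:
    """Deviance Information Criterion: DIC = Dbar + pD, pD = Dbar - D(thetahat).

    ``thetahat`` is the posterior mean of the subject-level parameters.
    Non-finite deviance draws are excluded (with a warning reporting the
    count); lower DIC indicates the better penalised fit.
    """
    dev = posterior.deviance.reshape(-1)
    finite = np.isfinite(dev)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} non-finite deviance draws")
        dev = dev[finite]
    dbar = float(dev.mean())
    theta_hat = posterior.subject_point_estimates()
    d_hat = -2.0 * model.loglik(theta_hat)
    pd_ = dbar - d_hat
    return dbar + pd_


def dic_from_deviance(dev_draws: np.ndarray, dev_at_mean: float) -> float:
    """DIC from a deviance sample and the deviance at the posterior mean."""
    dev_draws = np.asarray(dev_draws, dtype=float)
    dev_draws = dev_draws[np.isfinite(dev_draws)]
    dbar = float(dev_draws.mean())
    return dbar + (dbar - float(dev_at_mean))


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior contrast of a group mean between two conditions."""

    parameter: str
    cond_a: str
    cond_b: str
    m_diff: float
    hdi95: tuple
    hdi85: tuple

    @property
    def significant(self) -> bool:
        """True when the 95% HDI excludes zero."""
        return not (self.hdi95[0] <= 0.0 <= self.hdi95[1])


def posterior_contrast(posterior: PosteriorDraws, parameter: str,
                       cond_a: str, cond_b: str) -> ContrastSummary:
    """Draw-wise difference of group means (``cond_a`` minus ``cond_b``)."""
    if parameter in SHARED_PARAMS:
        raise KeyError(f"{parameter} is shared across conditions; no contrast exists")
    diff = (posterior.group_mu_flat(parameter, cond_a)
            - posterior.group_mu_flat(parameter, cond_b))
    return ContrastSummary(parameter=parameter, cond_a=cond_a, cond_b=cond_b,
                           m_diff=float(diff.mean()),
                           hdi95=hdi(diff, 0.95), hdi85=hdi(diff, 0.85))


def condition_table(posterior: PosteriorDraws) -> pd.DataFrame:
    """Per-parameter, per-condition posterior means with 95% HDIs, plus
    pairwise contrasts — the standard summary-table layout."""
    rows = []
    for name in posterior.param_names:
        draws = posterior.group_mu_flat(*_split(name))
        lo, hi = hdi(draws, 0.95)
        rows.append({"node": name, "mean": float(draws.mean()),
                     "hdi95_lo": lo, "hdi95_hi": hi})
    conds = posterior.conditions
    if len(conds) >= 2:
        for pa in RL_PARAMS:
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    c = posterior_contrast(posterior, pa, conds[j], conds[i])
                    rows.append({"node": f"{pa}[{c.cond_a}-{c.cond_b}]",
                                 "mean": c.m_diff,
                                 "hdi95_lo": c.hdi95[0], "hdi95_hi": c.hdi95[1]})
    return pd.DataFrame(rows)


def _split(name: str):
    if "[" in name:
        base, cond = name[:-1].split("[")
        return base, cond
    return name, None


def save_posterior(posterior: PosteriorDraws, path) -> None:
    """Persist draws + metadata as a portable compressed array container."""
    import json

    np.savez_compressed(
        path,
        subject=posterior.subject, group_mu=posterior.group_mu,
        group_sd=posterior.group_sd, deviance=posterior.deviance,
        meta=np.frombuffer(json.dumps({
            "param_names": posterior.param_names,
            "subjects": posterior.subjects,
            "conditions": posterior.conditions,
            "rhat": posterior.rhat,
            "accept_rate": posterior.accept_rate,
        }).encode(), dtype=np.uint8))


def load_posterior(path) -> PosteriorDraws:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        return PosteriorDraws(
            subject=z["subject"], group_mu=z["group_mu"],
            group_sd=z["group_sd"], deviance=z["deviance"],
            param_names=meta["param_names"], subjects=meta["subjects"],
            conditions=meta["conditions"], rhat=meta["rhat"],
            accept_rate=meta["accept_rate"])


def agent_params_from_posterior(posterior: PosteriorDraws):
    """Posterior-mean subject parameters as AgentParams, per subject x condition.

    Returns a list (ordered like ``posterior.subjects``) of dicts mapping
    condition to :class:`~rlddm.learning.AgentParams` — directly usable as a
    cohort for generative simulation.
    """
    from .learning import AgentParams

    point = posterior.subject_point_estimates()
    names = posterior.param_names
    cohort = []
    for s in range(point.shape[0]):
        by_cond = {}
        for cond in posterior.conditions:
            kw = {}
            for p in RL_PARAMS:
                kw["alpha_pos_raw" if p == "alpha_pos_raw" else p] = \
                    point[s, names.index(f"{p}[{cond}]")]
            by_cond[cond] = AgentParams(
                a=kw["a"], m=kw["m"],
                alpha_pos_raw=kw["alpha_pos_raw"],
                alpha_neg_raw=kw["alpha_neg_raw"],
                t=point[s, names.index("t")],
                z=point[s, names.index("z")],
                condition=cond)
        cohort.append(by_cond)
    return cohort
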