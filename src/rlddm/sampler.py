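"""Numba-accelerated adaptive Metropolis-within-Gibbs for the hierarchical RLDDM.

Parameter layout
----------------
Subject-level parameters are stored in a matrix ``theta[S, P]`` with
``P = 4 * C + 2`` columns for ``C`` conditions:

* columns ``4c .. 4c+3``: boundary separation ``a``, drift-rate scaling
  ``m``, and the two learning rates on the unbounded scale
  (``alpha_pos_raw``, ``alpha_neg_raw``) in condition ``c``;
* column ``4C``: non-decision time ``t`` (shared across conditions);
* column ``4C+1``: relative start point ``z`` (shared across conditions).

Each column has a group-level normal ``N(mu_p, sigma_p)``; group means get
conjugate normal updates, group SDs and subject values random-walk
Metropolis steps (proposal scales adapted during burn-in toward a 0.44
acceptance rate).  In the single-learning-rate variant the negative-rate
column mirrors the positive one and its group nodes are inactive.

The per-subject likelihood replays the delta-rule value trajectory and
scores every responded trial with the WFPT log density, so the model
likelihood at any point equals the sum of trial-wise WFPT terms exactly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .wfpt import SERIES_EPS, _logpdf_scalar

ADAPT_BLOCK = 50
TARGET_ACCEPT = 0.44
SD_PROPOSAL = 0.25
SD_BOUNDS = (1e-3, 10.0)


@njit(cache=True)
def _dataset_ll(choices, outcomes, dts, start, end,
                a, m, ap_raw, an_raw, tnd, z, q0, eps):
    ap = 1.0 / (1.0 + math.exp(-ap_raw))
    an = 1.0 / (1.0 + math.exp(-an_raw))
    qa = q0
    qb = q0
    ll = 0.0
    for i in range(start, end):
        v = m * (qa - qb)
        ll += _logpdf_scalar(dts[i], choices[i] == 0, v, a, z, tnd, eps)
        r = outcomes[i]
        if choices[i] == 0:
            pe = r - qa
            qa += (ap if pe > 0 else an) * pe
        else:
            pe = r - qb
            qb += (ap if pe > 0 else an) * pe
    return ll


@njit(cache=True)
def _row_dataset_ll(choices, outcomes, dts, offs, d, cond, theta_row, C, q0, eps):
    a = theta_row[4 * cond]
    m = theta_row[4 * cond + 1]
    ap_raw = theta_row[4 * cond + 2]
    an_raw = theta_row[4 * cond + 3]
    tnd = theta_row[4 * C]
    z = theta_row[4 * C + 1]
    return _dataset_ll(choices, outcomes, dts, offs[d], offs[d + 1],
                       a, m, ap_raw, an_raw, tnd, z, q0, eps)


@njit(cache=True)
def total_loglik(choices, outcomes, dts, offs, ds_subj, ds_cond,
                 theta, C, q0, eps):
    tot = 0.0
    for d in range(len(ds_subj)):
        tot += _row_dataset_ll(choices, outcomes, dts, offs, d,
                               ds_cond[d], theta[ds_subj[d]], C, q0, eps)
    return tot


@njit(cache=True)
def _run_chain(choices, outcomes, dts, offs, ds_subj, ds_cond,
               subj_ds_idx, subj_ds_off,
               S, C, single_rate,
               pmu_loc, pmu_scale, psd_scale,
               bounds_lo, bounds_hi,
               init_theta, init_scales,
               n_burn, n_draws, seed, q0, eps):
    np.random.seed(seed)
    P = 4 * C + 2
    D = len(ds_subj)

    theta = init_theta.copy()
    active = np.ones(P, dtype=np.bool_)
    if single_rate:
        for c in range(C):
            active[4 * c + 3] = False
            theta[:, 4 * c + 3] = theta[:, 4 * c + 2]

    gmu = np.empty(P)
    gsd = np.empty(P)
    for p in range(P):
        gmu[p] = theta[:, p].mean()
        sd = theta[:, p].std()
        gsd[p] = sd if sd > 0.1 else 0.1

    cur_ll = np.empty(D)
    for d in range(D):
        cur_ll[d] = _row_dataset_ll(choices, outcomes, dts, offs, d,
                                    ds_cond[d], theta[ds_subj[d]], C, q0, eps)

    scales = init_scales.copy()
    n_acc = np.zeros((S, P))
    n_try = np.zeros((S, P))

    out_theta = np.empty((n_draws, S, P))
    out_gmu = np.empty((n_draws, P))
    out_gsd = np.empty((n_draws, P))
    out_dev = np.empty(n_draws)

    prop_ll = np.empty(16)
    prop_d = np.empty(16, dtype=np.int64)

    total_iters = n_burn + n_draws
    for it in range(total_iters):
        # --- subject-level updates -------------------------------------
        for s in range(S):
            for p in range(P):
                if not active[p]:
                    continue
                n_try[s, p] += 1.0
                old = theta[s, p]
                new = old + scales[s, p] * np.random.normal()
                if new <= bounds_lo[p] or new >= bounds_hi[p]:
                    continue
                mirror = single_rate and p < 4 * C and p % 4 == 2
                theta[s, p] = new
                if mirror:
                    theta[s, p + 1] = new
                # datasets whose likelihood this parameter touches
                n_aff = 0
                old_sum = 0.0
                new_sum = 0.0
                bad = False
                for j in range(subj_ds_off[s], subj_ds_off[s + 1]):
                    d = subj_ds_idx[j]
                    if p < 4 * C and ds_cond[d] != p // 4:
                        continue
                    ll = _row_dataset_ll(choices, outcomes, dts, offs, d,
                                         ds_cond[d], theta[s], C, q0, eps)
                    prop_ll[n_aff] = ll
                    prop_d[n_aff] = d
                    n_aff += 1
                    old_sum += cur_ll[d]
                    new_sum += ll
                    if not np.isfinite(ll):
                        bad = True
                dmu = gmu[p]
                dsd = gsd[p]
                logr = (new_sum - old_sum
                        - 0.5 * ((new - dmu) / dsd) ** 2
                        + 0.5 * ((old - dmu) / dsd) ** 2)
                if (not bad) and (logr >= 0.0 or np.random.random() < math.exp(logr)):
                    for k in range(n_aff):
                        cur_ll[prop_d[k]] = prop_ll[k]
                    n_acc[s, p] += 1.0
                else:
                    theta[s, p] = old
                    if mirror:
                        theta[s, p + 1] = old

        # --- group-level updates ---------------------------------------
        for p in range(P):
            if not active[p]:
                continue
            xs = theta[:, p]
            # conjugate normal update for the group mean
            prec = S / gsd[p] ** 2 + 1.0 / pmu_scale[p] ** 2
            mean = (xs.sum() / gsd[p] ** 2 + pmu_loc[p] / pmu_scale[p] ** 2) / prec
            gmu[p] = mean + np.random.normal() / math.sqrt(prec)
            # random-walk MH on log sigma with a half-normal prior
            old_sd = gsd[p]
            new_sd = old_sd * math.exp(SD_PROPOSAL * np.random.normal())
            if SD_BOUNDS[0] < new_sd < SD_BOUNDS[1]:
                ssq = 0.0
                for s in range(S):
                    ssq += (xs[s] - gmu[p]) ** 2
                logr = (-S * math.log(new_sd) - 0.5 * ssq / new_sd ** 2
                        + S * math.log(old_sd) + 0.5 * ssq / old_sd ** 2
                        - 0.5 * (new_sd / psd_scale[p]) ** 2
                        + 0.5 * (old_sd / psd_scale[p]) ** 2
                        + math.log(new_sd) - math.log(old_sd))
                if logr >= 0.0 or np.random.random() < math.exp(logr):
                    gsd[p] = new_sd

        # --- proposal adaptation during burn-in ------------------------
        if it < n_burn and (it + 1) % ADAPT_BLOCK == 0:
            for s in range(S):
                for p in range(P):
                    if n_try[s, p] > 0:
                        rate = n_acc[s, p] / n_try[s, p]
                        scales[s, p] *= math.exp(1.2 * (rate - TARGET_ACCEPT))
                        if scales[s, p] < 1e-4:
                            scales[s, p] = 1e-4
                        elif scales[s, p] > 5.0:
                            scales[s, p] = 5.0
            n_acc[:, :] = 0.0
            n_try[:, :] = 0.0

        # --- retain ----------------------------------------------------
        if it >= n_burn:
            k = it - n_burn
            out_theta[k] = theta
            out_gmu[k] = gmu
            out_gsd[k] = gsd
            dev = 0.0
            for d in range(D):
                dev += cur_ll[d]
            out_dev[k] = -2.0 * dev

    acc_rate = 0.0
    n_rate = 0.0
    for s in range(S):
        for p in range(P):
            if n_try[s, p] > 0:
                acc_rate += n_acc[s, p] / n_try[s, p]
                n_rate += 1.0
    if n_rate > 0:
        acc_rate /= n_rate
    return out_theta, out_gmu, out_gsd, out_dev, acc_rate
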