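"""Delta-rule value learning and exploratory-choice classification.

The learner tracks one expected value per option, updated after feedback by
``Q <- Q + alpha * (R - Q)`` with separate learning rates for positive and
negative prediction errors.  The trial-wise drift rate of the diffusion
choice rule is ``v = m * (Q_A - Q_B)``, computed from the *pre-update*
values (the decision precedes the feedback).  Learning rates live on an
unbounded scale and are squashed through the logistic function at use
time, which is the only transform consistent with reported group means
below zero alongside rates in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import OMITTED, SubjectDataset

Q0_DEFAULT = (0.5, 0.5)  # midpoint of the outcome range


@dataclass(frozen=True)
class AgentParams:
    """One subject's RLDDM parameters.

    a : boundary separation (evidence units), > 0
    t : non-decision time (seconds), >= 0
    z : relative start point in (0, 1)
    m : drift-rate scaling (evidence per unit value difference)
    alpha_pos_raw, alpha_neg_raw : learning rates on the unbounded scale
    """

    a: float
    t: float
    z: float
    m: float
    alpha_pos_raw: float
    alpha_neg_raw: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError("boundary separation a must be > 0")
        if self.t < 0:
            raise ValueError("non-decision time t must be >= 0")
        if not (0.0 < self.z < 1.0):
            raise ValueError("start point z must lie in (0, 1)")
        for name in ("a", "t", "z", "m", "alpha_pos_raw", "alpha_neg_raw"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    @property
    def alpha_pos(self) -> float:
        return squash_rate(self.alpha_pos_raw)

    @property
    def alpha_neg(self) -> float:
        return squash_rate(self.alpha_neg_raw)


@dataclass
class QTrajectory:
    """Per-trial values, drift and prediction errors for one dataset.

    ``q_a``/``q_b`` hold the *pre-choice* expected values on each trial;
    ``drift`` is ``m * (q_a - q_b)`` evaluated from those values; ``pe`` is
    the prediction error of the chosen option (nan on omissions).
    """

    q_a: np.ndarray
    q_b: np.ndarray
    drift: np.ndarray
    pe: np.ndarray

    def __len__(self) -> int:
        return len(self.q_a)


def squash_rate(raw):
    """Map an unbounded learning-rate value onto (0, 1) (logistic)."""
    return expit(raw)


def update_q(q: float, outcome: float, alpha_pos: float, alpha_neg: float) -> float:
    """One delta-rule update; the sign of the prediction error selects the rate."""
    if outcome not in (0, 1, 0.0, 1.0):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    pe = outcome - q
    alpha = alpha_pos if pe > 0 else alpha_neg
    return q + alpha * pe


def compute_q_trajectory(dataset: SubjectDataset, params: AgentParams,
                         q0=Q0_DEFAULT) -> QTrajectory:
    """Run the learner over a dataset; only the chosen option updates.

    Omitted trials update nothing (no feedback was shown) but still occupy
    a slot in the trajectory so it stays aligned with the trial grid.
    """
    n = dataset.n_trials
    q_a = np.empty(n)
    q_b = np.empty(n)
    drift = np.empty(n)
    pe = np.full(n, np.nan)
    ap, an = params.alpha_pos, params.alpha_neg
    qa, qb = float(q0[0]), float(q0[1])
    for i in range(n):
        q_a[i], q_b[i] = qa, qb
        drift[i] = params.m * (qa - qb)
        c = dataset.choice[i]
        if c == OMITTED:
            continue
        r = dataset.outcome[i]
        if c == 0:
            pe[i] = r - qa
            qa = qa + (ap if pe[i] > 0 else an) * pe[i]
        else:
            pe[i] = r - qb
            qb = qb + (ap if pe[i] > 0 else an) * pe[i]
    return QTrajectory(q_a=q_a, q_b=q_b, drift=drift, pe=pe)


def classify_exploratory(dataset: SubjectDataset, traj: QTrajectory) -> np.ndarray:
    """Flag trials on which the strictly lower-valued option was chosen.

    Comparison uses the pre-choice values; ties are not exploratory;
    omitted trials are never flagged.
    """
    if len(traj) != dataset.n_trials:
        raise ValueError("trajectory length does not match trial count")
    chosen_q = np.where(dataset.choice == 0, traj.q_a, traj.q_b)
    other_q = np.where(dataset.choice == 0, traj.q_b, traj.q_a)
    flags = (chosen_q < other_q) & dataset.responded
    return flags
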