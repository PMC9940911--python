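"""Task design and fully synthetic cohorts (behavioural and voxel-map).

The default design mirrors a two-armed probabilistic reversal-learning
task: three 40-trial sessions, reward probabilities 80%:20% on the two
options, contingencies swapped after trial 60 (the reversal takes effect
from trial 61), a 3-second response window, and occasional omissions.
Behaviour is generated by closing the loop between the delta-rule learner
and the diffusion choice rule: the current value difference sets the
drift, the simulated walk yields choice and decision time, the outcome is
drawn from the schedule, and the chosen option's value is updated.

Omissions arise from two mechanisms: an independent Bernoulli lapse per
trial (rate ``omission_rate``) and, rarely, a diffusion that fails to
terminate inside the response window; both leave the trial without
outcome or value update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .data import OMITTED, SubjectDataset
from .learning import AgentParams
from .wfpt import DEFAULT_CAP, DEFAULT_STEP, _sim_fpt

RESPONSE_WINDOW_S = 3.0

PARAM_NAMES = ("a", "t", "z", "m", "alpha_pos_raw", "alpha_neg_raw")

#: Group-level parameter locations used as default study conditions.  The
#: patient ON/OFF values follow the fitted group means of the whole-task
#: dual-learning-rate model; the control (HC) column applies the reported
#: group contrasts (lower drift-rate scaling, higher negative learning
#: rate, faster non-decision time) to the OFF baseline.
DEFAULT_GROUP_MEANS = {
    "ON": {"a": 1.78, "t": 0.57, "z": 0.5, "m": 3.40, "alpha_pos_raw": 0.22, "alpha_neg_raw": -2.65},
    "OFF": {"a": 1.96, "t": 0.57, "z": 0.5, "m": 4.51, "alpha_pos_raw": -0.85, "alpha_neg_raw": -2.97},
    "HC": {"a": 1.96, "t": 0.42, "z": 0.5, "m": 2.80, "alpha_pos_raw": -0.85, "alpha_neg_raw": -1.65},
}

#: Between-subject spreads on the estimation scale; chosen once to give
#: individual-parameter scatter comparable to the reported subject-level
#: estimates.
DEFAULT_GROUP_SDS = {
    "a": 0.25, "t": 0.10, "z": 0.05, "m": 1.30,
    "alpha_pos_raw": 1.00, "alpha_neg_raw": 1.00,
}

DEFAULT_OMISSION_RATE = 0.015  # matches reported 0-8 omissions in 120 trials

# hard floors/ceilings applied to sampled subject parameters so every
# agent is simulable (a > 0, t > 0, z inside the open unit interval)
_CLIP = {"a": (0.3, 8.0), "t": (0.05, 1.5), "z": (0.15, 0.85)}


class InvalidDesignError(ValueError):
    """Raised when a task schedule is internally inconsistent."""


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial reward probabilities and session structure.

    ``p_reward`` has shape (n_trials, 2) — independent Bernoulli arms.
    ``session_bounds`` holds 1-based inclusive (start, end) ranges.
    ``reversal_trial`` is the last trial of the pre-reversal phase.
    """

    n_trials: int
    session_bounds: tuple
    p_reward: np.ndarray
    reversal_trial: int

    def __post_init__(self) -> None:
        total = sum(e - s + 1 for s, e in self.session_bounds)
        if total != self.n_trials:
            raise InvalidDesignError("session lengths must sum to n_trials")
        if self.p_reward.shape != (self.n_trials, 2):
            raise InvalidDesignError("p_reward must have shape (n_trials, 2)")

    def session_of(self, trial: np.ndarray) -> np.ndarray:
        """Map 1-based trial indices to 1-based session numbers."""
        out = np.zeros(len(trial), dtype=np.int64)
        for k, (s, e) in enumerate(self.session_bounds, start=1):
            out[(trial >= s) & (trial <= e)] = k
        return out

    def better_option(self) -> np.ndarray:
        """Index of the objectively higher-probability arm per trial."""
        return np.argmax(self.p_reward, axis=1)


def make_schedule(p_high: float = 0.8, trials_per_session: int = 40,
                  n_sessions: int = 3, reversal_trial: int = 60) -> TaskSchedule:
    """Build the reversal design: option A pays ``p_high`` up to and
    including ``reversal_trial``, then the arms swap exactly."""
    if not (0.5 < p_high <= 1.0):
        raise InvalidDesignError("p_high must lie in (0.5, 1]")
    n_trials = trials_per_session * n_sessions
    if not (1 <= reversal_trial < n_trials):
        raise InvalidDesignError("reversal_trial must be strictly inside the trial range")
    p = np.empty((n_trials, 2))
    p[:reversal_trial, 0] = p_high
    p[:reversal_trial, 1] = 1.0 - p_high
    p[reversal_trial:, 0] = 1.0 - p_high
    p[reversal_trial:, 1] = p_high
    bounds = tuple(
        (k * trials_per_session + 1, (k + 1) * trials_per_session)
        for k in range(n_sessions)
    )
    return TaskSchedule(n_trials=n_trials, session_bounds=bounds,
                        p_reward=p, reversal_trial=reversal_trial)


@dataclass
class CohortSpec:
    """Hierarchical sampling spec for a synthetic cohort.

    ``group_means`` maps condition -> parameter -> location on the
    estimation scale (learning rates unbounded; other parameters natural).
    Non-decision time and start point are subject traits shared across
    conditions: they are drawn once per subject from the first condition's
    entries.
    """

    n_subjects: int = 18
    group_means: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_GROUP_MEANS.items() if c != "HC"
    })
    group_sds: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SDS))
    omission_rate: float = DEFAULT_OMISSION_RATE
    seed: int | None = None

    @property
    def conditions(self) -> tuple:
        return tuple(self.group_means)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.omission_rate <= 0.5):
            raise ValueError("omission_rate must lie in [0, 0.5]")
        for cond, means in self.group_means.items():
            for p in PARAM_NAMES:
                if p not in means or not np.isfinite(means[p]):
                    raise ValueError(f"non-finite or missing mean for {p} in {cond}")
        for p in PARAM_NAMES:
            if self.group_sds.get(p, -1.0) < 0 or not np.isfinite(self.group_sds.get(p, np.nan)):
                raise ValueError(f"group sd for {p} must be finite and >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list:
    """Draw subject-level parameters from the group distributions.

    Returns one dict per subject mapping condition label to
    :class:`AgentParams`.  Draws are normal on the estimation scale;
    boundary separation, non-decision time and start point are clipped to
    simulable ranges.
    """
    spec.validate()
    cohort = []
    first_cond = spec.conditions[0]
    for _ in range(spec.n_subjects):
        # shared subject traits (not condition dependent)
        shared = {}
        for p in ("t", "z"):
            val = rng.normal(spec.group_means[first_cond][p], spec.group_sds[p])
            shared[p] = float(np.clip(val, *_CLIP[p]))
        subject = {}
        for cond in spec.conditions:
            means = spec.group_means[cond]
            draw = {}
            for p in ("a", "m", "alpha_pos_raw", "alpha_neg_raw"):
                val = rng.normal(means[p], spec.group_sds[p])
                if p in _CLIP:
                    val = float(np.clip(val, *_CLIP[p]))
                draw[p] = float(val)
            subject[cond] = AgentParams(condition=cond, t=shared["t"], z=shared["z"], **draw)
        cohort.append(subject)
    return cohort


@njit(cache=True)
def _gen_trials(p_reward, a, tnd, z, m, ap, an, omission_rate,
                q0a, q0b, step, cap, window, seed):
    np.random.seed(seed)
    n = p_reward.shape[0]
    choice = np.full(n, -1, dtype=np.int64)
    outcome = np.full(n, np.nan)
    dt = np.full(n, np.nan)
    qa, qb = q0a, q0b
    for i in range(n):
        if np.random.random() < omission_rate:
            continue
        v = m * (qa - qb)
        b, fpt = _sim_fpt(v, a, z, step, cap)
        rt = tnd + fpt
        if b < 0 or rt > window:
            continue  # no response inside the window -> omission
        ch = 0 if b == 1 else 1
        rew = 1.0 if np.random.random() < p_reward[i, ch] else 0.0
        choice[i] = ch
        outcome[i] = rew
        dt[i] = rt
        if ch == 0:
            pe = rew - qa
            qa += (ap if pe > 0 else an) * pe
        else:
            pe = rew - qb
            qb += (ap if pe > 0 else an) * pe
    return choice, outcome, dt


def generate_agent_dataset(params: AgentParams, schedule: TaskSchedule,
                           omission_rate: float, rng: np.random.Generator,
                           subject: str = "s01", q0=(0.5, 0.5),
                           step: float = DEFAULT_STEP, cap: float = DEFAULT_CAP,
                           response_window: float = RESPONSE_WINDOW_S) -> SubjectDataset:
    """Simulate one subject x condition through the full task."""
    seed = int(rng.integers(0, 2 ** 31 - 1))
    choice, outcome, dt = _gen_trials(
        schedule.p_reward, params.a, params.t, params.z, params.m,
        params.alpha_pos, params.alpha_neg, omission_rate,
        float(q0[0]), float(q0[1]), step, cap, response_window, seed)
    trial = np.arange(1, schedule.n_trials + 1)
    return SubjectDataset(
        subject=subject, condition=params.condition or "sim",
        session=schedule.session_of(trial), trial=trial,
        choice=choice, outcome=outcome, dt=dt)


def generate_cohort_data(cohort: list, schedule: TaskSchedule,
                         omission_rate: float = DEFAULT_OMISSION_RATE,
                         rng: np.random.Generator | None = None,
                         q0=(0.5, 0.5), step: float = DEFAULT_STEP,
                         cap: float = DEFAULT_CAP) -> list:
    """Simulate the full cohort; returns one dataset per subject x condition."""
    if rng is None:
        rng = np.random.default_rng()
    datasets = []
    for i, subject in enumerate(cohort):
        sid = f"s{i + 1:02d}"
        for cond, params in subject.items():
            datasets.append(generate_agent_dataset(
                params, schedule, omission_rate, rng,
                subject=sid, q0=q0, step=step, cap=cap))
    return datasets


def synth_voxel_cohort(n_subjects: int, grid_dims, effect_mask: np.ndarray,
                       effect_size: float, noise_sd: float,
                       rng: np.random.Generator,
                       behaviour: np.ndarray | None = None):
    """Voxel-map stack with a planted behaviour-connectivity correlation.

    Within ``effect_mask``, each voxel's across-subject values correlate
    with the behaviour vector at ``effect_size``; elsewhere the maps are
    pure noise.  ``behaviour`` defaults to standard-normal draws but an
    observed vector (e.g. measured exploration changes) can be planted
    instead.  Returns ``(stack, behaviour)`` with stack shape
    ``(n_subjects, *grid_dims)``.
    """
    effect_mask = np.asarray(effect_mask, dtype=bool)
    if effect_mask.shape != tuple(grid_dims):
        raise ValueError("effect_mask must match grid_dims")
    if abs(effect_size) > 1:
        raise ValueError("|effect_size| must be <= 1")
    if effect_size != 0 and not effect_mask.any():
        raise ValueError("non-zero effect_size requires a non-empty mask")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if behaviour is None:
        behaviour = rng.normal(size=n_subjects)
    else:
        behaviour = np.asarray(behaviour, dtype=float)
        if len(behaviour) != n_subjects or np.std(behaviour) == 0:
            raise ValueError("behaviour must have n_subjects entries and nonzero spread")
    b_std = (behaviour - behaviour.mean()) / behaviour.std()
    stack = noise_sd * rng.normal(size=(n_subjects,) + tuple(grid_dims))
    signal = noise_sd * effect_size * b_std
    attenuation = np.sqrt(1.0 - effect_size ** 2)
    stack[:, effect_mask] = attenuation * stack[:, effect_mask] + signal[:, None]
    return stack, behaviour


def synth_stim_volumes(n_subjects: int, grid_dims, rng: np.random.Generator,
                       radius: float = 2.5, jitter: float = 1.5) -> np.ndarray:
    """Synthetic binary stimulation volumes: spheres with jittered centres.

    A stand-in fixture for modelled stimulation volumes; returns a boolean
    stack of shape ``(n_subjects, *grid_dims)``.
    """
    dims = np.asarray(grid_dims, dtype=float)
    centre = (dims - 1) / 2.0
    coords = np.stack(np.meshgrid(*[np.arange(d) for d in grid_dims], indexing="ij"), axis=-1)
    stack = np.zeros((n_subjects,) + tuple(grid_dims), dtype=bool)
    for s in range(n_subjects):
        c = centre + rng.uniform(-jitter, jitter, size=3)
        r = radius * rng.uniform(0.8, 1.2)
        stack[s] = np.sum((coords - c) ** 2, axis=-1) <= r ** 2
    return stack
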