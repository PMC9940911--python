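"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Options are coded ``0`` (option A, the upper diffusion boundary) and
  ``1`` (option B, the lower boundary).  Omitted trials carry choice ``-1``,
  ``nan`` outcome and ``nan`` decision time.
* Trial indices are 1-based and anchored to the task grid, so omissions
  leave gaps instead of shifting later trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMITTED = -1
OPTION_LABELS = {0: "A", 1: "B", OMITTED: "omitted"}
LABEL_TO_CODE = {"A": 0, "B": 1, "omitted": OMITTED}


@dataclass
class SubjectDataset:
    """Ordered trial records for one subject in one condition.

    Parameters
    ----------
    subject : str
        Subject identifier.
    condition : str
        Condition label (e.g. ``"ON"``, ``"OFF"``, ``"HC"``).
    session : ndarray of int
        Session number (1-based) per trial.
    trial : ndarray of int
        1-based trial index on the task grid.
    choice : ndarray of int
        0 = option A, 1 = option B, -1 = omission.
    outcome : ndarray of float
        1.0 reward, 0.0 nothing, nan on omitted trials.
    dt : ndarray of float
        Decision time in seconds; nan on omitted trials.
    """

    subject: str
    condition: str
    session: np.ndarray
    trial: np.ndarray
    choice: np.ndarray
    outcome: np.ndarray
    dt: np.ndarray

    def __post_init__(self) -> None:
        self.session = np.asarray(self.session, dtype=np.int64)
        self.trial = np.asarray(self.trial, dtype=np.int64)
        self.choice = np.asarray(self.choice, dtype=np.int64)
        self.outcome = np.asarray(self.outcome, dtype=np.float64)
        self.dt = np.asarray(self.dt, dtype=np.float64)
        n = len(self.trial)
        for name in ("session", "choice", "outcome", "dt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column '{name}' length mismatch for {self.subject}")
        if n and np.any(np.diff(self.trial) <= 0):
            raise ValueError(f"trials of {self.subject}/{self.condition} are not strictly increasing")
        omitted = self.choice == OMITTED
        if np.any(~np.isnan(self.outcome[omitted])):
            raise ValueError("omitted trials must not carry an outcome")
        if np.any(~np.isnan(self.dt[omitted])):
            raise ValueError("omitted trials must not carry a decision time")

    @property
    def n_trials(self) -> int:
        return len(self.trial)

    @property
    def responded(self) -> np.ndarray:
        """Boolean mask of trials with a recorded response."""
        return self.choice != OMITTED

    @property
    def n_omissions(self) -> int:
        return int(np.sum(~self.responded))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "condition": self.condition,
                "session": self.session,
                "trial": self.trial,
                "choice": [OPTION_LABELS[c] for c in self.choice],
                "outcome": self.outcome,
                "dt_s": self.dt,
                "omitted": (~self.responded).astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubjectDataset":
        df = df.sort_values("trial")
        subject = str(df["subject"].iloc[0])
        condition = str(df["condition"].iloc[0])
        choice = np.array([LABEL_TO_CODE[str(c)] for c in df["choice"]], dtype=np.int64)
        return cls(
            subject=subject,
            condition=condition,
            session=df["session"].to_numpy(),
            trial=df["trial"].to_numpy(),
            choice=choice,
            outcome=df["outcome"].to_numpy(dtype=float),
            dt=df["dt_s"].to_numpy(dtype=float),
        )
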