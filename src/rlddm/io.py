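"""Delimited trial files, run configuration and run manifests.

One tidy long-format schema is shared by real and synthetic data:
``subject, condition, session, trial, choice, outcome, dt_s, omitted``
with 1-based trial indices, choice in {A, B, omitted}, outcomes in {0, 1}
(empty on omissions) and decision times in seconds inside the 3-second
response window.  Conditions are labels in the file, never file-name
conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import LABEL_TO_CODE, SubjectDataset
from .task import RESPONSE_WINDOW_S

TRIAL_COLUMNS = ["subject", "condition", "session", "trial", "choice",
                 "outcome", "dt_s", "omitted"]


class TrialFormatError(ValueError):
    """Malformed trial file; the message names the offending rows."""


def write_trials(datasets, path) -> None:
    """Write datasets to one delimited file (CSV)."""
    frames = [ds.to_frame() for ds in datasets]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def read_trials(path) -> list:
    """Read and validate a trial file; returns a list of SubjectDataset.

    Row numbers in error messages count the header as line 1.
    ``read_trials(write_trials(x))`` is the identity on valid data.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: no trial rows")
        return []
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing columns {missing}")
    errors = []
    for i, row in df.iterrows():
        line = i + 2
        choice = str(row["choice"])
        if choice not in LABEL_TO_CODE:
            errors.append(f"line {line}: unknown choice {choice!r}")
            continue
        if choice == "omitted":
            if not pd.isna(row["outcome"]):
                errors.append(f"line {line}: omitted trial carries an outcome")
            if not pd.isna(row["dt_s"]):
                errors.append(f"line {line}: omitted trial carries a decision time")
        else:
            dt = row["dt_s"]
            if pd.isna(dt) or not (0.0 < float(dt) <= RESPONSE_WINDOW_S):
                errors.append(
                    f"line {line}: dt_s={dt!r} outside (0, {RESPONSE_WINDOW_S}]")
            if pd.isna(row["outcome"]) or float(row["outcome"]) not in (0.0, 1.0):
                errors.append(f"line {line}: outcome must be 0 or 1")
    if errors:
        raise TrialFormatError(f"{path}: " + "; ".join(errors[:20]))
    datasets = []
    for (_, _), group in df.groupby(["subject", "condition"], sort=True):
        datasets.append(SubjectDataset.from_frame(group))
    return datasets


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through JSON."""

    stages: list = field(default_factory=lambda: ["simulate", "stats", "fit"])
    seed: int = 0
    mcmc: dict = field(default_factory=lambda: {"chains": 4, "burn": 7000, "draws": 15000})
    task: dict = field(default_factory=lambda: {
        "p_high": 0.8, "trials_per_session": 40, "n_sessions": 3, "reversal_trial": 60})
    paths: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_manifest(path, stage: str, seed, inputs=None, outputs=None,
                   parameters=None) -> None:
    """JSON run manifest: everything needed to regenerate a stage's outputs."""
    import rlddm

    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": inputs or [],
        "outputs": outputs or [],
        "parameters": parameters or {},
        "versions": {
            "rlddm": rlddm.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
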