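import numpy as np
import pytest

from rlddm.data import SubjectDataset
from rlddm.inference import ModelSpec, build_model, run_mcmc
from rlddm.task import CohortSpec, generate_cohort_data, make_schedule, sample_cohort


def make_dataset(choices, outcomes, dts=None, subject="s01", condition="OFF",
                 trials_per_session=None):
    """Hand-rolled dataset builder for unit tests.

    ``choices`` uses -1 for omissions; outcomes/dts on omitted slots are
    replaced by nan automatically.
    """
    choices = np.asarray(choices, dtype=np.int64)
    n = len(choices)
    outcomes = np.asarray(outcomes, dtype=float)
    dts = np.full(n, 1.0) if dts is None else np.asarray(dts, dtype=float)
    omitted = choices == -1
    outcomes = np.where(omitted, np.nan, outcomes)
    dts = np.where(omitted, np.nan, dts)
    tps = trials_per_session or n
    trial = np.arange(1, n + 1)
    session = (trial - 1) // tps + 1
    return SubjectDataset(subject=subject, condition=condition, session=session,
                          trial=trial, choice=choices, outcome=outcomes, dt=dts)


@pytest.fixture(scope="session")
def schedule():
    return make_schedule()


@pytest.fixture(scope="session")
def patient_cohort(schedule):
    """A synthetic 18-subject ON/OFF cohort at the study's design scale."""
    rng = np.random.default_rng(2024)
    spec = CohortSpec(n_subjects=18)
    cohort = sample_cohort(spec, rng)
    data = generate_cohort_data(cohort, schedule, rng=rng)
    return cohort, data


@pytest.fixture(scope="session")
def fitted_patients(patient_cohort):
    """Reduced-budget hierarchical fit of the synthetic patient cohort."""
    _, data = patient_cohort
    model = build_model(data, ModelSpec())
    post = run_mcmc(model, chains=2, burn=1000, draws=1000, seed=1234)
    return model, post
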