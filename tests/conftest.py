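import numpy as np
import pytest

from bartfnirs import models as m
from bartfnirs import synthetic_data as sd
from bartfnirs.bart_core import (
    CONTROL,
    PATIENT,
    BalloonCondition,
    SubjectDataset,
    TaskConfig,
    TrialRecord,
)


@pytest.fixture(scope="session")
def default_task() -> TaskConfig:
    return TaskConfig.default()


@pytest.fixture(scope="session")
def tiny_task() -> TaskConfig:
    """A single 3-pump balloon condition — small enough to enumerate every
    outcome sequence exactly."""
    return TaskConfig(conditions=(BalloonCondition("tiny", 3, 3),))


@pytest.fixture(scope="session")
def ewmvm_params() -> m.EWMVMParams:
    return m.EWMVMParams(phi=0.956, eta=0.049, gamma=0.004, tau=5.32, lam=2.32)


@pytest.fixture(scope="session")
def rfpm_params() -> m.RFPMParams:
    return m.RFPMParams(phi=0.956, eta=0.049, gamma=0.45, tau=5.32)


@pytest.fixture(scope="session")
def small_cohort(default_task):
    """A fixed-seed 4+4 EWMVM cohort on a shortened session (6 trials per
    condition) shared across tests that only need plausible data."""
    task = TaskConfig(
        conditions=(
            BalloonCondition("blue", 8, 6),
            BalloonCondition("green", 32, 6),
            BalloonCondition("red", 128, 6),
        )
    )
    groups = [
        sd.GroupSpec(PATIENT, 4, dict(sd._PATIENT_LOCS_EWMVM), dict.fromkeys(sd._PATIENT_LOCS_EWMVM, 0.1)),
        sd.GroupSpec(CONTROL, 4, dict(sd._CONTROL_LOCS_EWMVM), dict.fromkeys(sd._CONTROL_LOCS_EWMVM, 0.1)),
    ]
    datasets, truth = sd.simulate_cohort(groups, m.MODEL_EWMVM, task, seed=42)
    return task, datasets, truth


def make_trial(
    n_pumps: int,
    exploded: bool,
    max_pumps: int = 8,
    trial_index: int = 1,
    condition: str = "blue",
    explosion_point: int | None = None,
    subject_id: str = "s01",
    group: str = CONTROL,
) -> TrialRecord:
    if explosion_point is None:
        explosion_point = n_pumps if exploded else min(n_pumps + 1, max_pumps)
    return TrialRecord(
        subject_id=subject_id,
        group=group,
        trial_index=trial_index,
        condition=condition,
        max_pumps=max_pumps,
        explosion_point=explosion_point,
        n_pumps=n_pumps,
        exploded=exploded,
    )


def make_dataset(pumps_exploded, subject_id="s01", group=CONTROL, **kw) -> SubjectDataset:
    trials = [
        make_trial(n, e, trial_index=i + 1, subject_id=subject_id, group=group, **kw)
        for i, (n, e) in enumerate(pumps_exploded)
    ]
    return SubjectDataset(subject_id=subject_id, group=group, trials=trials)
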