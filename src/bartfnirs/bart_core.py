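"""Balloon risk task: design, trial-level data model, adjusted scores, table I/O.

The task is a sequential risk task: on each trial the participant repeatedly
pumps a virtual balloon.  Every successful pump adds ``reward_per_pump`` coins
to the trial's stake; the participant may stop at any time and bank the stake,
but if the balloon bursts first the stake is lost.  Three balloon colors carry
different maximum pump counts (8 / 32 / 128 by default), so their burst hazards
differ and participants must learn them from experience.

The standard behavioral index is the *adjusted score*: the mean number of pumps
over the trials that did **not** burst (burst trials censor the intended pump
count, so they are excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "PATIENT",
    "CONTROL",
    "BalloonCondition",
    "TaskConfig",
    "TrialRecord",
    "SubjectDataset",
    "AdjustedScoreUndefined",
    "TrialValidationError",
    "adjusted_score",
    "session_reward",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_datasets",
]

PATIENT = "patient"
CONTROL = "control"

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "trial_index",
    "condition",
    "max_pumps",
    "explosion_point",
    "n_pumps",
    "exploded",
]


class AdjustedScoreUndefined(ValueError):
    """No non-exploded trial exists for the requested condition.

    The adjusted score is the mean over cashed-out trials; when every balloon
    of a condition burst the score is *missing*, never zero.
    """


class TrialValidationError(ValueError):
    """A trial row violates the task's bookkeeping invariants."""


@dataclass(frozen=True)
class BalloonCondition:
    """One balloon color: its cap on pumps and how many trials it gets."""

    label: str
    max_pumps: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.max_pumps < 1:
            raise ValueError(f"max_pumps must be positive, got {self.max_pumps}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be positive, got {self.n_trials}")


@dataclass(frozen=True)
class TaskConfig:
    """Task design: balloon conditions, payoff per pump, burst mechanism.

    ``explosion_rule`` selects how the burst point of each balloon is drawn:

    ``"uniform"``
        the classic convention — the explosion point is uniform on the
        integers ``[1, max_pumps]``, so larger-capacity balloons have a lower
        per-pump hazard.
    ``"constant_hazard"``
        every pump bursts independently with probability ``1 / max_pumps``
        (geometric, truncation handled by the cap).
    """

    conditions: tuple[BalloonCondition, ...]
    reward_per_pump: float = 1.0
    explosion_rule: str = "uniform"

    def __post_init__(self) -> None:
        if self.reward_per_pump <= 0:
            raise ValueError("reward_per_pump must be > 0")
        if self.explosion_rule not in ("uniform", "constant_hazard"):
            raise ValueError(f"unknown explosion_rule {self.explosion_rule!r}")
        if len({c.label for c in self.conditions}) != len(self.conditions):
            raise ValueError("condition labels must be unique")

    @property
    def n_trials(self) -> int:
        return sum(c.n_trials for c in self.conditions)

    def condition(self, label: str) -> BalloonCondition:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    @classmethod
    def default(cls) -> "TaskConfig":
        """The canonical three-color design: blue/green/red capped at 8/32/128,
        30 trials each (90 total), one coin per successful pump."""
        return cls(
            conditions=(
                BalloonCondition("blue", 8, 30),
                BalloonCondition("green", 32, 30),
                BalloonCondition("red", 128, 30),
            ),
            reward_per_pump=1.0,
        )


@dataclass(frozen=True)
class TrialRecord:
    """One balloon trial.

    ``exploded`` is the complement of the cash-out indicator: an exploded
    trial ends at ``explosion_point`` with the stake lost; a cashed-out trial
    ends by choice with ``n_pumps`` pumps banked.
    """

    subject_id: str
    group: str
    trial_index: int
    condition: str
    max_pumps: int
    explosion_point: int
    n_pumps: int
    exploded: bool
    reward_earned: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.explosion_point <= self.max_pumps:
            raise TrialValidationError(
                f"explosion_point {self.explosion_point} outside [1, {self.max_pumps}]"
            )
        if self.n_pumps < 0:
            raise TrialValidationError("n_pumps must be non-negative")
        if self.exploded:
            if self.n_pumps != self.explosion_point:
                raise TrialValidationError(
                    f"exploded trial must have n_pumps == explosion_point "
                    f"({self.n_pumps} != {self.explosion_point})"
                )
        else:
            if self.n_pumps >= self.explosion_point:
                raise TrialValidationError(
                    f"cashed-out trial must have n_pumps < explosion_point "
                    f"({self.n_pumps} >= {self.explosion_point})"
                )
            if self.n_pumps > self.max_pumps:
                raise TrialValidationError("n_pumps exceeds max_pumps")

    def with_reward(self, reward_per_pump: float) -> "TrialRecord":
        earned = 0.0 if self.exploded else self.n_pumps * reward_per_pump
        return replace(self, reward_earned=earned)


@dataclass
class SubjectDataset:
    """A subject's full session, trials ordered by ``trial_index``."""

    subject_id: str
    group: str
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [t.trial_index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise TrialValidationError(
                f"trial_index not strictly increasing for subject {self.subject_id}"
            )
        for t in self.trials:
            if t.subject_id != self.subject_id:
                raise TrialValidationError(
                    f"trial subject_id {t.subject_id!r} != dataset {self.subject_id!r}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.condition, None)
        return list(seen)


def adjusted_score(dataset: SubjectDataset, condition: str | None = None) -> float:
    """Mean pumps over non-exploded trials, optionally within one condition.

    Raises :class:`AdjustedScoreUndefined` when no non-exploded trial exists;
    callers that build tables should map that to a missing value, not 0.
    """
    pumps = [
        t.n_pumps
        for t in dataset.trials
        if not t.exploded and (condition is None or t.condition == condition)
    ]
    if not pumps:
        raise AdjustedScoreUndefined(
            f"subject {dataset.subject_id}: no cashed-out trials"
            + (f" in condition {condition!r}" if condition else "")
        )
    return float(sum(pumps)) / len(pumps)


def adjusted_score_or_nan(dataset: SubjectDataset, condition: str | None = None) -> float:
    try:
        return adjusted_score(dataset, condition)
    except AdjustedScoreUndefined:
        return math.nan


def session_reward(dataset: SubjectDataset, reward_per_pump: float = 1.0) -> float:
    """Total banked reward: sum of n_pumps * r over cashed-out trials."""
    return sum(t.n_pumps * reward_per_pump for t in dataset.trials if not t.exploded)


# ---------------------------------------------------------------------------
# Table I/O — UTF-8 comma-delimited, one row per trial, booleans true/false.


def trials_to_frame(datasets: list[SubjectDataset]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": t.subject_id,
            "group": t.group,
            "trial_index": t.trial_index,
            "condition": t.condition,
            "max_pumps": t.max_pumps,
            "explosion_point": t.explosion_point,
            "n_pumps": t.n_pumps,
            "exploded": t.exploded,
        }
        for d in datasets
        for t in d.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_datasets(
    frame: pd.DataFrame, reward_per_pump: float = 1.0
) -> list[SubjectDataset]:
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")

    datasets: list[SubjectDataset] = []
    for subject_id, sub in frame.groupby("subject_id", sort=False):
        trials = []
        for row_number, row in sub.iterrows():
            try:
                trial = TrialRecord(
                    subject_id=str(row["subject_id"]),
                    group=str(row["group"]),
                    trial_index=_as_int(row["trial_index"], "trial_index"),
                    condition=str(row["condition"]),
                    max_pumps=_as_int(row["max_pumps"], "max_pumps"),
                    explosion_point=_as_int(row["explosion_point"], "explosion_point"),
                    n_pumps=_as_int(row["n_pumps"], "n_pumps"),
                    exploded=_as_bool(row["exploded"]),
                ).with_reward(reward_per_pump)
            except TrialValidationError as err:
                raise TrialValidationError(
                    f"row {row_number} (subject {row['subject_id']}): {err}"
                ) from err
            trials.append(trial)
        groups = {t.group for t in trials}
        if len(groups) != 1:
            raise TrialValidationError(
                f"subject {subject_id} carries multiple group labels: {sorted(groups)}"
            )
        datasets.append(
            SubjectDataset(subject_id=str(subject_id), group=trials[0].group, trials=trials)
        )
    return datasets


def _as_int(value, name: str) -> int:
    f = float(value)
    if not f.is_integer():
        raise TrialValidationError(f"{name} must be an integer, got {value!r}")
    return int(f)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise TrialValidationError(f"cannot parse boolean from {value!r}")


def write_trials(datasets: list[SubjectDataset], path) -> None:
    frame = trials_to_frame(datasets)
    frame = frame.assign(exploded=frame["exploded"].map({True: "true", False: "false"}))
    frame.to_csv(path, index=False)


def read_trials(path, reward_per_pump: float = 1.0) -> list[SubjectDataset]:
    frame = pd.read_csv(path, dtype={"subject_id": str, "group": str, "condition": str})
    return frame_to_datasets(frame, reward_per_pump=reward_per_pump)
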