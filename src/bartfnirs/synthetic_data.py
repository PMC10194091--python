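"""Synthetic cohorts: model-driven balloon-task sessions and prefrontal
HbO time series with a task-locked group amplitude difference.

The behavioral generator runs the cognitive models of :mod:`bartfnirs.models`
*forward*: subject parameters are drawn from group-level population
distributions, and each trial is played out pump-by-pump with the model's own
pump probabilities, so simulated data are exactly coherent with the fitted
likelihood.  Defaults emulate a case-control cohort of 19 patients and 32
controls performing 90 trials over three balloon colors, with the group
differences concentrated in the learning rate (eta) and inverse temperature
(tau).

The optical generator emits 8-channel oxygenated-hemoglobin series at 50 Hz:
a canonical-HRF response locked to each trial's pumping period, plus slow
drift, cardiac/respiratory/Mayer-wave oscillations, white noise, and sparse
motion artifacts (smooth spikes and step shifts), preceded by a 45 s rest
baseline.  A per-channel ``group_effect`` subtracts task amplitude for the
patient group only — by default at channel 4, emulating a localized
frontopolar/orbitofrontal activation deficit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import models as _m
from .bart_core import (
    CONTROL,
    PATIENT,
    SubjectDataset,
    TaskConfig,
    TrialRecord,
)
from .fnirs_glm import ChannelTimeSeries, hrf_convolve

__all__ = [
    "GroupSpec",
    "FnirsDesign",
    "default_group_specs",
    "recovery_group_specs",
    "simulate_subject",
    "simulate_cohort",
    "build_event_schedule",
    "simulate_fnirs",
]

# Group-level parameter locations on the natural scale.  eta and tau carry the
# case-control difference (patients learn slower and choose more randomly);
# phi is stated as the prior *burst* belief and converted to the model's
# not-burst convention; gamma/lam differences are small and non-separating.
_PATIENT_LOCS_EWMVM = {"phi": 1.0 - 0.044, "eta": 0.0016, "gamma": -0.010, "tau": 5.32, "lam": 2.32}
_CONTROL_LOCS_EWMVM = {"phi": 1.0 - 0.037, "eta": 0.049, "gamma": 0.004, "tau": 6.94, "lam": 2.807}

_PATIENT_LOCS_RFPM = {"phi": 1.0 - 0.044, "eta": 0.0016, "gamma": 0.40, "tau": 5.32}
_CONTROL_LOCS_RFPM = {"phi": 1.0 - 0.037, "eta": 0.049, "gamma": 0.45, "tau": 6.94}

# Population spread (SD on the unconstrained scale; see transforms below).
_DEFAULT_SCALES = {"phi": 0.3, "eta": 0.5, "gamma": 0.3, "tau": 0.2, "lam": 0.3}
_EWMVM_GAMMA_SCALE = 0.02  # identity scale: gamma is a small signed number


def _to_unconstrained(name: str, value: float, model: str) -> float:
    if name == "phi":
        return math.log(value / (1.0 - value))
    if name == "gamma" and model == _m.MODEL_EWMVM:
        return value
    return math.log(value)


def _to_natural(name: str, value: float, model: str) -> float:
    if name == "phi":
        return 1.0 / (1.0 + math.exp(-value))
    if name == "gamma" and model == _m.MODEL_EWMVM:
        return value
    return math.exp(value)


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution of one group's model parameters.

    ``locations`` are on the model's natural scale; ``scales`` are standard
    deviations on the unconstrained sampling scale (logit for phi, log for
    eta/tau/lam and RFPM gamma, identity for EWMVM gamma), so positivity and
    unit-interval bounds hold for every drawn subject.
    """

    label: str
    n_subjects: int
    locations: dict[str, float]
    scales: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if any(s < 0 for s in self.scales.values()):
            raise ValueError("scales must be >= 0")

    def draw_params(self, model: str, rng: np.random.Generator):
        names = _m.param_names(model)
        values = {}
        for name in names:
            loc = _to_unconstrained(name, self.locations[name], model)
            values[name] = _to_natural(
                name, loc + self.scales.get(name, 0.0) * rng.standard_normal(), model
            )
        if model == _m.MODEL_RFPM:
            return _m.RFPMParams(**values)
        return _m.EWMVMParams(**values)


def recovery_group_specs(
    model: str = _m.MODEL_EWMVM, n_per_group: int = 19
) -> list[GroupSpec]:
    """Cohort for eta/tau separation checks: the two groups differ *only* in
    learning rate and inverse temperature (set to the case/control reference
    values); phi, gamma and lam sit at common pooled locations, so any group
    signal found elsewhere is a false positive."""
    if model == _m.MODEL_EWMVM:
        pat_locs, ctl_locs = dict(_PATIENT_LOCS_EWMVM), dict(_CONTROL_LOCS_EWMVM)
    else:
        pat_locs, ctl_locs = dict(_PATIENT_LOCS_RFPM), dict(_CONTROL_LOCS_RFPM)
    for name in pat_locs:
        if name not in ("eta", "tau"):
            pooled = 0.5 * (pat_locs[name] + ctl_locs[name])
            pat_locs[name] = ctl_locs[name] = pooled
    scales = {n: _DEFAULT_SCALES[n] for n in _m.param_names(model)}
    if model == _m.MODEL_EWMVM:
        scales["gamma"] = _EWMVM_GAMMA_SCALE
    return [
        GroupSpec(PATIENT, n_per_group, pat_locs, dict(scales)),
        GroupSpec(CONTROL, n_per_group, ctl_locs, dict(scales)),
    ]


def default_group_specs(model: str = _m.MODEL_EWMVM) -> list[GroupSpec]:
    """The default case-control cohort: 19 patients, 32 controls, with the
    separating differences in eta and tau."""
    if model == _m.MODEL_EWMVM:
        pat_locs, ctl_locs = _PATIENT_LOCS_EWMVM, _CONTROL_LOCS_EWMVM
    else:
        pat_locs, ctl_locs = _PATIENT_LOCS_RFPM, _CONTROL_LOCS_RFPM
    scales = {n: _DEFAULT_SCALES[n] for n in _m.param_names(model)}
    if model == _m.MODEL_EWMVM:
        scales["gamma"] = _EWMVM_GAMMA_SCALE
    return [
        GroupSpec(PATIENT, 19, dict(pat_locs), dict(scales)),
        GroupSpec(CONTROL, 32, dict(ctl_locs), dict(scales)),
    ]


def _draw_explosion_point(cond_max: int, rule: str, rng: np.random.Generator) -> int:
    if rule == "uniform":
        return int(rng.integers(1, cond_max + 1))
    # constant per-pump hazard 1/max, capped at the balloon's limit
    point = 1 + int(rng.geometric(1.0 / cond_max))
    return min(point, cond_max)


def simulate_subject(
    params,
    config: TaskConfig,
    rng: np.random.Generator | int,
    subject_id: str = "s01",
    group: str = CONTROL,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
    include_practice: bool = False,
    n_practice: int = 8,
) -> SubjectDataset:
    """Play one full session forward under the given model parameters.

    Condition order is shuffled across the session.  Practice trials, when
    requested, are played (and update the belief) but never emitted into the
    analysis table, mirroring how a practice block shapes expectations
    without entering scoring or fitting.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    model = params.model

    labels = [c.label for c in config.conditions for _ in range(c.n_trials)]
    order = rng.permutation(len(labels))
    sequence = [labels[i] for i in order]
    if include_practice:
        practice = [labels[int(i)] for i in rng.integers(0, len(labels), n_practice)]
        sequence = practice + sequence
    n_skip = n_practice if include_practice else 0

    states: dict[str | None, _m.BeliefState] = {}
    trials: list[TrialRecord] = []
    for i, label in enumerate(sequence):
        cond = config.condition(label)
        key = label if dialects.per_condition_beliefs else None
        if key not in states:
            states[key] = _m.initial_belief(params, dialects)
        state = states[key]

        explosion_point = _draw_explosion_point(cond.max_pumps, config.explosion_rule, rng)
        n_pumps, exploded = _play_trial(
            state, params, cond.max_pumps, explosion_point,
            config.reward_per_pump, dialects, rng,
        )
        states[key] = _m.update_belief(
            _m.observe_trial(state, n_pumps, exploded), params, dialects
        )
        if i < n_skip:
            continue
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                group=group,
                trial_index=i - n_skip + 1,
                condition=label,
                max_pumps=cond.max_pumps,
                explosion_point=explosion_point,
                n_pumps=n_pumps,
                exploded=exploded,
            ).with_reward(config.reward_per_pump)
        )
    return SubjectDataset(subject_id=subject_id, group=group, trials=trials)


def _play_trial(
    state: _m.BeliefState,
    params,
    max_pumps: int,
    explosion_point: int,
    reward_per_pump: float,
    dialects: _m.ModelDialects,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """Sequential pump/stop decisions until stop, burst, or the pump cap."""
    if isinstance(params, _m.RFPMParams):
        v = _m.rfpm_optimal_pumps(state.p_burst, params, dialects, cap=max_pumps + 1.0)

    n = 0
    for l in range(1, max_pumps + 1):
        if isinstance(params, _m.RFPMParams):
            p_pump = _m.rfpm_pump_prob(l, v, params)
        else:
            U = _m.ewmvm_utility(l, state.p_burst, params, reward_per_pump, dialects)
            p_pump = _m.ewmvm_pump_prob(U, params)
        if rng.random() >= p_pump:
            return n, False  # chose to stop and cash out
        n = l
        if l == explosion_point:
            return n, True
    return n, False  # pump cap reached: forced cash-out


def simulate_cohort(
    groups: list[GroupSpec],
    model: str,
    config: TaskConfig,
    seed: int | np.random.SeedSequence,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
) -> tuple[list[SubjectDataset], pd.DataFrame]:
    """Simulate every subject of every group.

    Returns the datasets plus a *truth sidecar*: one row per subject with the
    drawn generating parameters, for parameter-recovery checks.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    datasets: list[SubjectDataset] = []
    truth_rows = []
    counter = 0
    for spec in groups:
        for _ in range(spec.n_subjects):
            counter += 1
            subject_id = f"{spec.label[:3]}{counter:03d}"
            params = spec.draw_params(model, rng)
            datasets.append(
                simulate_subject(
                    params, config, rng, subject_id=subject_id,
                    group=spec.label, dialects=dialects,
                )
            )
            row = {"subject_id": subject_id, "group": spec.label, "model": model}
            row.update({n: getattr(params, n) for n in _m.param_names(model)})
            truth_rows.append(row)
    return datasets, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Optical (HbO) generator


@dataclass(frozen=True)
class FnirsDesign:
    """Measurement model for the synthetic 8-channel HbO recordings.

    Amplitudes are in micromolar.  Trial timing: each pump decision occupies
    ``pump_duration_s``; feedback is 0.5 s; recovery is uniform on
    ``recovery_range_s``.  The 45 s pre-task rest is the implicit baseline of
    the downstream activation model.
    """

    n_channels: int = 8
    sampling_rate: float = 50.0
    task_amplitude: float = 0.5            # uM response to the pumping regressor
    drift_slope: float = 0.02              # uM per minute, linear drift
    cardiac_amp: float = 0.08              # ~1 Hz
    respiratory_amp: float = 0.05          # ~0.3 Hz
    mayer_amp: float = 0.06                # ~0.1 Hz
    noise_sd: float = 0.1                  # white noise, uM
    artifact_rate_per_min: float = 0.1     # spikes + step shifts combined
    spike_amplitude_sds: float = 5.0       # spike height in units of noise_sd
    rest_baseline_s: float = 45.0
    trailing_rest_s: float = 20.0
    pump_duration_s: float = 0.8
    feedback_s: float = 0.5
    recovery_range_s: tuple[float, float] = (1.0, 2.0)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")


DEFAULT_GROUP_EFFECT_CHANNEL = 4


def build_event_schedule(
    dataset: SubjectDataset,
    design: FnirsDesign,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pumping-period onsets/durations derived from the session's trials.

    Trials are laid out back-to-back after the rest baseline; events are
    guaranteed non-overlapping by construction.  Zero-pump trials still get a
    minimal decision period of one pump duration.
    """
    onset = design.rest_baseline_s
    rows = []
    for t in dataset.trials:
        duration = max(t.n_pumps, 1) * design.pump_duration_s
        rows.append({"onset_s": onset, "duration_s": duration, "label": "pumping"})
        lo, hi = design.recovery_range_s
        onset += duration + design.feedback_s + rng.uniform(lo, hi)
    return pd.DataFrame(rows)


def _validate_schedule(events: pd.DataFrame) -> None:
    ends = events["onset_s"].to_numpy() + events["duration_s"].to_numpy()
    starts = events["onset_s"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("event schedule has overlapping events")


def simulate_fnirs(
    design: FnirsDesign,
    datasets: list[SubjectDataset],
    group_effect: dict[int, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[ChannelTimeSeries]:
    """HbO series for every subject and channel.

    ``group_effect`` maps channel id -> amplitude reduction (uM) applied to
    the patient group only; the default injects a 0.25 uM deficit at channel
    4.  Pass ``{}`` for no group difference.
    """
    if group_effect is None:
        group_effect = {DEFAULT_GROUP_EFFECT_CHANNEL: 0.25}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    fs = design.sampling_rate

    out: list[ChannelTimeSeries] = []
    for d in datasets:
        events = build_event_schedule(d, design, rng)
        _validate_schedule(events)
        last_end = float(events.iloc[-1]["onset_s"] + events.iloc[-1]["duration_s"])
        duration = last_end + design.feedback_s + design.trailing_rest_s
        n = int(round(duration * fs))
        t = np.arange(n) / fs

        boxcar = np.zeros(n)
        for _, ev in events.iterrows():
            i0 = int(round(ev["onset_s"] * fs))
            i1 = min(int(round((ev["onset_s"] + ev["duration_s"]) * fs)), n)
            boxcar[i0:i1] = 1.0
        task_shape = hrf_convolve(boxcar, fs)

        for ch in range(1, design.n_channels + 1):
            amp = design.task_amplitude
            if d.group == PATIENT:
                amp -= group_effect.get(ch, 0.0)
            drift = design.drift_slope * (t / 60.0)
            osc = (
                design.cardiac_amp * np.sin(2 * np.pi * 1.0 * t + rng.uniform(0, 2 * np.pi))
                + design.respiratory_amp * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
                + design.mayer_amp * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
            )
            noise = design.noise_sd * rng.standard_normal(n)
            artifacts = _draw_artifacts(n, fs, design, rng)
            hbo = amp * task_shape + drift + osc + noise + artifacts
            out.append(
                ChannelTimeSeries(
                    subject_id=d.subject_id,
                    group=d.group,
                    channel=ch,
                    sampling_rate=fs,
                    values=hbo,
                    events=events.copy(),
                )
            )
    return out


def _draw_artifacts(
    n: int, fs: float, design: FnirsDesign, rng: np.random.Generator
) -> np.ndarray:
    """Sparse motion artifacts: smooth ~0.6 s spikes and baseline step shifts,
    each occurring at ``artifact_rate_per_min / 2``."""
    out = np.zeros(n)
    minutes = n / fs / 60.0
    n_spikes = rng.poisson(design.artifact_rate_per_min / 2.0 * minutes)
    n_steps = rng.poisson(design.artifact_rate_per_min / 2.0 * minutes)
    amp = design.spike_amplitude_sds * design.noise_sd
    for _ in range(n_spikes):
        center = rng.integers(0, n)
        width = 0.15 * fs  # gaussian sigma ~0.15 s -> ~0.6-0.9 s visible width
        i = np.arange(max(0, center - int(3 * width)), min(n, center + int(3 * width)))
        out[i] += amp * rng.choice([-1.0, 1.0]) * np.exp(-0.5 * ((i - center) / width) ** 2)
    for _ in range(n_steps):
        at = rng.integers(0, n)
        out[at:] += amp * rng.choice([-1.0, 1.0])
    return out
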