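"""Generative cognitive models of balloon-risk-task choices.

Two models of the pump/stop sequence are implemented as pure functions:

**RFPM** (re-parameterized four-parameter model) — the participant holds a
belief ``p_burst`` that the next pump bursts the balloon, updated after each
trial from the running counts of successful pumps and total pumps::

    p_burst = 1 - (phi + eta * cum_successes) / (1 + eta * cum_pumps)

chooses a target pump count ``v = gamma / (-ln(1 - p_burst))`` before the
trial, and pumps at opportunity ``l`` with logistic probability
``1 / (1 + exp(tau * (l - v)))``.

**EWMVM** (exponential-weight mean-variance model) — the belief is an
exponentially decaying blend of the prior and the observed burst frequency::

    w = 1 / (1 + eta * cum_pumps)
    p_burst = w * (1 - phi) + (1 - w) * P

and each pump opportunity is evaluated by a mean-variance utility with loss
aversion ``lam`` and risk preference ``gamma``; the pump probability is a
softmax of that utility with inverse temperature ``tau``.

Parameters
----------
phi : prior belief that a pump does **not** burst the balloon, in (0, 1).
eta : learning rate (> 0); 0 freezes the belief at its prior.
gamma : risk propensity; > 0 for RFPM, unbounded for EWMVM.
tau : inverse temperature (>= 0); 0 makes every pump/stop choice a coin flip.
lam : loss aversion (> 0, EWMVM only); weight on losing the accumulated stake.

Two printed variants of the target-pump rule and of the utility's loss weight
circulate in the literature; both are available through
:class:`ModelDialects` and the defaults are documented there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .bart_core import SubjectDataset, TrialRecord

__all__ = [
    "RFPMParams",
    "EWMVMParams",
    "BeliefState",
    "ModelDialects",
    "MODEL_RFPM",
    "MODEL_EWMVM",
    "param_names",
    "initial_belief",
    "observe_trial",
    "rfpm_update_belief",
    "rfpm_optimal_pumps",
    "rfpm_pump_prob",
    "ewmvm_update_belief",
    "ewmvm_utility",
    "ewmvm_pump_prob",
    "trial_loglik",
    "subject_loglik",
]

MODEL_RFPM = "RFPM"
MODEL_EWMVM = "EWMVM"

_P_CLAMP = 1e-12  # probabilities clamped to [1e-12, 1 - 1e-12] before logs


@dataclass(frozen=True)
class RFPMParams:
    phi: float
    eta: float
    gamma: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")
        if self.eta <= 0.0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.gamma < 0.0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.tau < 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    @property
    def model(self) -> str:
        return MODEL_RFPM


@dataclass(frozen=True)
class EWMVMParams:
    phi: float
    eta: float
    gamma: float  # unbounded risk preference (often labeled rho)
    tau: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")
        if self.eta <= 0.0:
            raise ValueError(f"eta must be > 0, got {self.eta}")
        if self.tau < 0.0:
            raise ValueError(f"tau must be >= 0, got {self.tau}")
        if self.lam <= 0.0:
            raise ValueError(f"lam must be > 0, got {self.lam}")

    @property
    def model(self) -> str:
        return MODEL_EWMVM


def param_names(model: str) -> list[str]:
    if model == MODEL_RFPM:
        return ["phi", "eta", "gamma", "tau"]
    if model == MODEL_EWMVM:
        return ["phi", "eta", "gamma", "tau", "lam"]
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class ModelDialects:
    """Resolved variants of the ambiguous printed formulas.

    optimal_pumps : {"inverse", "printed"}
        ``"inverse"`` (default): ``v = gamma / (-ln(1 - p_burst))`` — the
        canonical four-parameter rule; the target decreases as the balloon is
        believed riskier.  ``"printed"``: ``v = -gamma * ln(1 - p_burst)``,
        which *increases* with the burst belief and is kept only as an
        explicit fidelity variant.
    loss_weight : {"burst", "printed"}
        Weight on the accumulated-stake loss term of the utility.  The stake
        is lost when the balloon bursts, so the default weights the loss by
        ``p_burst``; ``"printed"`` uses ``1 - p_burst``.
    observed_rate : {"per_pump", "cumulative"}
        What the EWMVM belief blends toward.  ``"per_pump"`` (default):
        explosions per *pump* experienced so far — dimensionally consistent
        with ``p_burst`` (a per-pump hazard) and the variant that produces
        session statistics in the empirically observed range.
        ``"cumulative"``: explosions per *trial*, kept as a variant; it
        overstates the hazard roughly by the mean pump count and drives
        simulated agents to near-immediate stopping.
    per_condition_beliefs : bool
        Thread a separate belief state per balloon color instead of one
        shared state (default shared: one parameter set is fitted per
        subject, not per condition).
    """

    optimal_pumps: str = "inverse"
    loss_weight: str = "burst"
    observed_rate: str = "per_pump"
    per_condition_beliefs: bool = False

    def __post_init__(self) -> None:
        if self.optimal_pumps not in ("inverse", "printed"):
            raise ValueError(f"unknown optimal_pumps dialect {self.optimal_pumps!r}")
        if self.loss_weight not in ("burst", "printed"):
            raise ValueError(f"unknown loss_weight dialect {self.loss_weight!r}")
        if self.observed_rate not in ("cumulative", "per_pump"):
            raise ValueError(f"unknown observed_rate dialect {self.observed_rate!r}")


DEFAULT_DIALECTS = ModelDialects()


@dataclass(frozen=True)
class BeliefState:
    """Running belief about the burst hazard plus the counts feeding it."""

    p_burst: float
    cum_pumps: int = 0
    cum_successes: int = 0
    cum_explosions: int = 0
    n_trials_seen: int = 0

    def observed_burst_rate(self, dialects: ModelDialects, phi: float) -> float:
        """Burst frequency observed so far; the prior ``1 - phi`` before any
        trial has completed."""
        if dialects.observed_rate == "per_pump":
            if self.cum_pumps == 0:
                return 1.0 - phi
            return self.cum_explosions / self.cum_pumps
        if self.n_trials_seen == 0:
            return 1.0 - phi
        return self.cum_explosions / self.n_trials_seen


def _clamp_prob(p: float) -> float:
    return min(max(p, _P_CLAMP), 1.0 - _P_CLAMP)


def initial_belief(params, dialects: ModelDialects = DEFAULT_DIALECTS) -> BeliefState:
    """Belief before the first trial: ``p_burst = 1 - phi`` for both models."""
    state = BeliefState(p_burst=_clamp_prob(1.0 - params.phi))
    return state


def observe_trial(state: BeliefState, n_pumps: int, exploded: bool) -> BeliefState:
    """Fold one completed trial into the counts (p_burst left stale; call the
    model's update to refresh it)."""
    return replace(
        state,
        cum_pumps=state.cum_pumps + n_pumps,
        cum_successes=state.cum_successes + (n_pumps - 1 if exploded else n_pumps),
        cum_explosions=state.cum_explosions + int(exploded),
        n_trials_seen=state.n_trials_seen + 1,
    )


def rfpm_update_belief(state: BeliefState, params: RFPMParams) -> BeliefState:
    p = 1.0 - (params.phi + params.eta * state.cum_successes) / (
        1.0 + params.eta * state.cum_pumps
    )
    return replace(state, p_burst=_clamp_prob(p))


def ewmvm_update_belief(
    state: BeliefState,
    params: EWMVMParams,
    dialects: ModelDialects = DEFAULT_DIALECTS,
) -> BeliefState:
    w = 1.0 / (1.0 + params.eta * state.cum_pumps)
    rate = state.observed_burst_rate(dialects, params.phi)
    p = w * (1.0 - params.phi) + (1.0 - w) * rate
    return replace(state, p_burst=_clamp_prob(p))


def update_belief(state, params, dialects: ModelDialects = DEFAULT_DIALECTS):
    if isinstance(params, RFPMParams):
        return rfpm_update_belief(state, params)
    return ewmvm_update_belief(state, params, dialects)


def rfpm_optimal_pumps(
    p_burst: float,
    params: RFPMParams,
    dialects: ModelDialects = DEFAULT_DIALECTS,
    cap: float | None = None,
) -> float:
    """Target pump count chosen before the trial.

    When ``p_burst`` underflows the default rule diverges; ``cap`` (typically
    ``max_pumps + 1``) keeps the downstream logistic finite.
    """
    p = _clamp_prob(p_burst)
    hazard = -math.log1p(-p)
    if dialects.optimal_pumps == "printed":
        v = params.gamma * hazard
    else:
        v = params.gamma / hazard
    if cap is not None:
        v = min(v, cap)
    return v


def rfpm_pump_prob(l: float, v: float, params: RFPMParams) -> float:
    """Logistic pump probability at opportunity ``l``: 0.5 at ``l == v``,
    non-increasing in ``l``."""
    return _sigmoid(-params.tau * (l - v))


def ewmvm_utility(
    l: float,
    p_burst: float,
    params: EWMVMParams,
    reward_per_pump: float = 1.0,
    dialects: ModelDialects = DEFAULT_DIALECTS,
) -> float:
    """Mean-variance utility of pump ``l``: expected gain, minus the
    loss-averse expected loss of the ``(l-1)r`` stake, plus a
    ``gamma``-weighted variance bonus/penalty."""
    p = _clamp_prob(p_burst)
    r = reward_per_pump
    stake = (l - 1.0) * r
    loss_w = (1.0 - p) if dialects.loss_weight == "printed" else p
    gain = (1.0 - p) * r
    loss = loss_w * params.lam * stake
    variance = p * (1.0 - p) * (r + params.lam * stake) ** 2
    return gain - loss + params.gamma * variance


def ewmvm_pump_prob(U: float, params: EWMVMParams) -> float:
    """Softmax of the pump utility against the stop option (utility 0)."""
    return _sigmoid(params.tau * U)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _log_sigmoid(x: float) -> float:
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


def _pump_logprobs(
    trial_max_pumps: int,
    n_terms: int,
    state: BeliefState,
    params,
    reward_per_pump: float,
    dialects: ModelDialects,
) -> np.ndarray:
    """log pump probability at opportunities 1..n_terms given the pre-trial
    belief."""
    out = np.empty(n_terms)
    if isinstance(params, RFPMParams):
        v = rfpm_optimal_pumps(
            state.p_burst, params, dialects, cap=trial_max_pumps + 1.0
        )
        for i in range(n_terms):
            out[i] = _log_sigmoid(-params.tau * ((i + 1) - v))
    else:
        for i in range(n_terms):
            U = ewmvm_utility(i + 1.0, state.p_burst, params, reward_per_pump, dialects)
            out[i] = _log_sigmoid(params.tau * U)
    # clamp: pump probabilities treated as lying in [1e-12, 1 - 1e-12]
    np.clip(out, math.log(_P_CLAMP), math.log1p(-_P_CLAMP), out=out)
    return out


def trial_loglik(
    trial: TrialRecord,
    state: BeliefState,
    params,
    reward_per_pump: float = 1.0,
    dialects: ModelDialects = DEFAULT_DIALECTS,
) -> float:
    """Log-likelihood of one trial's pump/stop sequence.

    A cashed-out trial with ``n`` pumps contributes the ``n`` pump decisions
    plus the stop decision at opportunity ``n + 1``.  A burst trial
    contributes only the ``n`` pump decisions — the burst censors the stop
    choice — and so does a cash-out forced by the pump cap.
    """
    n = trial.n_pumps
    has_stop = (not trial.exploded) and n < trial.max_pumps
    logs = _pump_logprobs(
        trial.max_pumps, n + (1 if has_stop else 0), state, params,
        reward_per_pump, dialects,
    )
    ll = float(np.sum(logs[:n]))
    if has_stop:
        # log(1 - p) for the stop decision, from log p stably
        lp = logs[n]
        ll += math.log(-math.expm1(lp)) if lp > -36.0 else 0.0
    return ll


def subject_loglik(
    dataset: SubjectDataset,
    params,
    reward_per_pump: float = 1.0,
    dialects: ModelDialects = DEFAULT_DIALECTS,
) -> tuple[float, np.ndarray]:
    """Session log-likelihood and the per-trial vector (for LOO).

    The belief state is threaded across trials in ``trial_index`` order,
    shared across balloon colors unless ``dialects.per_condition_beliefs``.
    """
    idx = [t.trial_index for t in dataset.trials]
    if any(b <= a for a, b in zip(idx, idx[1:])):
        raise ValueError("trials must be ordered by trial_index")

    per_trial = np.empty(len(dataset.trials))
    states: dict[str | None, BeliefState] = {}

    def key(t: TrialRecord):
        return t.condition if dialects.per_condition_beliefs else None

    for i, trial in enumerate(dataset.trials):
        k = key(trial)
        if k not in states:
            states[k] = initial_belief(params, dialects)
        state = states[k]
        per_trial[i] = trial_loglik(trial, state, params, reward_per_pump, dialects)
        states[k] = update_belief(
            observe_trial(state, trial.n_pumps, trial.exploded), params, dialects
        )
    return float(per_trial.sum()), per_trial
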