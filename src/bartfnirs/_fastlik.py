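"""Numba-compiled trial-sequence likelihoods for the MCMC hot loop.

Cohort data are packed once into flat arrays (`pack_cohort`); the jitted
kernels then evaluate the full-cohort log-likelihood (and optionally the
per-trial vector) for one parameter matrix in tens of microseconds.  The
readable reference implementation lives in :mod:`bartfnirs.models`; the test
suite asserts the two agree to double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import models as _m
from .bart_core import SubjectDataset

__all__ = ["PackedCohort", "pack_cohort", "cohort_loglik", "cohort_pointwise"]

_LOG_LO = np.log(1e-12)
_LOG_HI = np.log1p(-1e-12)


@dataclass(frozen=True)
class PackedCohort:
    """Flat trial arrays for a cohort, subject boundaries in ``offsets``."""

    n_pumps: np.ndarray      # int64[n_trials_total]
    exploded: np.ndarray     # uint8 [n_trials_total]
    max_pumps: np.ndarray    # int64[n_trials_total]
    offsets: np.ndarray      # int64[n_subjects + 1]
    subject_ids: tuple[str, ...]
    groups: tuple[str, ...]
    reward_per_pump: float

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_trials(self) -> int:
        return int(self.offsets[-1])


def pack_cohort(
    datasets: list[SubjectDataset], reward_per_pump: float = 1.0
) -> PackedCohort:
    n_pumps, exploded, max_pumps, offsets = [], [], [], [0]
    for d in datasets:
        for t in d.trials:
            n_pumps.append(t.n_pumps)
            exploded.append(int(t.exploded))
            max_pumps.append(t.max_pumps)
        offsets.append(len(n_pumps))
    return PackedCohort(
        n_pumps=np.asarray(n_pumps, dtype=np.int64),
        exploded=np.asarray(exploded, dtype=np.uint8),
        max_pumps=np.asarray(max_pumps, dtype=np.int64),
        offsets=np.asarray(offsets, dtype=np.int64),
        subject_ids=tuple(d.subject_id for d in datasets),
        groups=tuple(d.group for d in datasets),
        reward_per_pump=float(reward_per_pump),
    )


def dialect_codes(dialects: _m.ModelDialects) -> tuple[int, int, int]:
    if dialects.per_condition_beliefs:
        raise NotImplementedError(
            "per-condition belief threading is available in the reference "
            "implementation (bartfnirs.models) but not in the compiled path "
            "used for estimation"
        )
    return (
        0 if dialects.optimal_pumps == "inverse" else 1,
        0 if dialects.loss_weight == "burst" else 1,
        0 if dialects.observed_rate == "cumulative" else 1,
    )


@njit(cache=True, inline="always")
def _log_sigmoid(x):
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True, inline="always")
def _clamp_log(x):
    if x < _LOG_LO:
        return _LOG_LO
    if x > _LOG_HI:
        return _LOG_HI
    return x


@njit(cache=True, inline="always")
def _clamp_prob(p):
    if p < 1e-12:
        return 1e-12
    if p > 1.0 - 1e-12:
        return 1.0 - 1e-12
    return p


@njit(cache=True)
def _subject_rfpm(n_pumps, exploded, max_pumps, phi, eta, gamma, tau,
                  opt_dialect, pointwise, base):
    cum_pumps = 0.0
    cum_succ = 0.0
    total = 0.0
    for k in range(n_pumps.shape[0]):
        p_burst = 1.0 - (phi + eta * cum_succ) / (1.0 + eta * cum_pumps)
        p_burst = _clamp_prob(p_burst)
        hazard = -np.log1p(-p_burst)
        if opt_dialect == 1:
            v = gamma * hazard
        else:
            v = gamma / hazard
        cap = max_pumps[k] + 1.0
        if v > cap:
            v = cap
        n = n_pumps[k]
        ll = 0.0
        for l in range(1, n + 1):
            ll += _clamp_log(_log_sigmoid(-tau * (l - v)))
        if exploded[k] == 0 and n < max_pumps[k]:
            lp = _clamp_log(_log_sigmoid(-tau * ((n + 1) - v)))
            ll += np.log(-np.expm1(lp))
        pointwise[base + k] = ll
        total += ll
        cum_pumps += n
        cum_succ += n - 1 if exploded[k] == 1 else n
    return total


@njit(cache=True)
def _subject_ewmvm(n_pumps, exploded, max_pumps, phi, eta, gamma, tau, lam, r,
                   loss_dialect, rate_dialect, pointwise, base):
    cum_pumps = 0.0
    cum_expl = 0.0
    n_seen = 0.0
    total = 0.0
    for k in range(n_pumps.shape[0]):
        w = 1.0 / (1.0 + eta * cum_pumps)
        if rate_dialect == 1:
            rate = (1.0 - phi) if cum_pumps == 0.0 else cum_expl / cum_pumps
        else:
            rate = (1.0 - phi) if n_seen == 0.0 else cum_expl / n_seen
        p = w * (1.0 - phi) + (1.0 - w) * rate
        p = _clamp_prob(p)
        loss_w = (1.0 - p) if loss_dialect == 1 else p
        n = n_pumps[k]
        ll = 0.0
        n_terms = n + 1 if (exploded[k] == 0 and n < max_pumps[k]) else n
        for l in range(1, n_terms + 1):
            stake = (l - 1.0) * r
            U = (1.0 - p) * r - loss_w * lam * stake \
                + gamma * p * (1.0 - p) * (r + lam * stake) ** 2
            lp = _clamp_log(_log_sigmoid(tau * U))
            if l <= n:
                ll += lp
            else:
                ll += np.log(-np.expm1(lp))
        pointwise[base + k] = ll
        total += ll
        cum_pumps += n
        cum_expl += 1.0 if exploded[k] == 1 else 0.0
        n_seen += 1.0
    return total


@njit(cache=True)
def _cohort_kernel(n_pumps, exploded, max_pumps, offsets, theta, is_ewmvm, r,
                   opt_dialect, loss_dialect, rate_dialect, pointwise):
    total = 0.0
    for s in range(offsets.shape[0] - 1):
        a, b = offsets[s], offsets[s + 1]
        if is_ewmvm:
            total += _subject_ewmvm(
                n_pumps[a:b], exploded[a:b], max_pumps[a:b],
                theta[s, 0], theta[s, 1], theta[s, 2], theta[s, 3], theta[s, 4],
                r, loss_dialect, rate_dialect, pointwise, a)
        else:
            total += _subject_rfpm(
                n_pumps[a:b], exploded[a:b], max_pumps[a:b],
                theta[s, 0], theta[s, 1], theta[s, 2], theta[s, 3],
                opt_dialect, pointwise, a)
    return total


def cohort_pointwise(
    packed: PackedCohort,
    theta: np.ndarray,
    model: str,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood for subject-parameter matrix
    ``theta`` (n_subjects x n_params, natural scale)."""
    opt_d, loss_d, rate_d = dialect_codes(dialects)
    pointwise = np.empty(packed.n_trials)
    total = _cohort_kernel(
        packed.n_pumps, packed.exploded, packed.max_pumps, packed.offsets,
        np.ascontiguousarray(theta, dtype=np.float64),
        model == _m.MODEL_EWMVM, packed.reward_per_pump,
        opt_d, loss_d, rate_d, pointwise,
    )
    return float(total), pointwise


def cohort_loglik(
    packed: PackedCohort,
    theta: np.ndarray,
    model: str,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
) -> float:
    return cohort_pointwise(packed, theta, model, dialects)[0]


@njit(cache=True)
def _cohort_kernel_batch(n_pumps, exploded, max_pumps, offsets, thetas, is_ewmvm,
                         r, opt_dialect, loss_dialect, rate_dialect, scratch, out):
    for w in range(thetas.shape[0]):
        out[w] = _cohort_kernel(
            n_pumps, exploded, max_pumps, offsets, thetas[w], is_ewmvm, r,
            opt_dialect, loss_dialect, rate_dialect, scratch,
        )


def cohort_loglik_batch(
    packed: PackedCohort,
    thetas: np.ndarray,
    model: str,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
) -> np.ndarray:
    """Total log-likelihood for a batch of subject-parameter matrices,
    shape (n_walkers, n_subjects, n_params) -> (n_walkers,).  One compiled
    call for the whole ensemble keeps the MCMC hot loop out of Python."""
    opt_d, loss_d, rate_d = dialect_codes(dialects)
    thetas = np.ascontiguousarray(thetas, dtype=np.float64)
    out = np.empty(thetas.shape[0])
    scratch = np.empty(packed.n_trials)
    _cohort_kernel_batch(
        packed.n_pumps, packed.exploded, packed.max_pumps, packed.offsets,
        thetas, model == _m.MODEL_EWMVM, packed.reward_per_pump,
        opt_d, loss_d, rate_d, scratch, out,
    )
    return out
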