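"""Independent oracles used by the test suite.

Everything here is deliberately naive — explicit loops, brute-force
enumeration, textbook formulas — and shares no code path with the package
implementation it checks.
"""

import math

import numpy as np

from bartfnirs import models as m
from conftest import make_trial


def pump_probability(l, state, params, r=1.0, dialects=m.DEFAULT_DIALECTS, max_pumps=8):
    """Per-pump probability straight from the model definitions."""
    if isinstance(params, m.RFPMParams):
        p = state.p_burst
        hazard = -math.log(1.0 - p)
        v = params.gamma * hazard if dialects.optimal_pumps == "printed" else params.gamma / hazard
        v = min(v, max_pumps + 1.0)
        return 1.0 / (1.0 + math.exp(min(params.tau * (l - v), 700.0)))
    p = state.p_burst
    stake = (l - 1.0) * r
    loss_w = (1.0 - p) if dialects.loss_weight == "printed" else p
    U = (1.0 - p) * r - loss_w * params.lam * stake + params.gamma * p * (1.0 - p) * (r + params.lam * stake) ** 2
    return 1.0 / (1.0 + math.exp(min(-params.tau * U, 700.0)))


def enumerate_outcomes(params, max_pumps, state=None, r=1.0, dialects=m.DEFAULT_DIALECTS):
    """All (n_pumps, exploded) outcomes of one uniform-explosion-point trial,
    with their joint probabilities and the choice-only probabilities.

    Returns a list of (n_pumps, exploded, p_choice, p_joint).
    """
    if state is None:
        state = m.initial_belief(params, dialects)
    M = max_pumps
    probs = [pump_probability(l, state, params, r, dialects, M) for l in range(1, M + 1)]
    out = []
    # cash out after n pumps by choice (needs explosion_point > n)
    for n in range(0, M):
        p_choice = 1.0
        for l in range(n):
            p_choice *= probs[l]
        p_choice *= 1.0 - probs[n]
        out.append((n, False, p_choice, p_choice * (M - n) / M))
    # burst at pump e (explosion_point == e and the agent pumped e times)
    for e in range(1, M + 1):
        p_choice = 1.0
        for l in range(e):
            p_choice *= probs[l]
        out.append((e, True, p_choice, p_choice / M))
    return out


def straight_line_subject_loglik(dataset, params, r=1.0, dialects=m.DEFAULT_DIALECTS):
    """Walk the trials with explicit loops, recomputing the belief by hand."""
    total = 0.0
    cum_pumps = cum_succ = cum_expl = n_seen = 0
    for trial in dataset.trials:
        # pre-trial belief
        if isinstance(params, m.RFPMParams):
            p = 1.0 - (params.phi + params.eta * cum_succ) / (1.0 + params.eta * cum_pumps)
        else:
            w = 1.0 / (1.0 + params.eta * cum_pumps)
            if dialects.observed_rate == "per_pump":
                rate = (1.0 - params.phi) if cum_pumps == 0 else cum_expl / cum_pumps
            else:
                rate = (1.0 - params.phi) if n_seen == 0 else cum_expl / n_seen
            p = w * (1.0 - params.phi) + (1.0 - w) * rate
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        state = m.BeliefState(p_burst=p)
        n = trial.n_pumps
        for l in range(1, n + 1):
            total += math.log(
                pump_probability(l, state, params, r, dialects, trial.max_pumps)
            )
        if not trial.exploded and n < trial.max_pumps:
            total += math.log(
                1.0 - pump_probability(n + 1, state, params, r, dialects, trial.max_pumps)
            )
        cum_pumps += n
        cum_succ += n - 1 if trial.exploded else n
        cum_expl += int(trial.exploded)
        n_seen += 1
    return total


def is_loo_naive(matrix):
    """From-scratch importance-sampling LOO on a (draws, trials) matrix.

    The leave-one-out predictive density of trial i is the self-normalized
    importance estimate with ratios 1/p_i — algebraically the harmonic mean
    of the likelihood draws.  With a handful of draws no tail smoothing is
    applicable, so this is the exact reference for small matrices and a
    close one (identical up to tail smoothing) for well-behaved weights.
    Returns LOOIC = -2 * elpd.
    """
    S, N = matrix.shape
    elpd = 0.0
    for i in range(N):
        ll = matrix[:, i]
        # log of harmonic mean: -log(mean(exp(-ll))), stabilized
        c = ll.min()
        elpd += c - math.log(np.mean(np.exp(-(ll - c))))
    return -2.0 * elpd


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted q-values by the textbook step-up rule."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * n / rank_from_top, prev)
        q[i] = val
        prev = val
    return q
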