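"""Hierarchical Bayesian estimation, convergence diagnostics, and
leave-one-out model comparison.

Model structure
---------------
Each subject's cognitive parameters are sampled on an unconstrained scale
(logit for phi; log for eta, tau, lam and the RFPM gamma; identity for the
signed EWMVM gamma) with a non-centered hierarchy::

    theta_sj = transform_j(mu_j + sigma_j * z_sj),   z_sj ~ N(0, 1)
    mu_j ~ N(0, mean_scale),   sigma_j ~ HalfNormal(sigma_scale)

so subject estimates shrink toward the group mean with a data-driven amount
of pooling.  The joint posterior is sampled with an affine-invariant
ensemble sampler (emcee) over numba-compiled likelihoods: each of the
``n_chains`` chains is an independent, MAP-initialised ensemble, giving the
between-chain variance that R-hat needs.  Split R-hat and effective sample
sizes come from arviz; any quantity with R-hat above 1.05 attaches a
convergence warning to the fit.

Model comparison uses Pareto-smoothed importance-sampling leave-one-out
cross-validation on the per-trial pointwise log-likelihood matrix
(``LOOIC = -2 * elpd_loo``) and Akaike-style weights
``w_i = exp(-0.5 * (LOOIC_i - LOOIC_min)) / sum(...)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize, special

from . import models as _m
from ._fastlik import (
    PackedCohort,
    cohort_loglik,
    cohort_loglik_batch,
    cohort_pointwise,
    pack_cohort,
)
from .bart_core import SubjectDataset

__all__ = [
    "SamplerConfig",
    "PriorConfig",
    "PosteriorFit",
    "FitComparison",
    "LooResult",
    "fit_hierarchical",
    "pointwise_loglik",
    "loo_ic",
    "akaike_weights",
    "subject_estimates",
    "compare_fits",
]

RHAT_LIMIT = 1.05
PARETO_K_LIMIT = 0.7


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``n_draws`` is the total number of retained posterior draws across all
    chains (default 4000 = 4 chains x 1000).  ``warmup`` counts discarded
    ensemble moves per chain; ``sample_steps`` ensemble moves are kept and
    thinned down to ``n_draws / n_chains`` draws per chain.
    ``target_accept`` is accepted for interface compatibility with
    gradient-based samplers; the ensemble sampler has no direct analogue and
    ignores it.
    """

    n_chains: int = 4
    n_draws: int = 4000
    warmup: int = 1000
    sample_steps: int = 60
    seed: int = 0
    target_accept: float = 0.8
    walkers_per_dim: float = 2.2

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.n_draws < self.n_chains:
            raise ValueError("n_draws must cover all chains")


@dataclass(frozen=True)
class PriorConfig:
    """Hyperpriors on the unconstrained scale.

    ``mean_scale`` is deliberately wide (5): plausible group values span
    several log-units (e.g. learning rates from ~1e-3 to ~0.1), and a tight
    prior on the group mean would bias extreme but realistic values.
    """

    mean_scale: float = 5.0
    sigma_scale: float = 1.0


def _transforms(model: str) -> list[str]:
    # one of: "logit", "log", "identity" per parameter
    if model == _m.MODEL_RFPM:
        return ["logit", "log", "log", "log"]
    return ["logit", "log", "identity", "log", "log"]


def _to_natural_matrix(u: np.ndarray, transforms: list[str]) -> np.ndarray:
    out = np.empty_like(u)
    for j, tr in enumerate(transforms):
        col = u[..., j]
        if tr == "logit":
            out[..., j] = special.expit(col)
        elif tr == "log":
            out[..., j] = np.exp(np.clip(col, -30.0, 30.0))
        else:
            out[..., j] = col
    return out


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one model on one cohort."""

    model: str
    param_names: list[str]
    subject_ids: list[str]
    groups: list[str]
    theta: np.ndarray  # (chains, draws, ndim) unconstrained sampler coordinates
    transforms: list[str]
    reward_per_pump: float
    dialects: _m.ModelDialects
    rhat: pd.Series = field(repr=False, default=None)
    ess: pd.Series = field(repr=False, default=None)
    converged: bool = True
    warnings_: list[str] = field(default_factory=list)

    # --- layout: [mu_j (J), log_sigma_j (J), z_sj (S*J)] -------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def _unpack(self, theta: np.ndarray):
        J, S = self.n_params, self.n_subjects
        mu = theta[..., :J]
        log_sigma = theta[..., J : 2 * J]
        z = theta[..., 2 * J :].reshape(*theta.shape[:-1], S, J)
        return mu, log_sigma, z

    def subject_draws(self) -> np.ndarray:
        """Natural-scale subject parameters, shape (chains, draws, S, J)."""
        mu, log_sigma, z = self._unpack(self.theta)
        u = mu[..., None, :] + np.exp(log_sigma)[..., None, :] * z
        return _to_natural_matrix(u, self.transforms)

    def group_location_draws(self) -> np.ndarray:
        """Natural-scale transform of the group mean, shape (chains, draws, J)
        (the population median for log/logit parameters)."""
        mu, _, _ = self._unpack(self.theta)
        return _to_natural_matrix(mu, self.transforms)

    def group_location_summary(self) -> pd.DataFrame:
        draws = self.group_location_draws().reshape(-1, self.n_params)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0),
                "hdi_2.5": lo,
                "hdi_97.5": hi,
            }
        )


def _log_posterior_factory(
    packed: PackedCohort,
    model: str,
    transforms: list[str],
    priors: PriorConfig,
    dialects: _m.ModelDialects,
):
    J = len(transforms)
    S = packed.n_subjects
    mean_var = priors.mean_scale**2
    sig_scale2 = priors.sigma_scale**2

    def log_post_batch(theta: np.ndarray) -> np.ndarray:
        """Vectorized over walkers: theta is (n_walkers, ndim)."""
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        mu = theta[:, :J]
        log_sigma = theta[:, J : 2 * J]
        bad = (np.abs(log_sigma) > 10.0).any(axis=1) | (np.abs(mu) > 60.0).any(axis=1)
        sigma = np.exp(np.clip(log_sigma, -10.0, 10.0))
        z = theta[:, 2 * J :].reshape(W, S, J)
        u = mu[:, None, :] + sigma[:, None, :] * z
        nat = _to_natural_matrix(u, transforms)
        ll = cohort_loglik_batch(packed, nat, model, dialects)
        lp = (
            -0.5 * np.sum(mu**2, axis=1) / mean_var
            - 0.5 * np.sum(sigma**2, axis=1) / sig_scale2
            + np.sum(log_sigma, axis=1)  # half-normal Jacobian, sigma = exp(log_sigma)
            - 0.5 * np.sum(z**2, axis=(1, 2))
        )
        out = ll + lp
        out[bad | ~np.isfinite(out)] = -np.inf
        return out

    return log_post_batch


def fit_hierarchical(
    datasets: list[SubjectDataset],
    model: str,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    reward_per_pump: float = 1.0,
    dialects: _m.ModelDialects = _m.DEFAULT_DIALECTS,
) -> PosteriorFit:
    """Joint posterior over group-level and subject-level parameters.

    Runs ``n_chains`` independent MAP-initialised ensembles; retains
    ``n_draws`` total draws; attaches convergence warnings whenever any
    split R-hat exceeds 1.05.
    """
    if len(datasets) < 2:
        raise ValueError("hierarchical estimation needs >= 2 subjects")
    if any(len(d.trials) == 0 for d in datasets):
        raise ValueError("every subject needs >= 1 trial")
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    names = _m.param_names(model)
    transforms = _transforms(model)
    packed = pack_cohort(datasets, reward_per_pump)

    J, S = len(names), packed.n_subjects
    ndim = J * (2 + S)
    log_post = _log_posterior_factory(packed, model, transforms, priors, dialects)

    ss = np.random.SeedSequence(sampler.seed)
    map_rng = np.random.default_rng(ss.spawn(1)[0])
    x_map = _stagewise_init(
        datasets, model, transforms, reward_per_pump, dialects, log_post, map_rng
    )

    nwalkers = int(np.ceil(sampler.walkers_per_dim * ndim / 2) * 2)
    nwalkers = max(nwalkers, 2 * ndim + 2)
    draws_per_chain = sampler.n_draws // sampler.n_chains

    chains = []
    for chain_ss in ss.spawn(sampler.n_chains):
        rng = np.random.default_rng(chain_ss)
        p0 = x_map[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))
        es = emcee.EnsembleSampler(
            nwalkers, ndim, log_post, vectorize=True,
            # differential-evolution moves mix far better than the default
            # stretch move in these high-dimensional, ridge-shaped posteriors
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        # the setter silently drops anything but a legacy state tuple
        es.random_state = np.random.RandomState(int(rng.integers(2**31 - 1))).get_state()
        state = es.run_mcmc(p0, sampler.warmup, progress=False)
        es.reset()
        es.run_mcmc(state, sampler.sample_steps, progress=False)
        flat = es.get_chain(flat=True)  # (steps * walkers, ndim)
        idx = np.linspace(0, len(flat) - 1, draws_per_chain).astype(int)
        chains.append(flat[idx])
    theta = np.stack(chains)  # (chains, draws, ndim)

    fit = PosteriorFit(
        model=model,
        param_names=names,
        subject_ids=list(packed.subject_ids),
        groups=list(packed.groups),
        theta=theta,
        transforms=transforms,
        reward_per_pump=reward_per_pump,
        dialects=dialects,
    )
    _attach_diagnostics(fit)
    return fit


def _stagewise_init(
    datasets: list[SubjectDataset],
    model: str,
    transforms: list[str],
    reward_per_pump: float,
    dialects: _m.ModelDialects,
    log_post,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walker initialisation in two stages.

    The joint posterior has weakly identified ridges (e.g. loss aversion
    trades off against the burst prior when the believed hazard is small), so
    a single optimisation from a neutral point routinely stalls in a spurious
    local mode.  Instead: (1) each subject is fitted independently by
    penalised maximum likelihood from a few multistarts; (2) the hierarchy is
    assembled from the moments of those per-subject estimates and polished by
    a short joint L-BFGS.  Only an initial point — correctness does not
    depend on it, mixing speed does.
    """
    J = len(transforms)
    starts = [np.zeros(J), _typical_start(model)]
    u_subj = np.empty((len(datasets), J))
    for s, d in enumerate(datasets):
        packed_s = pack_cohort([d], reward_per_pump)

        def neg_ll(u: np.ndarray) -> float:
            nat = _to_natural_matrix(u[None, :], transforms)
            ll = cohort_loglik(packed_s, nat, model, dialects)
            return -ll + 0.02 * float(u @ u)  # weak pull toward the origin

        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg_ll, x0 + 0.01 * rng.standard_normal(J),
                method="L-BFGS-B", options={"maxiter": 100},
            )
            if best is None or res.fun < best.fun:
                best = res
        u_subj[s] = best.x

    mu = u_subj.mean(axis=0)
    sigma = np.clip(u_subj.std(axis=0), 0.05, 2.0)
    z = (u_subj - mu) / sigma
    x0 = np.concatenate([mu, np.log(sigma), z.ravel()])
    res = optimize.minimize(
        lambda x: -float(log_post(x)[0]), x0, method="L-BFGS-B",
        options={"maxiter": 100, "maxfun": 30_000},
    )
    return res.x if np.isfinite(res.fun) else x0


def _typical_start(model: str) -> np.ndarray:
    """A behaviorally plausible unconstrained start: burst prior ~0.1,
    slow-ish learning, moderate determinism."""
    if model == _m.MODEL_RFPM:
        return np.array([2.0, -4.0, 1.0, 1.5])  # phi .88, eta .018, gamma e, tau 4.5
    return np.array([2.0, -4.0, 0.0, 1.5, 0.5])  # ... gamma 0, tau 4.5, lam 1.6


def _attach_diagnostics(fit: PosteriorFit) -> None:
    ds = az.convert_to_dataset(fit.theta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(ds)["x"].to_numpy().ravel()
        ess = az.ess(ds)["x"].to_numpy().ravel()
    labels = _coordinate_labels(fit)
    fit.rhat = pd.Series(rhat, index=labels)
    fit.ess = pd.Series(ess, index=labels)
    bad = fit.rhat[fit.rhat > RHAT_LIMIT]
    if len(bad):
        fit.converged = False
        fit.warnings_.append(
            f"{len(bad)}/{len(fit.rhat)} quantities have split R-hat > {RHAT_LIMIT} "
            f"(worst {bad.max():.3f} at {bad.idxmax()})"
        )


def _coordinate_labels(fit: PosteriorFit) -> list[str]:
    labels = [f"mu[{p}]" for p in fit.param_names]
    labels += [f"log_sigma[{p}]" for p in fit.param_names]
    labels += [
        f"z[{sid},{p}]" for sid in fit.subject_ids for p in fit.param_names
    ]
    return labels


def pointwise_loglik(fit: PosteriorFit, datasets: list[SubjectDataset]) -> np.ndarray:
    """Per-trial log-likelihood, shape (chains, draws, n_trials) — the input
    to PSIS-LOO (the LOO unit is the trial; the likelihood factorizes over
    trials once the belief state is threaded)."""
    packed = pack_cohort(datasets, fit.reward_per_pump)
    if list(packed.subject_ids) != fit.subject_ids:
        raise ValueError("datasets do not match the fitted cohort")
    subj = fit.subject_draws()  # (chains, draws, S, J)
    n_chains, n_draws = subj.shape[:2]
    out = np.empty((n_chains, n_draws, packed.n_trials))
    for c in range(n_chains):
        for d in range(n_draws):
            _, pw = cohort_pointwise(packed, subj[c, d], fit.model, fit.dialects)
            out[c, d] = pw
    return out


@dataclass(frozen=True)
class LooResult:
    looic: float
    se: float
    pareto_k: np.ndarray
    warnings_: tuple[str, ...] = ()


def loo_ic(matrix: np.ndarray) -> LooResult:
    """PSIS-LOO information criterion from a pointwise log-likelihood matrix
    of shape (draws, trials) or (chains, draws, trials)."""
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] * arr.shape[1] < 100:
        raise ValueError("need >= 100 posterior draws for a stable PSIS-LOO")
    idata = az.from_dict(log_likelihood={"obs": arr})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if arr.shape[0] > 1:
            # relative efficiency from the pointwise draws themselves
            ess = az.ess(az.convert_to_dataset(arr))["x"].to_numpy()
            reff = float(np.mean(ess) / (arr.shape[0] * arr.shape[1]))
        else:
            reff = 1.0
        res = az.loo(idata, pointwise=True, reff=reff)
    k = np.asarray(res.pareto_k)
    notes = []
    frac_bad = float(np.mean(k > PARETO_K_LIMIT))
    if frac_bad > 0.10:
        notes.append(
            f"{frac_bad:.0%} of trials have Pareto k > {PARETO_K_LIMIT}; "
            "the LOO estimate may be unreliable"
        )
    return LooResult(
        looic=float(-2.0 * res.elpd_loo),
        se=float(2.0 * res.se),
        pareto_k=k,
        warnings_=tuple(notes),
    )


def akaike_weights(looics) -> np.ndarray:
    """Relative-evidence weights w_i = exp(-0.5 dLOOIC_i) / sum, computed
    stably via the minimum shift."""
    arr = np.asarray(looics, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 LOOIC values to compare")
    delta = arr - arr.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def subject_estimates(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean of each subject's parameters on the natural scale —
    one row per subject, the input to group comparisons."""
    subj = fit.subject_draws()  # (chains, draws, S, J)
    means = subj.mean(axis=(0, 1))
    frame = pd.DataFrame(means, columns=fit.param_names)
    frame.insert(0, "subject_id", fit.subject_ids)
    frame.insert(1, "group", fit.groups)
    return frame


@dataclass(frozen=True)
class FitComparison:
    """LOOIC table for a set of candidate models on one cohort."""

    models: tuple[str, ...]
    looic: np.ndarray
    se: np.ndarray
    weights: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.models,
                "looic": self.looic,
                "looic_se": self.se,
                "looic_weight": self.weights,
            }
        )


def compare_fits(
    fits: list[PosteriorFit],
    datasets: list[SubjectDataset],
    allow_unconverged: bool = False,
) -> FitComparison:
    """LOOIC + Akaike weights across fitted models.

    Refuses fits carrying convergence warnings unless ``allow_unconverged``;
    comparing non-converged posteriors silently would be misleading.
    """
    for f in fits:
        if not f.converged and not allow_unconverged:
            raise ValueError(
                f"fit for {f.model} has convergence warnings {f.warnings_}; "
                "pass allow_unconverged=True to compare anyway"
            )
    loos = [loo_ic(pointwise_loglik(f, datasets)) for f in fits]
    looics = np.array([l.looic for l in loos])
    return FitComparison(
        models=tuple(f.model for f in fits),
        looic=looics,
        se=np.array([l.se for l in loos]),
        weights=akaike_weights(looics),
    )
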