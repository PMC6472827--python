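"""Marginal-likelihood estimation: nested sampling with an uncertainty
estimate, plus path-sampling and stepping-stone cross-checks.

All three estimators are generic over a :class:`PosteriorSpec` -- a prior
sampler, prior density, likelihood, and a prior-invariant MH proposal --
so the same code scores toy conjugate problems and phylogenetic models.

Nested sampling shrinks the prior volume geometrically
(``E[log X_i] = -i/n_live``); each iteration replaces the worst live
point with a constrained-prior draw obtained by subchain MCMC from a
random survivor.  It returns log Z, the information H, and the standard
error ``sqrt(H/n_live)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

__all__ = [
    "PosteriorSpec",
    "NsConfig",
    "EvidenceResult",
    "nested_sampling",
    "power_posterior",
    "path_sampling",
    "stepping_stone",
    "beta_schedule",
]


@dataclass
class PosteriorSpec:
    """Everything an evidence estimator needs to know about a model.

    ``propose(state, rng, scale)`` returns a proposal and its log
    Hastings adjustment; implementations should shrink their step with
    ``scale`` (nested sampling adapts it as the constrained region
    contracts; the power-posterior samplers pass 1.0).
    """

    sample_prior: Callable[[np.random.Generator], Any]
    log_prior: Callable[[Any], float]
    log_likelihood: Callable[[Any], float]
    propose: Callable[[Any, np.random.Generator, float], tuple[Any, float]]


@dataclass
class NsConfig:
    n_live: int = 100
    subchain_length: int = 20
    max_iterations: int = 100000
    evidence_tol: float = 1e-6
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_live < 2 or self.subchain_length < 1 or self.max_iterations < 1:
            raise ValueError("NsConfig fields must be positive (n_live >= 2)")


@dataclass
class EvidenceResult:
    logZ: float
    stderr: float
    information: float
    posterior_states: list = field(default_factory=list)
    posterior_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iterations: int = 0
    n_subchain_failures: int = 0


def _logsubexp(a: float, b: float) -> float:
    """log(e^a - e^b) for a > b."""
    return a + math.log1p(-math.exp(b - a))


def nested_sampling(spec: PosteriorSpec, cfg: NsConfig) -> EvidenceResult:
    """Classic nested-sampling recursion with subchain replacement."""
    rng = np.random.default_rng(cfg.seed)
    live = [spec.sample_prior(rng) for _ in range(cfg.n_live)]
    live_logl = [spec.log_likelihood(s) for s in live]
    live_logp = [spec.log_prior(s) for s in live]

    dead_states: list = []
    dead_logl: list[float] = []
    dead_logw: list[float] = []
    logz = -math.inf
    log_x_prev = 0.0
    failures = 0
    consecutive_failures = 0
    scale = 1.0
    it = 0
    while it < cfg.max_iterations:
        it += 1
        worst = int(np.argmin(live_logl))
        l_star = live_logl[worst]
        log_x = -it / cfg.n_live
        logw = _logsubexp(log_x_prev, log_x)
        log_x_prev = log_x
        dead_states.append(live[worst])
        dead_logl.append(l_star)
        dead_logw.append(logw)
        logz = np.logaddexp(logz, logw + l_star)

        # replace by constrained-prior MCMC from a random survivor
        seed_idx = int(rng.integers(cfg.n_live))
        while cfg.n_live > 1 and seed_idx == worst:
            seed_idx = int(rng.integers(cfg.n_live))
        cur, cur_logp, cur_logl = (
            live[seed_idx],
            live_logp[seed_idx],
            live_logl[seed_idx],
        )
        n_moves = 0
        for _ in range(cfg.subchain_length):
            prop, log_adj = spec.propose(cur, rng, scale)
            prop_logp = spec.log_prior(prop)
            if prop_logp == -math.inf:
                continue
            if math.log(rng.random()) < prop_logp - cur_logp + log_adj:
                prop_logl = spec.log_likelihood(prop)
                if prop_logl >= l_star:
                    cur, cur_logp, cur_logl = prop, prop_logp, prop_logl
                    n_moves += 1
        # adapt the proposal scale to the shrinking constrained region
        rate = n_moves / cfg.subchain_length
        if rate > 0.5:
            scale = min(scale * 1.3, 1e3)
        elif rate < 0.15:
            scale = max(scale * 0.7, 1e-9)
        if n_moves == 0:
            failures += 1
            consecutive_failures += 1
            if consecutive_failures > 50:
                raise RuntimeError(
                    "constrained-prior sampler stalled: no accepted move in "
                    "50 consecutive subchains"
                )
        else:
            consecutive_failures = 0
        live[worst], live_logp[worst], live_logl[worst] = cur, cur_logp, cur_logl

        remaining = max(live_logl) + log_x
        if remaining < math.log(cfg.evidence_tol) + logz:
            break

    # surviving live points share the final volume equally
    log_x_final = -it / cfg.n_live - math.log(cfg.n_live)
    for s, ll in zip(live, live_logl):
        dead_states.append(s)
        dead_logl.append(ll)
        dead_logw.append(log_x_final)
        logz = np.logaddexp(logz, log_x_final + ll)

    post_w = np.exp(np.array(dead_logw) + np.array(dead_logl) - logz)
    post_w /= post_w.sum()
    info = float(np.sum(post_w * (np.array(dead_logl) - logz)))
    info = max(info, 0.0)
    return EvidenceResult(
        logZ=float(logz),
        stderr=math.sqrt(info / cfg.n_live),
        information=info,
        posterior_states=dead_states,
        posterior_weights=post_w,
        n_iterations=it,
        n_subchain_failures=failures,
    )


# ---------------------------------------------------------------------------
# Power posteriors
# ---------------------------------------------------------------------------


def beta_schedule(n_steps: int, alpha: float = 0.3) -> np.ndarray:
    """Beta(alpha, 1)-spaced inverse temperatures in [0, 1]: dense near 0
    where the integrand varies fastest."""
    return (np.arange(n_steps + 1) / n_steps) ** (1.0 / alpha)


@dataclass
class PowerPosteriorResult:
    logZ_path: float
    logZ_stepping_stone: float
    betas: np.ndarray
    mean_loglik: np.ndarray
    stderr_path: float = float("nan")
    stderr_stepping_stone: float = float("nan")


def power_posterior(
    spec: PosteriorSpec,
    n_steps: int = 16,
    chain_length: int = 2000,
    burn_in: float = 0.25,
    seed: int = 1,
    alpha: float = 0.3,
) -> PowerPosteriorResult:
    """Sample p(x) L(x)^beta along a beta ladder (warm-started upward) and
    form both the thermodynamic-integration and stepping-stone estimates."""
    rng = np.random.default_rng(seed)
    betas = beta_schedule(n_steps, alpha)
    cur = spec.sample_prior(rng)
    cur_logp = spec.log_prior(cur)
    cur_logl = spec.log_likelihood(cur)
    mean_ll = np.zeros(betas.size)
    samples_ll: list[np.ndarray] = []
    burn = int(burn_in * chain_length)
    for k, beta in enumerate(betas):
        kept = []
        for step in range(chain_length):
            prop, log_adj = spec.propose(cur, rng, 1.0)
            prop_logp = spec.log_prior(prop)
            if prop_logp > -math.inf:
                prop_logl = spec.log_likelihood(prop)
                delta = (prop_logp - cur_logp) + beta * (prop_logl - cur_logl)
                if math.log(rng.random()) < delta + log_adj:
                    cur, cur_logp, cur_logl = prop, prop_logp, prop_logl
            if step >= burn:
                kept.append(cur_logl)
        arr = np.array(kept)
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite E_beta[log L] at beta={beta}")
        samples_ll.append(arr)
        mean_ll[k] = arr.mean()

    from .mcmc.summaries import compute_ess

    def _neff(arr: np.ndarray) -> float:
        if arr.size < 10 or arr.var() == 0:
            return float(arr.size)
        return max(compute_ess(arr), 2.0)

    logz_path = float(np.trapezoid(mean_ll, betas))
    # trapezoid weights; per-beta Monte Carlo error from autocorrelation-
    # adjusted sample sizes
    w = np.zeros(betas.size)
    w[0] = (betas[1] - betas[0]) / 2
    w[-1] = (betas[-1] - betas[-2]) / 2
    w[1:-1] = (betas[2:] - betas[:-2]) / 2
    var_path = 0.0
    for k, arr in enumerate(samples_ll):
        var_path += (w[k] ** 2) * arr.var() / _neff(arr)
    logz_ss = 0.0
    var_ss = 0.0
    for k in range(betas.size - 1):
        d = betas[k + 1] - betas[k]
        ll = samples_ll[k]
        step = float(np.logaddexp.reduce(d * ll) - math.log(ll.size))
        logz_ss += step
        ratios = np.exp(d * ll - np.max(d * ll))
        var_ss += ratios.var() / (ratios.mean() ** 2 * _neff(ll))
    return PowerPosteriorResult(
        logz_path, logz_ss, betas, mean_ll,
        stderr_path=math.sqrt(var_path),
        stderr_stepping_stone=math.sqrt(var_ss),
    )


def path_sampling(spec: PosteriorSpec, **kw) -> float:
    """Thermodynamic integration (trapezoid over E_beta[log L])."""
    return power_posterior(spec, **kw).logZ_path


def stepping_stone(spec: PosteriorSpec, **kw) -> float:
    """Stepping-stone product estimator on the same ladder."""
    return power_posterior(spec, **kw).logZ_stepping_stone
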