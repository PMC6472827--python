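"""Reversible-jump moves over the substitution-model space.

The chain moves along edges of the model graph: a *split* divides one
rate group in two (one fresh rate drawn via u ~ U(0,1), the pair
``(2u*r, 2(1-u)*r)`` preserving the group mean so a merge-back
reconstructs the original exactly; Jacobian ``4r``), a *merge* averages
two group rates (Jacobian ``1/(4r_new)``).  Indicator flips for unequal
frequencies, gamma rate variation and invariable sites draw newly
activated parameters from their priors, so their acceptance reduces to
the likelihood ratio.
"""

from __future__ import annotations

import functools
import itertools
import math

import numpy as np
from scipy.stats import dirichlet, expon

from ..substitution import SiteModel, _groups, canonical_code
from .operators import Operator, Proposal, _TunableScale
from .state import McmcState

__all__ = [
    "site_model_log_prior",
    "RJSplitMergeOperator",
    "FrequencyFlipOperator",
    "GammaFlipOperator",
    "InvariantFlipOperator",
    "GroupRateScaleOperator",
]

_FREQ_ALPHA = np.array([4.0, 4.0, 4.0, 4.0])


def site_model_log_prior(site: SiteModel, model_set: frozenset[str]) -> float:
    """Uniform prior over the model set, Exp(1) group rates,
    Bernoulli(1/2) indicators, Dirichlet(4,4,4,4) frequencies, Exp(1)
    gamma shape, U(0,1) invariable proportion."""
    if site.code not in model_set:
        return -math.inf
    lp = -math.log(len(model_set))
    lp -= float(np.sum(site.group_rates))  # Exp(1) log densities
    lp += 3 * math.log(0.5)
    if not site.freqs_equal:
        lp += float(dirichlet.logpdf(site.base_freqs, _FREQ_ALPHA))
    if site.use_gamma:
        lp -= site.gamma_shape
    return lp


@functools.lru_cache(maxsize=2048)
def _split_options(code: str, model_set: frozenset[str]):
    """(gid, moved position tuple, resulting digits); one entry per
    distinct refinement of the current rate partition inside the set."""
    opts = []
    groups = _groups(code)
    for gid, members in groups.items():
        if len(members) < 2:
            continue
        for k in range(1, len(members)):
            for moved in itertools.combinations(members[1:], k):
                digits = [int(c) for c in code]
                new_gid = max(digits) + 1
                for pos in moved:
                    digits[pos] = new_gid
                cand = canonical_code(digits)
                if cand in model_set:
                    opts.append((gid, moved, tuple(digits)))
    return tuple(opts)


@functools.lru_cache(maxsize=2048)
def _merge_options(code: str, model_set: frozenset[str]):
    opts = []
    gids = sorted(_groups(code))
    for g1, g2 in itertools.combinations(gids, 2):
        digits = tuple(g1 if int(c) == g2 else int(c) for c in code)
        cand = canonical_code(digits)
        if cand in model_set:
            opts.append((g1, g2, digits))
    return tuple(opts)


def _canonicalize_with_rates(digits, rate_of: dict[int, float]):
    relabel: dict[int, int] = {}
    rates: list[float] = []
    out = []
    for g in digits:
        if g not in relabel:
            relabel[g] = len(relabel) + 1
            rates.append(rate_of[g])
        out.append(str(relabel[g]))
    return "".join(out), np.array(rates)


class RJSplitMergeOperator(Operator):
    """Split/merge walk on rate-grouping codes within a model set."""

    name = "rj_split_merge"

    def __init__(self, model_set: frozenset[str], weight: float = 1.0):
        super().__init__(weight)
        self.model_set = model_set

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        site = state.site
        if rng.random() < 0.5:
            return self._split(state, site, rng)
        return self._merge(state, site, rng)

    def _split(self, state: McmcState, site: SiteModel, rng) -> Proposal:
        opts = _split_options(site.code, self.model_set)
        if not opts:
            return None
        gid, _moved, digits = opts[rng.integers(len(opts))]
        rate_of = {g: site.group_rates[g - 1] for g in set(int(c) for c in site.code)}
        r_old = rate_of[gid]
        u = rng.random()
        new_gid = max(int(c) for c in site.code) + 1
        rate_of[gid] = 2 * u * r_old
        rate_of[new_gid] = 2 * (1 - u) * r_old
        new_code, new_rates = _canonicalize_with_rates(digits, rate_of)
        new_site = site.with_(code=new_code, group_rates=new_rates)
        n_merge_back = len(_merge_options(new_code, self.model_set))
        log_adj = (
            math.log(len(opts)) - math.log(n_merge_back) + math.log(4 * r_old)
        )
        return state.with_(site=new_site), log_adj

    def _merge(self, state: McmcState, site: SiteModel, rng) -> Proposal:
        opts = _merge_options(site.code, self.model_set)
        if not opts:
            return None
        g1, g2, digits = opts[rng.integers(len(opts))]
        rate_of = {g: site.group_rates[g - 1] for g in set(int(c) for c in site.code)}
        r_new = 0.5 * (rate_of[g1] + rate_of[g2])
        rate_of[g1] = r_new
        del rate_of[g2]
        new_code, new_rates = _canonicalize_with_rates(digits, rate_of)
        new_site = site.with_(code=new_code, group_rates=new_rates)
        n_split_back = len(_split_options(new_code, self.model_set))
        log_adj = (
            math.log(len(opts)) - math.log(n_split_back) - math.log(4 * r_new)
        )
        return state.with_(site=new_site), log_adj


class FrequencyFlipOperator(Operator):
    """Toggle equal/estimated base frequencies (prior-draw activation)."""

    name = "flip_freqs"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        site = state.site
        if site.freqs_equal:
            freqs = rng.dirichlet(_FREQ_ALPHA)
            new = site.with_(freqs_equal=False, base_freqs=freqs)
            return state.with_(site=new), -float(dirichlet.logpdf(freqs, _FREQ_ALPHA))
        log_dens = float(dirichlet.logpdf(site.base_freqs, _FREQ_ALPHA))
        new = site.with_(freqs_equal=True, base_freqs=np.full(4, 0.25))
        return state.with_(site=new), log_dens


class GammaFlipOperator(Operator):
    """Toggle gamma rate heterogeneity (shape drawn from its Exp(1) prior)."""

    name = "flip_gamma"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        site = state.site
        if not site.use_gamma:
            shape = rng.exponential(1.0)
            new = site.with_(use_gamma=True, gamma_shape=shape)
            return state.with_(site=new), -float(expon.logpdf(shape))
        log_dens = float(expon.logpdf(site.gamma_shape))
        new = site.with_(use_gamma=False)
        return state.with_(site=new), log_dens


class InvariantFlipOperator(Operator):
    """Toggle the invariable-site proportion (p_inv ~ U(0,1) prior)."""

    name = "flip_inv"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        site = state.site
        if not site.use_inv:
            new = site.with_(use_inv=True, p_inv=rng.random())
            return state.with_(site=new), 0.0
        return state.with_(site=site.with_(use_inv=False, p_inv=0.0)), 0.0


class GroupRateScaleOperator(_TunableScale):
    """Multiplicative walk on one randomly chosen group rate."""

    name = "scale_group_rate"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        site = state.site
        s = self.draw_scale(rng)
        i = rng.integers(len(site.group_rates))
        rates = site.group_rates.copy()
        rates[i] *= s
        return state.with_(site=site.with_(group_rates=rates)), math.log(s)
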