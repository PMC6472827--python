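"""Felsenstein pruning likelihood with clock models and an
invariable-sites fast path.

The likelihood of an alignment given a time tree is computed over
compressed site patterns, with a discrete-gamma rate mixture and an
optional proportion of invariable sites.  For the invariable-sites term
only *invariant-capable* patterns (those where one nucleotide is
compatible with every tip state) can contribute, and their contribution is
a frequency sum -- no pruning pass at rate zero is needed.  A deliberately
plain per-site implementation (`log_likelihood_naive`) keeps the fast path
honest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import lognorm

from .alignment import SitePatterns
from .substitution import SiteModel, build_rate_matrix
from .trees import Node, TimeTree

__all__ = [
    "ClockModel",
    "branch_rates",
    "log_likelihood",
    "log_likelihood_naive",
    "TreeLikelihood",
    "PartialsCache",
]

_RESCALE_THRESHOLD = 1e-300


@dataclass
class ClockModel:
    """Strict or uncorrelated-lognormal relaxed molecular clock.

    The relaxed clock is discretized: each branch carries an integer
    category, and the branch rate is ``mean_rate`` times the lognormal
    quantile of that category (quantiles taken at the midpoints of
    ``n_rate_categories`` equal-probability bins, renormalized to mean 1 so
    the clock's time scale is identified by ``mean_rate`` alone).
    """

    kind: str = "strict"
    mean_rate: float = 1.0
    sigma: float = 0.0
    n_rate_categories: int = 20
    branch_categories: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "relaxed_lognormal"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")

    def quantile_rates(self) -> np.ndarray:
        """Normalized lognormal quantile rates for the categories."""
        n = self.n_rate_categories
        if self.sigma == 0:
            return np.ones(n)
        q = (np.arange(n) + 0.5) / n
        rates = lognorm.ppf(q, s=self.sigma, scale=math.exp(-0.5 * self.sigma**2))
        return rates / rates.mean()

    def with_(self, **kw) -> "ClockModel":
        return replace(self, **kw)


def branch_rates(clock: ClockModel, tree: TimeTree) -> dict[int, float]:
    """Substitution rate for each branch, keyed by child-node id."""
    nodes = [n for n in tree.preorder() if n.parent is not None]
    if clock.kind == "strict" or clock.sigma == 0:
        return {n.id: clock.mean_rate for n in nodes}
    qr = clock.quantile_rates()
    out = {}
    for n in nodes:
        cat = clock.branch_categories.get(n.id, clock.n_rate_categories // 2)
        out[n.id] = clock.mean_rate * qr[cat]
    return out


# ---------------------------------------------------------------------------
# Pruning over compressed patterns
# ---------------------------------------------------------------------------


class PartialsCache:
    """Per-node partial likelihood vectors with dirty flags.

    Partials are keyed by stable node id; ``mark_dirty`` invalidates a node
    and all its ancestors so a height or topology change recomputes only
    the affected path.
    """

    def __init__(self) -> None:
        self.partials: dict[int, np.ndarray] = {}
        self.log_scalers: dict[int, float] = {}
        self.dirty: set[int] = set()

    def mark_all_dirty(self) -> None:
        self.partials.clear()
        self.log_scalers.clear()
        self.dirty.clear()

    def mark_dirty(self, tree: TimeTree, node_ids: set[int]) -> None:
        by_id = {n.id: n for n in tree.preorder()}
        for nid in node_ids:
            node = by_id.get(nid)
            while node is not None:
                self.partials.pop(node.id, None)
                self.log_scalers.pop(node.id, None)
                node = node.parent


class TreeLikelihood:
    """Pruning likelihood over a fixed pattern set.

    Reusable across trees/parameters; holds a :class:`PartialsCache` that
    callers may exploit for single-edge updates via ``changed_nodes``.
    """

    def __init__(self, patterns: SitePatterns):
        self.patterns = patterns
        self.cache = PartialsCache()
        self._tips = {lab: patterns.tip_partials(lab) for lab in patterns.labels}
        self._signature: tuple | None = None

    def log_likelihood(
        self,
        tree: TimeTree,
        site: SiteModel,
        clock: ClockModel,
        changed_nodes: Optional[set[int]] = None,
    ) -> float:
        missing = {t.label for t in tree.taxa} ^ set(self.patterns.labels)
        if missing:
            raise ValueError(f"taxon set mismatch: {sorted(missing)}")
        Qm = build_rate_matrix(site)
        cat_rates = site.category_rates()
        rates = branch_rates(clock, tree)
        sig = (
            site.code,
            tuple(site.group_rates),
            tuple(site.base_freqs),
            site.gamma_shape if site.use_gamma else None,
            tuple(sorted(rates.items())),
        )
        if changed_nodes is None or sig != self._signature:
            self.cache.mark_all_dirty()
        else:
            self.cache.mark_dirty(tree, changed_nodes)
        self._signature = sig

        ncat = len(cat_rates)
        npat = self.patterns.n_patterns
        for node in tree.postorder():
            if node.id in self.cache.partials:
                continue
            partial = np.ones((ncat, npat, 4))
            if node.taxon is not None:
                partial *= self._tips[node.taxon.label][None, :, :]
            log_scaler = 0.0
            for child in node.children:
                edge = (node.height - child.height) * rates[child.id]
                cp = self.cache.partials[child.id]
                log_scaler += self.cache.log_scalers[child.id]
                for c in range(ncat):
                    P = Qm.transition_probabilities(edge * cat_rates[c])
                    partial[c] *= cp[c] @ P.T
            peak = partial.max()
            if 0 < peak < _RESCALE_THRESHOLD:
                partial /= peak
                log_scaler += math.log(peak)
            self.cache.partials[node.id] = partial
            self.cache.log_scalers[node.id] = log_scaler

        root_partial = self.cache.partials[tree.root.id]
        site_lik = np.einsum("cpk,k->p", root_partial, site.base_freqs) / ncat
        log_scaler = self.cache.log_scalers[tree.root.id]
        p_inv = site.p_inv if site.use_inv else 0.0
        with np.errstate(divide="ignore"):
            if p_inv > 0:
                inv_term = np.zeros(npat)
                inv = self.patterns.invariant_masks
                for k in range(4):
                    inv_term += ((inv >> k) & 1) * site.base_freqs[k]
                # variable part carries the rescaling factor, the invariant
                # frequency sum does not: combine in log space
                log_mix = np.logaddexp(
                    np.log((1 - p_inv) * site_lik) + log_scaler,
                    np.log(p_inv * inv_term),
                )
            else:
                log_mix = np.log(site_lik) + log_scaler
        if np.any(np.isnan(log_mix)):
            bad = int(np.argmax(np.isnan(log_mix)))
            raise ValueError(f"non-finite site likelihood at pattern {bad}")
        if np.any(np.isneginf(log_mix)):
            return -math.inf
        return float(np.dot(self.patterns.weights, log_mix))


def log_likelihood(
    patterns: SitePatterns,
    tree: TimeTree,
    site: SiteModel,
    clock: ClockModel,
) -> float:
    """P(D | T, site model, clock) via pruning over compressed patterns."""
    return TreeLikelihood(patterns).log_likelihood(tree, site, clock)


def log_likelihood_naive(
    patterns: SitePatterns,
    tree: TimeTree,
    site: SiteModel,
    clock: ClockModel,
) -> float:
    """Reference implementation: per-site recursion, no pattern sharing,
    invariable sites handled as an explicit rate-0 mixture component."""
    Qm = build_rate_matrix(site)
    cat_rates = list(site.category_rates())
    ncat = len(cat_rates)
    p_inv = site.p_inv if site.use_inv else 0.0
    rates = branch_rates(clock, tree)
    pi = site.base_freqs

    def site_partial(node: Node, tip_states: dict[str, np.ndarray], rate: float):
        part = np.ones(4)
        if node.taxon is not None:
            part = part * tip_states[node.taxon.label]
        for child in node.children:
            t = (node.height - child.height) * rates[child.id] * rate
            P = Qm.transition_probabilities(t)
            part = part * (P @ site_partial(child, tip_states, rate))
        return part

    total = 0.0
    for p in range(patterns.n_patterns):
        tip_states = {
            lab: patterns.tip_partials(lab)[p] for lab in patterns.labels
        }
        weight = int(patterns.weights[p])
        lik_var = sum(
            float(pi @ site_partial(tree.root, tip_states, r)) for r in cat_rates
        ) / ncat
        # rate-0 component: transition matrices collapse to the identity
        lik_inv = float(pi @ site_partial(tree.root, tip_states, 0.0))
        lik = (1 - p_inv) * lik_var + p_inv * lik_inv
        if lik <= 0:
            return -math.inf
        total += weight * math.log(lik)
    return total
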