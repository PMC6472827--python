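"""Posterior summaries: effective sample size, HPD intervals, credible
model sets, clade supports and the maximum-clade-credibility tree."""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ..trees import Node, TimeTree

__all__ = [
    "compute_ess",
    "hpd_interval",
    "credible_model_set",
    "clade_supports",
    "summarize_mcc",
    "MccSummary",
]


def compute_ess(x) -> float:
    """ESS = n / (1 + 2 sum of autocorrelations), truncated by Geyer's
    initial-positive-sequence rule.  A constant series has ESS 0."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    var = x.var()
    if var == 0:
        return 0.0
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1 :] / n
    rho = acov / acov[0]
    tau = 1.0
    m = 1
    while m + 1 < n:
        pair = rho[m] + rho[m + 1]
        if pair <= 0:
            break
        tau += 2 * pair
        m += 2
    return float(n / tau)


def hpd_interval(x, level: float = 0.95) -> tuple[float, float]:
    """Smallest interval containing ``level`` of the sample."""
    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    k = max(1, math.ceil(level * n))
    if k >= n:
        return float(xs[0]), float(xs[-1])
    widths = xs[k - 1 + np.arange(n - k + 1)] - xs[: n - k + 1]
    i = int(np.argmin(widths))
    return float(xs[i]), float(xs[i + k - 1])


def credible_model_set(codes, level: float = 0.95) -> list[tuple[str, float]]:
    """Smallest set of model codes with cumulative posterior frequency
    >= level; ties broken lexicographically.  Returns (code, frequency)
    pairs in decreasing frequency order."""
    codes = list(codes)
    n = len(codes)
    if n == 0:
        raise ValueError("empty model-code trace")
    counts = Counter(codes)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    cum = 0.0
    for code, c in ranked:
        out.append((code, c / n))
        cum += c / n
        if cum >= level - 1e-12:
            break
    return out


def _clades(tree: TimeTree) -> dict[frozenset, Node]:
    """Descendant sample-label set for every internal node (sampled
    ancestors contribute their own label to their clade)."""
    out: dict[frozenset, Node] = {}

    def rec(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.taxon.label])
        labels = frozenset().union(*(rec(c) for c in node.children))
        if node.taxon is not None:
            labels = labels | {node.taxon.label}
        out[labels] = node
        return labels

    rec(tree.root)
    return out


def clade_supports(trees: list[TimeTree]) -> dict[frozenset, float]:
    """Posterior frequency of each clade across a tree sample."""
    if not trees:
        raise ValueError("empty tree log")
    counts: Counter = Counter()
    for t in trees:
        counts.update(_clades(t).keys())
    n = len(trees)
    return {clade: c / n for clade, c in counts.items()}


@dataclass
class MccSummary:
    tree: TimeTree
    log_clade_credibility: float
    supports: dict[frozenset, float]
    height_mean: dict[frozenset, float]
    height_hpd: dict[frozenset, tuple[float, float]]


def summarize_mcc(trees: list[TimeTree], level: float = 0.95) -> MccSummary:
    """Maximum-clade-credibility tree with mean and HPD node heights.

    The MCC tree is the *sampled* tree maximizing the product of its
    clades' posterior frequencies (ties: first occurrence in the log).
    """
    supports = clade_supports(trees)
    best, best_score = None, -math.inf
    for t in trees:
        score = sum(math.log(supports[c]) for c in _clades(t))
        if score > best_score:
            best, best_score = t, score
    heights: dict[frozenset, list[float]] = {c: [] for c in _clades(best)}
    for t in trees:
        cl = _clades(t)
        for c, lst in heights.items():
            if c in cl:
                lst.append(cl[c].height)
    mean = {c: float(np.mean(h)) for c, h in heights.items()}
    hpd = {c: hpd_interval(h, level) for c, h in heights.items()}
    return MccSummary(best.copy(), best_score, supports, mean, hpd)
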