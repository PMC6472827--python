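"""Tree prior densities: serial coalescent, birth-death with serial
sampling and sampled ancestors, and the piecewise-constant birth-death
skyline.

The birth-death process starts from one lineage at the origin height t0;
each lineage births at rate lambda, dies at rate mu, is psi-sampled (and
then removed with probability r), and extant lineages are rho-sampled at
height 0.  The density of the sampled (pruned) labelled tree is a product
over tree elements:

* each edge from height ``a`` down to ``b`` contributes ``q(a)/q(b)``,
  where ``q`` solves ``d log q/dt = -(lambda+mu+psi) + 2*lambda*p0(t)``
  and ``p0(t)`` is the probability that a single lineage at height t
  leaves no sample at all;
* each bifurcation at height x contributes ``2*lambda(x)`` (the factor 2
  is the orientation count of a labelled split);
* each psi-sampled leaf at height y contributes
  ``psi*(r + (1-r)*p0(y))``; each sampled ancestor contributes
  ``psi*(1-r)``; each rho-sampled tip contributes ``rho``.

For piecewise-constant (skyline) rates the same product applies with
``q``/``p0`` evaluated per interval, glued continuously at the change
heights.  Densities condition on the origin and, by default, on observing
at least one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import quad

from .trees import TimeTree

__all__ = [
    "BDParams",
    "EpiParams",
    "SkylineParams",
    "CoalescentParams",
    "epi_to_canonical",
    "canonical_to_epi",
    "coalescent_log_density",
    "bd_serial_log_density",
    "bdsky_log_density",
]

_RHO_TIP_REL_TOL = 1e-10


@dataclass
class BDParams:
    """Canonical birth-death-sampling parameters."""

    t0: float  # origin height
    lam: float  # birth rate
    mu: float  # death rate
    psi: float = 0.0  # serial sampling rate
    r: float = 1.0  # removal-on-sampling probability
    rho: float = 0.0  # present-day sampling probability

    def __post_init__(self) -> None:
        if self.t0 <= 0 or self.lam <= 0 or self.mu < 0 or self.psi < 0:
            raise ValueError("need t0 > 0, lambda > 0, mu >= 0, psi >= 0")
        if not (0 <= self.r <= 1) or not (0 <= self.rho <= 1):
            raise ValueError("r and rho must lie in [0, 1]")
        if self.psi == 0 and self.rho == 0:
            raise ValueError("at least one of psi, rho must be positive")


@dataclass
class EpiParams:
    """Epidemiological reparameterization: Re = lambda/delta,
    delta = mu + psi*r, p = psi/delta."""

    Re: float
    delta: float
    p: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.Re <= 0 or self.delta <= 0:
            raise ValueError("Re and delta must be positive")
        if not (0 <= self.p <= 1) or not (0 <= self.r <= 1):
            raise ValueError("p and r must lie in [0, 1]")


def epi_to_canonical(e: EpiParams, t0: float = 1.0, rho: float = 0.0) -> BDParams:
    """Invert (Re, delta, p, r) -> (lambda, mu, psi, r)."""
    psi = e.p * e.delta
    lam = e.Re * e.delta
    mu = e.delta - psi * e.r
    if mu < -1e-12:
        raise ValueError(f"p*r = {e.p * e.r} > 1 implies mu < 0")
    return BDParams(t0=t0, lam=lam, mu=max(mu, 0.0), psi=psi, r=e.r, rho=rho)


def canonical_to_epi(b: BDParams) -> EpiParams:
    """Map (lambda, mu, psi, r) -> (Re, delta, p, r); needs delta > 0."""
    delta = b.mu + b.psi * b.r
    if delta <= 0:
        raise ValueError("delta = mu + psi*r must be positive")
    return EpiParams(Re=b.lam / delta, delta=delta, p=b.psi / delta, r=b.r)


@dataclass
class SkylineParams:
    """Piecewise-constant birth-death-sampling parameters.

    ``change_heights`` are the interval boundaries strictly inside
    (0, t0), ascending; rate arrays have one entry per interval, index 0
    covering the present.  ``r`` and ``rho`` are shared across intervals.
    """

    t0: float
    lam: Sequence[float]
    mu: Sequence[float]
    psi: Sequence[float]
    change_heights: Sequence[float] = field(default_factory=tuple)
    r: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        self.lam = tuple(float(x) for x in self.lam)
        self.mu = tuple(float(x) for x in self.mu)
        self.psi = tuple(float(x) for x in self.psi)
        self.change_heights = tuple(float(x) for x in self.change_heights)
        k = len(self.change_heights)
        if not (len(self.lam) == len(self.mu) == len(self.psi) == k + 1):
            raise ValueError("need one rate per interval (len(change_heights)+1)")
        if any(l <= 0 for l in self.lam) or any(m < 0 for m in self.mu) or any(
            p < 0 for p in self.psi
        ):
            raise ValueError("rates out of range")
        if not (0 <= self.r <= 1) or not (0 <= self.rho <= 1):
            raise ValueError("r and rho must lie in [0, 1]")
        bounds = (0.0,) + self.change_heights + (self.t0,)
        if any(b2 - b1 <= 1e-12 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(
                "change heights must be strictly increasing inside (0, t0)"
            )

    @property
    def n_intervals(self) -> int:
        return len(self.change_heights) + 1

    @classmethod
    def single(cls, b: BDParams) -> "SkylineParams":
        return cls(t0=b.t0, lam=(b.lam,), mu=(b.mu,), psi=(b.psi,), r=b.r, rho=b.rho)


@dataclass
class CoalescentParams:
    """Constant-size coalescent; pairwise merger rate 1/Ne in tree time."""

    Ne: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.Ne) or self.Ne <= 0:
            raise ValueError("Ne must be finite and positive")


# ---------------------------------------------------------------------------
# Coalescent
# ---------------------------------------------------------------------------


def coalescent_log_density(tree: TimeTree, c: CoalescentParams) -> float:
    """Serial (heterochronous) constant-size coalescent log density."""
    if tree.sampled_ancestors:
        raise ValueError("coalescent prior does not admit sampled ancestors")
    events: list[tuple[float, int]] = []
    for node in tree.preorder():
        if node.is_leaf:
            events.append((node.height, +1))
        else:
            events.append((node.height, -1))
    events.sort(key=lambda e: (e[0], -e[1]))
    logf = 0.0
    k = 0
    prev = 0.0
    for h, delta in events:
        if k >= 2:
            logf -= k * (k - 1) / 2 * (h - prev) / c.Ne
        prev = h
        if delta < 0:
            logf -= math.log(c.Ne)
        k += delta
    return logf


# ---------------------------------------------------------------------------
# Single-interval birth-death with serial sampling and sampled ancestors
# ---------------------------------------------------------------------------


def _c1c2(lam: float, mu: float, psi: float, rho: float) -> tuple[float, float]:
    c1 = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
    c2 = -(lam - mu - psi - 2 * lam * rho) / c1
    return c1, c2


def _p0(t: float, lam: float, mu: float, psi: float, rho: float) -> float:
    c1, c2 = _c1c2(lam, mu, psi, rho)
    x = math.exp(-c1 * t)
    frac = (x * (1 - c2) - (1 + c2)) / (x * (1 - c2) + (1 + c2))
    return (lam + mu + psi + c1 * frac) / (2 * lam)


def _log_q(t: float, lam: float, mu: float, psi: float, rho: float) -> float:
    c1, c2 = _c1c2(lam, mu, psi, rho)
    x = math.exp(-c1 * t)
    return math.log(4.0) - c1 * t - 2 * math.log(x * (1 - c2) + (1 + c2))


def _one_sample_probability(b: BDParams) -> float:
    """P(exactly one sample | origin) by quadrature over the sample height."""
    lq_t0 = _log_q(b.t0, b.lam, b.mu, b.psi, b.rho)
    total = b.rho * math.exp(lq_t0) if b.rho > 0 else 0.0
    if b.psi > 0:
        def integrand(y: float) -> float:
            lq = lq_t0 - _log_q(y, b.lam, b.mu, b.psi, b.rho)
            return math.exp(lq) * b.psi * (
                b.r + (1 - b.r) * _p0(y, b.lam, b.mu, b.psi, b.rho)
            )

        val, _ = quad(integrand, 0.0, b.t0, limit=200)
        total += val
    return total


def _apply_conditioning(logf: float, p0_t0: float, b: BDParams, conditioning: str) -> float:
    if conditioning == "none":
        return logf
    p_none = p0_t0
    if conditioning == "on_origin_survival":
        return logf - math.log1p(-p_none)
    if conditioning == "at_least_two":
        p_ge2 = 1.0 - p_none - _one_sample_probability(b)
        if p_ge2 <= 0:
            raise ValueError("P(>=2 samples) vanished under these parameters")
        return logf - math.log(p_ge2)
    raise ValueError(f"unknown conditioning {conditioning!r}")


def bd_serial_log_density(
    tree: TimeTree,
    b: BDParams,
    conditioning: str = "on_origin_survival",
) -> float:
    """Log density of a sampled-ancestor time tree under the constant-rate
    birth-death-sampling prior, conditioned on the origin.

    With ``r = 1`` any tree containing a sampled ancestor has density
    ``-inf`` (not an exception): removal upon sampling forbids sampled
    ancestors.  ``r = 0`` is the fossilized-birth-death special case.
    """
    t0 = tree.origin_height
    if t0 is None:
        raise ValueError("birth-death prior requires tree.origin_height")
    if b.t0 != t0:
        b = BDParams(t0=t0, lam=b.lam, mu=b.mu, psi=b.psi, r=b.r, rho=b.rho)
    if tree.root.height >= t0:
        return -math.inf
    lam, mu, psi, rho = b.lam, b.mu, b.psi, b.rho
    rho_tol = _RHO_TIP_REL_TOL * max(t0, 1.0)

    # labelled-tree convention: 2^{bifurcations} orientation factors (in
    # the node terms below) with a 1/n! exchangeable-labelling constant
    logf = -math.lgamma(len(tree.sampled_nodes) + 1)
    # edge factors q(top)/q(bottom), including the origin -> root edge
    for node in tree.preorder():
        top = t0 if node.parent is None else node.parent.height
        logf += _log_q(top, lam, mu, psi, rho) - _log_q(
            node.height, lam, mu, psi, rho
        )
    # node factors
    for node in tree.preorder():
        if len(node.children) == 2:
            logf += math.log(2 * lam)
        elif node.is_sampled_ancestor:
            if b.r == 1.0 or psi == 0:
                return -math.inf
            logf += math.log(psi * (1 - b.r))
        elif node.is_leaf:
            if rho > 0 and node.height <= rho_tol:
                logf += math.log(rho)
            else:
                if psi == 0:
                    return -math.inf
                term = psi * (b.r + (1 - b.r) * _p0(node.height, lam, mu, psi, rho))
                if term <= 0:
                    return -math.inf
                logf += math.log(term)
    return _apply_conditioning(logf, _p0(t0, lam, mu, psi, rho), b, conditioning)


# ---------------------------------------------------------------------------
# Birth-death skyline
# ---------------------------------------------------------------------------


class _SkylineGrid:
    """Per-interval (A_i, B_i) coefficients glued continuously at change
    heights; provides p(t) and edge-wise log-q integrals."""

    def __init__(self, s: SkylineParams):
        self.s = s
        self.bounds = (0.0,) + tuple(s.change_heights) + (s.t0,)
        self.A: list[float] = []
        self.B: list[float] = []
        p_prev = 1.0 - s.rho
        for i in range(s.n_intervals):
            lam, mu, psi = s.lam[i], s.mu[i], s.psi[i]
            A = math.sqrt((lam - mu - psi) ** 2 + 4 * lam * psi)
            B = ((1 - 2 * p_prev) * lam + mu + psi) / A
            self.A.append(A)
            self.B.append(B)
            p_prev = self._p_in(i, self.bounds[i + 1])

    def interval_of(self, t: float) -> int:
        # height t0 belongs to the top interval, 0 to the bottom one
        for i in range(self.s.n_intervals):
            if t <= self.bounds[i + 1]:
                return i
        return self.s.n_intervals - 1

    def _p_in(self, i: int, t: float) -> float:
        lam, mu, psi = self.s.lam[i], self.s.mu[i], self.s.psi[i]
        A, B = self.A[i], self.B[i]
        x = math.exp(-A * (t - self.bounds[i]))
        frac = ((1 + B) - x * (1 - B)) / ((1 + B) + x * (1 - B))
        return (lam + mu + psi - A * frac) / (2 * lam)

    def p(self, t: float) -> float:
        return self._p_in(self.interval_of(t), t)

    def _log_q_in(self, i: int, t: float) -> float:
        A, B = self.A[i], self.B[i]
        x = math.exp(-A * (t - self.bounds[i]))
        return math.log(4.0) - A * (t - self.bounds[i]) - 2 * math.log(
            x * (1 - B) + (1 + B)
        )

    def log_q_edge(self, top: float, bottom: float) -> float:
        """log of the edge survival factor q(top)/q(bottom), glued across
        any change heights the edge spans."""
        total = 0.0
        i = self.interval_of(top)
        j = self.interval_of(bottom)
        for k in range(j, i + 1):
            seg_top = min(top, self.bounds[k + 1])
            seg_bot = max(bottom, self.bounds[k])
            if seg_top <= seg_bot:
                continue
            total += self._log_q_in(k, seg_top) - self._log_q_in(k, seg_bot)
        return total


def bdsky_log_density(
    tree: TimeTree,
    s: SkylineParams,
    conditioning: str = "on_origin_survival",
) -> float:
    """Log density under the piecewise-constant birth-death skyline.

    Collapses to :func:`bd_serial_log_density` for a single interval.
    """
    t0 = tree.origin_height
    if t0 is None:
        raise ValueError("birth-death prior requires tree.origin_height")
    if any(u >= t0 for u in s.change_heights):
        raise ValueError("change heights must lie strictly below the origin")
    if s.t0 != t0:
        s = SkylineParams(
            t0=t0, lam=s.lam, mu=s.mu, psi=s.psi,
            change_heights=s.change_heights, r=s.r, rho=s.rho,
        )
    if tree.root.height >= t0:
        return -math.inf
    grid = _SkylineGrid(s)
    rho_tol = _RHO_TIP_REL_TOL * max(t0, 1.0)

    # same labelled-tree convention as bd_serial_log_density
    logf = -math.lgamma(len(tree.sampled_nodes) + 1)
    # edges, including origin -> root
    for node in tree.preorder():
        top = t0 if node.parent is None else node.parent.height
        logf += grid.log_q_edge(top, node.height)
    for node in tree.preorder():
        i = grid.interval_of(node.height)
        lam_i, psi_i = s.lam[i], s.psi[i]
        if len(node.children) == 2:
            logf += math.log(2 * lam_i)
        elif node.is_sampled_ancestor:
            if s.r == 1.0 or psi_i == 0:
                return -math.inf
            logf += math.log(psi_i * (1 - s.r))
        elif node.is_leaf:
            if s.rho > 0 and node.height <= rho_tol:
                logf += math.log(s.rho)
            else:
                if psi_i == 0:
                    return -math.inf
                term = psi_i * (s.r + (1 - s.r) * grid.p(node.height))
                if term <= 0:
                    return -math.inf
                logf += math.log(term)

    if conditioning == "none":
        return logf
    if conditioning == "on_origin_survival":
        return logf - math.log1p(-grid.p(t0))
    if conditioning == "at_least_two":
        lq_t0 = grid.log_q_edge(t0, 0.0)
        p1 = s.rho * math.exp(lq_t0) if s.rho > 0 else 0.0

        def integrand(y: float) -> float:
            i = grid.interval_of(y)
            if s.psi[i] == 0:
                return 0.0
            return math.exp(grid.log_q_edge(t0, y)) * s.psi[i] * (
                s.r + (1 - s.r) * grid.p(y)
            )

        pts = [u for u in s.change_heights if 0 < u < t0]
        val, _ = quad(integrand, 0.0, t0, points=pts or None, limit=200)
        p1 += val
        p_ge2 = 1.0 - grid.p(t0) - p1
        if p_ge2 <= 0:
            raise ValueError("P(>=2 samples) vanished under these parameters")
        return logf - math.log(p_ge2)
    raise ValueError(f"unknown conditioning {conditioning!r}")
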