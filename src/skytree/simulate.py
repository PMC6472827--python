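"""Direct simulation of trees and sequences: the generative counterpart
of every implemented model.

These simulators power three validation layers: (i) prior-equivalence
tests (MCMC with flat likelihood vs. direct simulation), (ii)
well-calibrated studies in which simulation parameters are drawn from the
inference priors so nominal credible-interval coverage is exact, and
(iii) posterior-predictive model-adequacy checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, compress_patterns
from .likelihood import ClockModel, TreeLikelihood, branch_rates
from .mcmc.kernel import OperatorSchedule, run_mcmc
from .mcmc.operators import (
    ExchangeOperator,
    SAToggleOperator,
    ScaleOperator,
    TreeScaleOperator,
    UniformNodeHeightOperator,
    WilsonBaldingOperator,
)
from .mcmc.state import McmcState
from .substitution import SiteModel, build_rate_matrix
from .treeprior import BDParams, SkylineParams, bd_serial_log_density, bdsky_log_density
from .trees import Node, Taxon, TimeTree

__all__ = [
    "RunawayPopulationError",
    "SimConfig",
    "run_simulation",
    "simulate_bd_tree",
    "simulate_coalescent_tree",
    "simulate_msc_pair",
    "simulate_sequences",
    "CalibrationConfig",
    "CalibrationResult",
    "well_calibrated_study",
    "AdequacyReport",
    "posterior_predictive_check",
]


class RunawayPopulationError(RuntimeError):
    """The forward simulation exceeded the population cap."""


@dataclass
class SimConfig:
    """Generative settings for a batch of tree (and optional sequence)
    simulations: model kind, parameters, conditioning and seed."""

    kind: str  # bd_serial | bdsky | coalescent | msc_pair
    params: object  # BDParams, SkylineParams, CoalescentParams or (tau, Ne)
    n_replicates: int = 1
    seed: int = 1
    conditioning: str = "none"  # none | at_least_n_samples
    min_samples: int = 2
    n_tips: int = 10  # coalescent only
    sequence_length: int = 0
    site: object = None  # SiteModel
    clock: object = None  # ClockModel

    def __post_init__(self) -> None:
        if self.kind not in ("bd_serial", "bdsky", "coalescent", "msc_pair"):
            raise ValueError(f"unknown simulation kind {self.kind!r}")
        if self.conditioning not in ("none", "at_least_n_samples"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def run_simulation(cfg: SimConfig):
    """Execute a :class:`SimConfig`.

    Returns ``(trees, alignments)`` for tree-generating kinds (alignments
    empty unless ``sequence_length > 0``) or a float array of divergence
    times for ``msc_pair``.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.kind == "msc_pair":
        tau, ne = cfg.params
        return np.array(
            [simulate_msc_pair(tau, ne, rng) for _ in range(cfg.n_replicates)]
        )
    trees = []
    for _ in range(cfg.n_replicates):
        if cfg.kind == "coalescent":
            trees.append(simulate_coalescent_tree(cfg.n_tips, cfg.params.Ne, rng))
        else:
            trees.append(
                simulate_bd_tree(
                    cfg.params, rng,
                    conditioning=cfg.conditioning,
                    min_samples=cfg.min_samples,
                )
            )
    alignments = []
    if cfg.sequence_length > 0:
        site = cfg.site if cfg.site is not None else SiteModel()
        clock = cfg.clock if cfg.clock is not None else ClockModel()
        for tree in trees:
            if tree is None:
                alignments.append(None)
            else:
                alignments.append(
                    simulate_sequences(tree, site, clock, cfg.sequence_length, rng)
                )
    return trees, alignments


# ---------------------------------------------------------------------------
# Birth-death forward (Gillespie) simulation
# ---------------------------------------------------------------------------


class _Individual:
    __slots__ = ("birth_tau", "events", "rho_sampled")

    def __init__(self, birth_tau: float):
        self.birth_tau = birth_tau
        # events: (tau, kind, payload); kind in {"birth", "psi"}
        self.events: list[tuple[float, str, object]] = []
        self.rho_sampled = False


def _attempt_bd_tree(
    s: SkylineParams,
    rng: np.random.Generator,
    population_cap: int,
) -> Optional[TimeTree]:
    """One forward pass; returns the pruned sampled tree or None."""
    t0 = s.t0
    # forward-time interval boundaries (tau = t0 - height)
    bounds_tau = [t0 - u for u in reversed(s.change_heights)] + [t0]
    rates_fwd = list(reversed(range(s.n_intervals)))  # interval index by tau slab

    inds = [_Individual(0.0)]
    active = [0]
    tau = 0.0
    slab = 0
    while active and tau < t0:
        i_int = rates_fwd[slab]
        lam, mu, psi = s.lam[i_int], s.mu[i_int], s.psi[i_int]
        total = len(active) * (lam + mu + psi)
        if total == 0:
            tau = bounds_tau[slab]
        else:
            tau_next = tau + rng.exponential(1.0 / total)
            if tau_next >= bounds_tau[slab]:
                tau = bounds_tau[slab]
                if tau >= t0:
                    break
                slab += 1
                continue
            tau = tau_next
            who = int(rng.integers(len(active)))
            idx = active[who]
            u = rng.random() * (lam + mu + psi)
            if u < lam:
                child = _Individual(tau)
                inds.append(child)
                active.append(len(inds) - 1)
                inds[idx].events.append((tau, "birth", len(inds) - 1))
                if len(active) > population_cap:
                    raise RunawayPopulationError(
                        f"population exceeded {population_cap}"
                    )
            elif u < lam + mu:
                active[who] = active[-1]
                active.pop()
            else:
                removed = rng.random() < s.r
                inds[idx].events.append((tau, "psi", removed))
                if removed:
                    active[who] = active[-1]
                    active.pop()
        if tau >= bounds_tau[slab]:
            slab = min(slab + 1, len(bounds_tau) - 1)

    if s.rho > 0:
        for idx in active:
            inds[idx].rho_sampled = rng.random() < s.rho

    counter = [0]
    tree_nodes: list[Node] = []

    def new_node(height: float, taxon: Optional[Taxon] = None) -> Node:
        node = Node(len(tree_nodes), height, taxon)
        tree_nodes.append(node)
        return node

    def build(idx: int) -> Optional[Node]:
        ind = inds[idx]
        items: list[tuple[float, str, object]] = []
        for tau_e, kind, payload in ind.events:
            if kind == "birth":
                sub = build(payload)
                if sub is not None:
                    items.append((tau_e, "bif", sub))
            else:
                items.append((tau_e, "sample", payload))
        if ind.rho_sampled:
            items.append((t0, "sample", None))
        current: Optional[Node] = None
        for tau_e, kind, payload in sorted(items, key=lambda x: -x[0]):
            h = t0 - tau_e
            if kind == "sample":
                counter[0] += 1
                taxon = Taxon(f"t{counter[0]}", h)
                if current is None:
                    current = new_node(h, taxon)
                else:
                    sa = new_node(h, taxon)
                    sa.add_child(current)
                    current = sa
            else:
                if current is None:
                    current = payload
                else:
                    bif = new_node(h)
                    bif.add_child(payload)
                    bif.add_child(current)
                    current = bif
        return current

    root = build(0)
    if root is None:
        return None
    return TimeTree(root, origin_height=t0)


def simulate_bd_tree(
    params: BDParams | SkylineParams,
    rng: np.random.Generator,
    conditioning: str = "none",
    min_samples: int = 1,
    max_tries: int = 10000,
    population_cap: int = 1_000_000,
) -> Optional[TimeTree]:
    """Forward (Gillespie) birth-death-sampling simulation from one
    lineage at the origin; returns the pruned sampled tree, or None when
    no individual is sampled (``conditioning="none"``).

    psi-sampled individuals that escape removal and are ancestral to later
    samples appear as degree-2 sampled-ancestor nodes.  With
    ``conditioning="at_least_n_samples"`` the attempt is repeated until at
    least ``min_samples`` samples are obtained.
    """
    s = SkylineParams.single(params) if isinstance(params, BDParams) else params
    if conditioning == "none":
        return _attempt_bd_tree(s, rng, population_cap)
    if conditioning != "at_least_n_samples":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    for _ in range(max_tries):
        tree = _attempt_bd_tree(s, rng, population_cap)
        if tree is not None and len(tree.sampled_nodes) >= min_samples:
            return tree
    raise RuntimeError(
        f"no tree with >= {min_samples} samples in {max_tries} attempts"
    )


# ---------------------------------------------------------------------------
# Coalescent
# ---------------------------------------------------------------------------


def simulate_coalescent_tree(
    tips: Sequence[Taxon] | int,
    Ne: float,
    rng: np.random.Generator,
) -> TimeTree:
    """Serial constant-size coalescent; pairwise merger rate 1/Ne.

    ``tips`` is either a taxon list (heterochronous allowed) or a count of
    contemporaneous tips at height 0.
    """
    if isinstance(tips, int):
        tips = [Taxon(f"t{i + 1}", 0.0) for i in range(tips)]
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    counter = [0]

    def make(height: float, taxon: Optional[Taxon] = None) -> Node:
        node = Node(counter[0], height, taxon)
        counter[0] += 1
        return node

    pending = sorted(tips, key=lambda t: t.sampling_time)
    t = pending[0].sampling_time
    lineages: list[Node] = []
    i = 0
    while len(lineages) > 1 or i < len(pending):
        while i < len(pending) and pending[i].sampling_time <= t + 1e-300:
            tx = pending[i]
            lineages.append(make(tx.sampling_time, tx))
            i += 1
        k = len(lineages)
        if k < 2:
            t = pending[i].sampling_time
            continue
        rate = k * (k - 1) / 2 / Ne
        wait = rng.exponential(1.0 / rate)
        if i < len(pending) and t + wait > pending[i].sampling_time:
            t = pending[i].sampling_time
            continue
        t += wait
        a, b = rng.choice(k, size=2, replace=False)
        parent = make(t)
        parent.add_child(lineages[a])
        parent.add_child(lineages[b])
        for j in sorted((a, b), reverse=True):
            lineages.pop(j)
        lineages.append(parent)
    return TimeTree(lineages[0])


def simulate_msc_pair(tau: float, Ne: float, rng: np.random.Generator) -> float:
    """Two-species, one-lineage-per-species gene divergence time.

    The pair coalesces in the ancestral population at rate 1/(2 Ne) per
    generation (diploid convention), so the expected divergence exceeds
    the speciation time ``tau`` by 2 Ne generations.
    """
    if tau < 0 or Ne <= 0:
        raise ValueError("need tau >= 0 and Ne > 0")
    return tau + rng.exponential(2.0 * Ne)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

_NUCS = np.array(list("ACGT"))


def simulate_sequences(
    tree: TimeTree,
    site: SiteModel,
    clock: ClockModel,
    length: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve sequences down the tree: root states from the stationary
    frequencies, per-site gamma/invariant rate classes, transitions via
    the model's matrix exponential."""
    Qm = build_rate_matrix(site)
    cat_rates = site.category_rates()
    p_inv = site.p_inv if site.use_inv else 0.0
    ncat = len(cat_rates)
    # per-site rate class: -1 = invariant (rate 0), else gamma category
    classes = rng.integers(ncat, size=length)
    if p_inv > 0:
        classes = np.where(rng.random(length) < p_inv, -1, classes)
    site_rates = np.where(classes < 0, 0.0, cat_rates[np.clip(classes, 0, None)])
    rates = branch_rates(clock, tree)

    states: dict[int, np.ndarray] = {
        tree.root.id: rng.choice(4, size=length, p=site.base_freqs)
    }
    for node in tree.preorder():
        if node.parent is None:
            continue
        edge = (node.parent.height - node.height) * rates[node.id]
        parent_states = states[node.parent.id]
        child = parent_states.copy()
        for rate in np.unique(site_rates):
            mask = site_rates == rate
            if rate * edge > 0:
                P = Qm.transition_probabilities(edge * rate)
                for src in range(4):
                    sel = mask & (parent_states == src)
                    n = int(sel.sum())
                    if n:
                        child[sel] = rng.choice(4, size=n, p=P[src])
        states[node.id] = child

    taxa = list(tree.taxa)
    seqs = {}
    for node in tree.preorder():
        if node.taxon is not None:
            seqs[node.taxon.label] = "".join(_NUCS[states[node.id]])
    return Alignment(taxa, seqs)


# ---------------------------------------------------------------------------
# Well-calibrated validation
# ---------------------------------------------------------------------------


@dataclass
class CalibrationConfig:
    """Settings for a well-calibrated study of the serial birth-death
    prior: uniform priors on the inferred parameters, fixed nuisance
    rates, strict-clock sequence simulation, and the per-replicate MCMC
    budget."""

    lam_bounds: tuple[float, float] = (0.8, 1.5)
    origin_bounds: tuple[float, float] = (1.5, 2.5)
    # inference priors default to the simulation priors (well-calibrated);
    # override to study deliberate prior mis-specification
    infer_lam_bounds: tuple[float, float] | None = None
    infer_origin_bounds: tuple[float, float] | None = None
    mu: float = 0.2
    psi: float = 0.4
    r: float = 0.0
    rho: float = 0.0
    seq_length: int = 300
    clock_rate: float = 1.0
    chain_length: int = 20000
    log_every: int = 25
    burn_in: float = 0.2
    level: float = 0.95
    min_samples: int = 2
    max_failure_fraction: float = 0.1


@dataclass
class CalibrationResult:
    table: pd.DataFrame
    coverage: dict[str, tuple[int, int]]  # param -> (hits, usable replicates)
    n_failures: int

    def coverage_fraction(self, param: str) -> float:
        k, n = self.coverage[param]
        return k / n


class OriginScaleOperator(ScaleOperator):
    """Multiplicative walk on the tree's origin height (kept above the
    root by auto-rejecting violating draws)."""

    name = "scale(origin)"

    def __init__(self, weight: float = 1.0, scale_factor: float = 0.85):
        super().__init__("origin", weight, scale_factor)

    def propose(self, state: McmcState, rng: np.random.Generator):
        s = self.draw_scale(rng)
        tree = state.tree.copy()
        new_origin = tree.origin_height * s
        if new_origin <= tree.root.height:
            return None
        tree.origin_height = new_origin
        return state.with_(tree=tree), math.log(s)


def _bd_target(cfg: CalibrationConfig, lik: TreeLikelihood,
               site: SiteModel, clock: ClockModel):
    lam_bounds = cfg.infer_lam_bounds or cfg.lam_bounds
    origin_bounds = cfg.infer_origin_bounds or cfg.origin_bounds

    def target(state: McmcState) -> float:
        lam = state.params["lam"]
        tree = state.tree
        origin = tree.origin_height
        if not (lam_bounds[0] <= lam <= lam_bounds[1]):
            return -math.inf
        if not (origin_bounds[0] <= origin <= origin_bounds[1]):
            return -math.inf
        if tree.root.height >= origin:
            return -math.inf
        b = BDParams(t0=origin, lam=lam, mu=cfg.mu, psi=cfg.psi, r=cfg.r, rho=cfg.rho)
        try:
            lp = bd_serial_log_density(tree, b, conditioning="at_least_two")
        except ValueError:
            return -math.inf
        if lp == -math.inf:
            return -math.inf
        return lp + lik.log_likelihood(tree, site, clock)

    return target


def well_calibrated_study(
    n_replicates: int,
    seed: int,
    cfg: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Draw (lambda, origin) from their priors, simulate a tree and
    alignment, run tree+parameter MCMC, and record whether the truth lies
    in each parameter's HPD interval.

    Failed replicates (runaway populations, no viable tree) are excluded
    and counted; more than ``max_failure_fraction`` failing fails the
    study outright.
    """
    cfg = cfg or CalibrationConfig()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_replicates)
    site = SiteModel()  # JC
    clock = ClockModel(kind="strict", mean_rate=cfg.clock_rate)
    rows = []
    n_failures = 0
    for rep, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        lam = rng.uniform(*cfg.lam_bounds)
        origin = rng.uniform(*cfg.origin_bounds)
        b = BDParams(t0=origin, lam=lam, mu=cfg.mu, psi=cfg.psi, r=cfg.r, rho=cfg.rho)
        try:
            tree = simulate_bd_tree(
                b, rng, conditioning="at_least_n_samples",
                min_samples=cfg.min_samples, max_tries=2000,
                population_cap=100_000,
            )
        except (RunawayPopulationError, RuntimeError):
            n_failures += 1
            continue
        aln = simulate_sequences(tree, site, clock, cfg.seq_length, rng)
        patterns = compress_patterns(aln)
        lik = TreeLikelihood(patterns)
        target = _bd_target(cfg, lik, site, clock)
        ilb = cfg.infer_lam_bounds or cfg.lam_bounds
        lam0 = lam if ilb[0] <= lam <= ilb[1] else 0.5 * (ilb[0] + ilb[1])
        state0 = McmcState(tree=tree, params={"lam": lam0})
        ops = [
            TreeScaleOperator(weight=2.0),
            UniformNodeHeightOperator(weight=6.0),
            ExchangeOperator(weight=2.0),
            WilsonBaldingOperator(weight=2.0),
            ScaleOperator("lam", weight=3.0),
            OriginScaleOperator(weight=3.0),
        ]
        if cfg.r < 1 and cfg.psi > 0:
            ops.append(SAToggleOperator(weight=2.0))
        schedule = OperatorSchedule(ops, tune_for=cfg.chain_length // 4)
        try:
            res = run_mcmc(
                state0, target, schedule,
                chain_length=cfg.chain_length, log_every=cfg.log_every,
                seed=int(rng.integers(2**31 - 1)),
                loggers=[
                    ("lam", lambda s: s.params["lam"]),
                    ("origin_height", lambda s: s.tree.origin_height),
                    ("root_height", lambda s: s.tree.root.height),
                ],
                validate_every=0, check_target_every=0,
            )
        except (ValueError, FloatingPointError):
            n_failures += 1
            continue
        trace = res.trace.burned(cfg.burn_in)
        from .mcmc.summaries import hpd_interval

        row = {"replicate": rep, "n_samples": len(tree.sampled_nodes)}
        for name, truth in (("lam", lam), ("origin", origin)):
            values = (
                trace["lam"] if name == "lam" else trace["origin_height"]
            )
            lo, hi = hpd_interval(values, cfg.level)
            row[f"{name}_true"] = truth
            row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
            row[f"{name}_hit"] = lo <= truth <= hi
        rows.append(row)

    if n_failures > cfg.max_failure_fraction * n_replicates:
        raise RuntimeError(
            f"{n_failures}/{n_replicates} replicates failed; study invalid"
        )
    table = pd.DataFrame(rows)
    coverage = {
        p: (int(table[f"{p}_hit"].sum()), len(table)) for p in ("lam", "origin")
    }
    return CalibrationResult(table, coverage, n_failures)


# ---------------------------------------------------------------------------
# Posterior-predictive model adequacy
# ---------------------------------------------------------------------------

_STATISTICS: dict[str, Callable[[TimeTree], float]] = {
    "root_height": lambda t: t.root.height,
    "tree_length": lambda t: t.tree_length,
}


@dataclass
class AdequacyReport:
    statistic: str
    observed: float
    simulated: np.ndarray
    p_value: float


def posterior_predictive_check(
    param_draws: Sequence[dict],
    simulate_fn: Callable[[dict, np.random.Generator], Optional[TimeTree]],
    observed_tree: TimeTree,
    statistic: str = "root_height",
    n_sims: int = 100,
    rng: np.random.Generator | None = None,
    retry_cap: int = 100,
) -> AdequacyReport:
    """Two-sided posterior-predictive p-value for a tree statistic.

    For each of ``n_sims`` posterior parameter draws a tree is simulated
    (unsampled attempts are retried up to ``retry_cap``); the p-value is
    ``2 * min(Pr(sim <= obs), Pr(sim >= obs))`` with a +1 continuity
    correction, capped at 1.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if len(param_draws) < n_sims:
        raise ValueError("need at least n_sims posterior draws")
    rng = rng if rng is not None else np.random.default_rng()
    stat = _STATISTICS[statistic]
    obs = stat(observed_tree)
    picks = rng.choice(len(param_draws), size=n_sims, replace=False)
    sims = []
    for i in picks:
        params = param_draws[int(i)]
        tree = None
        for _ in range(retry_cap):
            tree = simulate_fn(params, rng)
            if tree is not None:
                break
        if tree is None:
            raise RuntimeError("simulation produced no samples within retry cap")
        sims.append(stat(tree))
    sims = np.asarray(sims)
    le = (1 + int(np.sum(sims <= obs))) / (n_sims + 1)
    ge = (1 + int(np.sum(sims >= obs))) / (n_sims + 1)
    return AdequacyReport(statistic, obs, sims, min(1.0, 2 * min(le, ge)))
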