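"""Metropolis-Hastings proposal kernels.

Each operator's ``propose`` returns ``(new_state, log_adjustment)`` where
``log_adjustment`` is the log of (Hastings ratio x Jacobian), or ``None``
for an auto-rejected (inapplicable) proposal.  Scale draws are log-uniform,
so the combined adjustment for scaling d coordinates by s is d*log(s).

Tree operators never move a node past its parent or children; sampled
ancestors are degree-2 nodes whose heights equal their sampling times, and
the dedicated :class:`SAToggleOperator` moves them between leaf and
ancestor configurations with the matching dimension bookkeeping.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from ..trees import Node, TimeTree, Taxon
from .state import McmcState

__all__ = [
    "Operator",
    "ScaleOperator",
    "TreeScaleOperator",
    "UniformNodeHeightOperator",
    "TipHeightOperator",
    "ExchangeOperator",
    "WilsonBaldingOperator",
    "SAToggleOperator",
]

Proposal = Optional[tuple[McmcState, float]]


class Operator:
    name = "operator"
    tunable = False

    def __init__(self, weight: float = 1.0):
        if weight <= 0:
            raise ValueError("operator weight must be positive")
        self.weight = weight
        self.n_proposed = 0
        self.n_accepted = 0

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        raise NotImplementedError

    # Robbins-Monro style tuning toward a target acceptance rate
    def tune(self, accepted: bool, step: int) -> None:
        pass

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposed if self.n_proposed else float("nan")


class _TunableScale(Operator):
    tunable = True
    target_acceptance = 0.234

    def __init__(self, weight: float = 1.0, scale_factor: float = 0.75):
        super().__init__(weight)
        # draw s = exp(delta*(2u-1)) with delta = -log(scale_factor)
        self.log_window = -math.log(scale_factor)

    def draw_scale(self, rng: np.random.Generator) -> float:
        return math.exp(self.log_window * (2 * rng.random() - 1))

    def tune(self, accepted: bool, step: int) -> None:
        gain = 1.0 / math.sqrt(10 + step / 50.0)
        self.log_window = float(
            np.clip(
                self.log_window
                + gain * ((1.0 if accepted else 0.0) - self.target_acceptance),
                1e-3,
                10.0,
            )
        )


class ScaleOperator(_TunableScale):
    """Multiplicative random walk on one positive scalar parameter."""

    def __init__(self, key: str, weight: float = 1.0, scale_factor: float = 0.75):
        super().__init__(weight, scale_factor)
        self.key = key
        self.name = f"scale({key})"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        s = self.draw_scale(rng)
        x = state.params[self.key]
        return state.with_param(self.key, x * s), math.log(s)


class TreeScaleOperator(_TunableScale):
    """Scales every internal (non-sample) node height by a common factor."""

    name = "tree_scale"

    def __init__(self, weight: float = 1.0, scale_factor: float = 0.9):
        super().__init__(weight, scale_factor)

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        s = self.draw_scale(rng)
        tree = state.tree.copy()
        scaled = 0
        for node in tree.preorder():
            if node.taxon is None:
                node.height *= s
                scaled += 1
        # reject violated orderings (child above parent, or above origin)
        for node in tree.preorder():
            if node.parent is not None and node.parent.height < node.height:
                return None
        if tree.origin_height is not None and tree.root.height >= tree.origin_height:
            return None
        return state.with_(tree=tree), scaled * math.log(s)


class UniformNodeHeightOperator(Operator):
    """Redraws one bifurcation height uniformly between its neighbours."""

    name = "uniform_height"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        tree = state.tree.copy()
        candidates = [n for n in tree.preorder() if len(n.children) == 2 and n.taxon is None]
        if not candidates:
            return None
        node = candidates[rng.integers(len(candidates))]
        lo = max(c.height for c in node.children)
        if node.parent is not None:
            hi = node.parent.height
        elif tree.origin_height is not None:
            hi = tree.origin_height
        else:
            return None  # root without origin: use TreeScaleOperator instead
        if hi <= lo:
            return None
        node.height = lo + (hi - lo) * rng.random()
        return state.with_(tree=tree), 0.0


class TipHeightOperator(Operator):
    """Redraws a sampled node's time (leaf: U(0, parent); sampled
    ancestor: U(child, parent)).  Used when tip dates are free, e.g. in
    prior-equivalence studies."""

    name = "tip_height"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        tree = state.tree.copy()
        sampled = tree.sampled_nodes
        if not sampled:
            return None
        node = sampled[rng.integers(len(sampled))]
        lo = node.children[0].height if node.children else 0.0
        if node.parent is not None:
            hi = node.parent.height
        elif tree.origin_height is not None:
            hi = tree.origin_height
        else:
            return None
        if hi <= lo:
            return None
        h = lo + (hi - lo) * rng.random()
        node.height = h
        node.taxon = Taxon(node.taxon.label, h)
        return state.with_(tree=tree), 0.0


def _is_ancestor(a: Node, b: Node) -> bool:
    while b is not None:
        if b is a:
            return True
        b = b.parent
    return False


class ExchangeOperator(Operator):
    """Symmetric subtree swap: two non-nested subtrees trade parents."""

    name = "exchange"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        tree = state.tree.copy()
        nodes = [n for n in tree.preorder() if n.parent is not None]
        if len(nodes) < 2:
            return None
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        if a.parent is b.parent:
            return None
        if _is_ancestor(a, b) or _is_ancestor(b, a):
            return None
        if a.parent.height <= b.height or b.parent.height <= a.height:
            return None
        pa, pb = a.parent, b.parent
        ia, ib = pa.children.index(a), pb.children.index(b)
        pa.children[ia], pb.children[ib] = b, a
        a.parent, b.parent = pb, pa
        return state.with_(tree=tree), 0.0


class WilsonBaldingOperator(Operator):
    """Prune a subtree and regraft it onto a uniformly chosen edge.

    The attachment height is uniform on the feasible stretch of the target
    edge; re-attachment above the root uses the origin (when present) or a
    shifted-exponential draw with mean ``root_move_mean``.
    """

    name = "wilson_balding"

    def __init__(self, weight: float = 1.0, root_move_mean: float = 1.0):
        super().__init__(weight)
        self.root_move_mean = root_move_mean

    @staticmethod
    def _prune_candidates(tree: TimeTree) -> list[Node]:
        return [
            n
            for n in tree.preorder()
            if n.parent is not None and len(n.parent.children) == 2
        ]

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        tree = state.tree.copy()
        cands = self._prune_candidates(tree)
        if not cands:
            return None
        node = cands[rng.integers(len(cands))]
        p = node.parent
        sib = p.children[0] if p.children[1] is node else p.children[1]
        g = p.parent

        # reverse-move height density at the current attachment
        lo_old = max(node.height, sib.height)
        if g is not None:
            log_dens_old = -math.log(g.height - lo_old)
        elif tree.origin_height is not None:
            log_dens_old = -math.log(tree.origin_height - lo_old)
        else:
            log_dens_old = (
                -(p.height - lo_old) / self.root_move_mean
                - math.log(self.root_move_mean)
            )

        # detach node (and p); sib takes p's place
        if g is not None:
            gi = g.children.index(p)
            g.children[gi] = sib
            sib.parent = g
        else:
            sib.parent = None
            tree.root = sib

        # target slots: every remaining edge outside the moved subtree,
        # plus the above-root slot
        edges = [
            n
            for n in _subtree_nodes(tree.root)
            if n.parent is not None and not _is_ancestor(node, n)
        ]
        n_slots = len(edges) + 1
        pick = rng.integers(n_slots)
        if pick < len(edges):
            child = edges[pick]
            lo = max(node.height, child.height)
            hi = child.parent.height
            if hi <= lo:
                return None
            h = lo + (hi - lo) * rng.random()
            log_dens_new = -math.log(hi - lo)
            par = child.parent
            ci = par.children.index(child)
            p.children = [node, child]
            node.parent = p
            child.parent = p
            p.height = h
            par.children[ci] = p
            p.parent = par
        else:  # above the root
            lo = max(node.height, tree.root.height)
            if tree.origin_height is not None:
                hi = tree.origin_height
                if hi <= lo:
                    return None
                h = lo + (hi - lo) * rng.random()
                log_dens_new = -math.log(hi - lo)
            else:
                h = lo + rng.exponential(self.root_move_mean)
                log_dens_new = (
                    -(h - lo) / self.root_move_mean - math.log(self.root_move_mean)
                )
            old_root = tree.root
            p.children = [node, old_root]
            node.parent = p
            old_root.parent = p
            p.height = h
            p.parent = None
            tree.root = p

        n_cands_new = len(self._prune_candidates(tree))
        log_adj = (
            math.log(len(cands))
            - math.log(n_cands_new)
            + log_dens_old
            - log_dens_new
        )
        return state.with_(tree=tree), log_adj


def _subtree_nodes(root: Node) -> list[Node]:
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


class SAToggleOperator(Operator):
    """Toggles a sampled node between pendant leaf and sampled ancestor.

    Leaf -> ancestor deletes the attachment bifurcation (one height lost);
    ancestor -> leaf draws a new bifurcation height uniformly between the
    sample time and the node above.  The Hastings ratio is the inverse
    density of that uniform draw.
    """

    name = "sa_toggle"

    def propose(self, state: McmcState, rng: np.random.Generator) -> Proposal:
        tree = state.tree.copy()
        sampled = tree.sampled_nodes
        if not sampled:
            return None
        node = sampled[rng.integers(len(sampled))]
        if node.is_leaf:
            return self._leaf_to_sa(state, tree, node)
        return self._sa_to_leaf(state, tree, node, rng)

    def _leaf_to_sa(self, state: McmcState, tree: TimeTree, node: Node) -> Proposal:
        p = node.parent
        if p is None or len(p.children) != 2 or p.taxon is not None:
            return None
        sib = p.children[0] if p.children[1] is node else p.children[1]
        y = node.height
        if sib.height >= y:
            return None
        g = p.parent
        if g is not None:
            hi = g.height
        elif tree.origin_height is not None:
            hi = tree.origin_height
        else:
            return None
        if y >= hi:
            return None
        # collapse: node becomes a degree-2 ancestor of sib at height y
        if g is not None:
            gi = g.children.index(p)
            g.children[gi] = node
            node.parent = g
        else:
            node.parent = None
            tree.root = node
        node.children = [sib]
        sib.parent = node
        return state.with_(tree=tree), -math.log(hi - y)

    def _sa_to_leaf(
        self, state: McmcState, tree: TimeTree, node: Node, rng: np.random.Generator
    ) -> Proposal:
        child = node.children[0]
        y = node.height
        pa = node.parent
        if pa is not None:
            hi = pa.height
        elif tree.origin_height is not None:
            hi = tree.origin_height
        else:
            return None
        h = y + (hi - y) * rng.random()
        bif = tree.new_node(height=h)
        if pa is not None:
            pi = pa.children.index(node)
            pa.children[pi] = bif
            bif.parent = pa
        else:
            bif.parent = None
            tree.root = bif
        node.children = []
        bif.children = [node, child]
        node.parent = bif
        child.parent = bif
        return state.with_(tree=tree), math.log(hi - y)
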