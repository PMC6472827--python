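"""Shared fixtures: small trees, alignments and RNGs.

All fixtures are generated programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from skytree.alignment import Alignment
from skytree.trees import Node, Taxon, TimeTree


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def build_tree(spec, origin=None) -> TimeTree:
    """Build a TimeTree from a nested (height, children|label) spec.

    Leaves: ("A", height); internal: (height, child, child) or, for a
    sampled ancestor, ("label", height, child).
    """
    counter = [0]

    def rec(node_spec) -> Node:
        counter[0] += 1
        nid = counter[0]
        if len(node_spec) == 2 and isinstance(node_spec[0], str):
            label, h = node_spec
            return Node(nid, h, Taxon(label, h))
        if len(node_spec) == 3 and isinstance(node_spec[0], str):
            label, h, child = node_spec
            node = Node(nid, h, Taxon(label, h))
            node.add_child(rec(child))
            return node
        h = node_spec[0]
        node = Node(nid, h)
        for c in node_spec[1:]:
            node.add_child(rec(c))
        return node

    return TimeTree(rec(spec), origin_height=origin)


@pytest.fixture
def three_taxon_tree() -> TimeTree:
    # ((A:1,B:1):1,C:2);
    return build_tree((2.0, (1.0, ("A", 0.0), ("B", 0.0)), ("C", 0.0)))


@pytest.fixture
def sa_tree() -> TimeTree:
    # B is a sampled ancestor of A at height 1
    return build_tree((2.0, ("B", 1.0, ("A", 0.0)), ("C", 0.0)), origin=3.0)


@pytest.fixture
def small_alignment() -> Alignment:
    taxa = [Taxon("A", 0.0), Taxon("B", 0.0), Taxon("C", 0.0)]
    return Alignment(
        taxa,
        {"A": "ACGTAC", "B": "ACGTAT", "C": "ACGAAT"},
    )
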