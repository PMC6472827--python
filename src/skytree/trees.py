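"""Rooted time trees with sampled ancestors.

Node heights are measured backwards in time from the latest sampled tip
(height 0); an edge's length is ``parent.height - child.height``.  Sampled
ancestors -- samples that are direct ancestors of other samples -- are
degree-2 nodes carrying a taxon.  On disk they are exchanged in the common
zero-length-terminal-branch dialect; internally they stay degree-2.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass
from typing import Iterator, Optional

import dendropy

__all__ = [
    "Taxon",
    "Node",
    "TimeTree",
    "TreeValidationError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "read_trees",
    "write_nexus_trees",
    "tree_statistics",
]

# Pendant branches shorter than this fraction of the root height are decoded
# as sampled-ancestor attachments in the sampled_ancestor dialect.
SA_ZERO_TOL = 1e-10


class TreeValidationError(ValueError):
    pass


class NewickParseError(ValueError):
    pass


@dataclass(frozen=True)
class Taxon:
    """A sampled individual: a label and a sampling time (height >= 0)."""

    label: str
    sampling_time: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sampling_time) or self.sampling_time < 0:
            raise TreeValidationError(
                f"taxon {self.label!r}: sampling_time must be finite and >= 0"
            )


class Node:
    """Tree node. A node carrying a taxon is a sample (leaf or, with one
    child, a sampled ancestor)."""

    __slots__ = ("id", "height", "parent", "children", "taxon")

    def __init__(self, id: int, height: float = 0.0, taxon: Optional[Taxon] = None):
        self.id = id
        self.height = height
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.taxon = taxon

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_sampled_ancestor(self) -> bool:
        return self.taxon is not None and len(self.children) == 1

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        lab = self.taxon.label if self.taxon else ""
        return f"<Node {self.id} h={self.height:.4g} {lab}>"


class TimeTree:
    """A rooted time tree, optionally with an origin above the root."""

    def __init__(
        self,
        root: Node,
        origin_height: Optional[float] = None,
        validate: bool = True,
    ):
        self.root = root
        self.origin_height = origin_height
        self._next_id = 1 + max((n.id for n in self.preorder()), default=-1)
        if validate:
            self.validate()

    # -- iteration ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def nodes(self) -> list[Node]:
        return list(self.preorder())

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def sampled_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if n.taxon is not None]

    @property
    def sampled_ancestors(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_sampled_ancestor]

    @property
    def bifurcations(self) -> list[Node]:
        return [n for n in self.preorder() if len(n.children) == 2]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_leaf)

    @property
    def taxa(self) -> list[Taxon]:
        return [n.taxon for n in self.preorder() if n.taxon is not None]

    def new_node(self, height: float = 0.0, taxon: Optional[Taxon] = None) -> Node:
        node = Node(self._next_id, height, taxon)
        self._next_id += 1
        return node

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        seen_labels: set[str] = set()
        n_roots = 0
        for node in self.preorder():
            if node.parent is None:
                n_roots += 1
            else:
                if node.parent.height < node.height - 1e-12:
                    raise TreeValidationError(
                        f"node {node.id}: parent height {node.parent.height} "
                        f"< child height {node.height}"
                    )
            nc = len(node.children)
            if nc == 0:
                if node.taxon is None:
                    raise TreeValidationError(f"leaf node {node.id} has no taxon")
            elif nc == 1:
                if node.taxon is None:
                    raise TreeValidationError(
                        f"degree-2 node {node.id} carries no taxon "
                        "(only sampled ancestors may have one child)"
                    )
            elif nc == 2:
                if node.taxon is not None:
                    raise TreeValidationError(
                        f"bifurcation node {node.id} must not carry a taxon"
                    )
            else:
                raise TreeValidationError(f"node {node.id} has {nc} children")
            if node.taxon is not None:
                if node.taxon.label in seen_labels:
                    raise TreeValidationError(
                        f"duplicate taxon label {node.taxon.label!r}"
                    )
                seen_labels.add(node.taxon.label)
            if node.is_leaf and abs(node.height - node.taxon.sampling_time) > 1e-9 * max(
                1.0, self.root.height
            ):
                raise TreeValidationError(
                    f"leaf {node.taxon.label!r}: height {node.height} != "
                    f"sampling time {node.taxon.sampling_time}"
                )
            if node.is_sampled_ancestor and abs(
                node.height - node.taxon.sampling_time
            ) > 1e-9 * max(1.0, self.root.height):
                raise TreeValidationError(
                    f"sampled ancestor {node.taxon.label!r}: height mismatch"
                )
        if n_roots != 1:
            raise TreeValidationError(f"{n_roots} roots found")
        if self.origin_height is not None and self.origin_height <= self.root.height:
            raise TreeValidationError(
                f"origin height {self.origin_height} must exceed root height "
                f"{self.root.height}"
            )

    # -- copying -----------------------------------------------------------

    def copy(self) -> "TimeTree":
        mapping: dict[int, Node] = {}

        def rec(node: Node) -> Node:
            clone = Node(node.id, node.height, node.taxon)
            mapping[node.id] = clone
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        new_root = rec(self.root)
        tree = TimeTree(new_root, self.origin_height, validate=False)
        tree._next_id = self._next_id
        return tree

    @property
    def tree_length(self) -> float:
        total = 0.0
        for node in self.preorder():
            if node.parent is not None:
                total += node.parent.height - node.height
        return total

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree {self.n_tips} tips, root height {self.root.height:.4g}>"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(
    text: str,
    dialect: str = "binary",
    taxa: Optional[dict[str, Taxon]] = None,
) -> TimeTree:
    """Parse a Newick string into a :class:`TimeTree`.

    Heights are computed from branch lengths: the deepest tip sits at
    height 0.  With ``dialect="sampled_ancestor"`` a zero-length terminal
    branch hanging off a bifurcation is decoded as a degree-2 sampled
    ancestor.  ``taxa`` optionally maps labels to existing Taxon objects
    (their sampling times then override branch-length-implied tip heights
    only for validation purposes; heights always come from branch lengths).
    """
    if dialect not in ("binary", "sampled_ancestor"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    # depth from root in time units
    counter = [0]

    def build(dnode, depth: float) -> tuple[Node, float]:
        node = Node(counter[0], 0.0)
        counter[0] += 1
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        max_depth = depth
        for dchild in dnode.child_nodes():
            bl = dchild.edge.length
            if bl is None:
                bl = 0.0
            if bl < 0:
                raise TreeValidationError(f"negative branch length {bl}")
            child, d = build(dchild, depth + bl)
            node.add_child(child)
            max_depth = max(max_depth, d)
        if not dnode.child_nodes():
            if label is None:
                raise NewickParseError("unlabelled leaf")
            node.taxon = Taxon(label, 0.0)  # placeholder sampling time
        elif label is not None:
            node.taxon = Taxon(label, 0.0)
        node.height = -depth  # temporary: negative depth, rebased below
        return node, max_depth

    root, max_depth = build(dtree.seed_node, 0.0)

    nodes = []
    stack = [root]
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(n.children)
    for n in nodes:
        n.height = max_depth + n.height  # height = max_depth - depth
        if n.height < 0 and n.height > -1e-12:
            n.height = 0.0

    root_height = root.height
    if dialect == "sampled_ancestor":
        tol = SA_ZERO_TOL * max(root_height, 1e-30)
        for n in list(nodes):
            if (
                n.is_leaf
                and n.parent is not None
                and len(n.parent.children) == 2
                and n.parent.taxon is None
                and (n.parent.height - n.height) <= tol
            ):
                parent = n.parent
                parent.remove_child(n)
                parent.taxon = n.taxon
                nodes.remove(n)

    for n in nodes:
        if n.taxon is not None:
            if taxa is not None and n.taxon.label in taxa:
                n.taxon = taxa[n.taxon.label]
            else:
                n.taxon = Taxon(n.taxon.label, n.height)

    return TimeTree(root, validate=True)


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _newick_rec(node: Node, parent_height: Optional[float], out: io.StringIO) -> None:
    if node.is_sampled_ancestor:
        # serialize as a zero-length terminal branch on a fake bifurcation
        out.write("(")
        _newick_rec(node.children[0], node.height, out)
        out.write(f",{_quote(node.taxon.label)}:0.0)")
    elif node.is_leaf:
        out.write(_quote(node.taxon.label))
    else:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _newick_rec(child, node.height, out)
        out.write(")")
    if parent_height is not None:
        out.write(f":{parent_height - node.height:.12g}")


def write_newick(tree: TimeTree) -> str:
    """Serialize to Newick; sampled ancestors become zero-length tips."""
    out = io.StringIO()
    if tree.root.is_leaf:
        out.write(f"{_quote(tree.root.taxon.label)}:0.0")
    else:
        _newick_rec(tree.root, None, out)
    out.write(";")
    return out.getvalue()


def read_trees(path: str, dialect: str = "sampled_ancestor") -> list[TimeTree]:
    """Read Newick or NEXUS (sniffed) tree files into TimeTrees."""
    with open(path) as fh:
        head = fh.read(6)
    schema = "nexus" if head.lower().startswith("#nexus") else "newick"
    dtrees = dendropy.TreeList.get(path=path, schema=schema)
    return [parse_newick(t.as_string(schema="newick"), dialect=dialect) for t in dtrees]


def write_nexus_trees(trees: list[TimeTree], path: str) -> None:
    """Write a NEXUS tree file with a Translate block.

    Sampled ancestors use the zero-length-terminal-branch dialect (noted in
    the file header).
    """
    labels = sorted({t.label for tree in trees for t in tree.taxa})
    index = {lab: i + 1 for i, lab in enumerate(labels)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write(
            "[sampled ancestors encoded as zero-length terminal branches]\n"
        )
        fh.write("Begin taxa;\n")
        fh.write(f"    Dimensions ntax={len(labels)};\n    Taxlabels\n")
        for lab in labels:
            fh.write(f"        {_quote(lab)}\n")
        fh.write("        ;\nEnd;\n")
        fh.write("Begin trees;\n    Translate\n")
        fh.write(
            ",\n".join(f"        {index[lab]} {_quote(lab)}" for lab in labels)
        )
        fh.write("\n        ;\n")
        for i, tree in enumerate(trees):
            nwk = write_newick(tree)
            for lab in sorted(index, key=len, reverse=True):
                nwk = re.sub(
                    rf"(?<![A-Za-z0-9_.|+-]){re.escape(lab)}(?=:)",
                    str(index[lab]),
                    nwk,
                )
            fh.write(f"tree STATE_{i} = {nwk}\n")
        fh.write("End;\n")


def tree_statistics(tree: TimeTree) -> dict:
    """Root height, optional origin height, tree length and node counts."""
    stats = {
        "root_height": tree.root.height,
        "tree_length": tree.tree_length,
        "n_tips": tree.n_tips,
        "n_sampled_ancestors": len(tree.sampled_ancestors),
    }
    if tree.origin_height is not None:
        stats["origin_height"] = tree.origin_height
    return stats
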