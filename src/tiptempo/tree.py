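"""Rooted phylogenetic trees with genetic-distance branch lengths.

The tree model is deliberately small: nodes with a parent pointer, a list of
children, a branch length (substitutions/site) on the edge to the parent, and
an optional label. Branch lengths are genetic distances, not time — this is a
"non-clock" tree as produced by neighbour-joining, maximum-likelihood or
Bayesian inference. Everything downstream (root-to-tip regression, best-root
search) is built on two primitives defined here: root-to-tip distances, and
rerooting at an arbitrary point along an edge while preserving the unrooted
metric.

Conventions used throughout the package:

* an edge is identified by its *child* node;
* a fractional position along an edge is measured from the *parent* end,
  so fraction 0 is the parent and fraction 1 is the child;
* rerooting never leaves a degree-2 node behind: the old root, if reduced
  to a single child, is suppressed by fusing its two incident edges.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional

import dendropy

from .errors import (
    DuplicateTipLabelError,
    NegativeBranchLengthError,
    NewickParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "RootPlacement",
    "read_newick",
    "write_newick",
    "reroot",
    "root_to_tip_distances",
]


@dataclass(eq=False)
class Node:
    """A node of a rooted tree.

    ``length`` is the branch length (substitutions/site) of the edge to
    ``parent``; it is 0.0 for the root.
    """

    label: Optional[str] = None
    length: float = 0.0
    parent: Optional["Node"] = None
    children: List["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class PhyloTree:
    """A rooted tree with uniquely-labelled tips and non-negative lengths.

    Polytomies are first-class: no arbitrary resolution is ever performed.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- structure ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        """Yield nodes in preorder (root first, children in stored order)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    @property
    def tips(self) -> List[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> List[str]:
        return [t.label for t in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def edges(self) -> List[Node]:
        """All edges of the tree, each identified by its child node, in
        preorder. The root has no parent edge and is excluded."""
        return [n for n in self.preorder() if n.parent is not None]

    def _validate(self) -> None:
        seen: Dict[str, int] = {}
        for node in self.preorder():
            if node.is_leaf:
                if not node.label:
                    raise DuplicateTipLabelError("tip with empty label")
                seen[node.label] = seen.get(node.label, 0) + 1
            if node.parent is not None:
                if not (node.length >= 0.0) or node.length != node.length:
                    raise NegativeBranchLengthError(
                        f"edge above {_describe(node)} has invalid length "
                        f"{node.length!r}"
                    )
        dups = sorted(lbl for lbl, k in seen.items() if k > 1)
        if dups:
            raise DuplicateTipLabelError(
                "duplicate tip label(s): " + ", ".join(dups)
            )

    # -- metric ------------------------------------------------------------

    def depths(self) -> Dict[Node, float]:
        """Distance from the root to every node (sum of branch lengths)."""
        out: Dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + node.length
        return out

    def tip_tip_distances(self) -> Dict[frozenset, float]:
        """Unrooted path length between every pair of tips.

        Quadratic-time utility (ancestor-chain walk per pair); intended for
        validation and tests, not for large production trees.
        """
        depths = self.depths()
        chains: Dict[Node, Dict[Node, float]] = {}
        for tip in self.tips:
            chain: Dict[Node, float] = {}
            node: Optional[Node] = tip
            while node is not None:
                chain[node] = depths[node]
                node = node.parent
            chains[tip] = chain
        tips = self.tips
        out: Dict[frozenset, float] = {}
        for i, a in enumerate(tips):
            for b in tips[i + 1:]:
                # deepest shared ancestor
                mrca_depth = max(
                    d for n, d in chains[a].items() if n in chains[b]
                )
                out[frozenset((a.label, b.label))] = (
                    depths[a] + depths[b] - 2.0 * mrca_depth
                )
        return out

    def copy(self) -> "PhyloTree":
        """Deep structural copy; node objects are fresh."""
        mapping: Dict[Node, Node] = {}
        for node in self.preorder():
            clone = Node(label=node.label, length=node.length)
            mapping[node] = clone
            if node.parent is not None:
                parent = mapping[node.parent]
                clone.parent = parent
                parent.children.append(clone)
        return PhyloTree(mapping[self.root])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


@dataclass(frozen=True)
class RootPlacement:
    """A candidate root position: an edge (identified by its child node)
    plus a fraction in [0, 1] measured from the PARENT end of that edge."""

    child: Node
    fraction: float

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.child.parent is None:
            raise ValueError("placement edge must not be the root node")


# ---------------------------------------------------------------------------
# newick I/O (parsing delegated to dendropy)
# ---------------------------------------------------------------------------

def read_newick(text: str, clamp_negative: bool = False) -> PhyloTree:
    """Parse a single newick tree description into a :class:`PhyloTree`.

    Quoted labels, scientific-notation branch lengths and polytomies are
    accepted; internal node labels (e.g. support values) are preserved but
    unused. Missing branch lengths are treated as 0 with a warning. Negative
    branch lengths are rejected unless ``clamp_negative`` is set, in which
    case they are clamped to 0 with a warning.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"newick description must end with ';' (ended at character "
            f"{len(stripped)} with {stripped[-1:]!r})"
        )
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy reader errors carry line/column
        raise NewickParseError(f"malformed newick: {exc}") from exc

    def convert_one(dnode, parent: Optional[Node]) -> Node:
        length = dnode.edge.length
        label = dnode.label
        if parent is not None and length is None:
            logger.warning(
                "missing branch length above %r treated as 0",
                label if label else "(unnamed node)",
            )
            length = 0.0
        if parent is None:
            length = 0.0
        if length < 0.0:
            if clamp_negative:
                logger.warning(
                    "negative branch length %g above %r clamped to 0",
                    length, label,
                )
                length = 0.0
            else:
                raise NegativeBranchLengthError(
                    f"edge above {label!r} has negative length {length}; "
                    "pass clamp_negative to clamp to 0"
                )
        node = Node(label=label, length=float(length), parent=parent)
        if parent is not None:
            parent.children.append(node)
        return node

    root = convert_one(dtree.seed_node, None)
    stack = [(c, root) for c in reversed(dtree.seed_node.child_nodes())]
    while stack:
        dnode, parent = stack.pop()
        node = convert_one(dnode, parent)
        stack.extend((c, node) for c in reversed(dnode.child_nodes()))
    return PhyloTree(root)


_UNQUOTED_OK = re.compile(r"^[^\s()\[\]{}/\\,;:=*'\"`<>+-]+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to newick with full double precision lengths.

    ``read_newick(write_newick(t))`` reproduces topology, labels and branch
    lengths exactly (lengths are printed with repr, ≥ 17 significant digits).
    """
    buf = io.StringIO()

    def tail(node: Node) -> str:
        out = ""
        if node.children:
            out += ")"
        if node.label:
            out += _format_label(node.label)
        if node.parent is not None:
            out += ":" + repr(node.length)
        return out

    # iterative two-phase traversal (enter/exit) to handle deep trees
    stack = [("exit", tree.root), ("enter", tree.root)]
    while stack:
        phase, node = stack.pop()
        if phase == "enter":
            if node.children:
                buf.write("(")
                for i, child in enumerate(reversed(node.children)):
                    stack.append(("exit", child))
                    stack.append(("enter", child))
                    if i < len(node.children) - 1:
                        stack.append(("comma", child))
        elif phase == "comma":
            buf.write(",")
        else:
            buf.write(tail(node))
    buf.write(";")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# rerooting
# ---------------------------------------------------------------------------

def _reverse_path_to_root(node: Node) -> None:
    """Make ``node`` parentless by reversing all parent pointers on the path
    from ``node`` to the current root. Branch lengths travel with the edge."""
    path = []
    cur: Optional[Node] = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    # path = [node, ..., old_root]; edge (lower, upper) has length stored on
    # lower — snapshot lengths before any flip overwrites them
    lengths = [n.length for n in path]
    for (lower, upper), length in zip(zip(path, path[1:]), lengths):
        upper.children.remove(lower)
        upper.parent = lower
        upper.length = length
        lower.children.append(upper)
    node.parent = None
    node.length = 0.0


def _suppress_if_degree_two(node: Node) -> None:
    """Fuse the edges around an internal non-root node left with exactly one
    child (summing lengths). The old root after rerooting is the one caller."""
    if node.parent is not None and node.is_leaf and node.label is None:
        # an old root that had a single child is left as an unlabelled leaf
        node.parent.children.remove(node)
        node.parent = None
        return
    if node.parent is None or node.is_leaf or len(node.children) != 1:
        return
    child = node.children[0]
    parent = node.parent
    idx = parent.children.index(node)
    child.length += node.length
    child.parent = parent
    parent.children[idx] = child
    node.children = []
    node.parent = None


def reroot(tree: PhyloTree, placement: RootPlacement) -> PhyloTree:
    """Return a NEW tree rooted at ``placement`` (the input is not mutated).

    The root is a node splitting the placement edge at ``fraction`` × length
    from the parent end. All tip-tip path lengths are preserved exactly. If
    the fraction is exactly 0 (or 1 on an internal edge) the root is placed
    at the existing parent (child) node and no zero-length edge is created.
    A former root left with a single child is suppressed.

    Placing the root at the far end of a terminal edge (fraction 1 with a
    leaf child) keeps a zero-length pendant edge so the tip remains a tip.
    """
    # work on a copy; locate the placement edge by preorder index
    edges = tree.edges()
    try:
        edge_index = edges.index(placement.child)
    except ValueError:
        raise ValueError("placement edge does not belong to this tree")
    new_tree = tree.copy()
    child = new_tree.edges()[edge_index]
    parent = child.parent
    b = child.length
    x = placement.fraction
    old_root = new_tree.root

    if x == 0.0 or b == 0.0:
        new_root = parent
        if new_root is old_root:
            return new_tree
        _reverse_path_to_root(new_root)
    elif x == 1.0 and not child.is_leaf:
        new_root = child
        _reverse_path_to_root(new_root)
    else:
        # split the edge: parent --(x*b)-- R --((1-x)*b)-- child
        mid = Node(label=None)
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.length = x * b
        child.parent = mid
        child.length = (1.0 - x) * b
        mid.children.append(child)
        new_root = mid
        _reverse_path_to_root(new_root)

    _suppress_if_degree_two(old_root)
    return PhyloTree(new_root)


def root_to_tip_distances(tree: PhyloTree) -> Dict[str, float]:
    """Sum of branch lengths on the unique root-to-tip path, per tip label."""
    depths = tree.depths()
    return {tip.label: depths[tip] for tip in tree.tips}


def _describe(node: Node) -> str:
    if node.label:
        return f"node {node.label!r}"
    tips = []
    stack = [node]
    while stack and len(tips) < 3:
        n = stack.pop()
        if n.is_leaf:
            tips.append(n.label)
        else:
            stack.extend(n.children)
    return "internal node above tips " + ", ".join(map(str, tips))
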