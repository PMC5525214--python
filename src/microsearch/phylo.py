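"""Reference phylogeny: parsing, indexing and the level-wise structure.

The sparse EMD-UniFrac kernel traverses the tree strictly level by level
(deepest first), so the tree is stored with an explicit per-node depth
level and a list of node-id sets, one per level.  Trees may be
multifurcating; branch lengths are in the tree's own units and the root
carries no parent branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import skbio

from microsearch.errors import NewickParseError

__all__ = ["PhyloNode", "PhyloTree", "parse_newick"]


@dataclass
class PhyloNode:
    """One node of the phylogeny.

    ``length`` is the branch length to the parent (0.0 for the root,
    which has no parent branch and never contributes to distances).
    """

    id: int
    parent: int | None
    length: float
    children: list[int] = field(default_factory=list)
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted phylogeny with branch lengths, leaf index and depth levels.

    Attributes
    ----------
    nodes : list of PhyloNode
        Indexed by node id; ``nodes[root]`` is the root.
    leaf_index : dict
        Leaf label -> node id (labels are opaque strings).
    levels : list of set of int
        ``levels[d]`` holds the ids of all nodes at depth ``d``
        (root = level 0).  The sets partition the node ids.
    n_leaves : int
        Number of leaves (the dimensionality L of the abundance space).
    """

    def __init__(self, nodes: list[PhyloNode], root: int):
        self.nodes = nodes
        self.root = root
        self.leaf_index: dict[str, int] = {}
        self.level_of = [0] * len(nodes)
        # BFS to assign levels; also validates single-rootedness.
        order = [root]
        seen = {root}
        for nid in order:
            for cid in nodes[nid].children:
                self.level_of[cid] = self.level_of[nid] + 1
                order.append(cid)
                seen.add(cid)
        if len(seen) != len(nodes):
            raise NewickParseError("tree is not connected from the root")
        self.n_levels = max(self.level_of) + 1
        self.levels: list[set[int]] = [set() for _ in range(self.n_levels)]
        for nid, lev in enumerate(self.level_of):
            self.levels[lev].add(nid)
        for node in nodes:
            if node.is_leaf:
                if node.label is None:
                    raise NewickParseError(f"leaf node {node.id} has no label")
                if node.label in self.leaf_index:
                    raise NewickParseError(
                        f"duplicate leaf label {node.label!r}"
                    )
                self.leaf_index[node.label] = node.id
        self.n_leaves = len(self.leaf_index)

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestor_path(self, leaf: str) -> list[int]:
        """Node ids from ``leaf`` up to the root, inclusive.

        Raises KeyError for an unknown leaf label.
        """
        if leaf not in self.leaf_index:
            raise KeyError(f"unknown leaf label {leaf!r}")
        path = [self.leaf_index[leaf]]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def leaf_labels(self) -> list[str]:
        return sorted(self.leaf_index)

    def to_newick(self) -> str:
        """Serialize with branch lengths (17 significant digits)."""

        def fmt(nid: int) -> str:
            node = self.nodes[nid]
            label = node.label or ""
            if node.is_leaf:
                body = label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){label}"
            if node.parent is None:
                return body
            return f"{body}:{node.length:.17g}"

        return fmt(self.root) + ";"


def _prevalidate(text: str) -> None:
    """Structural checks with positions, ahead of the real parser."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at position {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of input"
        )
    stripped = text.rstrip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"missing terminal ';' (input ends at position {len(stripped)})"
        )


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Branch lengths are required on all non-root nodes; a root length, if
    present, is accepted and ignored.  Internal labels are optional.
    Multifurcations are allowed.

    Raises
    ------
    NewickParseError
        On unbalanced parentheses, a missing terminal semicolon, or
        duplicate leaf labels; the message names the offending position
        or label.
    """
    _prevalidate(text)
    try:
        sk_tree = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises several parse error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc

    nodes: list[PhyloNode] = []

    def build(sk_node, parent_id: int | None) -> int:
        nid = len(nodes)
        length = sk_node.length if sk_node.length is not None else 0.0
        if length < 0:
            raise NewickParseError(
                f"negative branch length {length} at node {sk_node.name!r}"
            )
        nodes.append(PhyloNode(nid, parent_id, float(length), [], sk_node.name))
        for child in sk_node.children:
            cid = build(child, nid)
            nodes[nid].children.append(cid)
        return nid

    root = build(sk_tree, None)
    return PhyloTree(nodes, root)
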