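"""Balance diagnostics for sampled phylogenies.

The Colless imbalance index of a rooted, strictly bifurcating tree is

    C = sum over internal nodes v of |L(v) - R(v)|

where L and R count the leaves in the two child subtrees.  C is 0 for a
perfectly balanced tree and (n-1)(n-2)/2 for a caterpillar; lower values
indicate that the sampled taxa spread more evenly over the clade.  The index
is purely topological and ignores branch lengths.

Node-depth summaries (root-to-internal-node path lengths, in branch-length
units) complement it: a sample that covers the deep diversity of a clade
yields many short depths near the root rather than a few long ones.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError
from .taxonomy_io import PhyloTree, TreeNode


def _leaf_counts(tree: PhyloTree) -> dict[int, int]:
    """Leaf count per node (postorder, iterative)."""
    counts: dict[int, int] = {}
    stack: list[tuple[TreeNode, bool]] = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf:
            counts[id(node)] = 1
        elif not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
    return counts


def _node_name(node: TreeNode) -> str:
    if node.label:
        return node.label
    leaves = []
    stack = [node]
    while stack and len(leaves) < 3:
        n = stack.pop()
        if n.is_leaf:
            leaves.append(n.label)
        else:
            stack.extend(reversed(n.children))
    return "node above {" + ", ".join(leaves) + ", ...}"


def colless_index(tree: PhyloTree) -> int:
    """Colless imbalance index of a rooted strictly bifurcating tree.

    Raises :class:`BalanceError` identifying the first polytomy or unary
    internal node encountered.
    """
    counts = _leaf_counts(tree)
    total = 0
    for node in tree.iter_nodes():
        if node.is_leaf:
            continue
        if len(node.children) != 2:
            kind = "unary node" if len(node.children) == 1 else "polytomy"
            raise BalanceError(
                f"{kind} ({len(node.children)} children) at {_node_name(node)}; "
                "the Colless index is defined for strictly bifurcating trees"
            )
        left, right = node.children
        total += abs(counts[id(left)] - counts[id(right)])
    return total


def resolve_polytomies(tree: PhyloTree) -> PhyloTree:
    """Deterministically resolve polytomies with zero-length branches.

    Children are folded in input order: (c1, c2, c3, ...) becomes
    ((c1, c2), c3), ...  This alters the Colless index relative to any other
    resolution and is intended only to make taxonomy-derived (multifurcating)
    trees comparable.
    """
    work = tree.copy()
    for node in list(work.iter_nodes()):
        while len(node.children) > 2:
            first, second = node.children[0], node.children[1]
            joint = TreeNode(None, 0.0)
            joint.add_child(first)
            joint.add_child(second)
            node.children[0] = joint
            joint.parent = node
            node.children.remove(second)
    return work


@dataclass
class NodeDepths:
    """Root-to-internal-node path lengths (root itself excluded)."""

    values: np.ndarray

    @property
    def min(self) -> float:
        return float(self.values.min()) if self.values.size else float("nan")

    @property
    def max(self) -> float:
        return float(self.values.max()) if self.values.size else float("nan")

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else float("nan")


def node_depths(tree: PhyloTree) -> NodeDepths:
    """Depths (branch-length units) of all non-root internal nodes."""
    depths = []
    stack: list[tuple[TreeNode, float]] = [(tree.root, 0.0)]
    while stack:
        node, depth = stack.pop()
        if not node.is_leaf and node.parent is not None:
            depths.append(depth)
        for c in node.children:
            stack.append((c, depth + (c.length or 0.0)))
    return NodeDepths(np.array(sorted(depths), dtype=float))


@dataclass
class BalanceReport:
    """Colless index plus the per-node imbalance table and depth summary."""

    colless: int
    leaf_count: int
    node_table: pd.DataFrame  # columns: node, left, right
    depths: NodeDepths


def balance_report(tree: PhyloTree) -> BalanceReport:
    counts = _leaf_counts(tree)
    rows = []
    for node in tree.iter_nodes():
        if node.is_leaf:
            continue
        if len(node.children) != 2:
            raise BalanceError(
                f"non-bifurcating node at {_node_name(node)}; "
                "resolve polytomies first"
            )
        left, right = node.children
        rows.append(
            {
                "node": _node_name(node),
                "left": counts[id(left)],
                "right": counts[id(right)],
            }
        )
    table = pd.DataFrame(rows, columns=["node", "left", "right"])
    colless = int((table["left"] - table["right"]).abs().sum())
    return BalanceReport(
        colless=colless,
        leaf_count=tree.leaf_count(),
        node_table=table,
        depths=node_depths(tree),
    )
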