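"""Diversity-preserving tree pruning.

A large phylogeny is reduced to a target leaf count by repeatedly locating
the *cherry* (sibling leaf pair) with the smallest pendant-distance sum and
deleting one of its two leaves, under a configurable keep policy:

* ``keep_shortest`` (default) removes the leaf with the longer pendant
  branch, discarding fast-evolving lineages that promote artifacts such as
  long-branch attraction;
* ``keep_longest`` is the mirror; ``random`` flips a fair coin.

The expensive part of this procedure is the distance bookkeeping.  Because
deleting a leaf only ever creates new cherries around the surviving sibling
(when the unary parent is suppressed and the survivor is itself a leaf),
it suffices to compute distances once up front and then only for each newly
formed leaf pair — a lazily invalidated min-heap (:class:`CherryQueue`)
makes each step O(log m).  ``prune_tree_naive`` recomputes the full cherry
list every iteration and serves as the reference implementation; both share
the same tie rules, so their outputs are identical for a shared seed.

Tie rules (fixed for reproducibility): equal cherry distances are broken by
lexicographic (min leaf name, max leaf name); equal pendant lengths within a
cherry remove the lexicographically later leaf.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .errors import PruneError, PruneExhaustedError
from .taxonomy_io import PhyloTree, TreeNode

POLICIES = ("keep_shortest", "keep_longest", "random")


@dataclass
class PruneStats:
    """Instrumentation: how many pendant-distance computations were performed."""

    distance_computations: int = 0
    removals: int = 0


def list_cherries(tree: PhyloTree, stats: Optional[PruneStats] = None):
    """All sibling leaf pairs as (leafA, leafB, distance), sorted by (distance, names).

    A multifurcating node with k leaf children contributes all k(k-1)/2
    pairs.  Non-sibling leaf pairs are never candidates.
    """
    pairs = tree.cherries()
    if stats is not None:
        stats.distance_computations += len(pairs)
    return pairs


class CherryQueue:
    """Min-heap of (distance, leafA, leafB) with lazy invalidation.

    Entries whose leaves have been removed from the tree are discarded when
    popped rather than rekeyed in place; tuple ordering gives the
    (distance, then lexicographic pair) pop order for free.
    """

    def __init__(self):
        self._heap: list[tuple[float, str, str]] = []

    @classmethod
    def from_tree(cls, tree: PhyloTree, stats: Optional[PruneStats] = None) -> "CherryQueue":
        q = cls()
        for a, b, d in list_cherries(tree, stats):
            heapq.heappush(q._heap, (d, a, b))
        return q

    def push(self, distance: float, leaf_a: str, leaf_b: str) -> None:
        if leaf_b < leaf_a:
            leaf_a, leaf_b = leaf_b, leaf_a
        heapq.heappush(self._heap, (distance, leaf_a, leaf_b))

    def pop_live(self, tree: PhyloTree) -> Optional[tuple[float, str, str]]:
        """Pop the minimum entry whose leaves are both still in the tree."""
        while self._heap:
            d, a, b = heapq.heappop(self._heap)
            if tree.has_leaf(a) and tree.has_leaf(b):
                return d, a, b
        return None

    def __len__(self):
        return len(self._heap)


def select_removal(
    tree: PhyloTree,
    leaf_a: str,
    leaf_b: str,
    policy: str,
    protected: frozenset[str] = frozenset(),
    rng: Optional[np.random.Generator] = None,
) -> Optional[str]:
    """Pick which member of a live cherry to remove, or None if both protected.

    ``keep_shortest`` removes the leaf with the longer pendant branch;
    ``keep_longest`` the shorter; ``random`` removes either with probability
    1/2 (a single rng draw, taken only when neither leaf is protected).
    A protected leaf is never returned.
    """
    if policy not in POLICIES:
        raise PruneError(f"unknown keep policy {policy!r}")
    a_prot, b_prot = leaf_a in protected, leaf_b in protected
    if a_prot and b_prot:
        return None
    if a_prot:
        return leaf_b
    if b_prot:
        return leaf_a
    if policy == "random":
        if rng is None:
            raise PruneError("random policy requires an rng")
        return leaf_a if int(rng.integers(2)) == 0 else leaf_b
    la = tree.leaf(leaf_a).length or 0.0
    lb = tree.leaf(leaf_b).length or 0.0
    if la == lb:
        return max(leaf_a, leaf_b)  # tie: remove the lexicographically later leaf
    longer = leaf_a if la > lb else leaf_b
    shorter = leaf_b if la > lb else leaf_a
    return longer if policy == "keep_shortest" else shorter


def prune_step(
    tree: PhyloTree,
    queue: CherryQueue,
    policy: str,
    protected: frozenset[str] = frozenset(),
    rng: Optional[np.random.Generator] = None,
    stats: Optional[PruneStats] = None,
) -> str:
    """Remove one leaf from the minimum live eligible cherry; returns its label.

    After removal the unary parent is suppressed (the surviving child's
    branch absorbs the suppressed branch).  If the survivor is a leaf that
    gained new leaf siblings, exactly those pair distances are computed and
    pushed; nothing else is recomputed.  Raises
    :class:`PruneExhaustedError` when every remaining cherry is fully
    protected.
    """
    while True:
        entry = queue.pop_live(tree)
        if entry is None:
            raise PruneExhaustedError("no eligible cherry remains")
        _, a, b = entry
        victim = select_removal(tree, a, b, policy, protected, rng)
        if victim is None:
            continue  # both protected: this cherry can never be pruned
        moved = tree.remove_leaf(victim)
        if stats is not None:
            stats.removals += 1
        if moved is not None and moved.is_leaf and moved.parent is not None:
            for sib in moved.parent.children:
                if sib is not moved and sib.is_leaf:
                    d = (moved.length or 0.0) + (sib.length or 0.0)
                    if stats is not None:
                        stats.distance_computations += 1
                    queue.push(d, moved.label, sib.label)
        return victim


def _prepare(
    tree: PhyloTree,
    target: int,
    protected: Iterable[str],
    restrict_taxon: Union[None, str, Iterable[str]],
) -> tuple[PhyloTree, frozenset[str], bool]:
    """Shared preconditions for both pruners.

    Returns (working copy, protected set, whether pruning should proceed);
    a target above the current leaf count is a warning, not an error.
    """
    if restrict_taxon is not None:
        if isinstance(restrict_taxon, str):
            work = tree.extract_clade(restrict_taxon)
        else:
            work = tree.extract_subtree(restrict_taxon)
    else:
        work = tree.copy()
    protected = frozenset(protected)
    unknown = protected - work.leaf_labels()
    if unknown:
        raise PruneError(f"protected leaves not in tree: {sorted(unknown)}")
    if target < 2:
        raise PruneError(f"target leaf count must be >= 2, got {target}")
    if target < len(protected):
        raise PruneError(
            f"target {target} is smaller than the protected set ({len(protected)})"
        )
    if target > work.leaf_count():
        warnings.warn(
            f"target {target} exceeds the current leaf count "
            f"({work.leaf_count()}); tree returned unchanged",
            stacklevel=3,
        )
        return work, protected, False
    return work, protected, True


def prune_tree(
    tree: PhyloTree,
    target: int,
    policy: str = "keep_shortest",
    protected: Iterable[str] = (),
    restrict_taxon: Union[None, str, Iterable[str]] = None,
    seed: Optional[int] = None,
    stats: Optional[PruneStats] = None,
) -> PhyloTree:
    """Prune a tree down to ``target`` leaves with incremental distance updates.

    If ``restrict_taxon`` names an internal clade label (str) or a leaf set,
    the minimal subtree spanning it is extracted first and only that part is
    pruned.  The input tree is never modified.  Deterministic given the seed.
    """
    if policy not in POLICIES:
        raise PruneError(f"unknown keep policy {policy!r}")
    work, protected, proceed = _prepare(tree, target, protected, restrict_taxon)
    if not proceed:
        return work
    rng = np.random.default_rng(seed)
    queue = CherryQueue.from_tree(work, stats)
    while work.leaf_count() > target:
        prune_step(work, queue, policy, protected, rng, stats)
    return work


def prune_tree_naive(
    tree: PhyloTree,
    target: int,
    policy: str = "keep_shortest",
    protected: Iterable[str] = (),
    restrict_taxon: Union[None, str, Iterable[str]] = None,
    seed: Optional[int] = None,
    stats: Optional[PruneStats] = None,
) -> PhyloTree:
    """Reference pruner: recomputes the full cherry list every iteration.

    Contract and tie rules are identical to :func:`prune_tree`; used as the
    oracle in equivalence tests and for measuring the distance-computation
    saving of the incremental queue.
    """
    if policy not in POLICIES:
        raise PruneError(f"unknown keep policy {policy!r}")
    work, protected, proceed = _prepare(tree, target, protected, restrict_taxon)
    if not proceed:
        return work
    rng = np.random.default_rng(seed)
    while work.leaf_count() > target:
        removed = None
        for a, b, _ in list_cherries(work, stats):
            victim = select_removal(work, a, b, policy, protected, rng)
            if victim is not None:
                work.remove_leaf(victim)
                if stats is not None:
                    stats.removals += 1
                removed = victim
                break
        if removed is None:
            raise PruneExhaustedError("no eligible cherry remains")
    return work
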