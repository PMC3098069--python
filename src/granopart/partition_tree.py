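"""Granular partitions as rooted trees with cuts.

A granularity tree is built from an ordered (coarse-to-fine) list of
partitions of one whole.  Instances that pass unchanged through several
successive cuts are stored once, at their shallowest depth; cut
enumeration re-inserts such pass-through leaves into every deeper cut, so
the enumerated levels reproduce the original partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import EntityKind, Partonomy, closure_pairs
from .errors import PartitionError, ReferenceError_


@dataclass
class GranularityTree:
    """Rooted tree of a granular partition.

    ``children`` maps each node to its ordered children; ``depth_of`` gives
    the 1-based depth (root = 1); ``depth`` is the total number of cuts.
    """

    root: str
    children: dict[str, tuple[str, ...]] = field(default_factory=dict)
    depth_of: dict[str, int] = field(default_factory=dict)
    depth: int = 1

    @property
    def nodes(self) -> list[str]:
        return sorted(self.depth_of)

    def parent_of(self, node: str) -> str | None:
        for parent, kids in self.children.items():
            if node in kids:
                return parent
        return None

    def is_leaf(self, node: str) -> bool:
        return not self.children.get(node)


@dataclass(frozen=True)
class InstanceLevel:
    """A cut through a granularity tree; index 1 is the finest cut."""

    index: int
    content: frozenset[str]

    def __post_init__(self):
        if not self.content:
            raise PartitionError(f"level {self.index} has empty content")


def build_granularity_tree(
    whole: str,
    partitions: Sequence[Iterable[str]],
    p: Partonomy,
) -> GranularityTree:
    """Assemble a granularity tree from coarse-to-fine partitions of ``whole``.

    Every member of every partition must be a proper part of the whole, and
    each finer partition must refine its predecessor: each member is either
    carried over unchanged or is a proper part of exactly one member of the
    coarser partition (partial overlap is rejected).
    """
    closed = closure_pairs(p)
    whole_parts = {c for (c, w) in closed if w == whole}
    if whole not in p.instances:
        raise ReferenceError_(f"unknown whole {whole!r}")

    tree = GranularityTree(root=whole)
    tree.depth_of[whole] = 1
    tree.children[whole] = ()
    current_cut: list[str] = [whole]

    for k, raw in enumerate(partitions, start=1):
        cut = list(raw)
        if len(set(cut)) != len(cut):
            raise PartitionError(f"partition {k} lists a member twice")
        assigned: dict[str, str] = {}
        for member in cut:
            if member not in p.instances:
                raise ReferenceError_(f"partition {k}: unknown instance {member!r}")
            if member not in whole_parts:
                raise ReferenceError_(
                    f"partition {k}: {member!r} is not a proper part of {whole!r}"
                )
            if member in tree.depth_of:
                # pass-through: the same instance re-listed in a finer cut
                continue
            hosts = [
                c
                for c in current_cut
                if c != member and (member, c) in closed
            ]
            if not hosts and whole in current_cut:
                hosts = [whole]
            if len(hosts) != 1:
                raise PartitionError(
                    f"partition {k}: {member!r} falls under "
                    f"{len(hosts)} cells of the coarser partition "
                    "(expected exactly one)"
                )
            assigned[member] = hosts[0]
        for member in cut:
            if member in assigned:
                host = assigned[member]
                tree.children[host] = tree.children.get(host, ()) + (member,)
                tree.children.setdefault(member, ())
                tree.depth_of[member] = k + 1
        current_cut = cut
    tree.depth = len(partitions) + 1
    return tree


def tree_from_partonomy(p: Partonomy, whole: str | None = None) -> GranularityTree:
    """Build the granularity tree directly from the direct-parthood graph,
    requiring it to be single-parented below ``whole`` (the unique maximum
    instance when omitted)."""
    from .core_model import maximum_instances

    if whole is None:
        maxima = maximum_instances(p)
        if len(maxima) != 1:
            raise PartitionError(
                f"partonomy has {len(maxima)} maximal instances; specify the whole"
            )
        whole = maxima[0]
    if whole not in p.instances:
        raise ReferenceError_(f"unknown whole {whole!r}")

    from .core_model import Relation

    kids: dict[str, list[str]] = {}
    parent_of: dict[str, str] = {}
    for e in p.edges:
        if e.relation == Relation.COUNTABLE_PROPER_PART_OF:
            continue
        kids.setdefault(e.parent, []).append(e.child)
        if e.child in parent_of and parent_of[e.child] != e.parent:
            raise PartitionError(
                f"{e.child!r} has two parents ({parent_of[e.child]!r}, "
                f"{e.parent!r}); the partonomy is not tree-shaped"
            )
        parent_of[e.child] = e.parent

    tree = GranularityTree(root=whole)
    tree.depth_of[whole] = 1
    stack = [whole]
    while stack:
        node = stack.pop()
        ordered = tuple(sorted(kids.get(node, ())))
        tree.children[node] = ordered
        for child in ordered:
            tree.depth_of[child] = tree.depth_of[node] + 1
            stack.append(child)
    tree.depth = max(tree.depth_of.values())
    return tree


def enumerate_levels(t: GranularityTree) -> list[InstanceLevel]:
    """One instance granularity level per cut, indexed 1 (finest) to
    ``t.depth`` (the root).  Pass-through leaves re-enter every cut deeper
    than their own depth."""
    levels: list[InstanceLevel] = []
    for d in range(t.depth, 0, -1):
        content = {n for n, nd in t.depth_of.items() if nd == d}
        content |= {
            n
            for n, nd in t.depth_of.items()
            if nd < d and t.is_leaf(n) and n != t.root
        }
        levels.append(InstanceLevel(index=t.depth - d + 1, content=frozenset(content)))
    return levels


def classify_tree(t: GranularityTree, p: Partonomy) -> str:
    """``bona_fide`` when every non-root node is an object or object
    aggregate, ``fiat`` when every non-root node is a fiat object part,
    ``mixed`` otherwise."""
    non_root = [n for n in t.depth_of if n != t.root]
    kinds = {p.kind_of(n) for n in non_root}
    if kinds <= {EntityKind.OBJECT, EntityKind.OBJECT_AGGREGATE}:
        return "bona_fide"
    if kinds == {EntityKind.FIAT_OBJECT_PART}:
        return "fiat"
    return "mixed"
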