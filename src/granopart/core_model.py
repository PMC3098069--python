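"""Domain model for typed part-whole partonomies.

Material types carry one of the three material-entity kinds (``object``,
``fiat_object_part``, ``object_aggregate``); parthood is stored at the
instance level as a strict order, with ``direct_proper_part_of`` edges
marking covering pairs and ``countable_proper_part_of`` edges linking the
countable to the non-countable representation of the same aggregate.

Order-theoretic validation (irreflexivity, antisymmetry, reduction
discipline of the direct edges) lives here as well, alongside the
mereological-sum check used throughout the linting modules.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

from .errors import (
    AnnotationError,
    OrderError,
    PreconditionError,
    ReferenceError_,
)


class EntityKind(str, Enum):
    """The three material-entity subtypes a material type can instantiate."""

    OBJECT = "object"
    FIAT_OBJECT_PART = "fiat_object_part"
    OBJECT_AGGREGATE = "object_aggregate"


class Relation(str, Enum):
    """Parthood edge labels.

    ``DIRECT_PROPER_PART_OF`` is a covering proper-parthood assertion,
    ``PROPER_PART_OF`` an unconstrained one; both participate in the same
    transitive closure.  ``COUNTABLE_PROPER_PART_OF`` relates the countable
    representation of an aggregate to its non-countable representation.
    """

    DIRECT_PROPER_PART_OF = "direct_proper_part_of"
    PROPER_PART_OF = "proper_part_of"
    COUNTABLE_PROPER_PART_OF = "countable_proper_part_of"


@dataclass(frozen=True)
class RepresentationLink:
    """Declares that a type is a resolution-dependent representation of a
    (fiat or aggregate) target type; ``countable`` distinguishes the
    count-noun from the mass-noun representation."""

    target_type: str
    countable: bool


@dataclass(frozen=True)
class MaterialTypeDef:
    id: str
    label: str
    kind: EntityKind
    name_giving_object_type: Optional[str] = None
    represents: Optional[RepresentationLink] = None


@dataclass(frozen=True)
class MaterialInstance:
    id: str
    type_id: str


@dataclass(frozen=True)
class ParthoodEdge:
    child: str
    parent: str
    relation: Relation = Relation.PROPER_PART_OF

    def __post_init__(self):
        if self.child == self.parent:
            # stored anyway so validation can report it, but flagged early
            # when constructed programmatically
            pass

    @property
    def pair(self) -> tuple[str, str]:
        return (self.child, self.parent)


@dataclass(frozen=True)
class Measure:
    instance: str
    quantity: str
    value: float
    unit: str = ""


@dataclass
class Partonomy:
    """A typed partonomy: type definitions, instances, parthood edges and
    optional scalar measures."""

    types: dict[str, MaterialTypeDef] = field(default_factory=dict)
    instances: dict[str, MaterialInstance] = field(default_factory=dict)
    edges: list[ParthoodEdge] = field(default_factory=list)
    measures: list[Measure] = field(default_factory=list)

    # -- construction helpers -------------------------------------------------

    def add_type(
        self,
        id: str,
        label: str,
        kind: EntityKind,
        name_giving_object_type: str | None = None,
        represents: RepresentationLink | None = None,
    ) -> MaterialTypeDef:
        if id in self.types:
            raise ReferenceError_(f"duplicate type id {id!r}")
        t = MaterialTypeDef(id, label, kind, name_giving_object_type, represents)
        self.types[id] = t
        return t

    def add_instance(self, id: str, type_id: str) -> MaterialInstance:
        if id in self.instances:
            raise ReferenceError_(f"duplicate instance id {id!r}")
        inst = MaterialInstance(id, type_id)
        self.instances[id] = inst
        return inst

    def add_edge(
        self, child: str, parent: str, relation: Relation = Relation.PROPER_PART_OF
    ) -> ParthoodEdge:
        e = ParthoodEdge(child, parent, relation)
        self.edges.append(e)
        return e

    def copy(self) -> "Partonomy":
        return _copy.deepcopy(self)

    # -- lookups --------------------------------------------------------------

    def type_of(self, instance_id: str) -> MaterialTypeDef:
        inst = self.instances.get(instance_id)
        if inst is None:
            raise ReferenceError_(f"unknown instance {instance_id!r}")
        t = self.types.get(inst.type_id)
        if t is None:
            raise ReferenceError_(
                f"instance {instance_id!r} has unknown type {inst.type_id!r}"
            )
        return t

    def kind_of(self, instance_id: str) -> EntityKind:
        return self.type_of(instance_id).kind

    def instances_of_type(self, type_id: str) -> list[str]:
        return sorted(i for i, inst in self.instances.items() if inst.type_id == type_id)

    def measures_for(self, instance_id: str, quantity: str) -> list[Measure]:
        return [
            m for m in self.measures if m.instance == instance_id and m.quantity == quantity
        ]

    # -- referential integrity ------------------------------------------------

    def check_references(self) -> None:
        """Raise on dangling identifiers or missing required annotations."""
        for iid, inst in self.instances.items():
            if inst.type_id not in self.types:
                raise ReferenceError_(
                    f"instance {iid!r} references unknown type {inst.type_id!r}"
                )
        for e in self.edges:
            for endpoint in (e.child, e.parent):
                if endpoint not in self.instances:
                    raise ReferenceError_(
                        f"edge {e.child!r} -> {e.parent!r} references unknown "
                        f"instance {endpoint!r}"
                    )
        for m in self.measures:
            if m.instance not in self.instances:
                raise ReferenceError_(
                    f"measure on unknown instance {m.instance!r}"
                )
        for tid, t in self.types.items():
            if t.kind in (EntityKind.FIAT_OBJECT_PART, EntityKind.OBJECT_AGGREGATE):
                if t.name_giving_object_type is None:
                    raise AnnotationError(
                        f"type {tid!r} of kind {t.kind.value} lacks a "
                        "name_giving_object_type"
                    )
            if t.name_giving_object_type is not None:
                giver = self.types.get(t.name_giving_object_type)
                if giver is None:
                    raise ReferenceError_(
                        f"type {tid!r}: unknown name-giving type "
                        f"{t.name_giving_object_type!r}"
                    )
                if giver.kind != EntityKind.OBJECT:
                    raise ReferenceError_(
                        f"type {tid!r}: name-giving type {giver.id!r} is not an object"
                    )
            if t.represents is not None:
                target = self.types.get(t.represents.target_type)
                if target is None:
                    raise ReferenceError_(
                        f"type {tid!r} represents unknown type "
                        f"{t.represents.target_type!r}"
                    )
                if target.kind == EntityKind.OBJECT:
                    raise ReferenceError_(
                        f"type {tid!r} represents {target.id!r}, which is an object; "
                        "representation targets must be aggregates or fiat parts"
                    )


# -- order reports ------------------------------------------------------------

IRREFLEXIVITY = "irreflexivity"
ANTISYMMETRY = "antisymmetry"
TRANSITIVITY_CLOSURE_GAP = "transitivity_closure_gap"
DIRECT_EDGE_REDUNDANCY = "direct_edge_redundancy"


@dataclass(frozen=True)
class OrderViolation:
    rule: str
    witnesses: tuple[str, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.rule}({', '.join(self.witnesses)})"


@dataclass
class OrderReport:
    violations: list[OrderViolation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def by_rule(self, rule: str) -> list[OrderViolation]:
        return [v for v in self.violations if v.rule == rule]

    def __str__(self) -> str:
        if self.ok:
            return "valid"
        return "; ".join(str(v) for v in self.violations)

    def to_dict(self) -> dict:
        return {
            "violations": [
                {"rule": v.rule, "witnesses": list(v.witnesses)} for v in self.violations
            ]
        }


# -- pure graph operations ----------------------------------------------------


def _pair_closure(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    g = nx.DiGraph(list(pairs))
    closed: set[tuple[str, str]] = set()
    for node in g:
        for desc in nx.descendants(g, node):
            closed.add((node, desc))
    # descendants() misses self-pairs created by explicit self loops
    closed.update((u, v) for u, v in g.edges if u == v)
    return closed


def transitive_closure(
    edges: Iterable[ParthoodEdge], p: Partonomy | None = None
) -> set[ParthoodEdge]:
    """Smallest transitively closed superset of ``edges``.

    Input edges are preserved; derived pairs are added with relation
    ``PROPER_PART_OF``.  When a partonomy is supplied, endpoints are
    checked against its instances.
    """
    edges = set(edges)
    if p is not None:
        for e in edges:
            for endpoint in (e.child, e.parent):
                if endpoint not in p.instances:
                    raise ReferenceError_(
                        f"edge {e.child!r} -> {e.parent!r}: unknown instance "
                        f"{endpoint!r}"
                    )
    existing_pairs = {e.pair for e in edges}
    closed = _pair_closure(existing_pairs)
    result = set(edges)
    for pair in closed - existing_pairs:
        result.add(ParthoodEdge(pair[0], pair[1], Relation.PROPER_PART_OF))
    return result


def transitive_reduction(closed: Iterable[ParthoodEdge]) -> set[ParthoodEdge]:
    """Unique minimal edge set whose transitive closure equals that of the
    input.  The input must be acyclic; for retained pairs the original edge
    objects are kept (a ``DIRECT_PROPER_PART_OF`` label wins over a plain
    ``PROPER_PART_OF`` duplicate)."""
    closed = list(closed)
    g = nx.DiGraph(e.pair for e in closed)
    if not nx.is_directed_acyclic_graph(g):
        raise OrderError("transitive reduction requires an acyclic edge set")
    reduced = nx.transitive_reduction(g)
    by_pair: dict[tuple[str, str], ParthoodEdge] = {}
    for e in closed:
        kept = by_pair.get(e.pair)
        if kept is None or (
            e.relation == Relation.DIRECT_PROPER_PART_OF
            and kept.relation != Relation.DIRECT_PROPER_PART_OF
        ):
            by_pair[e.pair] = e
    return {by_pair[pair] for pair in reduced.edges}


# -- strict-partial-order validation ------------------------------------------


def _mereological_edges(p: Partonomy) -> list[ParthoodEdge]:
    return [e for e in p.edges if e.relation != Relation.COUNTABLE_PROPER_PART_OF]


def closure_pairs(p: Partonomy, include_countable: bool = True) -> set[tuple[str, str]]:
    """Transitive closure of the partonomy's parthood, as instance-id pairs."""
    edges = p.edges if include_countable else _mereological_edges(p)
    return _pair_closure(e.pair for e in edges)


def validate_strict_partial_order(p: Partonomy) -> OrderReport:
    """Check the partonomy's parthood against the strict-order axioms and
    the reduction discipline of its direct edges.

    Violations are data, not exceptions.  Rules:

    * ``irreflexivity`` — an edge relating an instance to itself;
    * ``antisymmetry`` — a cycle in the parthood graph.  A two-node cycle
      consisting solely of countable edges is tolerated (the two nodes are
      representations of one aggregate), all other cycles are reported;
    * ``direct_edge_redundancy`` — a direct edge with an intermediate of
      the child's own kind between its endpoints (it is not a covering
      pair within its granulation);
    * ``transitivity_closure_gap`` — a plain proper-part edge that covers
      (no same-kind intermediate) in a document that otherwise labels its
      covering pairs as direct.  Documents asserting no direct edges at
      all are exempt.
    """
    report = OrderReport()
    self_edges = [e for e in p.edges if e.child == e.parent]
    for e in self_edges:
        report.violations.append(OrderViolation(IRREFLEXIVITY, (e.child,)))

    proper = [e for e in p.edges if e.child != e.parent]
    g = nx.DiGraph()
    g.add_nodes_from(p.instances)
    for e in proper:
        g.add_edge(e.child, e.parent)

    cyclic_nodes: set[str] = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) < 2:
            continue
        internal = [e for e in proper if e.child in scc and e.parent in scc]
        if len(scc) == 2 and all(
            e.relation == Relation.COUNTABLE_PROPER_PART_OF for e in internal
        ):
            continue  # mutual representations of the same aggregate
        cyclic_nodes.update(scc)
        report.violations.append(OrderViolation(ANTISYMMETRY, tuple(sorted(scc))))

    if cyclic_nodes:
        return report

    mereo = [e for e in proper if e.relation != Relation.COUNTABLE_PROPER_PART_OF]
    closed = _pair_closure(e.pair for e in mereo)

    def same_kind_intermediate(child: str, parent: str) -> str | None:
        child_kind = p.kind_of(child)
        for b in p.instances:
            if b in (child, parent):
                continue
            if (child, b) in closed and (b, parent) in closed:
                if p.kind_of(b) == child_kind:
                    return b
        return None

    direct = [e for e in mereo if e.relation == Relation.DIRECT_PROPER_PART_OF]
    plain = [e for e in mereo if e.relation == Relation.PROPER_PART_OF]

    for e in direct:
        mid = same_kind_intermediate(e.child, e.parent)
        if mid is not None:
            report.violations.append(
                OrderViolation(DIRECT_EDGE_REDUNDANCY, (e.child, mid, e.parent))
            )
    if direct:
        for e in plain:
            if (e.child, e.parent) in {d.pair for d in direct}:
                continue
            if same_kind_intermediate(e.child, e.parent) is None:
                report.violations.append(
                    OrderViolation(TRANSITIVITY_CLOSURE_GAP, (e.child, e.parent))
                )
    return report


# -- mereological sums --------------------------------------------------------


def parts_of(p: Partonomy, whole: str, closed: set[tuple[str, str]] | None = None) -> set[str]:
    """All proper parts of ``whole`` under the transitive closure."""
    if closed is None:
        closed = closure_pairs(p)
    return {child for (child, parent) in closed if parent == whole}


def atoms_under(
    p: Partonomy, x: str, closed: set[tuple[str, str]] | None = None
) -> set[str]:
    """Graph-theoretic atoms below ``x``: proper parts of ``x`` that have no
    proper parts themselves; ``x`` itself if it is partless."""
    if closed is None:
        closed = closure_pairs(p)
    has_parts = {parent for (_, parent) in closed}
    below = parts_of(p, x, closed)
    if not below:
        return {x}
    return {i for i in below if i not in has_parts}


def exhaustive_sum_check(
    members: Iterable[str], whole: str, p: Partonomy
) -> tuple[bool, frozenset[str]]:
    """Do the ``members`` mereologically sum to ``whole``?

    True iff the atoms under the members equal the atoms under the whole;
    the second component lists the uncovered atoms.  Every member must be a
    proper part of the whole.
    """
    members = list(members)
    closed = closure_pairs(p)
    whole_parts = parts_of(p, whole, closed)
    for m in members:
        if m not in p.instances:
            raise ReferenceError_(f"unknown member instance {m!r}")
        if m not in whole_parts:
            raise PreconditionError(
                f"member {m!r} is not a proper part of {whole!r}"
            )
    covered: set[str] = set()
    for m in members:
        covered |= atoms_under(p, m, closed)
    target = atoms_under(p, whole, closed)
    missing = frozenset(target - covered)
    return (not missing, missing)


def maximum_instances(p: Partonomy, kind: EntityKind | None = None) -> list[str]:
    """Instances with no proper whole above them (optionally restricted to a
    kind), sorted by id."""
    closed = closure_pairs(p, include_countable=False)
    has_whole = {child for (child, _) in closed}
    out = []
    for iid in p.instances:
        if iid in has_whole:
            continue
        if kind is not None and p.kind_of(iid) != kind:
            continue
        out.append(iid)
    return sorted(out)
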