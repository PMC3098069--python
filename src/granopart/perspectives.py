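"""Granularity perspectives and their integration into one framework.

The compositional object (CO) perspective — object subtypes layered by
direct proper parthood — is the backbone.  Around it, two-level
perspectives are built for fiat/aggregate counterparts (additional
compositional), for regional fiat parts (basic spatial), and for
countable/non-countable representation pairs (resolution); chains of fiat
parts within fiat parts yield instance-only spatial perspectives.
Perspectives are connected through overcrossing levels (shared content),
and the framework validator enforces the containment rules: at least two
levels per perspective, each level in exactly one perspective, each entity
in at most one level per perspective, and no perspective cut off from the
backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import networkx as nx

from .core_model import (
    EntityKind,
    ParthoodEdge,
    Partonomy,
    Relation,
    closure_pairs,
)
from .errors import (
    AnnotationError,
    ClassificationError,
    PerspectiveError,
    ReferenceError_,
)
from .report import LintReport, Severity


class GranularityType(str, Enum):
    NRG = "nrG"      # non-scale-dependent, single granulation relation
    SGRG = "sgrG"    # scale-dependent, grain size according to resolution
    SCALE = "scale"  # pure measure-threshold scale


class PerspectiveType(str, Enum):
    COMPOSITIONAL_OBJECT = "compositional_object"
    COMPOSITIONAL_OBJECT_OF_FIAT = "compositional_object_of_fiat"
    COMPOSITIONAL_AGGREGATE_OF_FIAT = "compositional_aggregate_of_fiat"
    COMPOSITIONAL_OBJECT_OF_AGGREGATE = "compositional_object_of_aggregate"
    COMPOSITIONAL_AGGREGATE_OF_OBJECT = "compositional_aggregate_of_object"
    COMPOSITIONAL_AGGREGATE_OF_AGGREGATE = "compositional_aggregate_of_aggregate"
    SPATIAL_FIAT_OF_OBJECT = "spatial_fiat_of_object"
    SPATIAL_FIAT_OF_AGGREGATE = "spatial_fiat_of_aggregate"
    RESOLUTION_OF_AGGREGATE = "resolution_of_aggregate"
    RESOLUTION_OF_AGGREGATE_WITH_FIAT = "resolution_of_aggregate_with_fiat"
    SPATIAL_FIAT_OF_FIAT = "spatial_fiat_of_fiat"
    SIZE_SCALE = "size_scale"

    @property
    def granularity_type(self) -> GranularityType:
        if self in (
            PerspectiveType.RESOLUTION_OF_AGGREGATE,
            PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT,
        ):
            return GranularityType.SGRG
        if self is PerspectiveType.SIZE_SCALE:
            return GranularityType.SCALE
        return GranularityType.NRG


@dataclass
class GranularityLevel:
    """A level within one perspective.

    ``content`` holds type ids, except for instance-only perspectives
    (fiat-of-fiat chains, size/scale binning) where it holds instance ids
    and ``instance_content`` is set.  ``value_slot`` is filled by the value
    assignment pass; ``scale_value`` only for size perspectives.
    """

    id: str
    perspective_id: str
    index: int
    content: frozenset[str]
    instance_content: bool = False
    value_slot: object = None
    scale_value: Optional[int] = None

    def __post_init__(self):
        if not self.content:
            raise PerspectiveError(f"level {self.id} has empty content")


@dataclass
class GranularityPerspective:
    id: str
    ptype: PerspectiveType
    levels: list[GranularityLevel] = field(default_factory=list)
    anchor_co_level: Optional[int] = None
    counterpart_type: Optional[str] = None

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, index: int) -> GranularityLevel:
        for lv in self.levels:
            if lv.index == index:
                return lv
        raise KeyError(index)


@dataclass
class GranularityFramework:
    perspectives: list[GranularityPerspective] = field(default_factory=list)
    # adjacent-level (RL) pairs: (perspective id, lower index, upper index)
    rl_edges: list[tuple[str, int, int]] = field(default_factory=list)
    # overcrossing (RP) perspective pairs, unordered, stored sorted
    rp_pairs: set[tuple[str, str]] = field(default_factory=set)
    # containment (RE): level id -> perspective id (levels sit in perspectives)
    re_containment: dict[str, str] = field(default_factory=dict)
    unclassified_edges: list[ParthoodEdge] = field(default_factory=list)
    rejected_fiat_branches: list[str] = field(default_factory=list)

    def perspective(self, pid: str) -> GranularityPerspective:
        for persp in self.perspectives:
            if persp.id == pid:
                return persp
        raise KeyError(pid)

    @property
    def co(self) -> GranularityPerspective:
        for persp in self.perspectives:
            if persp.ptype is PerspectiveType.COMPOSITIONAL_OBJECT:
                return persp
        raise KeyError("no compositional-object perspective in framework")

    def add(self, persp: GranularityPerspective) -> None:
        self.perspectives.append(persp)
        ordered = sorted(persp.levels, key=lambda lv: lv.index)
        for lower, upper in zip(ordered, ordered[1:]):
            self.rl_edges.append((persp.id, lower.index, upper.index))
        for lv in persp.levels:
            self.re_containment[lv.id] = persp.id


# -- edge classification -------------------------------------------------------

_DIRECTISH = (Relation.DIRECT_PROPER_PART_OF, Relation.PROPER_PART_OF)

# (child kind, parent kind) -> (tag, admissible relations); criterion lists
_EDGE_TAGS: dict[tuple[EntityKind, EntityKind], tuple[PerspectiveType, tuple]] = {
    (EntityKind.OBJECT, EntityKind.OBJECT): (
        PerspectiveType.COMPOSITIONAL_OBJECT,
        (Relation.DIRECT_PROPER_PART_OF,),
    ),
    (EntityKind.OBJECT, EntityKind.FIAT_OBJECT_PART): (
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT,
        (Relation.DIRECT_PROPER_PART_OF,),
    ),
    (EntityKind.OBJECT_AGGREGATE, EntityKind.FIAT_OBJECT_PART): (
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_FIAT,
        _DIRECTISH,
    ),
    (EntityKind.OBJECT, EntityKind.OBJECT_AGGREGATE): (
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_AGGREGATE,
        (Relation.DIRECT_PROPER_PART_OF,),
    ),
    (EntityKind.OBJECT_AGGREGATE, EntityKind.OBJECT): (
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT,
        _DIRECTISH,
    ),
    (EntityKind.OBJECT_AGGREGATE, EntityKind.OBJECT_AGGREGATE): (
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE,
        _DIRECTISH,
    ),
    (EntityKind.FIAT_OBJECT_PART, EntityKind.OBJECT): (
        PerspectiveType.SPATIAL_FIAT_OF_OBJECT,
        _DIRECTISH,
    ),
    (EntityKind.FIAT_OBJECT_PART, EntityKind.OBJECT_AGGREGATE): (
        PerspectiveType.SPATIAL_FIAT_OF_AGGREGATE,
        _DIRECTISH,
    ),
    (EntityKind.FIAT_OBJECT_PART, EntityKind.FIAT_OBJECT_PART): (
        PerspectiveType.SPATIAL_FIAT_OF_FIAT,
        _DIRECTISH,
    ),
}


def classify_edge(e: ParthoodEdge, p: Partonomy) -> PerspectiveType:
    """Deterministic (child kind, parent kind, relation) -> perspective tag
    mapping per the granulation-criterion lists; countable edges resolve to
    a resolution tag via the represented entity's kind."""
    child_type = p.type_of(e.child)
    parent_type = p.type_of(e.parent)
    if e.relation == Relation.COUNTABLE_PROPER_PART_OF:
        rep = child_type.represents or parent_type.represents
        if rep is None:
            raise ClassificationError(
                f"countable edge {e.child!r} -> {e.parent!r}: neither endpoint "
                "declares what it represents"
            )
        target = p.types.get(rep.target_type)
        if target is None:
            raise ReferenceError_(f"unknown represented type {rep.target_type!r}")
        if target.kind == EntityKind.OBJECT_AGGREGATE:
            return PerspectiveType.RESOLUTION_OF_AGGREGATE
        return PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT
    key = (child_type.kind, parent_type.kind)
    entry = _EDGE_TAGS.get(key)
    if entry is None or e.relation not in entry[1]:
        raise ClassificationError(
            f"edge {e.child!r} -{e.relation.value}-> {e.parent!r} "
            f"({child_type.kind.value} -> {parent_type.kind.value}) matches no "
            "granulation criterion"
        )
    return entry[0]


def classify_edges(
    p: Partonomy,
) -> tuple[dict[PerspectiveType, list[ParthoodEdge]], list[ParthoodEdge]]:
    """Classify every asserted edge; unclassifiable edges are returned, never
    dropped silently."""
    tagged: dict[PerspectiveType, list[ParthoodEdge]] = {}
    unclassified: list[ParthoodEdge] = []
    for e in p.edges:
        try:
            tag = classify_edge(e, p)
        except ClassificationError:
            unclassified.append(e)
            continue
        tagged.setdefault(tag, []).append(e)
    return tagged, unclassified


# -- compositional object backbone --------------------------------------------


def co_type_levels(p: Partonomy) -> dict[str, int]:
    """CO level per object subtype: 1 + length of the longest chain of
    object-subtype direct parthood beneath it (longest-path layering)."""
    g = nx.DiGraph()
    for e in p.edges:
        if e.relation != Relation.DIRECT_PROPER_PART_OF:
            continue
        ct, pt = p.type_of(e.child), p.type_of(e.parent)
        if ct.kind == pt.kind == EntityKind.OBJECT and ct.id != pt.id:
            g.add_edge(ct.id, pt.id)
    if not nx.is_directed_acyclic_graph(g):
        raise PerspectiveError("object-subtype direct parthood is cyclic")
    levels: dict[str, int] = {}
    for tid in nx.topological_sort(g):
        preds = list(g.predecessors(tid))
        levels[tid] = 1 if not preds else 1 + max(levels[q] for q in preds)
    return levels


def build_co_perspective(p: Partonomy) -> GranularityPerspective:
    """The backbone: object subtypes layered bottom-up by direct proper
    parthood.  Requires at least two distinct, connected object subtypes."""
    levels = co_type_levels(p)
    if not levels or max(levels.values()) < 2:
        raise PerspectiveError(
            "a compositional object perspective needs at least two object "
            "levels connected by direct proper parthood"
        )
    persp = GranularityPerspective(id="co", ptype=PerspectiveType.COMPOSITIONAL_OBJECT)
    for index in range(1, max(levels.values()) + 1):
        content = frozenset(t for t, lv in levels.items() if lv == index)
        persp.levels.append(
            GranularityLevel(
                id=f"co:L{index}",
                perspective_id=persp.id,
                index=index,
                content=content,
            )
        )
    return persp


def _co_level_of_type(co: GranularityPerspective, type_id: str) -> int | None:
    for lv in co.levels:
        if type_id in lv.content:
            return lv.index
    return None


def _anchor_level(
    p: Partonomy, co: GranularityPerspective, type_id: str
) -> int | None:
    """CO level a fiat/aggregate subtype is anchored to, via its name-giving
    object subtype."""
    t = p.types[type_id]
    if t.kind == EntityKind.OBJECT:
        return _co_level_of_type(co, type_id)
    if t.name_giving_object_type is None:
        raise AnnotationError(
            f"type {type_id!r} has no name-giving object type; cannot anchor it "
            "to a compositional-object level"
        )
    return _co_level_of_type(co, t.name_giving_object_type)


def _two_level_perspective(
    pid: str,
    ptype: PerspectiveType,
    lower: frozenset[str],
    upper: frozenset[str],
    anchor: int | None,
    counterpart: str,
) -> GranularityPerspective:
    persp = GranularityPerspective(
        id=pid, ptype=ptype, anchor_co_level=anchor, counterpart_type=counterpart
    )
    persp.levels.append(
        GranularityLevel(id=f"{pid}:L1", perspective_id=pid, index=1, content=lower)
    )
    persp.levels.append(
        GranularityLevel(id=f"{pid}:L2", perspective_id=pid, index=2, content=upper)
    )
    return persp


_ADDITIONAL_COMPOSITIONAL = (
    PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT,
    PerspectiveType.COMPOSITIONAL_OBJECT_OF_AGGREGATE,
    PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT,
    PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_FIAT,
    PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE,
)


def build_additional_compositional(
    p: Partonomy, co: GranularityPerspective
) -> list[GranularityPerspective]:
    """Two-level perspectives for fiat/aggregate counterparts of objects.

    One perspective per (perspective type, anchor CO level, counterpart
    subtype) key; the part subtypes of one CO level form the lower level,
    the counterpart the upper.  Aggregate-of-aggregate chains may exceed
    two levels and are layered like the backbone.
    """
    tagged, _ = classify_edges(p)
    out: list[GranularityPerspective] = []

    # aggregate-of-aggregate chains: layered, possibly > 2 levels
    agg_edges = tagged.get(PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE, [])
    if agg_edges:
        g = nx.DiGraph()
        for e in agg_edges:
            ct, pt = p.type_of(e.child).id, p.type_of(e.parent).id
            if ct != pt:
                g.add_edge(ct, pt)
        if not nx.is_directed_acyclic_graph(g):
            raise PerspectiveError("aggregate-of-aggregate parthood is cyclic")
        for comp_i, comp in enumerate(sorted(nx.weakly_connected_components(g), key=sorted)):
            sub = g.subgraph(comp)
            depth: dict[str, int] = {}
            for tid in nx.topological_sort(sub):
                preds = list(sub.predecessors(tid))
                depth[tid] = 1 if not preds else 1 + max(depth[q] for q in preds)
            pid = f"comp_agg_chain:{comp_i + 1}"
            anchor = min(
                (a for t in comp if (a := _anchor_level(p, co, t)) is not None),
                default=None,
            )
            persp = GranularityPerspective(
                id=pid,
                ptype=PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE,
                anchor_co_level=anchor,
                counterpart_type=sorted(comp)[0],
            )
            for index in range(1, max(depth.values()) + 1):
                persp.levels.append(
                    GranularityLevel(
                        id=f"{pid}:L{index}",
                        perspective_id=pid,
                        index=index,
                        content=frozenset(t for t, d in depth.items() if d == index),
                    )
                )
            out.append(persp)

    grouped: dict[tuple[PerspectiveType, int, str], set[str]] = {}
    for ptype in _ADDITIONAL_COMPOSITIONAL:
        if ptype is PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE:
            continue
        for e in tagged.get(ptype, []):
            child_t, parent_t = p.type_of(e.child), p.type_of(e.parent)
            if ptype is PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT:
                # the aggregate is the part: counterpart below, object above
                counterpart, lower_member = child_t, child_t
                anchor = _anchor_level(p, co, parent_t.id)
            else:
                counterpart, lower_member = parent_t, child_t
                anchor = _anchor_level(p, co, child_t.id)
            if counterpart.name_giving_object_type is None:
                raise AnnotationError(
                    f"counterpart type {counterpart.id!r} lacks a "
                    "name_giving_object_type"
                )
            if anchor is None:
                continue  # part subtype outside the CO backbone
            key = (ptype, anchor, counterpart.id)
            grouped.setdefault(key, set()).add(lower_member.id)
            if ptype is PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT:
                grouped[key].add(parent_t.id)

    for (ptype, anchor, counterpart), members in sorted(
        grouped.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
    ):
        pid = f"{ptype.value}:L{anchor}:{counterpart}"
        if ptype is PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT:
            lower = frozenset({counterpart})
            upper = frozenset(members - {counterpart})
        else:
            lower = frozenset(members)
            upper = frozenset({counterpart})
        out.append(
            _two_level_perspective(pid, ptype, lower, upper, anchor, counterpart)
        )
    return out


def build_spatial_basic(
    p: Partonomy, co: GranularityPerspective
) -> list[GranularityPerspective]:
    """Two-level spatial perspectives: fiat regional parts in the lower
    level, the objects (or aggregates) they cut in the upper.  Sibling fiat
    partitions of the same subtype pool into one lower level per
    (anchor CO level, fiat counterpart subtype) key."""
    tagged, _ = classify_edges(p)
    grouped: dict[tuple[PerspectiveType, int, str], set[str]] = {}
    for ptype in (
        PerspectiveType.SPATIAL_FIAT_OF_OBJECT,
        PerspectiveType.SPATIAL_FIAT_OF_AGGREGATE,
    ):
        for e in tagged.get(ptype, []):
            fiat_t, host_t = p.type_of(e.child), p.type_of(e.parent)
            anchor = _anchor_level(p, co, host_t.id)
            if anchor is None:
                continue
            if fiat_t.name_giving_object_type is None:
                raise AnnotationError(
                    f"fiat part type {fiat_t.id!r} lacks a name_giving_object_type"
                )
            key = (ptype, anchor, fiat_t.id)
            grouped.setdefault(key, set()).add(host_t.id)
    out = []
    for (ptype, anchor, fiat_tid), hosts in sorted(
        grouped.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2])
    ):
        pid = f"{ptype.value}:L{anchor}:{fiat_tid}"
        out.append(
            _two_level_perspective(
                pid, ptype, frozenset({fiat_tid}), frozenset(hosts), anchor, fiat_tid
            )
        )
    return out


def build_resolution(p: Partonomy) -> list[GranularityPerspective]:
    """One two-level perspective per represented aggregate/fiat type with
    both a countable and a non-countable representation declared; countable
    below.  Represented types with a single representation are skipped with
    a warning."""
    import warnings

    reps: dict[str, dict[bool, list[str]]] = {}
    for tid, t in sorted(p.types.items()):
        if t.represents is None:
            continue
        reps.setdefault(t.represents.target_type, {}).setdefault(
            t.represents.countable, []
        ).append(tid)
    out = []
    for target_id, by_flag in sorted(reps.items()):
        if True not in by_flag or False not in by_flag:
            warnings.warn(
                f"represented type {target_id!r} has only one representation; "
                "no resolution perspective built",
                stacklevel=2,
            )
            continue
        target = p.types[target_id]
        ptype = (
            PerspectiveType.RESOLUTION_OF_AGGREGATE
            if target.kind == EntityKind.OBJECT_AGGREGATE
            else PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT
        )
        pid = f"resolution:{target_id}"
        out.append(
            _two_level_perspective(
                pid,
                ptype,
                frozenset(by_flag[True]),
                frozenset(by_flag[False]),
                None,
                target_id,
            )
        )
    return out


def build_fiat_chain(p: Partonomy) -> list[GranularityPerspective]:
    """Instance-only perspectives from maximal fiat-within-fiat chains.

    Branching fiat subgraphs that are not simple chains are rejected from
    perspective building and reported on the framework.
    """
    build_fiat_chain.last_rejected = []
    fiat_edges = [
        e
        for e in p.edges
        if e.relation != Relation.COUNTABLE_PROPER_PART_OF
        and p.kind_of(e.child) == EntityKind.FIAT_OBJECT_PART
        and p.kind_of(e.parent) == EntityKind.FIAT_OBJECT_PART
    ]
    if not fiat_edges:
        return []
    g = nx.DiGraph(e.pair for e in fiat_edges)
    out = []
    rejected: list[str] = []
    for comp_i, comp in enumerate(
        sorted(nx.weakly_connected_components(g), key=sorted), start=1
    ):
        sub = g.subgraph(comp)
        is_chain = all(
            sub.out_degree(n) <= 1 and sub.in_degree(n) <= 1 for n in sub
        ) and nx.is_directed_acyclic_graph(sub)
        if not is_chain:
            rejected.append(
                "fiat subgraph {" + ", ".join(sorted(comp)) + "} branches; not a chain"
            )
            continue
        ordered = list(nx.topological_sort(sub))
        pid = f"fiat_chain:{comp_i}"
        persp = GranularityPerspective(
            id=pid, ptype=PerspectiveType.SPATIAL_FIAT_OF_FIAT
        )
        for index, iid in enumerate(ordered, start=1):
            persp.levels.append(
                GranularityLevel(
                    id=f"{pid}:L{index}",
                    perspective_id=pid,
                    index=index,
                    content=frozenset({iid}),
                    instance_content=True,
                )
            )
        out.append(persp)
    build_fiat_chain.last_rejected = rejected  # inspected by build_framework
    return out


build_fiat_chain.last_rejected = []


# -- framework assembly and overcrossing ---------------------------------------


def _overlap_content(lv: GranularityLevel, p: Partonomy | None) -> frozenset[str]:
    """Content used for overcross detection: instance content is lifted to
    type ids, and representation types also stand for their target."""
    if p is None:
        return lv.content
    out: set[str] = set()
    for cid in lv.content:
        if lv.instance_content:
            inst = p.instances.get(cid)
            out.add(inst.type_id if inst else cid)
        else:
            out.add(cid)
            t = p.types.get(cid)
            if t is not None and t.represents is not None:
                out.add(t.represents.target_type)
    return frozenset(out)


def detect_overcross(
    f: GranularityFramework, p: Partonomy | None = None
) -> set[tuple[tuple[str, str], tuple[tuple[str, str], ...]]]:
    """All unordered perspective pairs sharing content in at least one pair
    of levels.  Updates ``f.rp_pairs``; the result maps each overcrossing
    pair to the level-id pairs that share content."""
    result = set()
    perspectives = f.perspectives
    for i, a in enumerate(perspectives):
        for b in perspectives[i + 1 :]:
            shared: list[tuple[str, str]] = []
            for la in a.levels:
                ca = _overlap_content(la, p)
                for lb in b.levels:
                    if ca & _overlap_content(lb, p):
                        shared.append((la.id, lb.id))
            if shared:
                pair = tuple(sorted((a.id, b.id)))
                f.rp_pairs.add(pair)
                result.add((pair, tuple(sorted(shared))))
    return result


def build_framework(p: Partonomy) -> GranularityFramework:
    """Construct all buildable perspectives from a partonomy and wire them
    into one framework with overcrossings detected."""
    f = GranularityFramework()
    co = build_co_perspective(p)
    f.add(co)
    for persp in build_additional_compositional(p, co):
        f.add(persp)
    for persp in build_spatial_basic(p, co):
        f.add(persp)
    for persp in build_resolution(p):
        f.add(persp)
    for persp in build_fiat_chain(p):
        f.add(persp)
    f.rejected_fiat_branches = list(build_fiat_chain.last_rejected)
    _, unclassified = classify_edges(p)
    f.unclassified_edges = unclassified
    detect_overcross(f, p)
    return f


def validate_framework(f: GranularityFramework) -> LintReport:
    """Audit the assembled framework against the containment rules."""
    report = LintReport()
    for persp in f.perspectives:
        if persp.n_levels < 2:
            report.add(
                "keet_two_levels",
                Severity.ERROR,
                f"perspective {persp.id} has {persp.n_levels} level(s); "
                "at least two are required",
                [persp.id],
            )
    seen_levels: dict[str, str] = {}
    for persp in f.perspectives:
        for lv in persp.levels:
            if lv.id in seen_levels and seen_levels[lv.id] != persp.id:
                report.add(
                    "level_unique_perspective",
                    Severity.ERROR,
                    f"level {lv.id} is contained in two perspectives",
                    [lv.id, seen_levels[lv.id], persp.id],
                )
            seen_levels[lv.id] = persp.id
        membership: dict[str, list[str]] = {}
        for lv in persp.levels:
            for entity in lv.content:
                membership.setdefault(entity, []).append(lv.id)
        for entity, in_levels in sorted(membership.items()):
            if len(in_levels) > 1:
                report.add(
                    "entity_single_level",
                    Severity.ERROR,
                    f"entity {entity} occupies {len(in_levels)} levels of "
                    f"perspective {persp.id}",
                    [entity, *in_levels],
                )
    for a, b in sorted(f.rp_pairs):
        if a == b:
            report.add(
                "rp_irreflexive",
                Severity.ERROR,
                f"perspective {a} overcrosses itself",
                [a],
            )
    re_graph = nx.DiGraph()
    for level_id, pid in f.re_containment.items():
        re_graph.add_edge(level_id, pid)
    if not nx.is_directed_acyclic_graph(re_graph):
        cycle = nx.find_cycle(re_graph)
        report.add(
            "re_acyclic",
            Severity.ERROR,
            "containment relation has a cycle",
            [str(edge) for edge in cycle],
        )
    try:
        co_id = f.co.id
    except KeyError:
        report.add(
            "backbone_missing",
            Severity.ERROR,
            "framework has no compositional-object perspective",
            [p.id for p in f.perspectives] or ["<empty>"],
        )
        return report
    rp_graph = nx.Graph()
    rp_graph.add_nodes_from(persp.id for persp in f.perspectives)
    rp_graph.add_edges_from(f.rp_pairs)
    reachable = nx.node_connected_component(rp_graph, co_id)
    for persp in f.perspectives:
        if persp.id not in reachable:
            report.add(
                "perspective_cut_off",
                Severity.ERROR,
                f"perspective {persp.id} is not reachable from the "
                "compositional-object perspective via overcrossings",
                [persp.id],
            )
    for msg in f.rejected_fiat_branches:
        report.add("fiat_branching", Severity.WARNING, msg, [msg])
    for e in f.unclassified_edges:
        report.add(
            "unclassified_edge",
            Severity.WARNING,
            f"edge {e.child} -{e.relation.value}-> {e.parent} matches no "
            "granulation criterion",
            [e.child, e.parent],
        )
    return report


# -- instance rules ------------------------------------------------------------


def check_instance_rules(p: Partonomy, f: GranularityFramework) -> LintReport:
    """Audit instances against the numbered cumulative-constitutive rules of
    the compositional-object, additional-compositional and spatial
    granulations.  Rules that state permissions (CO 1, additional 2,
    spatial 1) cannot be violated and never yield findings.
    """
    report = LintReport()
    co = f.co
    closed = closure_pairs(p, include_countable=False)
    co_levels = {t: lv.index for lv in co.levels for t in lv.content}

    objects = [i for i in sorted(p.instances) if p.kind_of(i) == EntityKind.OBJECT]
    fiats = [
        i for i in sorted(p.instances) if p.kind_of(i) == EntityKind.FIAT_OBJECT_PART
    ]
    aggregates = [
        i for i in sorted(p.instances) if p.kind_of(i) == EntityKind.OBJECT_AGGREGATE
    ]

    def object_parts(iid: str) -> list[str]:
        return [
            c
            for (c, w) in closed
            if w == iid and p.kind_of(c) == EntityKind.OBJECT
        ]

    # CO rule 2: every object above the lowest CO level has >= 2 object parts
    for iid in objects:
        tid = p.instances[iid].type_id
        lv = co_levels.get(tid)
        if lv is None or lv == 1:
            continue
        if len(object_parts(iid)) < 2:
            report.add(
                "co_rule_2",
                Severity.ERROR,
                f"object {iid} (type {tid}, CO level {lv}) has fewer than two "
                "object proper parts",
                [iid],
            )

    # CO rule 3: all objects are proper parts of one maximum object
    maxima = [i for i in objects if not any(w for (c, w) in closed if c == i)]
    if len(maxima) > 1:
        report.add(
            "co_rule_3",
            Severity.ERROR,
            "granulation has more than one maximal object",
            maxima,
        )
    elif maxima:
        top = maxima[0]
        strays = [
            i for i in objects if i != top and (i, top) not in closed
        ]
        if strays:
            report.add(
                "co_rule_3",
                Severity.ERROR,
                f"objects not proper parts of the maximum object {top}",
                strays,
            )

    def anchor_of(iid: str) -> int | None:
        t = p.type_of(iid)
        if t.name_giving_object_type is None:
            return None
        return co_levels.get(t.name_giving_object_type)

    # additional-compositional rule 1: every aggregate has an object part at
    # its name-giving object's CO level
    for iid in aggregates:
        anchor = anchor_of(iid)
        if anchor is None:
            continue
        if not any(
            co_levels.get(p.instances[c].type_id) == anchor for c in object_parts(iid)
        ):
            report.add(
                "additional_rule_1",
                Severity.ERROR,
                f"aggregate {iid} has no object proper part at CO level {anchor} "
                "(the level of its name-giving object)",
                [iid],
            )

    # additional-compositional rule 3: every fiat part has an object part at
    # a CO level below its name-giving object's level
    for iid in fiats:
        anchor = anchor_of(iid)
        if anchor is None:
            continue
        lower_parts = [
            c
            for c in object_parts(iid)
            if (lv := co_levels.get(p.instances[c].type_id)) is not None and lv < anchor
        ]
        if not lower_parts:
            report.add(
                "additional_rule_3",
                Severity.ERROR,
                f"fiat part {iid} has no object proper part below CO level "
                f"{anchor} (the level of its name-giving object)",
                [iid],
            )

    # spatial rule 2: every fiat part is proper part of an object at its
    # name-giving object's CO level.  Aggregate-like fiat parts (those that
    # contain instances of their own name-giving type, e.g. a cell aggregate
    # named after its member cells) are hosted one level above instead.
    for iid in fiats:
        anchor = anchor_of(iid)
        if anchor is None:
            continue
        name_type = p.type_of(iid).name_giving_object_type
        contains_name_givers = any(
            p.instances[c].type_id == name_type
            for (c, w) in closed
            if w == iid
        )
        host_level = anchor + 1 if contains_name_givers else anchor
        wholes = [
            w
            for (c, w) in closed
            if c == iid
            and p.kind_of(w) == EntityKind.OBJECT
            and co_levels.get(p.instances[w].type_id) == host_level
        ]
        if not wholes:
            report.add(
                "spatial_rule_2",
                Severity.ERROR,
                f"fiat part {iid} is not a proper part of any object at CO "
                f"level {host_level}",
                [iid],
            )

    # spatial rule 3: an object (or aggregate) that is cut into fiat parts
    # has at least two of them
    for iid in objects + aggregates:
        fiat_parts = [
            c
            for (c, w) in closed
            if w == iid and p.kind_of(c) == EntityKind.FIAT_OBJECT_PART
        ]
        if len(fiat_parts) == 1:
            report.add(
                "spatial_rule_3",
                Severity.ERROR,
                f"{iid} is cut into a single fiat part {fiat_parts[0]}; a "
                "spatial granulation needs at least two",
                [iid, fiat_parts[0]],
            )

    # spatial rule 4: every fiat part is proper part of the maximum object
    if len(maxima) == 1:
        top = maxima[0]
        stray_fiats = [i for i in fiats if (i, top) not in closed]
        if stray_fiats:
            report.add(
                "spatial_rule_4",
                Severity.ERROR,
                f"fiat parts not proper parts of the maximum object {top}",
                stray_fiats,
            )
    return report
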