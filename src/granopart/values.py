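"""Structural granularity values.

The compositional-object backbone carries fixed naturals (1 = finest).
Fiat and aggregate levels receive open rational intervals strictly between
the adjacent naturals; overcrossing levels must agree bit-exactly, which
is why endpoints and representatives are :class:`fractions.Fraction`
values, never floats.  Nested fiat parts receive strictly contained
sub-intervals, assigned so that deepening a granulation never disturbs an
already assigned value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .core_model import EntityKind, Partonomy, Relation
from .errors import ConsistencyError, ParameterError, PerspectiveError
from .perspectives import (
    GranularityFramework,
    GranularityLevel,
    GranularityPerspective,
    PerspectiveType,
)
from .report import LintReport, Severity


@dataclass(frozen=True)
class FixedNatural:
    k: int

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("structural granularity naturals start at 1")

    @property
    def representative(self) -> Fraction:
        return Fraction(self.k)

    def to_dict(self) -> dict:
        return {"variant": "fixed_natural", "k": self.k}

    def __str__(self) -> str:
        return str(self.k)


@dataclass(frozen=True)
class RelativeInterval:
    lo: Fraction
    hi: Fraction
    representative: Fraction

    def __post_init__(self):
        if not (self.lo < self.representative < self.hi):
            raise ValueError(
                f"representative {self.representative} outside open interval "
                f"({self.lo}, {self.hi})"
            )

    @classmethod
    def between(cls, lo, hi, representative=None) -> "RelativeInterval":
        lo, hi = Fraction(lo), Fraction(hi)
        rep = Fraction(representative) if representative is not None else (lo + hi) / 2
        return cls(lo, hi, rep)

    def contains(self, other: "RelativeInterval") -> bool:
        return self.lo <= other.lo and other.hi <= self.hi

    def to_dict(self) -> dict:
        return {
            "variant": "relative_interval",
            "lo": str(self.lo),
            "hi": str(self.hi),
            "representative": str(self.representative),
        }

    def __str__(self) -> str:
        return f"({self.lo}, {self.hi})@{self.representative}"


Value = FixedNatural | RelativeInterval


@dataclass
class ValueMap:
    """Per-level and per-instance structural granularity values.

    ``unvalued`` lists entities outside every valued perspective; ``ties``
    records sibling fiat parts that received identical intervals (the
    framework orders nested parts only, so siblings tie by design).
    """

    level_values: dict[str, Value] = field(default_factory=dict)
    type_values: dict[str, Value] = field(default_factory=dict)
    instance_values: dict[str, Value] = field(default_factory=dict)
    unvalued: list[str] = field(default_factory=list)
    ties: list[tuple[str, ...]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "levels": {k: v.to_dict() for k, v in sorted(self.level_values.items())},
            "types": {k: v.to_dict() for k, v in sorted(self.type_values.items())},
            "instances": {
                k: v.to_dict() for k, v in sorted(self.instance_values.items())
            },
            "unvalued": sorted(self.unvalued),
            "ties": [list(t) for t in self.ties],
        }


def assign_backbone_values(co: GranularityPerspective) -> ValueMap:
    """Level i of the compositional-object perspective (bottom-up) gets the
    fixed natural i."""
    if co.ptype is not PerspectiveType.COMPOSITIONAL_OBJECT:
        raise ParameterError("backbone values require the compositional-object perspective")
    vm = ValueMap()
    for lv in co.levels:
        value = FixedNatural(lv.index)
        vm.level_values[lv.id] = value
        for tid in lv.content:
            vm.type_values[tid] = value
    return vm


def refine_fiat_chain_values(
    chain: Sequence[str], host: RelativeInterval
) -> dict[str, RelativeInterval]:
    """Equal-width disjoint ordered open sub-intervals of ``host`` for a
    chain ordered finest to coarsest; representatives are midpoints and
    strictly increase along the chain.  A single-member chain keeps the
    host interval itself."""
    chain = list(chain)
    n = len(chain)
    if n == 0:
        return {}
    width = (host.hi - host.lo) / n
    out: dict[str, RelativeInterval] = {}
    for i, member in enumerate(chain, start=1):
        lo = host.lo + (i - 1) * width
        hi = host.lo + i * width
        out[member] = RelativeInterval.between(lo, hi)
    return out


def _interval_for_counterpart(persp: GranularityPerspective) -> RelativeInterval | None:
    """Type-level interval implied by a two-level perspective's anchoring:
    additional-compositional counterparts sit above their anchor level,
    spatial fiat counterparts below theirs."""
    if persp.anchor_co_level is None:
        return None
    a = persp.anchor_co_level
    if persp.ptype in (
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT,
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_AGGREGATE,
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_FIAT,
    ):
        return RelativeInterval.between(a, a + 1)
    if persp.ptype is PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT:
        # the aggregate is the part of an object at the anchor level
        return RelativeInterval.between(a - 1, a)
    if persp.ptype in (
        PerspectiveType.SPATIAL_FIAT_OF_OBJECT,
        PerspectiveType.SPATIAL_FIAT_OF_AGGREGATE,
    ):
        return RelativeInterval.between(a - 1, a)
    return None


def propagate_framework_values(
    f: GranularityFramework,
    backbone: ValueMap,
    p: Partonomy | None = None,
) -> ValueMap:
    """Extend the backbone assignment to every valuable level, type and
    instance of the framework.

    Levels whose content overlaps a backbone level inherit its natural
    (two distinct naturals for one level is a consistency error); anchored
    counterpart levels get the open interval between the adjacent naturals;
    resolution levels split their host interval (countable representative
    below the non-countable one); nested fiat-part instances recurse into
    strictly contained sub-intervals so that later deepening never moves an
    existing value.
    """
    vm = ValueMap(
        level_values=dict(backbone.level_values),
        type_values=dict(backbone.type_values),
    )
    co = f.co
    co_content_values = dict(backbone.type_values)

    def set_type_value(tid: str, value: Value, context: str) -> None:
        existing = vm.type_values.get(tid)
        if existing is not None and existing != value:
            raise ConsistencyError(
                f"type {tid!r} receives conflicting values {existing} and "
                f"{value} ({context})"
            )
        vm.type_values[tid] = value

    # pass 1: naturals inherited through content overlap with the backbone
    for persp in f.perspectives:
        if persp.id == co.id:
            continue
        for lv in persp.levels:
            if lv.instance_content:
                continue
            inherited = {
                co_content_values[tid].k
                for tid in lv.content
                if isinstance(co_content_values.get(tid), FixedNatural)
            }
            if len(inherited) > 1:
                raise ConsistencyError(
                    f"level {lv.id} overcrosses two backbone levels "
                    f"{sorted(inherited)}"
                )
            if inherited:
                value = FixedNatural(inherited.pop())
                vm.level_values[lv.id] = value
                for tid in lv.content:
                    set_type_value(tid, value, f"overcross at {lv.id}")

    # pass 2: fiat/aggregate counterpart types -> open intervals between the
    # adjacent naturals.  With a partonomy at hand the interval follows the
    # type's name-giving object: regional parts (cuts of their name-giver)
    # sit in (L-1, L), aggregate-like parts (containing their name-givers)
    # in (L, L+1).  Without one, the perspective anchor decides.
    _counterpart_index = {
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT: 2,
        PerspectiveType.COMPOSITIONAL_OBJECT_OF_AGGREGATE: 2,
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_FIAT: 2,
        PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_OBJECT: 1,
        PerspectiveType.SPATIAL_FIAT_OF_OBJECT: 1,
        PerspectiveType.SPATIAL_FIAT_OF_AGGREGATE: 1,
    }
    if p is not None:
        from .core_model import closure_pairs

        closed = closure_pairs(p, include_countable=False)
        co_level_of_type = {
            tid: v.k
            for tid, v in backbone.type_values.items()
            if isinstance(v, FixedNatural)
        }

        def name_giving_interval(tid: str) -> RelativeInterval | None:
            t = p.types.get(tid)
            if t is None or t.represents is not None:
                return None
            if t.kind == EntityKind.OBJECT or t.name_giving_object_type is None:
                return None
            level = co_level_of_type.get(t.name_giving_object_type)
            if level is None:
                return None
            aggregate_like = any(
                p.instances[c].type_id == t.name_giving_object_type
                for iid in p.instances_of_type(tid)
                for (c, w) in closed
                if w == iid
            )
            if aggregate_like:
                return RelativeInterval.between(level, level + 1)
            return RelativeInterval.between(level - 1, level)

        valuable: set[str] = set()
        for persp in f.perspectives:
            for lv in persp.levels:
                if not lv.instance_content:
                    valuable.update(lv.content)
        for tid in sorted(valuable):
            if tid in vm.type_values:
                continue
            interval = name_giving_interval(tid)
            if interval is not None:
                set_type_value(tid, interval, "name-giving anchor")
        for persp in f.perspectives:
            for lv in persp.levels:
                if lv.instance_content or lv.id in vm.level_values:
                    continue
                vals = {vm.type_values.get(tid) for tid in lv.content}
                if len(vals) == 1 and None not in vals:
                    vm.level_values[lv.id] = vals.pop()
    else:
        for persp in f.perspectives:
            interval = _interval_for_counterpart(persp)
            if interval is None or persp.ptype not in _counterpart_index:
                continue
            lv = persp.level(_counterpart_index[persp.ptype])
            if lv.id in vm.level_values:
                continue
            vm.level_values[lv.id] = interval
            for tid in lv.content:
                set_type_value(tid, interval, f"anchored level {lv.id}")

    # pass 2b: aggregate-of-aggregate chains stack equal-width sub-intervals
    for persp in f.perspectives:
        if persp.ptype is not PerspectiveType.COMPOSITIONAL_AGGREGATE_OF_AGGREGATE:
            continue
        if persp.anchor_co_level is None:
            continue
        host = RelativeInterval.between(
            persp.anchor_co_level, persp.anchor_co_level + 1
        )
        ordered = sorted(persp.levels, key=lambda lv: lv.index)
        sub = refine_fiat_chain_values([lv.id for lv in ordered], host)
        for lv in ordered:
            if lv.id not in vm.level_values:
                vm.level_values[lv.id] = sub[lv.id]
                for tid in lv.content:
                    set_type_value(tid, sub[lv.id], f"aggregate chain {persp.id}")

    # pass 3: resolution levels split the represented type's interval
    for persp in f.perspectives:
        if persp.ptype not in (
            PerspectiveType.RESOLUTION_OF_AGGREGATE,
            PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT,
        ):
            continue
        host = vm.type_values.get(persp.counterpart_type)
        if not isinstance(host, RelativeInterval):
            continue  # represented type not valued; levels stay unvalued
        span = host.hi - host.lo
        countable = RelativeInterval(host.lo, host.hi, host.lo + span / 3)
        mass = RelativeInterval(host.lo, host.hi, host.lo + 2 * span / 3)
        lower, upper = persp.level(1), persp.level(2)
        vm.level_values[lower.id] = countable
        vm.level_values[upper.id] = mass
        for tid in lower.content:
            set_type_value(tid, countable, f"resolution {persp.id}")
        for tid in upper.content:
            set_type_value(tid, mass, f"resolution {persp.id}")

    if p is None:
        return vm

    # pass 4: instance values; nested fiat parts recurse into sub-intervals
    fiat_children: dict[str, list[str]] = {}
    fiat_parents: dict[str, list[str]] = {}
    for e in p.edges:
        if e.relation == Relation.COUNTABLE_PROPER_PART_OF:
            continue
        if (
            p.kind_of(e.child) == EntityKind.FIAT_OBJECT_PART
            and p.kind_of(e.parent) == EntityKind.FIAT_OBJECT_PART
        ):
            fiat_children.setdefault(e.parent, []).append(e.child)
            fiat_parents.setdefault(e.child, []).append(e.parent)

    def fiat_value(iid: str) -> RelativeInterval | None:
        cached = vm.instance_values.get(iid)
        if isinstance(cached, RelativeInterval):
            return cached
        parents = fiat_parents.get(iid, [])
        if not parents:
            tv = vm.type_values.get(p.instances[iid].type_id)
            if not isinstance(tv, RelativeInterval):
                return None
            vm.instance_values[iid] = tv
            return tv
        parent_values = [v for q in parents if (v := fiat_value(q)) is not None]
        if not parent_values:
            return None
        host = min(parent_values, key=lambda v: v.representative)
        value = RelativeInterval.between(host.lo, host.representative)
        vm.instance_values[iid] = value
        return value

    # topmost fiats first so recursion terminates on parents
    for iid in sorted(set(fiat_children) | set(fiat_parents)):
        fiat_value(iid)

    for siblings in fiat_children.values():
        valued = [s for s in sorted(siblings) if s in vm.instance_values]
        if len(valued) > 1:
            vm.ties.append(tuple(valued))

    for iid in sorted(p.instances):
        if iid in vm.instance_values:
            continue
        tv = vm.type_values.get(p.instances[iid].type_id)
        if tv is None:
            vm.unvalued.append(iid)
        else:
            vm.instance_values[iid] = tv
    return vm


def check_value_monotonicity(p: Partonomy, v: ValueMap) -> LintReport:
    """Representatives must strictly increase from part to whole along every
    parthood edge; countable (resolution) edges are exempt up to equality."""
    report = LintReport()
    for e in p.edges:
        if e.child == e.parent:
            continue
        cv = v.instance_values.get(e.child)
        pv = v.instance_values.get(e.parent)
        if cv is None or pv is None:
            continue
        if e.relation == Relation.COUNTABLE_PROPER_PART_OF:
            ok = cv.representative <= pv.representative
        else:
            ok = cv.representative < pv.representative
        if not ok:
            report.add(
                "value_monotonicity",
                Severity.ERROR,
                f"part {e.child} (value {cv}) does not precede its whole "
                f"{e.parent} (value {pv})",
                [e.child, e.parent],
            )
    return report


def build_size_perspective(
    p: Partonomy,
    quantity: str,
    thresholds: Sequence[float | Fraction],
) -> GranularityPerspective:
    """Instance-only perspective binning instances of measured size into
    half-open threshold intervals; level index doubles as the scale
    granularity value.  Instances lacking the measure are excluded with a
    warning; an empty bin is a perspective error."""
    thresholds = [Fraction(t).limit_denominator(10**9) if isinstance(t, float) else Fraction(t) for t in thresholds]
    if not thresholds:
        raise PerspectiveError("a size perspective needs at least one threshold")
    if sorted(thresholds) != thresholds or len(set(thresholds)) != len(thresholds):
        raise ParameterError("thresholds must be strictly ascending")
    bins: list[list[str]] = [[] for _ in range(len(thresholds) + 1)]
    for iid in sorted(p.instances):
        ms = p.measures_for(iid, quantity)
        if not ms:
            warnings.warn(
                f"instance {iid!r} has no {quantity!r} measure; excluded from "
                "the size perspective",
                stacklevel=2,
            )
            continue
        value = Fraction(ms[0].value).limit_denominator(10**9)
        index = sum(1 for t in thresholds if value >= t)
        bins[index].append(iid)
    empty = [i + 1 for i, b in enumerate(bins) if not b]
    if empty:
        raise PerspectiveError(
            f"size perspective has empty level(s) {empty}; adjust thresholds"
        )
    pid = f"size:{quantity}"
    persp = GranularityPerspective(id=pid, ptype=PerspectiveType.SIZE_SCALE)
    for i, members in enumerate(bins, start=1):
        persp.levels.append(
            GranularityLevel(
                id=f"{pid}:L{i}",
                perspective_id=pid,
                index=i,
                content=frozenset(members),
                instance_content=True,
                scale_value=i,
            )
        )
    return persp


def values_table(
    vm: ValueMap, f: GranularityFramework | None = None
) -> list[tuple[str, str, str, str, str, str]]:
    """Rows (entity, perspective, level, representative, lo, hi) for TSV
    export; levels first, then instances."""
    rows: list[tuple[str, str, str, str, str, str]] = []
    level_persp = {}
    if f is not None:
        for persp in f.perspectives:
            for lv in persp.levels:
                level_persp[lv.id] = (persp.id, str(lv.index))
    for level_id, value in sorted(vm.level_values.items()):
        pid, idx = level_persp.get(level_id, ("", ""))
        lo, hi = _bounds(value)
        rows.append((level_id, pid, idx, str(value.representative), lo, hi))
    for iid, value in sorted(vm.instance_values.items()):
        lo, hi = _bounds(value)
        rows.append((iid, "", "", str(value.representative), lo, hi))
    return rows


def _bounds(value: Value) -> tuple[str, str]:
    if isinstance(value, RelativeInterval):
        return str(value.lo), str(value.hi)
    return str(value.k), str(value.k)
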