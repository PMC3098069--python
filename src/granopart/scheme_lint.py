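"""Auditing external granularity schemes.

An external scheme is an ordered list of named levels with member types —
the shape in which published granularity schemes for anatomy are printed.
The auditor checks such a scheme, over an instantiating partonomy, against
the seven classical granularity principles plus the two later general
principles, the single-level contract of the level-lookup function, and
this framework's own consistency rules (no mixing of compositional and
spatial levels in one perspective, no 'object aggregate' kind for types
whose instances contain fiat portions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core_model import (
    EntityKind,
    Partonomy,
    closure_pairs,
    exhaustive_sum_check,
    maximum_instances,
)
from .errors import SchemeError, SchemeLookupError
from .report import LintReport, Severity


@dataclass(frozen=True)
class SchemeLevel:
    label: str
    kind: Optional[EntityKind] = None
    members: tuple[str, ...] = ()


@dataclass
class ExternalScheme:
    """An ordered granularity scheme: levels fine to coarse, each carrying
    a kind annotation and the ids of the types it houses."""

    name: str
    ordered_levels: list[SchemeLevel] = field(default_factory=list)
    declared: str = "compositional"

    def __post_init__(self):
        labels = [lv.label for lv in self.ordered_levels]
        if len(set(labels)) != len(labels):
            raise SchemeError(f"scheme {self.name!r} repeats a level label")

    @property
    def n_levels(self) -> int:
        return len(self.ordered_levels)

    def level_index(self, label: str) -> int:
        for i, lv in enumerate(self.ordered_levels, start=1):
            if lv.label == label:
                return i
        raise SchemeLookupError(f"scheme {self.name!r} has no level {label!r}")

    def member_types(self) -> set[str]:
        return {m for lv in self.ordered_levels for m in lv.members}

    def restricted_to_kinds(self, kinds: Iterable[EntityKind]) -> "ExternalScheme":
        kinds = set(kinds)
        return ExternalScheme(
            name=f"{self.name}[{'|'.join(sorted(k.value for k in kinds))}]",
            ordered_levels=[lv for lv in self.ordered_levels if lv.kind in kinds],
            declared=self.declared,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "declared": self.declared,
            "levels": [
                {
                    "label": lv.label,
                    "kind": lv.kind.value if lv.kind else None,
                    "members": list(lv.members),
                }
                for lv in self.ordered_levels
            ],
        }


def gr_lookup(scheme: ExternalScheme, t: str) -> str:
    """The level a type resides in; exactly one by contract."""
    hits = [lv.label for lv in scheme.ordered_levels if t in lv.members]
    if not hits:
        raise SchemeLookupError(f"type {t!r} is unknown to scheme {scheme.name!r}")
    if len(hits) > 1:
        raise SchemeError(
            f"scheme {scheme.name!r} places {t!r} in {len(hits)} levels "
            f"({', '.join(hits)}); the level lookup must be single-valued"
        )
    return hits[0]


def _level_instances(scheme: ExternalScheme, p: Partonomy) -> list[list[str]]:
    out = []
    for lv in scheme.ordered_levels:
        members = set(lv.members)
        out.append(
            sorted(i for i, inst in p.instances.items() if inst.type_id in members)
        )
    return out


def check_kumar_principles(scheme: ExternalScheme, p: Partonomy) -> LintReport:
    """Audit the scheme + instantiating partonomy against the seven
    principles and the two general principles.  The report is total: each
    principle appears exactly once, pass or fail; the causal and temporal
    principles (6, 7) and, absent measures, the size principle (5) are
    reported as not evaluable.  'Next higher level' reads the scheme's own
    printed order.
    """
    report = LintReport()
    closed = closure_pairs(p, include_countable=False)
    per_level = _level_instances(scheme, p)
    n = scheme.n_levels

    empty = [lv.label for lv in scheme.ordered_levels if not lv.members]
    if empty:
        report.add(
            "kumar_p1",
            Severity.ERROR,
            "levels without any grain type",
            empty,
        )
    else:
        report.add(
            "kumar_p1", Severity.INFO, "every level is determined by a grain type"
        )

    p2_failures: list[str] = []
    for k in range(n - 1):
        here, above = per_level[k], set(per_level[k + 1])
        if not here or not above:
            continue
        for i in here:
            if not any((i, j) in closed for j in above):
                p2_failures.append(i)
    if p2_failures:
        report.add(
            "kumar_p2",
            Severity.ERROR,
            "grains that are not part of any grain of the next higher level",
            p2_failures,
        )
    else:
        report.add(
            "kumar_p2",
            Severity.INFO,
            "every grain is part of a grain of the next higher level",
        )

    maxima = maximum_instances(p)
    if len(maxima) != 1:
        report.add(
            "kumar_p3",
            Severity.NOT_EVALUABLE,
            f"partonomy has {len(maxima)} maximal instances; no unique whole to "
            "sum to",
        )
        whole = None
    else:
        whole = maxima[0]
        p3_failures: list[str] = []
        for lv, instances in zip(scheme.ordered_levels, per_level):
            if not instances or whole in instances:
                continue
            complete, _missing = exhaustive_sum_check(instances, whole, p)
            if not complete:
                p3_failures.append(lv.label)
        if p3_failures:
            report.add(
                "kumar_p3",
                Severity.ERROR,
                f"levels whose grains do not sum to the whole {whole}",
                p3_failures,
            )
        else:
            report.add(
                "kumar_p3",
                Severity.INFO,
                "every instantiated level sums exhaustively to the whole",
            )

    report.add(
        "kumar_p4",
        Severity.INFO,
        "grains of one level need not be of equal size (non-requirement)",
    )

    quantities = {m.quantity for m in p.measures}
    if not quantities:
        report.add(
            "kumar_p5",
            Severity.NOT_EVALUABLE,
            "no measures supplied; size comparison needs an explicit quantity",
        )
    else:
        p5_failures: list[str] = []
        for k in range(n - 1):
            here, above = per_level[k], set(per_level[k + 1])
            for i in here:
                for j in above:
                    if (i, j) not in closed:
                        continue
                    for q in sorted(quantities):
                        mi = p.measures_for(i, q)
                        mj = p.measures_for(j, q)
                        if mi and mj and not (mi[0].value < mj[0].value):
                            p5_failures.append(f"{i}<{j}")
        if p5_failures:
            report.add(
                "kumar_p5",
                Severity.ERROR,
                "grains not smaller than the next-higher entities they are part of",
                p5_failures,
            )
        else:
            report.add(
                "kumar_p5",
                Severity.INFO,
                "measured grains are smaller than their next-higher wholes",
            )

    report.add(
        "kumar_p6",
        Severity.NOT_EVALUABLE,
        "causal-law association of levels is outside spatio-structural scope",
    )
    report.add(
        "kumar_p7",
        Severity.NOT_EVALUABLE,
        "temporal level change is outside spatio-structural scope",
    )

    g1_failures: list[str] = []
    g2_failures: list[str] = []
    for k in range(n):
        here = per_level[k]
        coarser = {i for lvl in per_level[k + 1 :] for i in lvl}
        finer = {i for lvl in per_level[:k] for i in lvl}
        for i in here:
            if k < n - 1 and coarser and not any((i, j) in closed for j in coarser):
                g1_failures.append(i)
            if k > 0 and finer and not any((j, i) in closed for j in finer):
                g2_failures.append(i)
    if g1_failures:
        report.add(
            "kumar_g1",
            Severity.ERROR,
            "instances below the top level with no whole at any coarser level",
            g1_failures,
        )
    else:
        report.add(
            "kumar_g1",
            Severity.INFO,
            "every non-top instance has a whole at some coarser level",
        )
    if g2_failures:
        report.add(
            "kumar_g2",
            Severity.ERROR,
            "instances above the bottom level with no part at any finer level",
            g2_failures,
        )
    else:
        report.add(
            "kumar_g2",
            Severity.INFO,
            "every non-bottom instance has a part at some finer level",
        )
    return report


def check_scheme_consistency(
    scheme: ExternalScheme, p: Partonomy | None = None
) -> LintReport:
    """Framework-consistency audit of an external scheme.

    A scheme declared compositional must not mix fiat-kind levels into its
    object/aggregate levels; a type kinded 'object aggregate' whose
    instances contain fiat portions (or loose members of other types)
    should be re-kinded as a fiat object part and renamed accordingly.
    """
    report = LintReport()
    kinds_present = {lv.kind for lv in scheme.ordered_levels if lv.kind is not None}
    bona_fide = {EntityKind.OBJECT, EntityKind.OBJECT_AGGREGATE}
    if scheme.declared == "compositional" and kinds_present & bona_fide:
        for lv in scheme.ordered_levels:
            if lv.kind == EntityKind.FIAT_OBJECT_PART:
                report.add(
                    "mixed_perspective",
                    Severity.ERROR,
                    f"level {lv.label!r} houses fiat object parts inside a "
                    "compositional (object/aggregate) perspective; move it to a "
                    "spatial perspective",
                    [lv.label],
                )
    if p is None:
        return report

    closed = closure_pairs(p, include_countable=False)
    for tid in sorted(scheme.member_types() & set(p.types)):
        t = p.types[tid]
        if t.kind != EntityKind.OBJECT_AGGREGATE:
            continue
        offenders: set[str] = set()
        for iid in p.instances_of_type(tid):
            member_ids = {
                c
                for (c, w) in closed
                if w == iid and p.instances[c].type_id == t.name_giving_object_type
            }
            for (c, w) in closed:
                if w != iid or c in member_ids:
                    continue
                if p.kind_of(c) == EntityKind.FIAT_OBJECT_PART:
                    offenders.add(p.instances[c].type_id)
                elif not any((c, m) in closed for m in member_ids):
                    # loose content (e.g. matrix molecules) between the members
                    offenders.add(p.instances[c].type_id)
        if offenders:
            labels = sorted(p.types[o].label for o in offenders if o in p.types)
            suffix = labels[0] if labels else "fiat object part"
            report.add(
                "aggregate_misuse",
                Severity.ERROR,
                f"type {t.label!r} is kinded 'object aggregate' but its "
                f"instances contain {', '.join(labels) or 'fiat portions'}; "
                f"rename it to {t.label + ' with ' + suffix!r} and re-kind it "
                "as a fiat object part",
                [tid, *sorted(offenders)],
            )
    return report
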