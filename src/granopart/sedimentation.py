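"""Type granularity from instance granularity.

A type settles at the lowest instance granularity level any of its
instances occupies; types whose extensions span several levels are the
level-crossing types characteristic of cumulative-constitutive
organization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .core_model import Partonomy
from .errors import ReferenceError_
from .partition_tree import InstanceLevel


@dataclass
class TypeLevelMap:
    """Mapping from type id to the (1-based, bottom-up) level index the type
    sedimented to."""

    assignments: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, type_id: str) -> int:
        return self.assignments[type_id]

    def __contains__(self, type_id: str) -> bool:
        return type_id in self.assignments

    def to_dict(self) -> dict:
        return dict(sorted(self.assignments.items()))


def _level_memberships(
    levels: Sequence[InstanceLevel], p: Partonomy
) -> dict[str, set[int]]:
    membership: dict[str, set[int]] = {}
    for level in levels:
        for iid in level.content:
            if iid not in p.instances:
                raise ReferenceError_(f"level {level.index} lists unknown instance {iid!r}")
            membership.setdefault(iid, set()).add(level.index)
    return membership


def sediment_types(levels: Sequence[InstanceLevel], p: Partonomy) -> TypeLevelMap:
    """Assign each instantiated type the minimum level index over its
    instances' level memberships.

    Instances absent from every level raise; types without instances are
    omitted with a warning (ontologies commonly declare uninstantiated
    types).
    """
    membership = _level_memberships(levels, p)
    covered = {iid for level in levels for iid in level.content}
    by_type: dict[str, set[int]] = {}
    for iid, inst in p.instances.items():
        if iid not in covered:
            continue
        by_type.setdefault(inst.type_id, set()).update(membership[iid])
    out = TypeLevelMap()
    for type_id in sorted(p.types):
        if type_id in by_type:
            out.assignments[type_id] = min(by_type[type_id])
        elif not any(inst.type_id == type_id for inst in p.instances.values()):
            warnings.warn(
                f"type {type_id!r} has no instances; omitted from the level map",
                stacklevel=2,
            )
    return out


def detect_crossing_types(
    levels: Sequence[InstanceLevel], p: Partonomy
) -> set[tuple[str, frozenset[int]]]:
    """Types whose instances occupy more than one level, with the occupied
    index set."""
    membership = _level_memberships(levels, p)
    by_type: dict[str, set[int]] = {}
    for iid, indices in membership.items():
        by_type.setdefault(p.instances[iid].type_id, set()).update(indices)
    return {
        (type_id, frozenset(indices))
        for type_id, indices in by_type.items()
        if len(indices) > 1
    }
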