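"""Deterministic generators and bundled fixtures.

The generator emulates cumulative-constitutive organization: object layers
connected by direct parthood, with a configurable fraction of each layer
attached directly to the maximum object instead of a whole of the adjacent
layer (free cells, extracellular molecules), optional fiat
"aggregate with portion" types with countable/non-countable
representation pairs, and optional fiat partitions of the maximum object.

Bundled fixtures provide small worked partonomies (a cumulative organ with
three compositional cuts, a three-level compositional chain, an organ with
a nested fiat-part chain, an anatomy demo) and two published external
schemes (a twelve-level human-anatomy scheme, a seven-level salient
scheme plus its five transitional levels).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core_model import (
    EntityKind,
    Partonomy,
    Relation,
    RepresentationLink,
)
from .errors import FixtureLookupError, ParameterError
from .scheme_lint import ExternalScheme, SchemeLevel

DIRECT = Relation.DIRECT_PROPER_PART_OF


@dataclass
class GeneratorParams:
    """Parameters of the cumulative partonomy generator.

    ``branching[k-1]`` is the number of level-k children per level-(k+1)
    whole (k = 1..n-1); ``free_fraction[k-1]`` the fraction of level-k
    instances attached directly to the maximum object (k = 1..n-2; the
    layer just below the maximum attaches there anyway).
    """

    n_co_levels: int = 4
    branching: int | list[int] = 2
    free_fraction: float | list[float] = 0.0
    with_ecm: bool = False
    n_fiat_parts: int = 0
    seed: int = 0
    free_attach: str = "max"  # or "intermediate"

    def normalized(self) -> tuple[list[int], list[float]]:
        n = self.n_co_levels
        if n < 2:
            raise ParameterError("n_co_levels must be at least 2")
        branching = (
            list(self.branching)
            if isinstance(self.branching, (list, tuple))
            else [self.branching] * (n - 1)
        )
        if len(branching) != n - 1 or any(b < 2 for b in branching):
            raise ParameterError(
                "branching must give one value >= 2 per level below the top"
            )
        free = (
            list(self.free_fraction)
            if isinstance(self.free_fraction, (list, tuple))
            else [self.free_fraction] * max(n - 2, 0)
        )
        if len(free) == n - 1:
            if free[-1] != 0:
                raise ParameterError(
                    "a free fraction at the level below the maximum has no "
                    "effect; it must be 0"
                )
            free = free[:-1]
        if len(free) != max(n - 2, 0) or any(not (0 <= x < 1) for x in free):
            raise ParameterError(
                "free_fraction must give one value in [0, 1) per level 1..n-2"
            )
        if self.with_ecm and n < 3:
            raise ParameterError("with_ecm requires at least 3 object levels")
        if self.n_fiat_parts and self.n_fiat_parts < 2:
            raise ParameterError("n_fiat_parts must be 0 or at least 2")
        if self.free_attach not in ("max", "intermediate"):
            raise ParameterError("free_attach must be 'max' or 'intermediate'")
        return branching, free


def generate_cumulative_partonomy(params: GeneratorParams) -> Partonomy:
    """Deterministic cumulative-constitutive partonomy.

    With all free fractions zero the result is a pure constitutive
    hierarchy (every cut sums exhaustively); any positive fraction makes
    the corresponding layer's type cross instance granularity levels.
    """
    branching, free = params.normalized()
    n = params.n_co_levels
    rng = random.Random(params.seed)
    p = Partonomy()
    for k in range(1, n + 1):
        p.add_type(f"gen:T{k}", f"level-{k} object", EntityKind.OBJECT)

    counters = {k: 0 for k in range(1, n + 1)}

    def new_instance(level: int) -> str:
        counters[level] += 1
        iid = f"gen:I{level}_{counters[level]}"
        p.add_instance(iid, f"gen:T{level}")
        return iid

    def grow(parent: str, level: int) -> list[str]:
        """Attach a full subtree of levels ``level`` .. 1 under ``parent``."""
        made = []
        for _ in range(branching[level - 1]):
            child = new_instance(level)
            p.add_edge(child, parent, DIRECT)
            made.append(child)
            if level > 1:
                grow(child, level - 1)
        return made

    top = new_instance(n)
    grow(top, n - 1)

    regular_counts = dict(counters)
    for k in range(n - 2, 0, -1):
        ff = free[k - 1]
        if ff <= 0:
            continue
        n_free = max(1, round(ff * regular_counts[k]))
        for _ in range(n_free):
            free_inst = new_instance(k)
            if params.free_attach == "intermediate" and k + 2 <= n:
                hosts = [
                    i
                    for i, inst in p.instances.items()
                    if inst.type_id == f"gen:T{k + 2}"
                ]
                host = rng.choice(sorted(hosts))
            else:
                host = top
            p.add_edge(free_inst, host, DIRECT)
            if k > 1:
                grow(free_inst, k - 1)

    if params.with_ecm:
        member_level = n - 1
        p.add_type(
            "gen:AggF",
            f"level-{member_level} aggregate with portion",
            EntityKind.FIAT_OBJECT_PART,
            name_giving_object_type=f"gen:T{member_level}",
        )
        p.add_type(
            "gen:RepC",
            f"level-{member_level} cluster with portion",
            EntityKind.FIAT_OBJECT_PART,
            name_giving_object_type=f"gen:T{member_level}",
            represents=RepresentationLink("gen:AggF", countable=True),
        )
        p.add_type(
            "gen:RepM",
            "portion of substance",
            EntityKind.FIAT_OBJECT_PART,
            name_giving_object_type=f"gen:T{member_level}",
            represents=RepresentationLink("gen:AggF", countable=False),
        )
        members = sorted(
            i
            for i, inst in p.instances.items()
            if inst.type_id == f"gen:T{member_level}"
        )
        half = max(1, len(members) // 2)
        groups = [members[:half], members[half:] or members[:1]]
        for gi, group in enumerate(groups, start=1):
            agg = f"gen:agg_{gi}"
            p.add_instance(agg, "gen:AggF")
            for m in group:
                p.add_edge(m, agg, DIRECT)
            for _ in range(2):  # matrix molecules between the members
                ecm = new_instance(1)
                p.add_edge(ecm, agg, DIRECT)
            p.add_edge(agg, top, DIRECT)

    if params.n_fiat_parts:
        p = generate_fiat_partition(p, top, params.n_fiat_parts, params.seed)
    return p


def generate_fiat_partition(
    p: Partonomy, whole: str, k: int, seed: int
) -> Partonomy:
    """Return a copy of ``p`` with ``whole`` cut into ``k`` pairwise disjoint
    fiat parts whose contents union to the whole's direct non-fiat parts."""
    if k < 2:
        raise ParameterError("a fiat partition needs at least two parts")
    if whole not in p.instances:
        raise ParameterError(f"unknown whole {whole!r}")
    members = sorted(
        e.child
        for e in p.edges
        if e.parent == whole
        and e.relation != Relation.COUNTABLE_PROPER_PART_OF
        and p.kind_of(e.child) != EntityKind.FIAT_OBJECT_PART
    )
    if k > len(members):
        raise ParameterError(
            f"cannot cut {whole!r} into {k} parts; it has only "
            f"{len(members)} direct non-fiat parts"
        )
    out = p.copy()
    whole_type = p.instances[whole].type_id
    fiat_type = f"fiat:part_of_{whole_type.split(':')[-1]}"
    if fiat_type not in out.types:
        out.add_type(
            fiat_type,
            f"fiat part of {p.types[whole_type].label}",
            EntityKind.FIAT_OBJECT_PART,
            name_giving_object_type=whole_type,
        )
    rng = random.Random(seed)
    shuffled = list(members)
    rng.shuffle(shuffled)
    groups: list[list[str]] = [[] for _ in range(k)]
    for i, m in enumerate(shuffled):
        groups[i % k].append(m)
    for gi, group in enumerate(groups, start=1):
        part = f"fiat:{whole}_part_{gi}"
        out.add_instance(part, fiat_type)
        for m in sorted(group):
            out.add_edge(m, part, DIRECT)
        out.add_edge(part, whole, DIRECT)
    return out


# -- bundled fixtures ----------------------------------------------------------


def _fig2_organ() -> Partonomy:
    p = Partonomy()
    p.add_type("molecule", "molecule", EntityKind.OBJECT)
    p.add_type("organelle", "organelle", EntityKind.OBJECT)
    p.add_type("cell", "cell", EntityKind.OBJECT)
    p.add_type("organ", "organ", EntityKind.OBJECT)
    p.add_instance("O", "organ")
    for c in ("q", "r"):
        p.add_instance(c, "cell")
    for o in ("m", "n", "o", "p"):
        p.add_instance(o, "organelle")
    for mol in "abcdefghijkl":
        p.add_instance(mol, "molecule")
    # cut (i): cells q, r and extracellular molecules a-d
    for child in ("q", "r", "a", "b", "c", "d"):
        p.add_edge(child, "O", DIRECT)
    # cut (ii): organelles m-p and cellular molecules e-h, beneath the cells
    for child in ("m", "n", "e", "f"):
        p.add_edge(child, "q", DIRECT)
    for child in ("o", "p", "g", "h"):
        p.add_edge(child, "r", DIRECT)
    # cut (iii): organelle molecules i-l
    for child, host in (("i", "m"), ("j", "n"), ("k", "o"), ("l", "p")):
        p.add_edge(child, host, DIRECT)
    return p


def fig2_cuts() -> list[list[str]]:
    """The three compositional cuts of the cumulative organ, coarse to fine."""
    return [
        ["q", "r", "a", "b", "c", "d"],
        ["m", "n", "o", "p", "a", "b", "c", "d", "e", "f", "g", "h"],
        list("abcdefghijkl"),
    ]


def _fig5_co() -> Partonomy:
    p = Partonomy()
    p.add_type("organelle", "organelle", EntityKind.OBJECT)
    p.add_type("cell", "cell", EntityKind.OBJECT)
    p.add_type("organ", "organ", EntityKind.OBJECT)
    p.add_instance("organ1", "organ")
    for ci in (1, 2):
        cell = f"cell{ci}"
        p.add_instance(cell, "cell")
        p.add_edge(cell, "organ1", DIRECT)
        for oi in (1, 2):
            org = f"organelle{ci}{oi}"
            p.add_instance(org, "organelle")
            p.add_edge(org, cell, DIRECT)
    return p


def _fig11_organ() -> Partonomy:
    p = Partonomy()
    p.add_type("cell", "cell", EntityKind.OBJECT)
    p.add_type("organ", "organ", EntityKind.OBJECT)
    p.add_type(
        "fiat_organ_part",
        "fiat organ part",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="organ",
    )
    p.add_instance("organ1", "organ")
    p.add_instance("cell1", "cell")
    p.add_instance("cell2", "cell")
    for fi in (1, 2, 3):
        p.add_instance(f"fop{fi}", "fiat_organ_part")
    p.add_edge("cell1", "fop1", DIRECT)
    p.add_edge("fop1", "fop2", DIRECT)
    p.add_edge("fop2", "fop3", DIRECT)
    p.add_edge("fop3", "organ1", DIRECT)
    p.add_edge("cell2", "organ1", DIRECT)
    return p


_KUMAR_LEVELS: list[tuple[str, str, EntityKind]] = [
    ("Biological macromolecule", "kumar:macromolecule", EntityKind.OBJECT),
    ("Subcellular organelle", "kumar:organelle", EntityKind.OBJECT),
    (
        "Collection of subcellular organelles",
        "kumar:organelle_collection",
        EntityKind.FIAT_OBJECT_PART,
    ),
    ("Cell", "kumar:cell", EntityKind.OBJECT),
    ("Collection of cells", "kumar:cell_collection", EntityKind.FIAT_OBJECT_PART),
    ("Tissue subdivision", "kumar:tissue_subdivision", EntityKind.FIAT_OBJECT_PART),
    ("Tissue", "kumar:tissue", EntityKind.FIAT_OBJECT_PART),
    ("Organ part", "kumar:organ_part", EntityKind.FIAT_OBJECT_PART),
    ("Organ", "kumar:organ", EntityKind.OBJECT),
    ("Cardinal body part", "kumar:cardinal_body_part", EntityKind.FIAT_OBJECT_PART),
    ("Organ system", "kumar:organ_system", EntityKind.FIAT_OBJECT_PART),
    ("Organism", "kumar:organism", EntityKind.OBJECT),
]


def _kumar_human() -> ExternalScheme:
    return ExternalScheme(
        name="kumar_human",
        declared="compositional",
        ordered_levels=[
            SchemeLevel(label=label, kind=kind, members=(tid,))
            for label, tid, kind in _KUMAR_LEVELS
        ],
    )


def _kumar_demo() -> Partonomy:
    """A small anatomy instantiating part of the twelve-level scheme:
    molecules < cells < organs < cardinal parts / organ system < body.
    The organ system overlaps both cardinal body parts (the lung sits in
    the chest, the brain in the head), so the printed adjacency of the two
    fiat levels fails the part-of-next-higher-level principle."""
    p = Partonomy()
    p.add_type("kumar:macromolecule", "Biological macromolecule", EntityKind.OBJECT)
    p.add_type("kumar:cell", "Cell", EntityKind.OBJECT)
    p.add_type("kumar:organ", "Organ", EntityKind.OBJECT)
    p.add_type("kumar:organism", "Organism", EntityKind.OBJECT)
    p.add_type(
        "kumar:cardinal_body_part",
        "Cardinal body part",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="kumar:organism",
    )
    p.add_type(
        "kumar:organ_system",
        "Organ system",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="kumar:organ",
    )
    p.add_instance("body", "kumar:organism")
    for fiat in ("head", "chest"):
        p.add_instance(fiat, "kumar:cardinal_body_part")
        p.add_edge(fiat, "body", DIRECT)
    p.add_instance("resp", "kumar:organ_system")
    p.add_edge("resp", "body", DIRECT)
    p.add_instance("lung", "kumar:organ")
    p.add_edge("lung", "chest", DIRECT)
    p.add_edge("lung", "resp", DIRECT)
    p.add_instance("brain", "kumar:organ")
    p.add_edge("brain", "head", DIRECT)
    cells = {"lung": ("c1", "c2"), "brain": ("c3", "c4")}
    mol_i = 0
    for organ, cc in cells.items():
        for c in cc:
            p.add_instance(c, "kumar:cell")
            p.add_edge(c, organ, DIRECT)
            for _ in range(2):
                mol_i += 1
                p.add_instance(f"mol{mol_i}", "kumar:macromolecule")
                p.add_edge(f"mol{mol_i}", c, DIRECT)
    return p


_FMA_SALIENT: list[tuple[str, str, EntityKind]] = [
    ("Biological macromolecule", "fma:macromolecule", EntityKind.OBJECT),
    ("Cell", "fma:cell", EntityKind.OBJECT),
    ("Portion of tissue", "fma:portion_of_tissue", EntityKind.FIAT_OBJECT_PART),
    ("Organ", "fma:organ", EntityKind.OBJECT),
    ("Organ system", "fma:organ_system", EntityKind.FIAT_OBJECT_PART),
    ("Cardinal body part", "fma:cardinal_body_part", EntityKind.FIAT_OBJECT_PART),
    ("Body", "fma:body", EntityKind.OBJECT),
]

_FMA_TRANSITIONAL: list[tuple[str, str, EntityKind]] = [
    ("Cardinal cell part", "fma:cardinal_cell_part", EntityKind.FIAT_OBJECT_PART),
    ("Cardinal tissue part", "fma:cardinal_tissue_part", EntityKind.FIAT_OBJECT_PART),
    ("Cardinal organ part", "fma:cardinal_organ_part", EntityKind.FIAT_OBJECT_PART),
    (
        "Organ system subdivision",
        "fma:organ_system_subdivision",
        EntityKind.FIAT_OBJECT_PART,
    ),
    (
        "Subdivision of cardinal body part",
        "fma:subdivision_of_cardinal_body_part",
        EntityKind.FIAT_OBJECT_PART,
    ),
]


def _fma_scheme(levels: list[tuple[str, str, EntityKind]], name: str, declared: str) -> ExternalScheme:
    return ExternalScheme(
        name=name,
        declared=declared,
        ordered_levels=[
            SchemeLevel(label=label, kind=kind, members=(tid,))
            for label, tid, kind in levels
        ],
    )


_FIXTURES = {
    "fig2_organ": _fig2_organ,
    "fig5_co": _fig5_co,
    "fig11_organ": _fig11_organ,
    "kumar_human": _kumar_human,
    "kumar_demo": _kumar_demo,
    "fma_scheme": lambda: _fma_scheme(_FMA_SALIENT, "fma_salient", "compositional"),
    "fma_transitional": lambda: _fma_scheme(
        _FMA_TRANSITIONAL, "fma_transitional", "spatial"
    ),
}


def fixture(name: str) -> Partonomy | ExternalScheme:
    """A fresh copy of a bundled fixture.

    Partonomies: ``fig2_organ`` (cumulative organ with three cuts),
    ``fig5_co`` (three-level compositional chain), ``fig11_organ`` (nested
    fiat-part chain in an organ), ``kumar_demo`` (anatomy demo
    instantiating the twelve-level scheme).  Schemes: ``kumar_human``,
    ``fma_scheme`` (salient levels), ``fma_transitional``.
    """
    try:
        maker = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(_FIXTURES))}"
        ) from None
    return maker()
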