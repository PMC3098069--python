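import pytest

from granopart.core_model import EntityKind, ParthoodEdge, Partonomy, Relation, RepresentationLink
from granopart.errors import ClassificationError, PerspectiveError
from granopart.perspectives import (
    GranularityFramework,
    GranularityLevel,
    GranularityPerspective,
    PerspectiveType,
    build_additional_compositional,
    build_co_perspective,
    build_fiat_chain,
    build_framework,
    build_resolution,
    build_spatial_basic,
    check_instance_rules,
    classify_edge,
    classify_edges,
    detect_overcross,
    validate_framework,
)
from granopart.synthetic_data import GeneratorParams, generate_cumulative_partonomy

DIRECT = Relation.DIRECT_PROPER_PART_OF


def cell_aggregate_world() -> Partonomy:
    """Organ containing two 'cell aggregate with ECM' parts; cells and ECM
    molecules inside the aggregates; representation pair declared."""
    p = Partonomy()
    p.add_type("molecule", "molecule", EntityKind.OBJECT)
    p.add_type("cell", "cell", EntityKind.OBJECT)
    p.add_type("organ", "organ", EntityKind.OBJECT)
    p.add_type(
        "cell_agg_ecm",
        "cell aggregate with ECM",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="cell",
    )
    p.add_type(
        "cell_cluster",
        "cell cluster with portion of ECM",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="cell",
        represents=RepresentationLink("cell_agg_ecm", countable=True),
    )
    p.add_type(
        "portion_of_tissue",
        "portion of tissue",
        EntityKind.FIAT_OBJECT_PART,
        name_giving_object_type="cell",
        represents=RepresentationLink("cell_agg_ecm", countable=False),
    )
    p.add_instance("O", "organ")
    for ci in range(1, 5):
        p.add_instance(f"c{ci}", "cell")
        p.add_edge(f"c{ci}", "O", DIRECT)
        for mi in (1, 2):
            p.add_instance(f"m{ci}{mi}", "molecule")
            p.add_edge(f"m{ci}{mi}", f"c{ci}", DIRECT)
    for ai, members in enumerate((("c1", "c2"), ("c3", "c4")), start=1):
        agg = f"agg{ai}"
        p.add_instance(agg, "cell_agg_ecm")
        for m in members:
            p.add_edge(m, agg, DIRECT)
        ecm = f"ecm{ai}"
        p.add_instance(ecm, "molecule")
        p.add_edge(ecm, agg, DIRECT)
        p.add_edge(agg, "O", DIRECT)
    return p


class TestClassifyEdge:
    def test_object_into_object_is_compositional(self, fig2):
        e = next(e for e in fig2.edges if e.child == "q")
        assert classify_edge(e, fig2) is PerspectiveType.COMPOSITIONAL_OBJECT

    def test_object_into_fiat(self):
        p = cell_aggregate_world()
        e = next(e for e in p.edges if e.pair == ("c1", "agg1"))
        assert classify_edge(e, p) is PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT

    def test_fiat_into_object_is_spatial(self, fig11):
        e = next(e for e in fig11.edges if e.pair == ("fop3", "organ1"))
        assert classify_edge(e, fig11) is PerspectiveType.SPATIAL_FIAT_OF_OBJECT

    def test_fiat_into_fiat(self, fig11):
        e = next(e for e in fig11.edges if e.pair == ("fop1", "fop2"))
        assert classify_edge(e, fig11) is PerspectiveType.SPATIAL_FIAT_OF_FIAT

    def test_countable_edge_resolves_via_represented_kind(self):
        p = cell_aggregate_world()
        p.add_instance("cl1", "cell_cluster")
        p.add_instance("pt1", "portion_of_tissue")
        e = p.add_edge("cl1", "pt1", Relation.COUNTABLE_PROPER_PART_OF)
        assert (
            classify_edge(e, p)
            is PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT
        )

    def test_plain_object_object_edge_unclassifiable(self, fig2):
        e = ParthoodEdge("i", "q", Relation.PROPER_PART_OF)
        with pytest.raises(ClassificationError):
            classify_edge(e, fig2)

    def test_classify_edges_never_drops_silently(self, fig2):
        fig2.add_edge("i", "q", Relation.PROPER_PART_OF)
        tagged, unclassified = classify_edges(fig2)
        assert len(unclassified) == 1
        assert sum(len(v) for v in tagged.values()) + 1 == len(fig2.edges)


class TestCoPerspective:
    def test_fig5_three_levels(self, fig5):
        co = build_co_perspective(fig5)
        assert [sorted(lv.content) for lv in co.levels] == [
            ["organelle"], ["cell"], ["organ"],
        ]

    def test_single_object_subtype_fails(self):
        p = Partonomy()
        p.add_type("t", "t", EntityKind.OBJECT)
        p.add_instance("x", "t")
        with pytest.raises(PerspectiveError):
            build_co_perspective(p)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_generator_level_count_recovered(self, n):
        p = generate_cumulative_partonomy(
            GeneratorParams(n_co_levels=n, branching=2, seed=0)
        )
        co = build_co_perspective(p)
        assert co.n_levels == n
        assert [sorted(lv.content) for lv in co.levels] == [
            [f"gen:T{k}"] for k in range(1, n + 1)
        ]

    def test_cumulative_layering_keeps_molecules_at_bottom(self, fig2):
        # molecules are direct parts of the organ too, yet stay at level 1
        co = build_co_perspective(fig2)
        assert sorted(co.levels[0].content) == ["molecule"]
        assert sorted(co.levels[-1].content) == ["organ"]


class TestAdditionalCompositional:
    def test_cell_aggregate_perspective(self):
        p = cell_aggregate_world()
        co = build_co_perspective(p)
        persps = build_additional_compositional(p, co)
        # ECM molecules directly in the aggregate anchor a second, separate
        # perspective at the molecule level; pick the cell-anchored one
        cell_level = next(
            q
            for q in persps
            if q.counterpart_type == "cell_agg_ecm" and q.anchor_co_level == 2
        )
        assert cell_level.n_levels == 2
        assert cell_level.levels[0].content == frozenset({"cell"})
        assert cell_level.levels[1].content == frozenset({"cell_agg_ecm"})
        assert cell_level.anchor_co_level == 2

    def test_no_counterparts_no_perspectives(self, fig5):
        co = build_co_perspective(fig5)
        assert build_additional_compositional(fig5, co) == []

    def test_count_matches_brute_force_grouping(self):
        p = generate_cumulative_partonomy(
            GeneratorParams(
                n_co_levels=4, branching=3, free_fraction=0.3, with_ecm=True,
                n_fiat_parts=3, seed=5,
            )
        )
        co = build_co_perspective(p)
        persps = build_additional_compositional(p, co)
        co_level = {t: lv.index for lv in co.levels for t in lv.content}
        expected = set()
        for e in p.edges:
            ct, pt = p.type_of(e.child), p.type_of(e.parent)
            if (
                ct.kind == EntityKind.OBJECT
                and pt.kind == EntityKind.FIAT_OBJECT_PART
                and e.relation == DIRECT
            ):
                expected.add((co_level[ct.id], pt.id))
        got = {
            (q.anchor_co_level, q.counterpart_type)
            for q in persps
            if q.ptype is PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT
        }
        assert got == expected


class TestSpatialBasic:
    def test_fiat_organ_part_perspective(self, fig11):
        co = build_co_perspective(fig11)
        persps = build_spatial_basic(fig11, co)
        assert len(persps) == 1
        sp = persps[0]
        assert sp.levels[0].content == frozenset({"fiat_organ_part"})
        assert sp.levels[1].content == frozenset({"organ"})

    def test_no_fiat_parts_empty(self, fig5):
        co = build_co_perspective(fig5)
        assert build_spatial_basic(fig5, co) == []

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_every_fiat_type_in_exactly_one_lower_level(self, k):
        from granopart.synthetic_data import generate_fiat_partition

        p = generate_cumulative_partonomy(
            GeneratorParams(n_co_levels=3, branching=4, seed=k)
        )
        p = generate_fiat_partition(p, "gen:I3_1", k, seed=k)
        co = build_co_perspective(p)
        persps = build_spatial_basic(p, co)
        for iid, inst in p.instances.items():
            if p.kind_of(iid) != EntityKind.FIAT_OBJECT_PART:
                continue
            hosting = [
                q for q in persps if inst.type_id in q.levels[0].content
            ]
            assert len(hosting) == 1


class TestResolution:
    def test_representation_pair_builds_one_perspective(self):
        p = cell_aggregate_world()
        persps = build_resolution(p)
        assert len(persps) == 1
        persp = persps[0]
        assert persp.ptype is PerspectiveType.RESOLUTION_OF_AGGREGATE_WITH_FIAT
        assert persp.levels[0].content == frozenset({"cell_cluster"})  # countable low
        assert persp.levels[1].content == frozenset({"portion_of_tissue"})

    def test_no_links_empty(self, fig5):
        assert build_resolution(fig5) == []

    def test_single_representation_skipped_with_warning(self):
        p = cell_aggregate_world()
        p.types.pop("portion_of_tissue")
        with pytest.warns(UserWarning):
            assert build_resolution(p) == []

    def test_count_equals_complete_representation_pairs(self):
        p = cell_aggregate_world()
        expected = 0
        by_target = {}
        for t in p.types.values():
            if t.represents:
                by_target.setdefault(t.represents.target_type, set()).add(
                    t.represents.countable
                )
        expected = sum(1 for flags in by_target.values() if flags == {True, False})
        assert len(build_resolution(p)) == expected == 1


class TestFiatChain:
    def test_fig11_chain_order(self, fig11):
        persps = build_fiat_chain(fig11)
        assert len(persps) == 1
        chain = [sorted(lv.content)[0] for lv in persps[0].levels]
        assert chain == ["fop1", "fop2", "fop3"]
        assert all(lv.instance_content for lv in persps[0].levels)

    def test_no_fiat_fiat_edges_empty(self, fig5):
        assert build_fiat_chain(fig5) == []

    def test_chain_order_equals_topological_sort(self, fig11):
        import networkx as nx

        g = nx.DiGraph()
        for e in fig11.edges:
            if (
                fig11.kind_of(e.child) == EntityKind.FIAT_OBJECT_PART
                and fig11.kind_of(e.parent) == EntityKind.FIAT_OBJECT_PART
            ):
                g.add_edge(e.child, e.parent)
        expected = list(nx.topological_sort(g))
        persps = build_fiat_chain(fig11)
        assert [sorted(lv.content)[0] for lv in persps[0].levels] == expected

    def test_branching_fiat_subgraph_rejected(self, fig11):
        fig11.add_instance("fop1b", "fiat_organ_part")
        fig11.add_edge("fop1b", "fop2", DIRECT)
        persps = build_fiat_chain(fig11)
        assert persps == []
        assert build_fiat_chain.last_rejected


class TestOvercross:
    def test_overlapping_perspectives_overcross_at_shared_levels(self):
        p = cell_aggregate_world()
        f = build_framework(p)
        # compositional cell-of-aggregate and spatial aggregate-of-organ
        # perspectives share the aggregate type; both touch the backbone
        assert any("co" in pair for pair in f.rp_pairs)
        comp = next(
            q.id for q in f.perspectives
            if q.ptype is PerspectiveType.COMPOSITIONAL_OBJECT_OF_FIAT
            and q.counterpart_type == "cell_agg_ecm"
        )
        spat = next(
            q.id for q in f.perspectives
            if q.ptype is PerspectiveType.SPATIAL_FIAT_OF_OBJECT
        )
        assert tuple(sorted((comp, spat))) in f.rp_pairs

    def test_disjoint_perspectives_do_not_overcross(self):
        a = GranularityPerspective("a", PerspectiveType.COMPOSITIONAL_OBJECT)
        a.levels = [
            GranularityLevel("a:L1", "a", 1, frozenset({"x"})),
            GranularityLevel("a:L2", "a", 2, frozenset({"y"})),
        ]
        b = GranularityPerspective("b", PerspectiveType.SPATIAL_FIAT_OF_OBJECT)
        b.levels = [
            GranularityLevel("b:L1", "b", 1, frozenset({"u"})),
            GranularityLevel("b:L2", "b", 2, frozenset({"v"})),
        ]
        f = GranularityFramework()
        f.add(a)
        f.add(b)
        assert detect_overcross(f) == set()
        assert f.rp_pairs == set()

    def test_overcross_equals_brute_force_intersections(self):
        p = cell_aggregate_world()
        f = build_framework(p)

        def lifted(level):
            out = set()
            for cid in level.content:
                if level.instance_content:
                    out.add(p.instances[cid].type_id)
                else:
                    out.add(cid)
                    t = p.types.get(cid)
                    if t and t.represents:
                        out.add(t.represents.target_type)
            return out

        expected = set()
        for i, a in enumerate(f.perspectives):
            for b in f.perspectives[i + 1:]:
                if any(
                    lifted(la) & lifted(lb)
                    for la in a.levels
                    for lb in b.levels
                ):
                    expected.add(tuple(sorted((a.id, b.id))))
        assert f.rp_pairs == expected


class TestValidateFramework:
    def test_default_synthetic_framework_clean(self):
        p = generate_cumulative_partonomy(
            GeneratorParams(
                n_co_levels=4, branching=3, free_fraction=0.3, with_ecm=True,
                n_fiat_parts=3, seed=7,
            )
        )
        f = build_framework(p)
        assert validate_framework(f).ok

    def test_entity_in_two_levels_of_one_perspective_flagged(self, fig5):
        f = build_framework(fig5)
        co = f.co
        # force 'cell' into the organ level as well
        top = co.levels[-1]
        co.levels[-1] = GranularityLevel(
            top.id, top.perspective_id, top.index, top.content | {"cell"}
        )
        report = validate_framework(f)
        assert report.by_rule("entity_single_level")

    def test_short_perspective_flagged(self):
        f = GranularityFramework()
        a = GranularityPerspective("co", PerspectiveType.COMPOSITIONAL_OBJECT)
        a.levels = [GranularityLevel("co:L1", "co", 1, frozenset({"x"}))]
        f.add(a)
        report = validate_framework(f)
        assert report.by_rule("keet_two_levels")

    def test_cut_off_perspective_flagged(self):
        f = GranularityFramework()
        a = GranularityPerspective("co", PerspectiveType.COMPOSITIONAL_OBJECT)
        a.levels = [
            GranularityLevel("co:L1", "co", 1, frozenset({"x"})),
            GranularityLevel("co:L2", "co", 2, frozenset({"y"})),
        ]
        b = GranularityPerspective("b", PerspectiveType.SPATIAL_FIAT_OF_OBJECT)
        b.levels = [
            GranularityLevel("b:L1", "b", 1, frozenset({"u"})),
            GranularityLevel("b:L2", "b", 2, frozenset({"v"})),
        ]
        f.add(a)
        f.add(b)
        detect_overcross(f)
        report = validate_framework(f)
        assert report.by_rule("perspective_cut_off")


class TestInstanceRules:
    def test_fig11_clean(self, fig11):
        f = build_framework(fig11)
        assert check_instance_rules(fig11, f).ok

    def test_fig2_organelles_fail_two_part_rule(self, fig2):
        # each organelle hosts exactly one molecule, so the two-object-parts
        # rule fires for all four of them (the worked organ is a sketch, not
        # a rule-conforming granulation)
        f = build_framework(fig2)
        report = check_instance_rules(fig2, f)
        witnesses = {w for v in report.by_rule("co_rule_2") for w in v.witnesses}
        assert witnesses == {"m", "n", "o", "p"}
        assert not report.by_rule("co_rule_3")
        assert not report.by_rule("spatial_rule_2")

    def test_object_with_single_object_part_flagged(self, fig5):
        fig5.add_instance("cell3", "cell")
        fig5.add_edge("cell3", "organ1", DIRECT)
        fig5.add_instance("organelle31", "organelle")
        fig5.add_edge("organelle31", "cell3", DIRECT)
        f = build_framework(fig5)
        report = check_instance_rules(fig5, f)
        assert any("cell3" in v.witnesses for v in report.by_rule("co_rule_2"))

    def test_fiat_with_parts_only_at_name_giving_level_flagged(self):
        # the fiat part's only object part sits at its name-giver's own level
        p = Partonomy()
        p.add_type("cell", "cell", EntityKind.OBJECT)
        p.add_type("organ", "organ", EntityKind.OBJECT)
        p.add_type(
            "fop", "fiat organ part", EntityKind.FIAT_OBJECT_PART,
            name_giving_object_type="organ",
        )
        p.add_instance("O", "organ")
        for c in ("c1", "c2"):
            p.add_instance(c, "cell")
            p.add_edge(c, "O", DIRECT)
        p.add_instance("O3", "organ")  # childless organ inside the fiat part
        p.add_instance("f1", "fop")
        p.add_instance("f2", "fop")
        p.add_edge("O3", "f1", Relation.PROPER_PART_OF)  # organ-level part only
        p.add_edge("f1", "O", DIRECT)
        p.add_edge("f2", "O", DIRECT)
        p.add_instance("c5", "cell")
        p.add_edge("c5", "f2", DIRECT)
        f = build_framework(p)
        report = check_instance_rules(p, f)
        assert any("f1" in v.witnesses for v in report.by_rule("additional_rule_3"))
        assert not any(
            "f2" in v.witnesses for v in report.by_rule("additional_rule_3")
        )
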