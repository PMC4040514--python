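"""Scene ingestion, selection, colour rules, and anatomical validity."""

from __future__ import annotations

import random

import networkx as nx
import pytest
import pydantic

import anatokb as ak
from anatokb import schema as S
from anatokb.fixture import tendon_insertion_query_text
from anatokb.model import Triple, TripleStore, lit, var
from anatokb.query import parse_query
from anatokb.rules import saturate
from anatokb.scene import (
    SceneError,
    SceneManifest,
    SceneObject,
    apply_colour_rules,
    check_scene_validity,
    dump_manifest,
    extract_scene,
    ingest_scene,
    load_manifest,
    select_objects,
)
from conftest import mcf


class TestIngest:
    def test_leg_manifest_triples(self, fixture):
        triples = set(ingest_scene(fixture.scene))
        assert Triple(mcf("id"), S.DISPLAYS, mcf("Leg")) in triples
        assert Triple(mcf("id"), S.CONTAINS, mcf("id1")) in triples
        assert Triple(mcf("id1"), S.DESCRIBES, mcf("Left_sartorius")) in triples
        assert Triple(mcf("id1"), S.HASMESH, lit("../geometries/l_sartorius.obj")) in triples
        assert Triple(mcf("id"), S.RDF_TYPE, S.SCENE_3D) in triples

    def test_zero_object_manifest_warns_and_emits_two_triples(self, caplog):
        manifest = SceneManifest(scene_id="mcf:empty", displays="mcf:Knee")
        with caplog.at_level("WARNING"):
            triples = ingest_scene(manifest)
        assert len(triples) == 2
        assert "no objects" in caplog.text

    def test_duplicate_object_id_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            SceneManifest(
                scene_id="mcf:s",
                displays="mcf:Knee",
                objects=[
                    SceneObject(id="mcf:o1", describes="mcf:A", mesh="a.obj"),
                    SceneObject(id="mcf:o1", describes="mcf:B", mesh="b.obj"),
                ],
            )

    def test_missing_describes_and_mesh_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            SceneObject(id="mcf:o1", describes="", mesh="a.obj")
        with pytest.raises(pydantic.ValidationError):
            SceneObject(id="mcf:o1", describes="mcf:A", mesh="")

    def test_position_needs_sixteen_numbers(self):
        SceneObject(id="mcf:o", describes="mcf:A", mesh="m.obj", position=tuple(range(16)))
        with pytest.raises(pydantic.ValidationError):
            SceneObject(id="mcf:o", describes="mcf:A", mesh="m.obj", position=(1.0, 2.0))

    @pytest.mark.parametrize("seed", range(30))
    def test_ingest_extract_roundtrip_random_scenes(self, seed):
        rng = random.Random(seed)
        objects = [
            SceneObject(
                id=f"mcf:obj{i}",
                describes=f"mcf:Ent{rng.randrange(20)}",
                mesh=f"meshes/m{i}.obj",
                texture=f"tex/t{i}.jpg" if rng.random() < 0.5 else None,
                colour=rng.choice(["yellow", "red", None]),
                position=tuple(float(rng.randrange(10)) for _ in range(16))
                if rng.random() < 0.3
                else None,
            )
            for i in range(rng.randint(1, 6))
        ]
        manifest = SceneManifest(scene_id="mcf:scene", displays="mcf:Body", objects=objects)
        store = TripleStore(ingest_scene(manifest))
        assert extract_scene(store, mcf("scene")) == manifest

    def test_json_roundtrip(self, fixture):
        assert load_manifest(dump_manifest(fixture.scene)) == fixture.scene


class TestSelect:
    def test_entity_target_selects_the_describing_object(self, closed_fixture):
        sel = select_objects(closed_fixture, mcf("id"), mcf("Left_sartorius"))
        assert sel.ids() == {mcf("id1").value}
        assert sel.colours[mcf("id1")] == "yellow"

    def test_undepicted_entity_selects_nothing(self, closed_fixture):
        sel = select_objects(closed_fixture, mcf("id"), mcf("Ear"))
        assert sel.ids() == set()

    def test_superclass_target_selects_specializations(self, closed_fixture):
        # Sartorius selects its left specialization's object through R4+R1
        sel = select_objects(closed_fixture, mcf("id"), mcf("Sartorius"))
        assert sel.ids() == {mcf("id1").value}
        # Bone reaches the tibia object through rightSubClassOf and transitivity
        sel = select_objects(closed_fixture, mcf("id"), mcf("Bone"))
        assert sel.ids() == {mcf("id4").value}

    def test_query_target_maps_answers_to_objects(self, closed_fixture):
        q = parse_query(tendon_insertion_query_text())
        sel = select_objects(closed_fixture, mcf("id"), q, colour="orange")
        assert sel.ids() == {mcf("id4").value}
        assert set(sel.colours.values()) == {"orange"}

    def test_unknown_scene_rejected(self, closed_fixture):
        with pytest.raises(SceneError):
            select_objects(closed_fixture, mcf("nonexistent_scene"), mcf("Bone"))

    def test_selection_subset_of_scene_objects(self, closed_fixture):
        contained = {
            t.object.value for t in closed_fixture.match((mcf("id"), S.CONTAINS, var("o")))
        }
        for target in (mcf("Bone"), mcf("Sartorius"), mcf("Leg")):
            assert select_objects(closed_fixture, mcf("id"), target).ids() <= contained

    def test_selection_monotone_under_fact_addition(self, fixture, core_rules):
        closed = saturate(fixture.store, core_rules)
        before = select_objects(closed, mcf("id"), mcf("Bone")).ids()
        bigger = closed.copy()
        bigger.add(Triple(mcf("Left_sartorius"), S.SUBCLASSOF, mcf("Bone")))
        bigger = saturate(bigger, core_rules)
        after = select_objects(bigger, mcf("id"), mcf("Bone")).ids()
        assert before <= after

    def test_subclass_selection_equals_graph_closure_oracle(self, closed_fixture, fixture):
        """Brute force: entailed subclasses of the target from an independent
        transitive closure of asserted subclass+laterality edges."""
        g = nx.DiGraph()
        for pred in (S.SUBCLASSOF, S.LEFT_SUBCLASSOF, S.RIGHT_SUBCLASSOF):
            for t in fixture.store.match((var("a"), pred, var("b"))):
                g.add_edge(t.subject.value, t.object.value)
        target = mcf("Bone")
        wanted = {target.value} | (
            nx.ancestors(g, target.value) if g.has_node(target.value) else set()
        )
        expected = {
            c.object.value
            for c in closed_fixture.match((mcf("id"), S.CONTAINS, var("o")))
            if any(
                d.object.value in wanted
                for d in closed_fixture.match((c.object, S.DESCRIBES, var("e")))
            )
        }
        assert select_objects(closed_fixture, mcf("id"), target).ids() == expected


class TestColourRules:
    def test_bone_object_turns_yellow(self, closed_fixture):
        coloured = apply_colour_rules(closed_fixture)
        assert Triple(mcf("id4"), S.HASCOLOUR, lit("yellow")) in coloured

    def test_muscle_objects_untouched(self, closed_fixture):
        coloured = apply_colour_rules(closed_fixture)
        for oid in ("id1", "id2", "id3"):
            assert coloured.match((mcf(oid), S.HASCOLOUR, var("c"))) == []

    def test_idempotent(self, closed_fixture):
        once = apply_colour_rules(closed_fixture)
        twice = apply_colour_rules(once)
        assert twice.facts == once.facts

    def test_colour_touches_only_bone_describing_objects(self, closed_fixture):
        coloured = apply_colour_rules(closed_fixture)
        for new in coloured.facts - closed_fixture.facts:
            assert new.predicate == S.HASCOLOUR
            described = coloured.match((new.subject, S.DESCRIBES, var("e")))
            assert any(
                Triple(d.object, S.SUBCLASSOF, mcf("Bone")) in coloured for d in described
            )


class TestValidity:
    def test_leg_scene_is_valid(self, closed_fixture):
        assert check_scene_validity(closed_fixture, mcf("id")).ok

    def test_unrelated_object_flagged(self, fixture, core_rules):
        store = fixture.store.copy()
        store.add(Triple(mcf("id"), S.CONTAINS, mcf("id9")))
        store.add(Triple(mcf("id9"), S.RDF_TYPE, S.OBJECT_3D))
        store.add(Triple(mcf("id9"), S.DESCRIBES, mcf("Tympanic_membrane")))
        closed = saturate(store, core_rules)
        report = check_scene_validity(closed, mcf("id"))
        assert len(report) == 1
        assert ("object", mcf("id9").value) in report.violations[0].binding

    def test_unknown_scene_rejected(self, closed_fixture):
        with pytest.raises(SceneError):
            check_scene_validity(closed_fixture, mcf("ghost"))

    def test_function_display_checks_contribution(self, core_rules):
        store = TripleStore(
            [
                Triple(mcf("fs"), S.RDF_TYPE, S.SCENE_3D),
                Triple(mcf("fs"), S.DISPLAYS, mcf("Movement_of_knee")),
                Triple(mcf("fs"), S.CONTAINS, mcf("o1")),
                Triple(mcf("o1"), S.RDF_TYPE, S.OBJECT_3D),
                Triple(mcf("o1"), S.DESCRIBES, mcf("Sartorius")),
                Triple(mcf("fs"), S.CONTAINS, mcf("o2")),
                Triple(mcf("o2"), S.RDF_TYPE, S.OBJECT_3D),
                Triple(mcf("o2"), S.DESCRIBES, mcf("Tympanic_membrane")),
                Triple(mcf("Sartorius"), S.CONTRIBUTESTO, mcf("Knee_flexion")),
                Triple(mcf("Knee_flexion"), S.ISINVOLVEDIN, mcf("Movement_of_knee")),
            ]
        )
        closed = saturate(store, core_rules)
        report = check_scene_validity(closed, mcf("fs"))
        assert len(report) == 1  # the sartorius contributes (via R10); the membrane does not
        assert ("object", mcf("o2").value) in report.violations[0].binding

    def test_report_equals_bruteforce_relatedness(self, closed_fixture):
        """Per-object reachability over entailed subClassOf/PartOf edges,
        recomputed with networkx."""
        g = nx.DiGraph()
        for pred in (S.SUBCLASSOF, S.PARTOF):
            for t in closed_fixture.match((var("a"), pred, var("b"))):
                g.add_edge(t.subject.value, t.object.value)
        d = closed_fixture.match((mcf("id"), S.DISPLAYS, var("d")))[0].object.value
        expected_bad = set()
        for c in closed_fixture.match((mcf("id"), S.CONTAINS, var("o"))):
            e = closed_fixture.match((c.object, S.DESCRIBES, var("e")))[0].object.value
            ok = e == d
            for x, y in ((e, d), (d, e)):
                if g.has_node(x) and g.has_node(y) and nx.has_path(g, x, y):
                    ok = True
            if not ok:
                expected_bad.add(c.object.value)
        report = check_scene_validity(closed_fixture, mcf("id"))
        assert {dict(v.binding)["object"] for v in report.violations} == expected_bad
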