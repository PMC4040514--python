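"""The packaged reference knowledge base.

A small, fully deterministic store exercising every part of the machinery:
the anatomy taxonomy with left/right specializations, the partonomy and
insertion facts, the function taxonomy and its links to structures, and a
leg scene whose objects describe muscles and a bone.

Every triple carries a provenance tag:

``printed``
    stated verbatim as a triple in the source material this fixture encodes
    (knee-joint laterality, the joint/articular-system partonomy, the
    sartorius tendon insertion, the function-taxonomy examples, the leg-scene
    block, the patella block);
``prose``
    stated in running text rather than as an explicit triple (the worked
    muscle example: sartorius and biceps femoris contribute to knee flexion,
    five extensors contribute to knee extension, and both motions are
    involved in the movement of the knee);
``connective``
    added by this package, the minimum glue needed to make the worked
    inferences, the tendon-insertion query, and the scene checks executable
    (tibia partonomy, Bone superclass links, muscle partonomy of the leg,
    the subtree content of the knee joint, one bone object in the scene).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import schema as S
from .model import DEFAULT_PREFIXES, Term, Triple, TripleStore, iri
from .scene import SceneManifest, SceneObject, ingest_scene

PRINTED = "printed"
PROSE = "prose"
CONNECTIVE = "connective"


def mcf(local: str) -> Term:
    return iri(DEFAULT_PREFIXES["mcf"] + local)


def fma(local: str) -> Term:
    return iri(DEFAULT_PREFIXES["fma"] + local)


@dataclass(frozen=True)
class Fixture:
    store: TripleStore
    scene: SceneManifest
    provenance: dict[Triple, str]

    def tagged(self, tag: str) -> set[Triple]:
        return {t for t, v in self.provenance.items() if v == tag}


def leg_scene_manifest() -> SceneManifest:
    """The leg scene: three muscle objects (as printed) plus one connective
    bone object (id4) standing for the bones the full scene also contains."""
    return SceneManifest(
        scene_id="mcf:id",
        displays="mcf:Leg",
        objects=[
            SceneObject(id="mcf:id1", describes="mcf:Left_sartorius", mesh="../geometries/l_sartorius.obj"),
            SceneObject(id="mcf:id2", describes="mcf:Left_bicepsfemoris", mesh="../geometries/l_bicepsfemoris.obj"),
            SceneObject(id="mcf:id3", describes="mcf:Left_semimembranosus", mesh="../geometries/l_semimembranosus.obj"),
            SceneObject(id="mcf:id4", describes="mcf:Right_tibia", mesh="../geometries/r_tibia.obj"),
        ],
    )


def knee_joint_subtree() -> TripleStore:
    """The knee-joint subclass subtree *without* its laterality triples.

    This is the input on which laterality expansion regenerates the
    Left_/Right_ knee-joint specializations; the main fixture already contains
    them, so expanding there raises the collision error by design.
    """
    store = TripleStore()
    store.add(Triple(mcf("Femoropatellar_joint"), S.SUBCLASSOF, mcf("knee_joint")))
    store.add(Triple(mcf("Femorotibial_joint"), S.SUBCLASSOF, mcf("knee_joint")))
    return store


def tendon_insertion_query_text() -> str:
    """The bones on which the tendons of the sartorius are inserted.

    A reconstruction of the worked query-to-scene example (the original
    SPARQL text is not available verbatim): four patterns walking from
    tendon subclasses through the sartorius partonomy to insertion targets.
    Run it against the *saturated* fixture — the answer then includes both the
    asserted epiphysis insertion and the whole bone reached through the
    insertion-propagation rule over the partonomy.
    """
    return (
        "PREFIX mcf: <%s>\n"
        "PREFIX rdfs: <%s>\n"
        "SELECT ?bone WHERE {\n"
        "  ?tendon rdfs:subClassOf mcf:Tendon .\n"
        "  ?tendon mcf:PartOf ?sart .\n"
        "  ?sart rdfs:subClassOf mcf:Sartorius .\n"
        "  ?tendon mcf:InsertOn ?bone .\n"
        "}\n" % (DEFAULT_PREFIXES["mcf"], DEFAULT_PREFIXES["rdfs"])
    )


#: The five knee extensors of the worked muscle example.
KNEE_EXTENSORS = (
    "Tensor_fascia_lata",
    "Rectus_femoris",
    "Vastus_lateralis",
    "Vastus_medialis",
    "Vastus_intermedius",
)


def _tagged_triples() -> list[tuple[Triple, str]]:
    sub, part, ins = S.SUBCLASSOF, S.PARTOF, S.INSERTON
    t: list[tuple[Triple, str]] = []

    # --- anatomy taxonomy: laterality of the knee joint ---------------------
    t.append((Triple(mcf("Left_knee_joint"), S.LEFT_SUBCLASSOF, mcf("knee_joint")), PRINTED))
    t.append((Triple(mcf("Right_knee_joint"), S.RIGHT_SUBCLASSOF, mcf("knee_joint")), PRINTED))
    # knee-joint subtree content (figure only partially legible -> connective)
    for fact in knee_joint_subtree():
        t.append((fact, CONNECTIVE))

    # --- partonomy and insertions -------------------------------------------
    t.append((Triple(mcf("Joint"), part, mcf("Articular_System")), PRINTED))
    t.append((
        Triple(mcf("Distal_Tendon_Of_Right_Sartorius"), ins,
               mcf("Medial_part_of_proximal_epiphysis_of_right_tibia")),
        PRINTED,
    ))
    t.append((Triple(mcf("Patella"), sub, mcf("CircularTriangularBone")), PRINTED))
    t.append((Triple(mcf("Patella"), part, mcf("Knee")), PRINTED))
    t.append((Triple(mcf("u"), S.RDF_TYPE, mcf("Patella")), PRINTED))
    t.append((Triple(mcf("Femur"), S.SAMEAS, fma("Femur")), PRINTED))

    # tendon/sartorius glue for the tendon-insertion query
    t.append((Triple(mcf("Distal_Tendon_Of_Right_Sartorius"), sub, mcf("Tendon")), CONNECTIVE))
    t.append((Triple(mcf("Distal_Tendon_Of_Right_Sartorius"), part, mcf("Right_sartorius")), CONNECTIVE))
    t.append((Triple(mcf("Right_sartorius"), S.RIGHT_SUBCLASSOF, mcf("Sartorius")), CONNECTIVE))
    t.append((Triple(mcf("Left_sartorius"), S.LEFT_SUBCLASSOF, mcf("Sartorius")), CONNECTIVE))
    # tibia partonomy + bone taxonomy (lets the insertion propagate to the
    # whole bone and the colour rule reach the scene's bone object)
    t.append((Triple(mcf("Medial_part_of_proximal_epiphysis_of_right_tibia"), part, mcf("Right_tibia")), CONNECTIVE))
    t.append((Triple(mcf("Right_tibia"), S.RIGHT_SUBCLASSOF, mcf("Tibia")), CONNECTIVE))
    t.append((Triple(mcf("Tibia"), sub, mcf("Bone")), CONNECTIVE))
    t.append((Triple(mcf("CircularTriangularBone"), sub, mcf("Bone")), CONNECTIVE))

    # muscle partonomy of the leg (scene validity: contained muscles are
    # parts of the displayed leg, reached through their specializations)
    for muscle in ("Sartorius", "Biceps_femoris", "Semimembranosus"):
        t.append((Triple(mcf(muscle), part, mcf("Leg")), CONNECTIVE))
    t.append((Triple(mcf("Tibia"), part, mcf("Leg")), CONNECTIVE))
    t.append((Triple(mcf("Left_bicepsfemoris"), S.LEFT_SUBCLASSOF, mcf("Biceps_femoris")), CONNECTIVE))
    t.append((Triple(mcf("Left_semimembranosus"), S.LEFT_SUBCLASSOF, mcf("Semimembranosus")), CONNECTIVE))

    # --- function taxonomy ---------------------------------------------------
    t.append((Triple(mcf("Extension_Of_The_Knee"), sub, mcf("Simple_Movement")), PRINTED))
    t.append((Triple(mcf("Eversion_Of_The_Foot"), S.ISINVOLVEDIN, mcf("Mobility_Of_Ankle_Joints")), PRINTED))
    t.append((Triple(mcf("Knee"), S.HASFUNCTION, mcf("Knee_Movement")), PRINTED))
    t.append((Triple(mcf("Joint_Cartilage"), S.HASFUNCTION, mcf("Ensure_Sliding_Motion_Of_Articular_Surface")), PRINTED))
    t.append((Triple(mcf("Joint_Cartilage"), S.HASFUNCTION, mcf("Ensure_Transmission_And_Amortization_Of_Charges")), PRINTED))
    t.append((Triple(mcf("Toe"), S.CONTRIBUTESTO, mcf("Body_Stability")), PRINTED))

    # --- worked muscle example (stated in running text) ----------------------
    t.append((Triple(mcf("Sartorius"), S.CONTRIBUTESTO, mcf("Knee_flexion")), PROSE))
    t.append((Triple(mcf("Biceps_femoris"), S.CONTRIBUTESTO, mcf("Knee_flexion")), PROSE))
    t.append((Triple(mcf("Knee_flexion"), S.ISINVOLVEDIN, mcf("Movement_of_knee")), PROSE))
    for muscle in KNEE_EXTENSORS:
        t.append((Triple(mcf(muscle), S.CONTRIBUTESTO, mcf("Knee_extension")), PROSE))
    t.append((Triple(mcf("Knee_extension"), S.ISINVOLVEDIN, mcf("Movement_of_knee")), PROSE))
    return t


def reference_fixture() -> Fixture:
    """Build the packaged fixture: store + leg scene manifest + provenance.

    Deterministic: two consecutive builds are identical.  Scene triples are
    produced by ingesting the manifest; the three muscle objects' triples are
    tagged ``printed`` (with the third mesh statement corrected from the
    source's obvious id2/id3 slip) and the bone object's are ``connective``.
    """
    store = TripleStore()
    provenance: dict[Triple, str] = {}
    for fact, tag in _tagged_triples():
        store.add(fact)
        provenance[fact] = tag
    scene = leg_scene_manifest()
    bone_object = mcf("id4")
    for fact in ingest_scene(scene, store.prefixes):
        store.add(fact)
        is_connective = bone_object in (fact.subject, fact.object)
        provenance[fact] = CONNECTIVE if is_connective else PRINTED
    return Fixture(store, scene, provenance)
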