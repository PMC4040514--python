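"""Bridge between the knowledge base and 3D content.

A scene manifest declares a 3D scene (what body part or function it displays)
and its mesh-backed objects, each describing one anatomical entity.  Ingesting
a manifest turns it into triples; from there the knowledge base drives object
selection ("highlight whatever the query answers describe"), conventional
colouring (bones are yellow), and anatomical validity checking (everything a
scene contains should belong to what it displays).

Mesh and texture files are referenced by path only — geometry is never parsed
here; identification of 3D content is deliberately separated from its storage
and processing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dfield

import networkx as nx
from pydantic import BaseModel, Field, field_validator, model_validator

from . import schema as S
from .model import LITERAL, PrefixTable, Term, Triple, TripleStore, iri, lit, var
from .query import AnswerTable, Query, evaluate
from .rules import ClosedStore, RuleSet, saturate
from .schema import ValidationReport, Violation, default_ruleset

logger = logging.getLogger(__name__)

DEFAULT_HIGHLIGHT = "yellow"


class SceneError(ValueError):
    pass


class SceneObject(BaseModel):
    """One mesh-backed object in a scene; ``describes`` names the anatomical
    entity the mesh depicts.  ``position`` is a row-major 4x4 matrix."""

    id: str
    describes: str
    mesh: str = Field(min_length=1)
    texture: str | None = None
    colour: str | None = None
    position: tuple[float, ...] | None = None

    @field_validator("describes")
    @classmethod
    def _describes_nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("describes target missing")
        return v

    @field_validator("position")
    @classmethod
    def _position_16(cls, v):
        if v is not None and len(v) != 16:
            raise ValueError(f"position needs 16 numbers, got {len(v)}")
        return v


class SceneManifest(BaseModel):
    scene_id: str
    displays: str
    objects: list[SceneObject] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_ids(self):
        ids = [o.id for o in self.objects]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate object id(s): {dupes}")
        return self


@dataclass(frozen=True)
class SelectionSet:
    """Objects of one scene to highlight, with a colour per object."""

    scene_id: Term
    selected: tuple[Term, ...]
    colours: dict[Term, str] = dfield(default_factory=dict)

    def ids(self) -> set[str]:
        return {t.value for t in self.selected}


def _expand(name: str, prefixes: PrefixTable) -> Term:
    if name.startswith("http://") or name.startswith("https://"):
        return iri(name)
    try:
        return iri(prefixes.expand(name))
    except KeyError:
        raise SceneError(f"unknown prefix in {name!r}") from None


def load_manifest(text: str) -> SceneManifest:
    """Parse a JSON manifest document."""
    return SceneManifest.model_validate(json.loads(text))


def dump_manifest(manifest: SceneManifest) -> str:
    return json.dumps(manifest.model_dump(exclude_none=True), indent=2, sort_keys=True) + "\n"


def ingest_scene(manifest: SceneManifest, prefixes: PrefixTable | None = None) -> list[Triple]:
    """Turn a manifest into its triples.

    Emits rdf:type and Displays for the scene, then per object: Contains,
    rdf:type, Describes, hasMesh, and hasTexture / hasColour / Position when
    present.  Position is encoded as a literal of 16 whitespace-separated
    numbers.  Names are expanded against ``prefixes`` (default table if
    omitted); full IRIs pass through.
    """
    table = prefixes if prefixes is not None else PrefixTable()
    scene = _expand(manifest.scene_id, table)
    out = [
        Triple(scene, S.RDF_TYPE, S.SCENE_3D),
        Triple(scene, S.DISPLAYS, _expand(manifest.displays, table)),
    ]
    if not manifest.objects:
        logger.warning("scene %s has no objects", manifest.scene_id)
    for obj in manifest.objects:
        oid = _expand(obj.id, table)
        out.append(Triple(scene, S.CONTAINS, oid))
        out.append(Triple(oid, S.RDF_TYPE, S.OBJECT_3D))
        out.append(Triple(oid, S.DESCRIBES, _expand(obj.describes, table)))
        out.append(Triple(oid, S.HASMESH, lit(obj.mesh)))
        if obj.texture is not None:
            out.append(Triple(oid, S.HASTEXTURE, lit(obj.texture)))
        if obj.colour is not None:
            out.append(Triple(oid, S.HASCOLOUR, lit(obj.colour)))
        if obj.position is not None:
            out.append(Triple(oid, S.POSITION, lit(" ".join(repr(x) for x in obj.position))))
    return out


def extract_scene(store: TripleStore, scene: Term, prefixes: PrefixTable | None = None) -> SceneManifest:
    """Rebuild a manifest from a scene's triples (inverse of ingest_scene)."""
    table = prefixes if prefixes is not None else store.prefixes
    displayed = store.match((scene, S.DISPLAYS, var("d")))
    if Triple(scene, S.RDF_TYPE, S.SCENE_3D) not in store or not displayed:
        raise SceneError(f"unknown scene {scene}")

    def one_literal(oid: Term, pred: Term) -> str | None:
        hits = store.match((oid, pred, var("v")))
        return hits[0].object.value if hits else None

    objects = []
    for t in store.match((scene, S.CONTAINS, var("o"))):
        oid = t.object
        describes = store.match((oid, S.DESCRIBES, var("e")))
        if not describes:
            raise SceneError(f"object {oid} has no Describes triple")
        pos_text = one_literal(oid, S.POSITION)
        objects.append(
            SceneObject(
                id=table.compact(oid.value),
                describes=table.compact(describes[0].object.value),
                mesh=one_literal(oid, S.HASMESH) or "",
                texture=one_literal(oid, S.HASTEXTURE),
                colour=one_literal(oid, S.HASCOLOUR),
                position=tuple(float(x) for x in pos_text.split()) if pos_text else None,
            )
        )
    objects.sort(key=lambda o: o.id)
    return SceneManifest(
        scene_id=table.compact(scene.value),
        displays=table.compact(displayed[0].object.value),
        objects=objects,
    )


def _scene_objects(store: TripleStore, scene: Term) -> list[Term]:
    if Triple(scene, S.RDF_TYPE, S.SCENE_3D) not in store:
        raise SceneError(f"unknown scene {scene}")
    return [t.object for t in store.match((scene, S.CONTAINS, var("o")))]


def select_objects(
    closed: TripleStore,
    scene: Term,
    target: Query | Term,
    colour: str = DEFAULT_HIGHLIGHT,
) -> SelectionSet:
    """Objects of ``scene`` whose described entity matches ``target``.

    With a :class:`Query` target, an object is selected when its described
    entity appears anywhere in the query's answers.  With an entity IRI, an
    object is selected when it describes the entity itself or any entailed
    subclass of it — so targeting ``Bone`` on a saturated store picks up
    left/right specializations through the laterality and transitivity rules.
    """
    contained = _scene_objects(closed, scene)
    if isinstance(target, Query):
        answers: AnswerTable = evaluate(target, closed)
        wanted = {t for row in answers.rows for t in row if t.kind != LITERAL}
    else:
        wanted = {target} | {
            t.subject for t in closed.match((var("e"), S.SUBCLASSOF, target))
        }
    selected = tuple(
        sorted(
            (o for o in contained if any(
                t.object in wanted for t in closed.match((o, S.DESCRIBES, var("e")))
            )),
            key=lambda t: t.value,
        )
    )
    assert set(selected) <= set(contained)
    return SelectionSet(scene, selected, {o: colour for o in selected})


def selection_to_json(sel: SelectionSet, prefixes: PrefixTable | None = None) -> str:
    table = prefixes if prefixes is not None else PrefixTable()
    payload = {
        "scene_id": table.compact(sel.scene_id.value),
        "selected": [
            {"id": table.compact(o.value), "colour": sel.colours.get(o, DEFAULT_HIGHLIGHT)}
            for o in sel.selected
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def apply_colour_rules(closed: ClosedStore) -> ClosedStore:
    """Apply the conventional-colour rule to a saturated store.

    Every 3D object describing a (direct or entailed) subclass of Bone gains
    ``hasColour "yellow"``; everything else is untouched.  Idempotent under
    the store's set semantics.
    """
    colour_only = RuleSet((default_ruleset(include_colour_rule=True)["R12"],))
    return saturate(closed, colour_only, log_derivations=bool(closed.proofs))


def _related(closed: TripleStore, a: Term, b: Term, graph: nx.DiGraph) -> bool:
    if a == b:
        return True
    for x, y in ((a, b), (b, a)):
        if graph.has_node(x.value) and graph.has_node(y.value) and nx.has_path(graph, x.value, y.value):
            return True
    return False


def check_scene_validity(closed: TripleStore, scene: Term) -> ValidationReport:
    """Flag contained objects unrelated to what the scene displays.

    An object is valid when its described entity equals the displayed entity
    or reaches it along entailed subClassOf/PartOf edges (in either direction
    of specialization: a Leg scene admits parts of the leg and their
    left/right specializations).  When the scene displays a *function*, the
    described entity must contribute to it (hasFunction or contributesTo in
    the closure) — an extension beyond structural display.
    """
    displayed = closed.match((scene, S.DISPLAYS, var("d")))
    if Triple(scene, S.RDF_TYPE, S.SCENE_3D) not in closed or not displayed:
        raise SceneError(f"unknown scene {scene}")
    d = displayed[0].object

    graph = nx.DiGraph()
    for pred in (S.SUBCLASSOF, S.PARTOF):
        for t in closed.match((var("a"), pred, var("b"))):
            graph.add_edge(t.subject.value, t.object.value)

    is_function = bool(
        closed.match((var("x"), S.CONTRIBUTESTO, d)) or closed.match((var("x"), S.HASFUNCTION, d))
    ) and not graph.has_node(d.value)

    report = ValidationReport()
    for oid in _scene_objects(closed, scene):
        for t in closed.match((oid, S.DESCRIBES, var("e"))):
            e = t.object
            if is_function:
                ok = bool(
                    Triple(e, S.CONTRIBUTESTO, d) in closed or Triple(e, S.HASFUNCTION, d) in closed
                )
            else:
                ok = _related(closed, e, d, graph)
            if not ok:
                report.violations.append(
                    Violation("scene-validity", (("describes", e.value), ("object", oid.value)))
                )
    report.violations.sort(key=lambda v: v.binding)
    return report
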