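"""Seeded synthetic-ontology generator for property testing.

Emulates the gross structure of an anatomical knowledge base: a subclass
taxonomy tree of anatomical classes, a forest of functions linked by
involvement edges, cross edges (partonomy, insertions, function links) sampled
at configurable per-node densities, and laterality expansion applied to a
fraction of the depth-1 subtrees.  Entirely reproducible from the seed; class
names come from a deterministic counter so diffs stay stable.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from . import schema as S
from .model import DEFAULT_PREFIXES, Term, Triple, TripleStore, iri
from .schema import LateralityPolicy, expand_laterality


class SynthParams(BaseModel):
    """Generator knobs.  Densities are per-node Bernoulli probabilities."""

    depth: int = Field(default=3, ge=1)
    branching: int = Field(default=2, ge=0)
    n_functions: int = Field(default=8, ge=0)
    p_partof: float = Field(default=0.3, ge=0.0, le=1.0)
    p_inserton: float = Field(default=0.15, ge=0.0, le=1.0)
    p_hasfunction: float = Field(default=0.2, ge=0.0, le=1.0)
    p_contributesto: float = Field(default=0.2, ge=0.0, le=1.0)
    p_isinvolvedin: float = Field(default=0.5, ge=0.0, le=1.0)
    laterality_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    seed: int = 0


def _anat(i: int) -> Term:
    return iri(DEFAULT_PREFIXES["mcf"] + f"Anat{i:04d}")


def _func(i: int) -> Term:
    return iri(DEFAULT_PREFIXES["mcf"] + f"Func{i:04d}")


def generate_synthetic_ontology(params: SynthParams | None = None, **kwargs) -> TripleStore:
    """Generate a store from ``params`` (keyword overrides accepted).

    Structure: ``Anat0000`` roots a subclass tree of the stated depth and
    branching (anchored under the Anatomical-entity top class); each non-root
    anatomy node may gain a PartOf edge to an earlier node (keeping the
    partonomy acyclic) and an InsertOn edge to any other node; functions form
    an IsInvolvedIn forest over earlier nodes; anatomy->function edges are
    sampled for hasFunction and contributesTo; finally a sampled fraction of
    the depth-1 subtrees receive Left_/Right_ laterality expansion.
    """
    if params is None:
        params = SynthParams(**kwargs)
    elif kwargs:
        params = params.model_copy(update=kwargs)
    rng = np.random.default_rng(params.seed)
    store = TripleStore()

    # subclass taxonomy tree, breadth-first, counter-named
    nodes: list[Term] = [_anat(0)]
    store.add(Triple(nodes[0], S.SUBCLASSOF, S.ANATOMICAL_ENTITY))
    level = [nodes[0]]
    counter = 1
    for _ in range(params.depth - 1):
        nxt: list[Term] = []
        for parent in level:
            for _ in range(params.branching):
                child = _anat(counter)
                counter += 1
                store.add(Triple(child, S.SUBCLASSOF, parent))
                nodes.append(child)
                nxt.append(child)
        level = nxt

    # partonomy (acyclic: edges point to strictly earlier nodes) + insertions
    for i, node in enumerate(nodes[1:], start=1):
        if rng.random() < params.p_partof:
            j = int(rng.integers(0, i))
            store.add(Triple(node, S.PARTOF, nodes[j]))
        if rng.random() < params.p_inserton:
            j = int(rng.integers(0, len(nodes)))
            if j != i:
                store.add(Triple(node, S.INSERTON, nodes[j]))

    # function forest over IsInvolvedIn
    functions = [_func(i) for i in range(params.n_functions)]
    for i, f in enumerate(functions):
        if i > 0 and rng.random() < params.p_isinvolvedin:
            j = int(rng.integers(0, i))
            store.add(Triple(f, S.ISINVOLVEDIN, functions[j]))

    # structure -> function cross edges
    if functions:
        for node in nodes:
            if rng.random() < params.p_hasfunction:
                f = functions[int(rng.integers(0, len(functions)))]
                store.add(Triple(node, S.HASFUNCTION, f))
            if rng.random() < params.p_contributesto:
                f = functions[int(rng.integers(0, len(functions)))]
                store.add(Triple(node, S.CONTRIBUTESTO, f))

    # laterality on a fraction of the depth-1 subtrees
    policy = LateralityPolicy()
    depth1 = nodes[1:1 + params.branching]
    for root in depth1:
        if rng.random() < params.laterality_fraction:
            store = expand_laterality(store, root, policy)
    return store
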