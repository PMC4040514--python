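from __future__ import annotations

import random

import pytest

import anatokb as ak
from anatokb import schema as S
from anatokb.model import Triple, TripleStore, iri, lit, var
from anatokb.rules import Rule, RuleSet

MCF = ak.DEFAULT_PREFIXES["mcf"]


def mcf(local: str):
    return iri(MCF + local)


#: A small predicate pool biased toward the domain relations so random stores
#: actually trigger the core rules.
PREDICATES = [
    S.SUBCLASSOF,
    S.PARTOF,
    S.ISINVOLVEDIN,
    S.INSERTON,
    S.HASFUNCTION,
    S.CONTRIBUTESTO,
    S.LEFT_SUBCLASSOF,
    S.RIGHT_SUBCLASSOF,
]


def random_store(rng: random.Random, n_triples: int, n_entities: int = 12) -> TripleStore:
    entities = [mcf(f"E{i}") for i in range(n_entities)]
    store = TripleStore()
    for _ in range(n_triples):
        store.add(
            Triple(rng.choice(entities), rng.choice(PREDICATES), rng.choice(entities))
        )
    return store


def random_pattern(rng: random.Random, n_entities: int = 12):
    def term(position):
        r = rng.random()
        if r < 0.4:
            return var(rng.choice("xyz"))
        if position == 1:
            return rng.choice(PREDICATES)
        return mcf(f"E{rng.randrange(n_entities)}")

    return (term(0), term(1), term(2))


def random_safe_rule(rng: random.Random, rule_id: str) -> Rule:
    """A random safe rule with 1-3 body atoms over a small variable pool."""
    n_body = rng.randint(1, 3)
    body = tuple(random_pattern(rng) for _ in range(n_body))
    body_vars = sorted({t.value for atom in body for t in atom if t.is_var})
    def head_term(position):
        if body_vars and rng.random() < 0.6:
            return var(rng.choice(body_vars))
        if position == 1:
            return rng.choice(PREDICATES)
        return mcf(f"H{rng.randrange(5)}")
    head = (head_term(0), head_term(1), head_term(2))
    return Rule(rule_id, body, head)


@pytest.fixture(scope="session")
def fixture():
    return ak.reference_fixture()


@pytest.fixture(scope="session")
def core_rules():
    return ak.default_ruleset()


@pytest.fixture(scope="session")
def closed_fixture(fixture, core_rules):
    return ak.saturate(fixture.store, core_rules)
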