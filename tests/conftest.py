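import numpy as np
import pytest

from krgai.kg_core import KnowledgeGraph, Triple, Vocab


def build_graph(triples: list[tuple[str, str, str]]) -> KnowledgeGraph:
    """Labelled triples -> KnowledgeGraph with first-appearance vocab."""
    vocab = Vocab()
    coded = set()
    for h, r, t in triples:
        coded.add(
            Triple(vocab.add_entity(h), vocab.add_relation(r), vocab.add_entity(t))
        )
    return KnowledgeGraph(vocab=vocab, triples=coded)


@pytest.fixture
def single_edge_graph():
    return build_graph([("a", "r", "b")])


@pytest.fixture
def path_graph():
    return build_graph([("a", "r", "b"), ("b", "r", "c")])


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_graph(rng, n_entities=8, n_relations=3, n_triples=12) -> KnowledgeGraph:
    vocab = Vocab(
        entity_labels=[f"e{i}" for i in range(n_entities)],
        relation_labels=[f"r{i}" for i in range(n_relations)],
    )
    triples = set()
    while len(triples) < n_triples:
        h, t = rng.integers(n_entities, size=2)
        if h == t:
            continue
        triples.add(Triple(int(h), int(rng.integers(n_relations)), int(t)))
    return KnowledgeGraph(vocab=vocab, triples=triples)
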