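"""Knowledge-graph data model, triple-file I/O and graph statistics.

A knowledge graph is a triple store ``G = (E, R, T)``: a set of entities
``E``, a set of typed relations ``R`` and a set of directed triples
``(h, r, t)``.  Everything downstream (the synthetic benchmark generator,
the reasoning model, the evaluation protocol) operates on the integer-coded
:class:`KnowledgeGraph` defined here.

The on-disk format is the de-facto KG-benchmark layout: one
``head<TAB>relation<TAB>tail`` triple per line, UTF-8, ``#`` comments
skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger("krgai")

__all__ = [
    "Vocab",
    "Triple",
    "KnowledgeGraph",
    "InductiveSplit",
    "read_triples",
    "write_triples",
    "write_vocab",
    "graph_stats",
    "neighborhood",
    "avg_reachable_distance",
    "GraphFormatError",
    "EmptyGraphError",
]


class GraphFormatError(ValueError):
    """Malformed triple file (wrong field count, empty file, bad labels)."""


class EmptyGraphError(ValueError):
    """An operation that needs edges was given an edgeless graph."""


class Vocab:
    """Bijective label <-> contiguous-index maps for entities and relations."""

    def __init__(
        self,
        entity_labels: Sequence[str] = (),
        relation_labels: Sequence[str] = (),
    ):
        self.entity_labels: list[str] = []
        self.relation_labels: list[str] = []
        self._ent_index: dict[str, int] = {}
        self._rel_index: dict[str, int] = {}
        for e in entity_labels:
            self.add_entity(e)
        for r in relation_labels:
            self.add_relation(r)

    # -- construction ----------------------------------------------------
    def add_entity(self, label: str) -> int:
        idx = self._ent_index.get(label)
        if idx is None:
            idx = len(self.entity_labels)
            self.entity_labels.append(label)
            self._ent_index[label] = idx
        return idx

    def add_relation(self, label: str) -> int:
        idx = self._rel_index.get(label)
        if idx is None:
            idx = len(self.relation_labels)
            self.relation_labels.append(label)
            self._rel_index[label] = idx
        return idx

    # -- lookup ----------------------------------------------------------
    def entity_index(self, label: str) -> int:
        return self._ent_index[label]

    def relation_index(self, label: str) -> int:
        return self._rel_index[label]

    def has_entity(self, label: str) -> bool:
        return label in self._ent_index

    def has_relation(self, label: str) -> bool:
        return label in self._rel_index

    @property
    def n_entities(self) -> int:
        return len(self.entity_labels)

    @property
    def n_relations(self) -> int:
        return len(self.relation_labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Vocab)
            and self.entity_labels == other.entity_labels
            and self.relation_labels == other.relation_labels
        )


class Triple(NamedTuple):
    """An integer-coded directed edge ``(head, relation, tail)``."""

    head: int
    relation: int
    tail: int


@dataclass
class KnowledgeGraph:
    """``G = (E, R, T)`` with an adjacency index for message passing.

    ``adjacency[u]`` lists ``(relation, neighbor, direction)`` where
    ``direction`` is +1 for triples with ``u`` as head and -1 for triples
    with ``u`` as tail.  Message-passing neighborhoods are derived from it
    by :func:`neighborhood`.
    """

    vocab: Vocab
    triples: set[Triple] = field(default_factory=set)

    def __post_init__(self):
        self._adjacency: list[list[tuple[int, int, int]]] | None = None
        for t in self.triples:
            self._check_triple(t)

    def _check_triple(self, t: Triple) -> None:
        n_e, n_r = self.vocab.n_entities, self.vocab.n_relations
        if not (0 <= t.head < n_e and 0 <= t.tail < n_e):
            raise IndexError(f"entity index out of range in {t} (|E|={n_e})")
        if not (0 <= t.relation < n_r):
            raise IndexError(f"relation index out of range in {t} (|R|={n_r})")

    @property
    def n_entities(self) -> int:
        return self.vocab.n_entities

    @property
    def n_relations(self) -> int:
        return self.vocab.n_relations

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    @property
    def adjacency(self) -> list[list[tuple[int, int, int]]]:
        if self._adjacency is None:
            adj: list[list[tuple[int, int, int]]] = [
                [] for _ in range(self.n_entities)
            ]
            for h, r, t in sorted(self.triples):
                adj[h].append((r, t, +1))
                adj[t].append((r, h, -1))
            self._adjacency = adj
        return self._adjacency

    def add_triple(self, t: Triple) -> None:
        self._check_triple(t)
        self.triples.add(t)
        self._adjacency = None

    def sorted_triples(self) -> list[Triple]:
        return sorted(self.triples)

    def undirected_edges(self) -> np.ndarray:
        """Unique undirected (u, v) pairs as an (m, 2) int array."""
        if not self.triples:
            return np.empty((0, 2), dtype=np.int64)
        pairs = {(min(h, t), max(h, t)) for h, _, t in self.triples if h != t}
        return np.array(sorted(pairs), dtype=np.int64)


@dataclass
class InductiveSplit:
    """An inductive benchmark: entity-disjoint train and test graphs.

    Test queries are held-out triples over the test graph's vocabulary and
    are never message-passing edges of the test graph; validation and
    training queries live on the train graph.  Both graphs share one
    relation vocabulary (the target relation of held-out queries never
    occurs as an edge, so it must be carried explicitly).
    """

    train_graph: KnowledgeGraph
    test_graph: KnowledgeGraph
    test_queries: list[Triple]
    valid_queries: list[Triple]
    train_queries: list[Triple] = field(default_factory=list)

    def validate(self) -> None:
        train_ents = set(self.train_graph.vocab.entity_labels)
        test_ents = set(self.test_graph.vocab.entity_labels)
        overlap = train_ents & test_ents
        if overlap:
            raise ValueError(
                f"train/test entity sets overlap ({len(overlap)} shared labels)"
            )
        n_e = self.test_graph.n_entities
        edge_set = self.test_graph.triples
        for q in self.test_queries:
            if not (0 <= q.head < n_e and 0 <= q.tail < n_e):
                raise ValueError(f"test query {q} outside test graph")
            if q in edge_set:
                raise ValueError(f"test query {q} leaks into test message graph")
        if self.train_graph.vocab.relation_labels != (
            self.test_graph.vocab.relation_labels
        ):
            raise ValueError("train/test relation vocabularies differ")


# ---------------------------------------------------------------------------
# Triple-file I/O
# ---------------------------------------------------------------------------

def read_triples(path: str | Path) -> KnowledgeGraph:
    """Parse a tab-separated triple file into a :class:`KnowledgeGraph`.

    Vocabulary indices follow first appearance; exact duplicate lines are
    collapsed (set semantics of T) with the count logged.  Lines that are
    empty or start with ``#`` are skipped; a line with fewer than three
    tab-separated fields is an error naming the line number; extra fields
    are ignored.
    """
    path = Path(path)
    vocab = Vocab()
    triples: set[Triple] = set()
    n_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            n_lines += 1
            h = vocab.add_entity(fields[0])
            r = vocab.add_relation(fields[1])
            t = vocab.add_entity(fields[2])
            triples.add(Triple(h, r, t))
    if n_lines == 0:
        raise EmptyGraphError(f"{path}: no triples found")
    n_dup = n_lines - len(triples)
    if n_dup:
        logger.info("read_triples(%s): collapsed %d duplicate lines", path, n_dup)
    logger.info(
        "read_triples(%s): %d triples, %d entities, %d relations",
        path, len(triples), vocab.n_entities, vocab.n_relations,
    )
    return KnowledgeGraph(vocab=vocab, triples=triples)


def write_triples(graph: KnowledgeGraph, path: str | Path) -> Path:
    """Write labeled triples, sorted by (head, relation, tail) index.

    The sort makes the byte content a pure function of the triple set,
    independent of in-memory insertion order.
    """
    if not graph.triples:
        raise EmptyGraphError("refusing to write an empty graph")
    path = Path(path)
    ents, rels = graph.vocab.entity_labels, graph.vocab.relation_labels
    with path.open("w", encoding="utf-8") as fh:
        for h, r, t in graph.sorted_triples():
            fh.write(f"{ents[h]}\t{rels[r]}\t{ents[t]}\n")
    logger.info("write_triples(%s): %d triples", path, graph.n_triples)
    return path


def write_vocab(vocab: Vocab, path: str | Path) -> Path:
    """Dump entity then relation labels as ``label<TAB>index`` TSV blocks."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# entities\n")
        for i, label in enumerate(vocab.entity_labels):
            fh.write(f"{label}\t{i}\n")
        fh.write("# relations\n")
        for i, label in enumerate(vocab.relation_labels):
            fh.write(f"{label}\t{i}\n")
    logger.info(
        "write_vocab(%s): %d entities, %d relations",
        path, vocab.n_entities, vocab.n_relations,
    )
    return path


# ---------------------------------------------------------------------------
# Neighborhoods and graph statistics
# ---------------------------------------------------------------------------

def neighborhood(
    graph: KnowledgeGraph, u: int, inverse: bool = True
) -> list[tuple[int, int]]:
    """First-order message neighborhood ``N(u)`` as ``(relation, v)`` pairs.

    A triple ``(u, r, v)`` yields ``(r, v)``: the tail's state flows into
    the head under relation ``r``.  With ``inverse`` on (the default), a
    triple ``(v, r, u)`` additionally yields ``(r + |R|, v)``, the inverse
    relation, so information can flow against edge direction and
    reachability over message edges is symmetric.
    """
    if not (0 <= u < graph.n_entities):
        raise IndexError(f"entity index {u} out of range (|E|={graph.n_entities})")
    n_r = graph.n_relations
    out: list[tuple[int, int]] = []
    for r, v, direction in graph.adjacency[u]:
        if direction > 0:
            out.append((r, v))
        elif inverse:
            out.append((r + n_r, v))
    return out


def avg_reachable_distance(
    graph: KnowledgeGraph,
    *,
    node_cap: int = 5000,
    n_sample_sources: int = 1000,
    seed: int = 0,
) -> float:
    """Mean shortest-path length over reachable node pairs, undirected view.

    Every directed edge is treated as an undirected unit-weight edge;
    unreachable pairs and self-pairs are excluded from both numerator and
    denominator.  Graphs above ``node_cap`` nodes are estimated from BFS
    over ``n_sample_sources`` uniformly sampled sources (seeded) and the
    estimate is flagged in the log.
    """
    edges = graph.undirected_edges()
    if edges.shape[0] == 0:
        raise EmptyGraphError("avg_reachable_distance undefined on edgeless graph")
    n = graph.n_entities
    data = np.ones(edges.shape[0])
    adj = coo_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n, n))
    if n > node_cap:
        rng = np.random.default_rng(seed)
        sources = rng.choice(n, size=min(n_sample_sources, n), replace=False)
        logger.info(
            "avg_reachable_distance: |E|=%d > cap %d, estimating from %d sources",
            n, node_cap, len(sources),
        )
    else:
        sources = np.arange(n)
    dist = shortest_path(
        adj, method="D", directed=False, unweighted=True, indices=sources
    )
    finite = np.isfinite(dist) & (dist > 0)
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        raise EmptyGraphError("no reachable node pairs")
    # each unordered pair appears twice in the full matrix; the ratio is
    # unchanged, so no correction is needed (nor under source sampling).
    return float(dist[finite].sum() / n_pairs)


def graph_stats(graph: KnowledgeGraph, **dist_kwargs) -> dict:
    """Entity/relation/triple counts plus the average reachable distance."""
    return {
        "n_entities": graph.n_entities,
        "n_relations": graph.n_relations,
        "n_triples": graph.n_triples,
        "avg_reachable_distance": avg_reachable_distance(graph, **dist_kwargs),
    }
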