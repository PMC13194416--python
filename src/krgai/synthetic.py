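"""Synthetic plant-style knowledge graphs and inductive benchmark splits.

Real plant KGs mix deep taxonomic chains (species -> genus -> family ->
order -> class), ecological association chains (infection, vectoring,
predation, habitat) and a long tail of noisy heterogeneous relations.
None of the published graphs this package targets are deposited, so this
module generates graphs with the same structural signature: multi-level
taxonomy forests, pendant ecological chains of 4-6 hops, imbalanced
relation frequencies, and entity-disjoint inductive train/test splits
carved by random walks with restart.

The prediction targets are *compositional*: every species is linked to its
k-hop taxonomic ancestor by a held-out target relation that never occurs
as a graph edge, so a model can only solve the benchmark by composing k
relation hops — the long-range regime the reasoning model is built for.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kg_core import (
    EmptyGraphError,
    InductiveSplit,
    KnowledgeGraph,
    Triple,
    Vocab,
    avg_reachable_distance,
    read_triples,
    write_triples,
)

logger = logging.getLogger("krgai")

__all__ = [
    "GeneratorConfig",
    "PartitionConfig",
    "generate_plant_kg",
    "random_walk_partition",
    "make_inductive_benchmark",
    "make_benchmark",
    "save_benchmark",
    "load_benchmark",
    "PRESETS",
]

TAXONOMY_RELATIONS = ("in_genus", "in_family", "in_order", "in_class")
BACKBONE_RELATION = "sister_clade"
ECO_RELATIONS = (
    "infected_by",
    "vector",
    "natural_enemy",
    "grows_in",
    "pollinated_by",
)


class ConfigError(ValueError):
    """A generator or partition configuration is invalid."""


class RegenerationError(RuntimeError):
    """A split came out degenerate; regenerate with a larger graph."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape of the generated plant KG.

    The taxonomy is a forest: each of ``n_orders`` order-groups carries its
    own class-level root, so every species sits at the bottom of a 4-hop
    chain species -> genus -> family -> order -> class even in minimal
    configs.  ``target_relation_hops`` (k) selects the held-out rule: each
    species is paired with its ancestor exactly k taxonomy hops up.
    ``noise_edge_rate`` adds that fraction of schema edges as random
    intra-component edges with a power-law over relation types (plant KGs
    have highly imbalanced relation frequencies).

    ``clade_sizes`` optionally groups the order-trees into clades: the
    class roots of each clade are joined in a ring by a ``sister_clade``
    backbone relation, the way sister taxa are linked at the top of real
    phylogenies.  Clades make each connected component carry many
    type-identical class-level nodes, so a model can only pick the right
    k-hop ancestor by actually composing the path — a 1-hop "looks like a
    class" shortcut does not identify the target.  Ring size also sets a
    component's internal path lengths, which is how the presets realize
    their distance regimes.  Sizes must sum to ``n_orders``; ``None``
    leaves every order-tree its own component.
    """

    n_orders: int = 12
    n_families_per_order: int = 2
    n_genera_per_family: int = 2
    n_species_per_genus: int = 4
    n_eco_chains: int = 6
    eco_chain_length: int = 5
    target_relation_hops: int = 4
    noise_edge_rate: float = 0.15
    clade_sizes: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_orders,
            self.n_families_per_order,
            self.n_genera_per_family,
            self.n_species_per_genus,
        )
        if any(c < 1 for c in counts):
            raise ConfigError("all taxonomy counts must be >= 1")
        if self.n_eco_chains < 0:
            raise ConfigError("n_eco_chains must be >= 0")
        if self.n_eco_chains > 0 and self.eco_chain_length < 2:
            raise ConfigError("eco_chain_length must be >= 2")
        if not (0.0 <= self.noise_edge_rate <= 1.0):
            raise ConfigError("noise_edge_rate must be in [0, 1]")
        if not (1 <= self.target_relation_hops <= len(TAXONOMY_RELATIONS)):
            raise ConfigError(
                f"target_relation_hops must be in "
                f"[1, {len(TAXONOMY_RELATIONS)}]"
            )
        if self.clade_sizes is not None:
            if any(s < 1 for s in self.clade_sizes):
                raise ConfigError("clade sizes must be >= 1")
            if sum(self.clade_sizes) != self.n_orders:
                raise ConfigError("clade_sizes must sum to n_orders")

    @property
    def target_relation_label(self) -> str:
        return f"taxon_ancestor_{self.target_relation_hops}"


@dataclass(frozen=True)
class PartitionConfig:
    """Random-walk-with-restart sampling parameters for subgraph carving."""

    walk_length: int = 50
    walks_per_node: int = 10
    restart_probability: float = 0.3
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ConfigError("walk_length and walks_per_node must be >= 1")
        if not (0.0 < self.restart_probability <= 1.0):
            raise ConfigError("restart_probability must be in (0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError("train_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Graph generation
# ---------------------------------------------------------------------------

def generate_plant_kg(
    config: GeneratorConfig,
) -> tuple[KnowledgeGraph, list[Triple]]:
    """Generate a plant-style KG plus its held-out compositional targets.

    Returns the graph and the list of rule instances
    ``(species, taxon_ancestor_k, ancestor)`` implied by composing exactly
    ``target_relation_hops`` taxonomy edges.  Rule instances are NOT edges
    of the graph — they are the prediction targets.  Identical configs
    (including seed) produce identical graphs.
    """
    rng = np.random.default_rng(config.seed)
    vocab = Vocab()
    for rel in TAXONOMY_RELATIONS:
        vocab.add_relation(rel)
    backbone = vocab.add_relation(BACKBONE_RELATION)
    for rel in ECO_RELATIONS:
        vocab.add_relation(rel)
    target_rel = vocab.add_relation(config.target_relation_label)

    # order-tree o belongs to clade clade_of[o]
    if config.clade_sizes is None:
        clade_of = list(range(config.n_orders))
    else:
        clade_of = [
            c for c, size in enumerate(config.clade_sizes) for _ in range(size)
        ]

    triples: set[Triple] = set()
    component: dict[int, int] = {}  # entity -> order-group id
    species_chain: list[list[int]] = []  # per species: [species..class] path

    def emit(h: int, r: int, t: int) -> None:
        triples.add(Triple(h, r, t))

    in_genus, in_family, in_order, in_class = (
        vocab.relation_index(r) for r in TAXONOMY_RELATIONS
    )

    all_species: list[int] = []
    class_roots: list[int] = []
    for o in range(config.n_orders):
        cls = vocab.add_entity(f"class_{o}")
        order = vocab.add_entity(f"order_{o}")
        class_roots.append(cls)
        component[cls] = component[order] = clade_of[o]
        emit(order, in_class, cls)
        for f in range(config.n_families_per_order):
            fam = vocab.add_entity(f"family_{o}_{f}")
            component[fam] = clade_of[o]
            emit(fam, in_order, order)
            for g in range(config.n_genera_per_family):
                gen = vocab.add_entity(f"genus_{o}_{f}_{g}")
                component[gen] = clade_of[o]
                emit(gen, in_family, fam)
                for s in range(config.n_species_per_genus):
                    sp = vocab.add_entity(f"species_{o}_{f}_{g}_{s}")
                    component[sp] = clade_of[o]
                    emit(sp, in_genus, gen)
                    all_species.append(sp)
                    species_chain.append([sp, gen, fam, order, cls])

    # phylogenetic backbone: class roots of each clade joined in a ring
    if config.clade_sizes is not None:
        by_clade: dict[int, list[int]] = {}
        for o, cls in enumerate(class_roots):
            by_clade.setdefault(clade_of[o], []).append(cls)
        for roots in by_clade.values():
            if len(roots) == 2:
                emit(roots[0], backbone, roots[1])
            elif len(roots) > 2:
                for i, a in enumerate(roots):
                    emit(a, backbone, roots[(i + 1) % len(roots)])

    # ecological chains: pendant paths anchored at random species, with a
    # power-law over eco relation types (imbalanced frequencies)
    eco_idx = [vocab.relation_index(r) for r in ECO_RELATIONS]
    eco_weights = 1.0 / np.arange(1, len(eco_idx) + 1)
    eco_weights /= eco_weights.sum()
    for c in range(config.n_eco_chains):
        anchor = int(rng.choice(all_species))
        prev = anchor
        for i in range(config.eco_chain_length):
            node = vocab.add_entity(f"eco_{c}_{i}")
            component[node] = component[anchor]
            rel = int(rng.choice(eco_idx, p=eco_weights))
            emit(prev, rel, node)
            prev = node

    # noise edges: intra-component, so the component structure (and hence
    # the inductive partition) stays intact, and confined to organism-level
    # entities (species and ecological nodes) — real plant KGs carry their
    # noise in observational/ecological assertions while the upper
    # taxonomic backbone is curated
    n_schema = len(triples)
    n_noise = int(round(config.noise_edge_rate * n_schema))
    noise_pool = set(all_species) | {
        e for e, lbl in zip(range(vocab.n_entities), vocab.entity_labels)
        if lbl.startswith("eco_")
    }
    by_comp: dict[int, list[int]] = {}
    for ent, comp in component.items():
        if ent in noise_pool:
            by_comp.setdefault(comp, []).append(ent)
    edge_rels = [vocab.relation_index(r) for r in TAXONOMY_RELATIONS] + eco_idx
    noise_weights = 1.0 / np.arange(1, len(edge_rels) + 1)
    noise_weights /= noise_weights.sum()
    comp_ids = sorted(by_comp)
    comp_sizes = np.array([len(by_comp[c]) for c in comp_ids], dtype=float)
    comp_probs = comp_sizes / comp_sizes.sum()
    added = 0
    attempts = 0
    while added < n_noise and attempts < 50 * max(n_noise, 1):
        attempts += 1
        comp = comp_ids[int(rng.choice(len(comp_ids), p=comp_probs))]
        members = by_comp[comp]
        if len(members) < 2:
            continue
        u, v = rng.choice(len(members), size=2, replace=False)
        rel = int(rng.choice(edge_rels, p=noise_weights))
        t = Triple(members[int(u)], rel, members[int(v)])
        if t not in triples:
            triples.add(t)
            added += 1

    if vocab.n_entities < 2:
        raise ConfigError("config implies fewer than 2 entities")

    k = config.target_relation_hops
    rule_instances = [
        Triple(chain[0], target_rel, chain[k]) for chain in species_chain
    ]
    graph = KnowledgeGraph(vocab=vocab, triples=triples)
    logger.info(
        "generate_plant_kg: %d entities, %d relations, %d triples "
        "(%d noise), %d rule instances",
        graph.n_entities, graph.n_relations, graph.n_triples, added,
        len(rule_instances),
    )
    return graph, rule_instances


# ---------------------------------------------------------------------------
# Random-walk partitioning
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def random_walk_partition(
    graph: KnowledgeGraph, config: PartitionConfig
) -> list[frozenset[int]]:
    """Carve the graph into disjoint entity sets via walks with restart.

    From every node, ``walks_per_node`` undirected walks of ``walk_length``
    steps are run; at each step the walker teleports back to its start
    with ``restart_probability`` and otherwise moves to a uniformly random
    neighbor.  Each start's visited set is a candidate subgraph;
    overlapping candidates are greedily merged (union-find over shared
    nodes) until the sets are disjoint.  Walks use the undirected view,
    consistent with the undirected distance statistics reported for such
    benchmarks.  Connected components are, by construction, processed
    independently: a walk can never leave its component.
    """
    n = graph.n_entities
    if n == 0:
        raise EmptyGraphError("cannot partition an empty graph")
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for h, _, t in graph.sorted_triples():
        if h != t:
            nbrs[h].append(t)
            nbrs[t].append(h)
    rng = np.random.default_rng(config.seed)
    uf = _UnionFind(n)
    p = config.restart_probability
    for start in range(n):
        visited = {start}
        for _ in range(config.walks_per_node):
            cur = start
            for _ in range(config.walk_length):
                if rng.random() < p or not nbrs[cur]:
                    cur = start
                else:
                    cur = nbrs[cur][int(rng.integers(len(nbrs[cur])))]
                visited.add(cur)
        first = min(visited)
        for v in visited:
            uf.union(first, v)
    groups: dict[int, set[int]] = {}
    for v in range(n):
        groups.setdefault(uf.find(v), set()).add(v)
    parts = sorted((frozenset(g) for g in groups.values()), key=min)
    logger.info(
        "random_walk_partition: %d nodes -> %d disjoint subgraphs", n, len(parts)
    )
    return parts


# ---------------------------------------------------------------------------
# Inductive benchmark assembly
# ---------------------------------------------------------------------------

def _induce(
    graph: KnowledgeGraph, entities: set[int], relation_labels: list[str]
) -> tuple[KnowledgeGraph, dict[int, int]]:
    """Subgraph on ``entities`` with a fresh entity vocab, shared relations."""
    vocab = Vocab(relation_labels=relation_labels)
    remap: dict[int, int] = {}
    labels = graph.vocab.entity_labels
    triples: set[Triple] = set()
    for h, r, t in graph.sorted_triples():
        if h in entities and t in entities:
            hh = remap.setdefault(h, vocab.add_entity(labels[h]))
            tt = remap.setdefault(t, vocab.add_entity(labels[t]))
            triples.add(Triple(hh, r, tt))
    return KnowledgeGraph(vocab=vocab, triples=triples), remap


def make_inductive_benchmark(
    graph: KnowledgeGraph,
    rule_instances: list[Triple],
    pcfg: PartitionConfig,
    *,
    test_side: str = "random",
) -> InductiveSplit:
    """Assemble an entity-disjoint train/test split from walk subgraphs.

    Subgraphs are assigned to train/test by ``train_fraction`` (train gets
    ``floor(fraction * n)``).  ``test_side`` controls which subgraphs the
    test side draws: ``"random"`` (seeded shuffle), ``"long"`` (the
    longest-average-distance subgraphs — emulating benchmarks whose test
    graphs trace complete taxonomic/ecological chains) or ``"short"`` (the
    densest/shortest — emulating test sets sampled for local density
    within taxonomic groups).  Rule instances with both endpoints on the
    test side become test queries; 10% of train-side instances become
    validation queries, the rest training queries.
    """
    if test_side not in ("random", "long", "short"):
        raise ConfigError(f"unknown test_side {test_side!r}")
    parts = random_walk_partition(graph, pcfg)
    if len(parts) < 2:
        raise RegenerationError(
            "partition produced fewer than 2 subgraphs; use a larger or more "
            "modular graph"
        )
    rng = np.random.default_rng(pcfg.seed)
    order = list(rng.permutation(len(parts)))
    if test_side != "random":
        dists = []
        for i in order:
            sub, _ = _induce(graph, set(parts[i]), graph.vocab.relation_labels)
            try:
                d = avg_reachable_distance(sub)
            except EmptyGraphError:
                d = 0.0
            dists.append(d)
        # ascending distance; ties keep the shuffled order
        order = [i for _, i in sorted(zip(dists, order), key=lambda p: p[0])]
    n_train = int(math.floor(pcfg.train_fraction * len(parts)))
    n_train = min(max(n_train, 1), len(parts) - 1)
    if test_side == "long":
        train_idx, test_idx = order[:n_train], order[n_train:]
    elif test_side == "short":
        test_idx = order[: len(parts) - n_train]
        train_idx = order[len(parts) - n_train:]
    else:
        train_idx, test_idx = order[:n_train], order[n_train:]
    train_ents = set().union(*(parts[i] for i in train_idx))
    test_ents = set().union(*(parts[i] for i in test_idx))

    rels = graph.vocab.relation_labels
    train_graph, train_map = _induce(graph, train_ents, list(rels))
    test_graph, test_map = _induce(graph, test_ents, list(rels))
    if not train_graph.triples or not test_graph.triples:
        raise RegenerationError("a side has no edges; regenerate larger")

    def project(inst: Triple, remap: dict[int, int]) -> Triple | None:
        if inst.head in remap and inst.tail in remap:
            return Triple(remap[inst.head], inst.relation, remap[inst.tail])
        return None

    train_side = [q for q in (project(i, train_map) for i in rule_instances) if q]
    test_queries = [q for q in (project(i, test_map) for i in rule_instances) if q]
    if not train_side or not test_queries:
        raise RegenerationError(
            "a side has zero rule-instance queries; regenerate with a larger "
            "graph or more subgraphs"
        )
    perm = rng.permutation(len(train_side))
    n_valid = max(1, int(round(0.1 * len(train_side))))
    valid_queries = [train_side[i] for i in perm[:n_valid]]
    train_queries = [train_side[i] for i in perm[n_valid:]]
    if not train_queries:
        raise RegenerationError("no training queries left after validation split")

    split = InductiveSplit(
        train_graph=train_graph,
        test_graph=test_graph,
        test_queries=test_queries,
        valid_queries=valid_queries,
        train_queries=train_queries,
    )
    split.validate()
    logger.info(
        "make_inductive_benchmark: train |E|=%d |T|=%d queries=%d "
        "(+%d valid) / test |E|=%d |T|=%d queries=%d",
        train_graph.n_entities, train_graph.n_triples, len(train_queries),
        len(valid_queries), test_graph.n_entities, test_graph.n_triples,
        len(test_queries),
    )
    return split


# ---------------------------------------------------------------------------
# Presets and file round-trip
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Preset:
    generator: GeneratorConfig
    partition: PartitionConfig
    test_side: str


PRESETS: dict[str, Preset] = {
    # long-chain regime: test graphs carry the chain-heavy subgraphs, so
    # test average distances exceed train (the harder long-range testbed)
    "pnkg-like": Preset(
        generator=GeneratorConfig(
            n_orders=64,
            n_families_per_order=1,
            n_genera_per_family=1,
            n_species_per_genus=1,
            n_eco_chains=6,
            eco_chain_length=6,
            target_relation_hops=4,
            noise_edge_rate=0.05,
            clade_sizes=(12, 12, 10, 10, 10, 10),
        ),
        partition=PartitionConfig(),
        test_side="long",
    ),
    # dense-test regime: test side draws the shortest-distance subgraphs,
    # train keeps the long backbone rings
    "dps-like": Preset(
        generator=GeneratorConfig(
            n_orders=40,
            n_families_per_order=1,
            n_genera_per_family=1,
            n_species_per_genus=1,
            n_eco_chains=8,
            eco_chain_length=6,
            target_relation_hops=4,
            noise_edge_rate=0.05,
            clade_sizes=(12, 12, 4, 4, 4, 4),
        ),
        partition=PartitionConfig(),
        test_side="short",
    ),
}


def make_benchmark(preset: str, seed: int) -> InductiveSplit:
    """Generate a preset benchmark end-to-end with a single seed."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
    p = PRESETS[preset]
    gcfg = replace(p.generator, seed=seed)
    pcfg = replace(p.partition, seed=seed)
    graph, rules = generate_plant_kg(gcfg)
    return make_inductive_benchmark(graph, rules, pcfg, test_side=p.test_side)


def _write_queries(
    queries: list[Triple], vocab: Vocab, rels: list[str], path: Path
) -> None:
    ents = vocab.entity_labels
    with path.open("w", encoding="utf-8") as fh:
        for h, r, t in sorted(queries):
            fh.write(f"{ents[h]}\t{rels[r]}\t{ents[t]}\n")


def save_benchmark(split: InductiveSplit, out_dir: str | Path) -> Path:
    """Write a split as plain TSV files (graphs, queries, relation vocab)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rels = split.train_graph.vocab.relation_labels
    write_triples(split.train_graph, out / "train.tsv")
    write_triples(split.test_graph, out / "test_graph.tsv")
    _write_queries(
        split.train_queries, split.train_graph.vocab, rels, out / "train_queries.tsv"
    )
    _write_queries(
        split.valid_queries, split.train_graph.vocab, rels, out / "valid_queries.tsv"
    )
    _write_queries(
        split.test_queries, split.test_graph.vocab, rels, out / "test_queries.tsv"
    )
    with (out / "relations.tsv").open("w", encoding="utf-8") as fh:
        for i, r in enumerate(rels):
            fh.write(f"{r}\t{i}\n")
    return out


def _read_queries(path: Path, vocab: Vocab) -> list[Triple]:
    out = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            h, r, t = line.split("\t")[:3]
            out.append(
                Triple(
                    vocab.entity_index(h), vocab.relation_index(r),
                    vocab.entity_index(t),
                )
            )
    return out


def load_benchmark(bench_dir: str | Path) -> InductiveSplit:
    """Reload a split written by :func:`save_benchmark`."""
    d = Path(bench_dir)
    rels: list[str] = []
    with (d / "relations.tsv").open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rels.append(line.split("\t")[0])

    def load_graph(path: Path) -> KnowledgeGraph:
        raw = read_triples(path)
        vocab = Vocab(relation_labels=rels)
        remap_r = {
            i: vocab.relation_index(lbl)
            for i, lbl in enumerate(raw.vocab.relation_labels)
        }
        for e in raw.vocab.entity_labels:
            vocab.add_entity(e)
        triples = {
            Triple(h, remap_r[r], t) for h, r, t in raw.triples
        }
        return KnowledgeGraph(vocab=vocab, triples=triples)

    train_graph = load_graph(d / "train.tsv")
    test_graph = load_graph(d / "test_graph.tsv")
    split = InductiveSplit(
        train_graph=train_graph,
        test_graph=test_graph,
        test_queries=_read_queries(d / "test_queries.tsv", test_graph.vocab),
        valid_queries=_read_queries(d / "valid_queries.tsv", train_graph.vocab),
        train_queries=_read_queries(d / "train_queries.tsv", train_graph.vocab),
    )
    split.validate()
    return split
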