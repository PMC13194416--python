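"""The dual-channel inductive KG reasoning network.

Given a graph ``G=(E,R,T)`` and a query ``(h, q, ?)``, the network is
query-conditioned: node states start at zero except the head row, which
is set to the query relation's embedding, so no per-entity parameters
exist and the model transfers to graphs of unseen entities.

Each full layer runs two parallel channels over the node-state matrix
``E^(l)`` (|E| x d):

* a **global channel** — multi-head kernelized linear self-attention,
  ``phi(Q) (phi(K)^T V)`` with ``phi(x) = ELU(x) + 1``; associativity of
  the product makes the cost linear in |E| while remaining exactly equal
  to the quadratic-order computation;
* a **local channel** — attentive relational message passing: each edge
  ``(u, r, v)`` carries the message ``W_phi (e_v + r_r)``, scored by
  ``LeakyReLU(W_att . msg)`` and softmax-normalized over ``N(u)``.

Per node, the self, global and local feature vectors are fused by an
attention over the three branches (``alpha_i = softmax(LeakyReLU(w . e_i))``),
optionally replaced by plain sum or learned concat for comparison.
Relation states are updated between layers by a linear map (or swapped
for per-layer free tables).  A two-layer MLP (hidden 64, ReLU, sigmoid)
scores candidate triples from the final states.

A stack of ``n_base_gnn_layers`` local-only layers (the base GNN) runs
first: global attention over the nearly-empty initial states carries no
usable signal, so structural features are accumulated locally before the
full dual-channel layers engage.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .kg_core import KnowledgeGraph, neighborhood

logger = logging.getLogger("krgai")

__all__ = [
    "ModelConfig",
    "NumericError",
    "init_params",
    "read_relation_embeddings",
    "init_node_states",
    "kernel_phi",
    "global_head",
    "global_module",
    "message",
    "local_module",
    "fuse",
    "relation_update",
    "forward",
    "forward_batch",
    "score_triple",
    "score_logits",
    "GraphCache",
    "reset_mac_count",
    "get_mac_count",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.01
CHECKPOINT_VERSION = "krgai-ckpt-1"


class NumericError(FloatingPointError):
    """Non-finite values appeared inside the network."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``dim`` is the embedding width d (divisible by ``n_heads``);
    ``n_total_layers`` L counts base-GNN plus dual-channel layers;
    ``normalize_global`` opts into the row-normalized linear attention
    (``phi(Q) (phi(K)^T 1)`` denominator) — off by default, matching the
    plain associative product; the normalized form is the numerically
    stable choice for training on graphs of hundreds of nodes.
    """

    dim: int = 32
    n_heads: int = 4
    n_total_layers: int = 5
    n_base_gnn_layers: int = 2
    kernel: str = "elu-plus-one"
    normalize_global: bool = False
    fusion_mode: str = "attention"
    ablate_global: bool = False
    ablate_local: bool = False
    layer_independent_relations: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.dim % self.n_heads != 0:
            raise ValueError(
                f"dim {self.dim} not divisible by n_heads {self.n_heads}"
            )
        if not (1 <= self.n_total_layers <= 6):
            raise ValueError("n_total_layers must be in [1, 6]")
        if not (0 <= self.n_base_gnn_layers <= self.n_total_layers):
            raise ValueError("n_base_gnn_layers must be in [0, L]")
        if self.kernel != "elu-plus-one":
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.fusion_mode not in ("attention", "sum", "concat"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")

    @property
    def head_dim(self) -> int:
        return self.dim // self.n_heads


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _xavier(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_out = shape[-1] if len(shape) > 1 else 1
    fan_in = shape[-2] if len(shape) > 1 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def read_relation_embeddings(
    path: str | Path, relation_labels: list[str], dim: int
) -> np.ndarray:
    """Parse a ``label<TAB>v1,...,vd`` table of pre-trained relation vectors.

    Returns a ``(n_relations, dim)`` array aligned with ``relation_labels``;
    labels absent from the file raise, extra labels are ignored.
    """
    table: dict[str, np.ndarray] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            label, _, vec = line.partition("\t")
            values = np.fromiter(
                (float(x) for x in vec.split(",") if x.strip()), dtype=float
            )
            if values.size != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values, got {values.size}"
                )
            table[label] = values
    missing = [r for r in relation_labels if r not in table]
    if missing:
        raise ValueError(f"{path}: missing embeddings for relations {missing}")
    return np.stack([table[r] for r in relation_labels])


def init_params(
    n_relations: int,
    cfg: ModelConfig,
    rel_embeddings: np.ndarray | None = None,
) -> dict[str, Tensor]:
    """Seeded Xavier-uniform parameter set for ``n_relations`` relations.

    The relation table has ``2 * n_relations`` rows: forward relations
    plus their inverse-augmented counterparts.  ``rel_embeddings``
    optionally initializes the forward rows from a pre-trained table
    (the inverse rows stay Xavier-initialized).
    """
    rng = np.random.default_rng(cfg.seed)
    d, dk = cfg.dim, cfg.head_dim
    params: dict[str, np.ndarray] = {}
    params["rel_embed"] = _xavier(rng, 2 * n_relations, d)
    if rel_embeddings is not None:
        if rel_embeddings.shape != (n_relations, d):
            raise ValueError(
                f"pre-trained relation table has shape {rel_embeddings.shape}, "
                f"expected {(n_relations, d)}"
            )
        params["rel_embed"][:n_relations] = rel_embeddings
    for i in range(cfg.n_total_layers):
        for h in range(cfg.n_heads):
            params[f"L{i}.WQ{h}"] = _xavier(rng, d, dk)
            params[f"L{i}.WK{h}"] = _xavier(rng, d, dk)
            params[f"L{i}.WV{h}"] = _xavier(rng, d, dk)
        params[f"L{i}.Wm"] = _xavier(rng, d, d)
        params[f"L{i}.Wphi"] = _xavier(rng, d, d)
        params[f"L{i}.Watt"] = _xavier(rng, d)
        params[f"L{i}.wfuse"] = _xavier(rng, d)
        if cfg.fusion_mode == "concat":
            params[f"L{i}.Wcat"] = _xavier(rng, 3 * d, d)
        if cfg.layer_independent_relations:
            if i > 0:
                params[f"L{i}.rel_table"] = _xavier(rng, 2 * n_relations, d)
        else:
            params[f"L{i}.Wrel"] = _xavier(rng, d, d)
    params["scorer.W1"] = _xavier(rng, 3 * d, 64)
    params["scorer.b1"] = np.zeros(64)
    params["scorer.W2"] = _xavier(rng, 64, 1)
    params["scorer.b2"] = np.zeros(1)
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Graph cache: flat message-edge arrays for vectorized passing
# ---------------------------------------------------------------------------

class GraphCache:
    """Message edges of a graph flattened to index arrays, sorted by target.

    ``edge_u[j]`` receives message j from ``edge_v[j]`` under relation
    ``edge_rel[j]`` (inverse-augmented: a triple (h,r,t) yields a forward
    message edge into h and an inverse one, relation r+|R|, into t).
    """

    def __init__(self, graph: KnowledgeGraph, inverse: bool = True):
        us, rs, vs = [], [], []
        for u in range(graph.n_entities):
            for r, v in neighborhood(graph, u, inverse=inverse):
                us.append(u)
                rs.append(r)
                vs.append(v)
        self.edge_u = np.asarray(us, dtype=np.int64)
        self.edge_rel = np.asarray(rs, dtype=np.int64)
        self.edge_v = np.asarray(vs, dtype=np.int64)
        self.n_entities = graph.n_entities
        self.n_relations = graph.n_relations


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

_MAC_COUNT = {"global": 0}


def reset_mac_count() -> None:
    _MAC_COUNT["global"] = 0


def get_mac_count() -> int:
    """Multiply-accumulate operations executed by the global channel."""
    return _MAC_COUNT["global"]


def kernel_phi(x: Tensor) -> Tensor:
    """The positive attention kernel ``ELU(x) + 1``; > 0 for finite x.

    Evaluated as ``exp(min(x, 0)) + relu(x)`` — identical to ELU(x)+1 in
    exact arithmetic but immune to the catastrophic cancellation that
    rounds ``(e^x - 1) + 1`` to zero for x below about -36.
    """
    pos = x.relu()
    return (x - pos).exp() + pos


def init_node_states(
    graph: KnowledgeGraph, query: tuple[int, int], rel_states: Tensor
) -> Tensor:
    """Query-conditioned initial node states (|E| x d).

    The head row carries the query relation's embedding; every other row
    is zero.  The scheme uses no entity identity, which is what makes the
    network inductive: relabeling entities permutes rows and nothing else.
    """
    head, q_rel = query
    if not (0 <= head < graph.n_entities):
        raise IndexError(f"query head {head} not in graph")
    onehot = np.zeros((graph.n_entities, 1))
    onehot[head, 0] = 1.0
    return Tensor(onehot) * rel_states.take(np.asarray([q_rel]), axis=0)


def _init_states_batch(
    n_entities: int,
    queries: list[tuple[int, int]],
    rel_states: Tensor,
) -> Tensor:
    heads = np.asarray([q[0] for q in queries])
    rels = np.asarray([q[1] for q in queries])
    B = len(queries)
    onehot = np.zeros((B, n_entities, 1))
    onehot[np.arange(B), heads, 0] = 1.0
    q_emb = rel_states.take(rels, axis=0)  # (B, d)
    return Tensor(onehot) * q_emb.expand_dims(1)


def global_head(
    E: Tensor,
    WQ: Tensor,
    WK: Tensor,
    WV: Tensor,
    *,
    normalize: bool = False,
) -> Tensor:
    """One linear-attention head: ``phi(Q) (phi(K)^T V)``.

    The kernelized product is associated right-to-left, so the |E| x |E|
    score matrix never materializes and cost is linear in |E|.  With
    ``normalize``, row i is divided by ``phi(Q)_i . (phi(K)^T 1)``.
    """
    Q = E @ WQ
    K = E @ WK
    V = E @ WV
    phiQ = kernel_phi(Q)
    phiK = kernel_phi(K)
    KV = phiK.swapaxes(-1, -2) @ V  # (dk, dk)
    out = phiQ @ KV
    n = E.shape[-2]
    d, dk = WQ.shape
    batch = int(np.prod(E.shape[:-2])) if E.ndim > 2 else 1
    _MAC_COUNT["global"] += batch * (3 * n * d * dk + 2 * n * dk * dk)
    if normalize:
        ksum = phiK.sum(axis=-2, keepdims=True)  # (1, dk)
        denom = (phiQ * ksum).sum(axis=-1, keepdims=True)
        out = out / (denom + 1e-12)
        _MAC_COUNT["global"] += batch * n * dk
    if not np.isfinite(out.data).all():
        raise NumericError("non-finite output in global attention head")
    return out


def global_module(
    E: Tensor, params: dict[str, Tensor], layer: int, cfg: ModelConfig
) -> Tensor:
    """Multi-head global channel: concat of head outputs, then ``W_m``."""
    heads = [
        global_head(
            E,
            params[f"L{layer}.WQ{h}"],
            params[f"L{layer}.WK{h}"],
            params[f"L{layer}.WV{h}"],
            normalize=cfg.normalize_global,
        )
        for h in range(cfg.n_heads)
    ]
    out = concat(heads, axis=-1) @ params[f"L{layer}.Wm"]
    n = E.shape[-2]
    batch = int(np.prod(E.shape[:-2])) if E.ndim > 2 else 1
    _MAC_COUNT["global"] += batch * n * cfg.dim * cfg.dim
    return out


def message(
    u: int,
    r: int,
    v: int,
    E: Tensor,
    R: Tensor,
    Wphi: Tensor,
) -> Tensor:
    """The message ``W_phi (e_v + r_r)`` carried by edge (u, r, v)."""
    ev = E.take(np.asarray([v]), axis=0)
    rr = R.take(np.asarray([r]), axis=0)
    return ((ev + rr) @ Wphi.swapaxes(-1, -2)).reshape(-1)


def local_module(
    E: Tensor,
    R: Tensor,
    cache: GraphCache,
    Wphi: Tensor,
    Watt: Tensor,
) -> Tensor:
    """Attentive relational message passing over first-order neighborhoods.

    Per node u: messages from N(u) are scored by
    ``gamma = LeakyReLU(W_att . msg)``, softmax-normalized to beta over
    N(u), and summed.  Isolated nodes receive a zero row.
    """
    n = cache.n_entities
    if cache.edge_u.size == 0:
        return E * 0.0
    ax = E.ndim - 2  # node axis
    Ev = E.take(cache.edge_v, axis=ax)
    Rr = R.take(cache.edge_rel, axis=0)
    M = (Ev + Rr) @ Wphi.swapaxes(-1, -2)
    gamma = (M * Watt).sum(axis=-1)
    # segment softmax over each target's incoming edges; the max shift is
    # a constant (it cancels in beta), so it is computed outside the tape
    gmax = np.full(gamma.shape[:-1] + (n,), -np.inf)
    idx = (slice(None),) * (gamma.ndim - 1) + (cache.edge_u,)
    np.maximum.at(gmax, idx, gamma.data)
    shifted = gamma - Tensor(gmax[idx])
    exp_g = shifted.exp()
    denom = exp_g.segment_sum(cache.edge_u, n, axis=-1)
    beta = exp_g / denom.take(cache.edge_u, axis=-1)
    weighted = beta.expand_dims(-1) * M
    return weighted.segment_sum(cache.edge_u, n, axis=ax)


def fuse(
    e_self: Tensor,
    e_global: Tensor | None,
    e_local: Tensor | None,
    w: Tensor,
    mode: str = "attention",
    *,
    ablate_global: bool = False,
    ablate_local: bool = False,
    Wcat: Tensor | None = None,
) -> Tensor:
    """Combine self / global / local branches per node.

    ``attention``: branch scores ``f_i = exp(LeakyReLU(w . e_i))`` are
    normalized to alpha over the active branches and the branches are
    averaged with those weights.  Ablation flags force the corresponding
    alpha to zero before renormalization.  ``sum`` adds the active
    branches; ``concat`` concatenates all three (ablated ones zeroed) and
    projects back to width d with ``Wcat``.
    """
    branches: list[Tensor | None] = [
        e_self,
        None if (ablate_global or e_global is None) else e_global,
        None if (ablate_local or e_local is None) else e_local,
    ]
    active = [b for b in branches if b is not None]
    if not active:
        raise ValueError("all fusion branches ablated")
    if mode == "sum":
        out = active[0]
        for b in active[1:]:
            out = out + b
        return out
    if mode == "concat":
        if Wcat is None:
            raise ValueError("concat fusion needs Wcat")
        zero = e_self * 0.0
        parts = [b if b is not None else zero for b in branches]
        return concat(parts, axis=-1) @ Wcat
    # attention fusion
    scores = [(b * w).sum(axis=-1).leaky_relu(LEAKY_SLOPE) for b in active]
    smax = np.max(np.stack([s.data for s in scores], axis=0), axis=0)
    fs = [(s - Tensor(smax)).exp() for s in scores]
    denom = fs[0]
    for f in fs[1:]:
        denom = denom + f
    out = None
    for f, b in zip(fs, active):
        term = (f / denom).expand_dims(-1) * b
        out = term if out is None else out + term
    return out


def relation_update(
    R: Tensor,
    params: dict[str, Tensor],
    layer: int,
    layer_independent: bool = False,
) -> Tensor:
    """Between-layer relation refresh: ``R W_rel``, or a free per-layer table."""
    if layer_independent:
        return params[f"L{layer + 1}.rel_table"]
    return R @ params[f"L{layer}.Wrel"]


def forward_batch(
    graph: KnowledgeGraph,
    queries: list[tuple[int, int]],
    params: dict[str, Tensor],
    cfg: ModelConfig,
    cache: GraphCache | None = None,
) -> tuple[Tensor, Tensor]:
    """Run the full stack for a batch of queries on one graph.

    Returns final node states (B x |E| x d) and relation states
    (2|R| x d).  Layers 0..n_base-1 are local-only (the base GNN); the
    remaining layers fuse self, global and local branches per node.
    """
    if not queries:
        raise ValueError("empty query batch")
    cache = cache or GraphCache(graph)
    R_states = params["rel_embed"]
    E = _init_states_batch(graph.n_entities, queries, R_states)
    for i in range(cfg.n_total_layers):
        Wphi, Watt = params[f"L{i}.Wphi"], params[f"L{i}.Watt"]
        if i < cfg.n_base_gnn_layers:
            E = local_module(E, R_states, cache, Wphi, Watt)
        else:
            e_global = (
                None
                if cfg.ablate_global
                else global_module(E, params, i, cfg)
            )
            e_local = (
                None
                if cfg.ablate_local
                else local_module(E, R_states, cache, Wphi, Watt)
            )
            E = fuse(
                E,
                e_global,
                e_local,
                params[f"L{i}.wfuse"],
                mode=cfg.fusion_mode,
                ablate_global=cfg.ablate_global,
                ablate_local=cfg.ablate_local,
                Wcat=params.get(f"L{i}.Wcat"),
            )
        if not np.isfinite(E.data).all():
            raise NumericError(f"non-finite node states after layer {i}")
        if i < cfg.n_total_layers - 1:
            R_states = relation_update(
                R_states, params, i, cfg.layer_independent_relations
            )
    return E, R_states


def forward(
    graph: KnowledgeGraph,
    query: tuple[int, int],
    params: dict[str, Tensor],
    cfg: ModelConfig,
    cache: GraphCache | None = None,
) -> tuple[Tensor, Tensor]:
    """Single-query forward pass; returns (|E| x d, 2|R| x d) states."""
    E, R = forward_batch(graph, [query], params, cfg, cache)
    return E.reshape(E.shape[1], E.shape[2]), R


def score_logits(
    e_h: Tensor, r_q: Tensor, e_t: Tensor, params: dict[str, Tensor]
) -> Tensor:
    """Pre-sigmoid MLP score of ``concat(e_h, r_q, e_t)``; any batch shape."""
    x = concat([e_h, r_q, e_t], axis=-1)
    hidden = (x @ params["scorer.W1"] + params["scorer.b1"]).relu()
    return (hidden @ params["scorer.W2"] + params["scorer.b2"]).sum(axis=-1)


def score_triple(
    e_h: Tensor, r_q: Tensor, e_t: Tensor, params: dict[str, Tensor]
) -> Tensor:
    """Triple probability in (0, 1): sigmoid of the MLP score."""
    return score_logits(e_h, r_q, e_t, params).sigmoid()


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    params: dict[str, Tensor],
    cfg: ModelConfig,
    path: str | Path,
    *,
    relation_labels: list[str] | None = None,
) -> Path:
    """Serialize parameters + config echo + version tag to one archive."""
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(cfg),
        "relation_labels": relation_labels,
    }
    arrays = {k.replace(".", "__"): v.data for k, v in params.items()}
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ), **arrays)
    path.write_bytes(buf.getvalue())
    logger.info("save_checkpoint(%s): %d tensors", path, len(arrays))
    return path


def load_checkpoint(
    path: str | Path,
) -> tuple[dict[str, Tensor], ModelConfig, list[str] | None]:
    """Reload a checkpoint; raises on version mismatch."""
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {meta.get('version')!r} unsupported "
                f"(expected {CHECKPOINT_VERSION})"
            )
        params = {
            k.replace("__", "."): Tensor(npz[k], requires_grad=True)
            for k in npz.files
            if k != "__meta__"
        }
    cfg = ModelConfig(**meta["config"])
    return params, cfg, meta.get("relation_labels")
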