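"""Negative sampling, the ranking objective, Adam training and evaluation.

Training follows the standard negative-sampling recipe for KG link
prediction: each positive query ``(h, q, t)`` is contrasted against ``n``
corrupted tails drawn uniformly from the graph's entities, filtered so no
known-true triple is labeled negative.  The loss per positive is

    L = -log p(h,q,t) - (1/n) * sum_i log(1 - p(h,q,t_i'))

Evaluation mirrors the GraIL protocol: the true tail is ranked against 49
sampled negative tails (Hits@10, pessimistic ties) and AUC-PR is computed
over pooled positive scores with one sampled negative per positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .autodiff import Tensor
from .kg_core import InductiveSplit, KnowledgeGraph, Triple
from .model import (
    GraphCache,
    ModelConfig,
    NumericError,
    forward_batch,
    init_params,
    score_logits,
)

logger = logging.getLogger("krgai")

__all__ = [
    "TrainConfig",
    "EvalReport",
    "sample_negatives",
    "loss",
    "train",
    "rank_tail",
    "hits_at_k",
    "auc_pr",
    "evaluate",
]

PROB_CLAMP = 1e-7


class DegenerateGraphError(ValueError):
    """No valid negative tail exists for a positive triple."""


class ProtocolError(ValueError):
    """The evaluation protocol's preconditions were violated."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (Adam with L2 weight decay)."""

    n_negatives: int = 64
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.n_negatives, self.batch_size) < 1:
            raise ValueError("n_negatives and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("bad optimizer settings")


@dataclass
class EvalReport:
    """Link-prediction metrics plus the protocol metadata to reproduce them."""

    hits_at_10: float
    auc_pr: float
    n_queries: int
    n_candidates_per_query: int
    seed: int
    auc_pr_pooling: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "hits_at_10": self.hits_at_10,
            "auc_pr": self.auc_pr,
            "n_queries": self.n_queries,
            "n_candidates_per_query": self.n_candidates_per_query,
            "seed": self.seed,
            "auc_pr_pooling": self.auc_pr_pooling,
        }


# ---------------------------------------------------------------------------
# Negative sampling and loss
# ---------------------------------------------------------------------------

def _true_tails(graph: KnowledgeGraph, head: int, rel: int) -> set[int]:
    return {t.tail for t in graph.triples if t.head == head and t.relation == rel}


def sample_negatives(
    positive: Triple,
    graph: KnowledgeGraph,
    n: int,
    rng: np.random.Generator,
    *,
    known_true: set[int] | None = None,
) -> list[Triple]:
    """Draw ``n`` filtered corrupted-tail negatives for ``positive``.

    Tails are uniform over entities, resampling any tail that equals the
    positive's or completes a known-true triple.  ``known_true`` lets the
    caller pass a precomputed truth set (e.g. including held-out rule
    instances); by default the graph's own edges are used.
    """
    if graph.n_entities < 2:
        raise DegenerateGraphError("graph has fewer than 2 entities")
    forbidden = set(known_true) if known_true is not None else _true_tails(
        graph, positive.head, positive.relation
    )
    forbidden.add(positive.tail)
    if len(forbidden) >= graph.n_entities:
        raise DegenerateGraphError(
            "every entity is a true tail; no valid negative exists"
        )
    out: list[Triple] = []
    while len(out) < n:
        cand = rng.integers(graph.n_entities, size=n - len(out))
        for c in cand:
            c = int(c)
            if c not in forbidden:
                out.append(Triple(positive.head, positive.relation, c))
                if len(out) == n:
                    break
    return out


def loss(p_pos: float, p_negs: list[float]) -> float:
    """Negative-sampling objective for one positive and its negatives.

    ``-log p_pos - (1/n) sum log(1 - p_neg)``, probabilities clamped to
    [1e-7, 1 - 1e-7] so the logs stay finite.
    """
    if not p_negs:
        raise ValueError("need at least one negative probability")
    lo, hi = PROB_CLAMP, 1.0 - PROB_CLAMP
    p = min(max(p_pos, lo), hi)
    total = -np.log(p)
    total -= np.mean([np.log(1.0 - min(max(q, lo), hi)) for q in p_negs])
    return float(total)


# ---------------------------------------------------------------------------
# Scoring helpers
# ---------------------------------------------------------------------------

def _score_candidates(
    E: Tensor,
    R: Tensor,
    queries: list[Triple],
    cand_tails: np.ndarray,
    params: dict[str, Tensor],
) -> Tensor:
    """Logits (B x C) for candidate tails of each query in the batch."""
    B, N, d = E.shape
    C = cand_tails.shape[1]
    flat = E.reshape(B * N, d)
    heads = np.asarray([q.head for q in queries])
    rels = np.asarray([q.relation for q in queries])
    e_h = flat.take(np.arange(B) * N + heads, axis=0)  # (B, d)
    r_q = R.take(rels, axis=0)  # (B, d)
    flat_idx = (np.arange(B)[:, None] * N + cand_tails).reshape(-1)
    e_t = flat.take(flat_idx, axis=0).reshape(B, C, d)
    e_h3 = e_h.expand_dims(1).broadcast_to((B, C, d))
    r_q3 = r_q.expand_dims(1).broadcast_to((B, C, d))
    return score_logits(e_h3, r_q3, e_t, params)


class _Adam:
    """Adam with additive L2 weight decay, deterministic update order."""

    def __init__(self, params: dict[str, Tensor], lr: float, wd: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, wd
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k in sorted(self.params):
            p = self.params[k]
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(
    split: InductiveSplit,
    mcfg: ModelConfig,
    tcfg: TrainConfig,
    *,
    rel_embeddings: np.ndarray | None = None,
) -> tuple[dict[str, Tensor], list[dict]]:
    """Train on the split's train graph; return best checkpoint + history.

    Per epoch, positives are shuffled and processed in batches; each
    positive is scored jointly with ``n_negatives`` filtered corrupted
    tails from a single query-conditioned forward pass.  The checkpoint
    with the best validation Hits@10 (ties: latest epoch) is returned.
    History rows carry ``epoch``, ``loss`` (mean per positive) and
    ``val_hits10``.
    """
    graph = split.train_graph
    cache = GraphCache(graph)
    params = init_params(graph.n_relations, mcfg, rel_embeddings=rel_embeddings)
    opt = _Adam(params, tcfg.learning_rate, tcfg.weight_decay)
    rng = np.random.default_rng(tcfg.seed)
    positives = list(split.train_queries)
    if not positives:
        raise ValueError("split has no training queries")
    # truth sets per (head, relation): graph edges plus all rule instances,
    # so sibling positives are never sampled as negatives
    truth: dict[tuple[int, int], set[int]] = {}
    for t in list(graph.triples) + positives + split.valid_queries:
        truth.setdefault((t.head, t.relation), set()).add(t.tail)

    history: list[dict] = []
    best_params: dict[str, Tensor] | None = None
    best_val = -1.0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(len(positives))
        epoch_loss = 0.0
        for lo in range(0, len(order), tcfg.batch_size):
            batch = [positives[i] for i in order[lo:lo + tcfg.batch_size]]
            cand = np.empty((len(batch), 1 + tcfg.n_negatives), dtype=np.int64)
            for b, pos in enumerate(batch):
                negs = sample_negatives(
                    pos, graph, tcfg.n_negatives, rng,
                    known_true=truth[(pos.head, pos.relation)],
                )
                cand[b, 0] = pos.tail
                cand[b, 1:] = [t.tail for t in negs]
            E, R = forward_batch(
                graph, [(p.head, p.relation) for p in batch], params, mcfg,
                cache,
            )
            z = _score_candidates(E, R, batch, cand, params)
            # -log sigmoid(z_pos) = softplus(-z); -log(1-sigmoid(z)) = softplus(z)
            zpos = z.take(np.asarray([0]), axis=1)
            zneg = z.take(np.arange(1, 1 + tcfg.n_negatives), axis=1)
            batch_loss = (-zpos).softplus().mean() + zneg.softplus().mean()
            if not np.isfinite(batch_loss.data):
                raise NumericError(
                    f"non-finite loss at epoch {epoch}, "
                    f"batch starting at positive {lo}"
                )
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            epoch_loss += float(batch_loss.data) * len(batch)
        mean_loss = epoch_loss / len(positives)
        val = evaluate(
            split, params, mcfg,
            n_candidates=50,
            seed=int(rng.integers(2 ** 31)),
            side="valid",
        )
        history.append(
            {"epoch": epoch, "loss": mean_loss, "val_hits10": val.hits_at_10}
        )
        logger.info(
            "epoch %d: loss %.4f, val Hits@10 %.3f",
            epoch, mean_loss, val.hits_at_10,
        )
        if val.hits_at_10 >= best_val:
            best_val = val.hits_at_10
            best_params = {
                k: Tensor(p.data.copy(), requires_grad=True)
                for k, p in params.items()
            }
    assert best_params is not None
    return best_params, history


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------

def rank_tail(
    query: Triple, candidate_tails: list[int], scores: list[float]
) -> int:
    """Pessimistic rank of the true tail among scored candidates.

    ``rank = 1 + #(strictly greater) + #(tied with the true tail)``,
    ties counted over the other candidates.
    """
    if len(candidate_tails) != len(scores):
        raise ProtocolError("candidates and scores misaligned")
    try:
        pos = candidate_tails.index(query.tail)
    except ValueError:
        raise ProtocolError(f"true tail {query.tail} missing from candidates")
    s = np.asarray(scores, dtype=float)
    true_score = s[pos]
    others = np.delete(s, pos)
    return int(1 + (others > true_score).sum() + (others == true_score).sum())


def hits_at_k(ranks: list[int], k: int) -> float:
    """Fraction of ranks <= k."""
    if not ranks:
        raise ValueError("empty rank list")
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be >= 1")
    return float(np.mean([r <= k for r in ranks]))


def auc_pr(scores: list[float], labels: list[int]) -> float:
    """Average precision over pooled scores (ties grouped at thresholds)."""
    labels_arr = np.asarray(labels)
    if len(set(labels_arr.tolist())) < 2:
        raise ValueError("auc_pr needs both positive and negative labels")
    return float(average_precision_score(labels_arr, np.asarray(scores)))


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

def evaluate(
    split: InductiveSplit,
    params: dict[str, Tensor],
    mcfg: ModelConfig,
    *,
    n_candidates: int = 50,
    seed: int = 0,
    side: str = "test",
    batch_size: int = 32,
    score_fn=None,
) -> EvalReport:
    """Rank each held-out query's true tail against sampled negatives.

    ``side="test"`` evaluates test queries on the test graph;
    ``side="valid"`` evaluates validation queries on the train graph.
    Hits@10 uses ``n_candidates - 1`` filtered negatives plus the truth;
    AUC-PR pools each query's positive score with its first negative's.
    ``score_fn(E, R, queries, cand) -> (B, C) array`` may replace the MLP
    scorer (debug oracle hook).
    """
    if side == "test":
        graph, queries = split.test_graph, split.test_queries
    elif side == "valid":
        graph, queries = split.train_graph, split.valid_queries
    else:
        raise ValueError(f"unknown side {side!r}")
    if not queries:
        raise ProtocolError(f"no queries on side {side!r}")
    cache = GraphCache(graph)
    rng = np.random.default_rng(seed)
    truth: dict[tuple[int, int], set[int]] = {}
    for t in list(graph.triples) + queries:
        truth.setdefault((t.head, t.relation), set()).add(t.tail)
    ranks: list[int] = []
    pooled_scores: list[float] = []
    pooled_labels: list[int] = []
    for lo in range(0, len(queries), batch_size):
        batch = queries[lo:lo + batch_size]
        cand = np.empty((len(batch), n_candidates), dtype=np.int64)
        for b, q in enumerate(batch):
            negs = sample_negatives(
                q, graph, n_candidates - 1, rng,
                known_true=truth[(q.head, q.relation)],
            )
            cand[b, 0] = q.tail
            cand[b, 1:] = [t.tail for t in negs]
        E, R = forward_batch(
            graph, [(q.head, q.relation) for q in batch], params, mcfg, cache
        )
        if score_fn is None:
            z = _score_candidates(E, R, batch, cand, params)
            probs = z.sigmoid().data
        else:
            probs = np.asarray(score_fn(E, R, batch, cand))
        for b, q in enumerate(batch):
            ranks.append(
                rank_tail(q, cand[b].tolist(), probs[b].tolist())
            )
            pooled_scores.extend([float(probs[b, 0]), float(probs[b, 1])])
            pooled_labels.extend([1, 0])
    return EvalReport(
        hits_at_10=hits_at_k(ranks, 10),
        auc_pr=auc_pr(pooled_scores, pooled_labels),
        n_queries=len(queries),
        n_candidates_per_query=n_candidates,
        seed=seed,
    )
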