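"""Layer operations: kernel, global/local channels, fusion, scoring."""

import numpy as np
import pytest

from krgai.autodiff import Tensor
from krgai.kg_core import KnowledgeGraph, Triple, Vocab
from krgai.model import (
    GraphCache,
    ModelConfig,
    forward,
    forward_batch,
    fuse,
    get_mac_count,
    global_head,
    global_module,
    init_node_states,
    init_params,
    kernel_phi,
    load_checkpoint,
    local_module,
    message,
    relation_update,
    reset_mac_count,
    save_checkpoint,
    score_triple,
)

from conftest import build_graph, random_graph

rng = np.random.default_rng(11)


def quadratic_attention_oracle(E, WQ, WK, WV):
    """The explicit |E| x |E| computation (phi(Q) phi(K)^T) V."""
    def phi(x):
        return np.where(x > 0, x, np.exp(x) - 1.0) + 1.0

    Q, K, V = E @ WQ, E @ WK, E @ WV
    return (phi(Q) @ phi(K).T) @ V


# ---------------------------------------------------------------------------
# config and kernel
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(dim=30, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(n_total_layers=7)
    with pytest.raises(ValueError):
        ModelConfig(kernel="softmax")
    # degenerate all-base allocation is allowed (depth-allocation experiments)
    ModelConfig(n_total_layers=3, n_base_gnn_layers=3)


def test_kernel_phi_values():
    x = Tensor(np.array([0.0, 2.0, -20.0]))
    out = kernel_phi(x).data
    assert out[0] == pytest.approx(1.0)
    assert out[1] == pytest.approx(3.0)
    assert out[2] == pytest.approx(np.exp(-20.0), rel=1e-12)


def test_kernel_phi_positive_on_grid():
    x = np.linspace(-50, 50, 2001)
    assert (kernel_phi(Tensor(x)).data > 0).all()


# ---------------------------------------------------------------------------
# global channel
# ---------------------------------------------------------------------------

def test_global_head_zero_states_give_zero():
    W = [Tensor(rng.normal(size=(6, 3))) for _ in range(3)]
    out = global_head(Tensor(np.zeros((5, 6))), *W)
    assert np.allclose(out.data, 0.0)


def test_global_head_single_entity_closed_form():
    e = rng.normal(size=(1, 4))
    WQ, WK, WV = (Tensor(rng.normal(size=(4, 2))) for _ in range(3))
    out = global_head(Tensor(e), WQ, WK, WV)
    phi = lambda x: np.where(x > 0, x, np.exp(x) - 1) + 1
    q, k, v = e @ WQ.data, e @ WK.data, e @ WV.data
    expected = (phi(q) @ phi(k).T).item() * v
    assert np.allclose(out.data, expected, atol=1e-12)


def test_global_head_matches_quadratic_oracle():
    E = rng.normal(size=(5, 8))
    WQ, WK, WV = (rng.normal(size=(8, 4)) for _ in range(3))
    out = global_head(Tensor(E), Tensor(WQ), Tensor(WK), Tensor(WV))
    assert np.allclose(
        out.data, quadratic_attention_oracle(E, WQ, WK, WV), atol=1e-6
    )


def test_global_module_single_head_is_projected_head():
    cfg = ModelConfig(dim=8, n_heads=1, n_total_layers=1, n_base_gnn_layers=0)
    params = init_params(2, cfg)
    E = Tensor(rng.normal(size=(6, 8)))
    out = global_module(E, params, 0, cfg)
    head = global_head(
        E, params["L0.WQ0"], params["L0.WK0"], params["L0.WV0"]
    )
    assert np.allclose(out.data, head.data @ params["L0.Wm"].data, atol=1e-12)


def test_global_module_head_order_symmetric():
    cfg = ModelConfig(dim=8, n_heads=2, n_total_layers=1, n_base_gnn_layers=0)
    params = init_params(2, cfg)
    # make both heads share parameters: permuting head order is then a no-op
    for w in ("WQ", "WK", "WV"):
        params[f"L0.{w}1"] = Tensor(params[f"L0.{w}0"].data.copy())
    E = Tensor(rng.normal(size=(5, 8)))
    out1 = global_module(E, params, 0, cfg)
    swapped = dict(params)
    for w in ("WQ", "WK", "WV"):
        swapped[f"L0.{w}0"], swapped[f"L0.{w}1"] = (
            params[f"L0.{w}1"], params[f"L0.{w}0"],
        )
    out2 = global_module(E, swapped, 0, cfg)
    assert np.allclose(out1.data, out2.data)


def test_global_mac_count_scales_linearly():
    cfg = ModelConfig(dim=16, n_heads=4, n_total_layers=1, n_base_gnn_layers=0)
    params = init_params(2, cfg)
    counts = []
    for n in (64, 128):
        reset_mac_count()
        global_module(Tensor(rng.normal(size=(n, 16))), params, 0, cfg)
        counts.append(get_mac_count())
    assert counts[1] / counts[0] <= 2.2


# ---------------------------------------------------------------------------
# local channel
# ---------------------------------------------------------------------------

def graph_two_neighbors():
    # u=0 receives from tails v1=1 and v2=2 via relation 0
    vocab = Vocab(entity_labels=["u", "v1", "v2"], relation_labels=["r"])
    return KnowledgeGraph(
        vocab=vocab, triples={Triple(0, 0, 1), Triple(0, 0, 2)}
    )


def test_message_forms():
    E = Tensor(np.array([[0.0, 0.0], [1.0, 0.0]]))
    R = Tensor(np.array([[0.0, 1.0]]))
    Wid = Tensor(np.eye(2))
    assert np.allclose(
        message(0, 0, 1, E, R, Wid).data, np.array([1.0, 1.0])
    )
    zeroE = Tensor(np.zeros((2, 2)))
    zeroR = Tensor(np.zeros((1, 2)))
    assert np.allclose(message(0, 0, 1, zeroE, zeroR, Wid).data, 0.0)
    Wdiag = Tensor(np.array([[2.0, 0.0], [0.0, 3.0]]))
    E2 = Tensor(np.array([[0.0, 0.0], [1.0, 0.0]]))
    R2 = Tensor(np.array([[0.0, 1.0]]))
    assert np.allclose(message(0, 0, 1, E2, R2, Wdiag).data, np.array([2.0, 3.0]))


def test_local_single_neighbor_passes_message_through():
    g = build_graph([("u", "r", "v")])
    cache = GraphCache(g, inverse=False)
    E = Tensor(rng.normal(size=(2, 3)))
    R = Tensor(rng.normal(size=(1, 3)))
    Wphi = Tensor(rng.normal(size=(3, 3)))
    Watt = Tensor(rng.normal(size=3))
    out = local_module(E, R, cache, Wphi, Watt)
    expected = (E.data[1] + R.data[0]) @ Wphi.data.T
    assert np.allclose(out.data[0], expected, atol=1e-12)
    assert np.allclose(out.data[1], 0.0)  # isolated under forward-only edges


def test_local_identical_messages_average_equally():
    g = graph_two_neighbors()
    cache = GraphCache(g, inverse=False)
    E = np.zeros((3, 2))
    E[1] = E[2] = [1.0, -2.0]  # identical tail states -> identical messages
    out = local_module(
        Tensor(E), Tensor(np.zeros((1, 2))), cache,
        Tensor(np.eye(2)), Tensor(rng.normal(size=2)),
    )
    assert np.allclose(out.data[0], [1.0, -2.0], atol=1e-12)


def test_local_attention_hand_softmax():
    """gamma = (ln 2, 0) must give beta = (2/3, 1/3)."""
    g = graph_two_neighbors()
    cache = GraphCache(g, inverse=False)
    E = np.zeros((3, 2))
    E[1] = [np.log(2.0), 5.0]
    E[2] = [0.0, 7.0]
    out = local_module(
        Tensor(E), Tensor(np.zeros((1, 2))), cache,
        Tensor(np.eye(2)), Tensor(np.array([1.0, 0.0])),
    )
    expected = (2 / 3) * E[1] + (1 / 3) * E[2]
    assert np.allclose(out.data[0], expected, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def test_fuse_identical_branches_reproduce_input():
    e = Tensor(rng.normal(size=(4, 6)))
    w = Tensor(rng.normal(size=6))
    out = fuse(e, e, e, w, mode="attention")
    assert np.allclose(out.data, e.data, atol=1e-12)


def test_fuse_zero_weight_vector_gives_uniform_alphas():
    es = [Tensor(rng.normal(size=(3, 4))) for _ in range(3)]
    out = fuse(es[0], es[1], es[2], Tensor(np.zeros(4)), mode="attention")
    expected = (es[0].data + es[1].data + es[2].data) / 3
    assert np.allclose(out.data, expected, atol=1e-12)


def test_fuse_hand_softmax_alphas():
    """Branch scores (ln 2, 0, 0) -> alpha = (1/2, 1/4, 1/4)."""
    w = Tensor(np.array([1.0]))
    e_self = Tensor(np.array([[np.log(2.0)]]))
    zero = Tensor(np.array([[0.0]]))
    out = fuse(e_self, zero, zero, w, mode="attention")
    assert out.data[0, 0] == pytest.approx(0.5 * np.log(2.0))


def test_fuse_ablation_renormalizes():
    e_self, e_g, e_l = (Tensor(rng.normal(size=(2, 3))) for _ in range(3))
    w = Tensor(np.zeros(3))
    out = fuse(e_self, e_g, e_l, w, mode="attention", ablate_global=True)
    assert np.allclose(out.data, (e_self.data + e_l.data) / 2, atol=1e-12)


def test_fuse_sum_and_concat_modes():
    e_self, e_g, e_l = (Tensor(rng.normal(size=(2, 3))) for _ in range(3))
    w = Tensor(rng.normal(size=3))
    assert np.allclose(
        fuse(e_self, e_g, e_l, w, mode="sum").data,
        e_self.data + e_g.data + e_l.data,
    )
    Wcat = Tensor(rng.normal(size=(9, 3)))
    out = fuse(e_self, e_g, e_l, w, mode="concat", Wcat=Wcat)
    expected = np.concatenate(
        [e_self.data, e_g.data, e_l.data], axis=-1
    ) @ Wcat.data
    assert np.allclose(out.data, expected)


# ---------------------------------------------------------------------------
# relation update, init, forward
# ---------------------------------------------------------------------------

def test_relation_update_linear_map():
    R = Tensor(np.array([[1.0, 2.0]]))
    params = {"L0.Wrel": Tensor(np.array([[0.0, 1.0], [1.0, 0.0]]))}
    assert np.allclose(relation_update(R, params, 0).data, [[2.0, 1.0]])
    params_id = {"L0.Wrel": Tensor(np.eye(2))}
    assert np.allclose(relation_update(R, params_id, 0).data, R.data)
    zero = Tensor(np.zeros((3, 2)))
    assert np.allclose(relation_update(zero, params, 0).data, 0.0)


def test_relation_update_layer_independent_table():
    params = {"L1.rel_table": Tensor(rng.normal(size=(4, 2)))}
    R = Tensor(rng.normal(size=(4, 2)))
    out = relation_update(R, params, 0, layer_independent=True)
    assert out is params["L1.rel_table"]


def test_init_node_states_single_nonzero_row():
    g = build_graph([("a", "r", "b"), ("b", "s", "c")])
    R = Tensor(rng.normal(size=(4, 5)))
    states = init_node_states(g, (1, 0), R)
    assert np.allclose(states.data[1], R.data[0])
    assert np.allclose(np.delete(states.data, 1, axis=0), 0.0)
    zero = init_node_states(g, (0, 0), Tensor(np.zeros((4, 5))))
    assert np.allclose(zero.data, 0.0)
    with pytest.raises(IndexError):
        init_node_states(g, (99, 0), R)


def test_forward_matches_manual_layer_chain(rng=np.random.default_rng(3)):
    """Composing forward == chaining the per-layer ops by hand."""
    g = random_graph(rng, n_entities=6, n_relations=2, n_triples=8)
    cfg = ModelConfig(
        dim=8, n_heads=2, n_total_layers=3, n_base_gnn_layers=1, seed=3
    )
    params = init_params(g.n_relations, cfg)
    cache = GraphCache(g)
    E_fwd, R_fwd = forward(g, (0, 1), params, cfg)

    R = params["rel_embed"]
    E = init_node_states(g, (0, 1), R)
    for i in range(3):
        Wphi, Watt = params[f"L{i}.Wphi"], params[f"L{i}.Watt"]
        if i < 1:
            E = local_module(E, R, cache, Wphi, Watt)
        else:
            eg = global_module(E, params, i, cfg)
            el = local_module(E, R, cache, Wphi, Watt)
            E = fuse(E, eg, el, params[f"L{i}.wfuse"], mode="attention")
        if i < 2:
            R = relation_update(R, params, i)
    assert np.abs(E_fwd.data - E.data).max() < 1e-6
    assert np.abs(R_fwd.data - R.data).max() < 1e-6


def test_forward_ablate_global_equals_local_only_model():
    g = random_graph(np.random.default_rng(4), n_entities=7, n_triples=10)
    cfg = ModelConfig(dim=8, n_heads=2, n_total_layers=2, n_base_gnn_layers=0,
                      ablate_global=True, seed=1)
    params = init_params(g.n_relations, cfg)
    E1, _ = forward(g, (2, 0), params, cfg)
    # manual local-only chain (no global branch at all)
    R = params["rel_embed"]
    E = init_node_states(g, (2, 0), R)
    cache = GraphCache(g)
    for i in range(2):
        el = local_module(E, R, cache, params[f"L{i}.Wphi"], params[f"L{i}.Watt"])
        E = fuse(E, None, el, params[f"L{i}.wfuse"], mode="attention")
        if i < 1:
            R = relation_update(R, params, i)
    assert np.allclose(E1.data, E.data, atol=1e-12)


def test_forward_zero_parameters_give_zero_states():
    g = build_graph([("a", "r", "b"), ("b", "r", "c")])
    cfg = ModelConfig(dim=4, n_heads=1, n_total_layers=1, n_base_gnn_layers=0)
    params = init_params(g.n_relations, cfg)
    for k, p in params.items():
        if not k.startswith("scorer"):
            p.data[...] = 0.0
    E, _ = forward(g, (0, 0), params, cfg)
    assert np.allclose(E.data, 0.0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def zero_scorer(d):
    return {
        "scorer.W1": Tensor(np.zeros((3 * d, 64))),
        "scorer.b1": Tensor(np.zeros(64)),
        "scorer.W2": Tensor(np.zeros((64, 1))),
        "scorer.b2": Tensor(np.zeros(1)),
    }


def test_score_zero_weights_is_half():
    d = 4
    p = zero_scorer(d)
    out = score_triple(
        Tensor(rng.normal(size=d)), Tensor(rng.normal(size=d)),
        Tensor(rng.normal(size=d)), p,
    )
    assert out.data == pytest.approx(0.5)


def test_score_strictly_in_unit_interval():
    d = 4
    cfg = ModelConfig(dim=d, n_heads=1)
    p = init_params(2, cfg)
    for _ in range(50):
        out = score_triple(
            Tensor(rng.normal(size=d) * 10), Tensor(rng.normal(size=d) * 10),
            Tensor(rng.normal(size=d) * 10), p,
        ).data
        assert 0.0 < out < 1.0


def test_score_hand_case_sigmoid_ln3():
    """Pre-activation ln 3 must give probability 3/4."""
    d = 1
    p = zero_scorer(d)
    p["scorer.b1"] = Tensor(np.r_[np.log(3.0), np.zeros(63)])
    W2 = np.zeros((64, 1))
    W2[0, 0] = 1.0
    p["scorer.W2"] = Tensor(W2)
    out = score_triple(
        Tensor(np.zeros(d)), Tensor(np.zeros(d)), Tensor(np.zeros(d)), p
    )
    assert out.data == pytest.approx(0.75)


def test_scoring_invariant_under_entity_relabeling():
    g = random_graph(np.random.default_rng(5), n_entities=12, n_triples=18)
    cfg = ModelConfig(dim=8, n_heads=2, n_total_layers=3, n_base_gnn_layers=1,
                      seed=5)
    params = init_params(g.n_relations, cfg)
    perm = np.random.default_rng(6).permutation(g.n_entities)
    g2 = KnowledgeGraph(
        vocab=g.vocab,
        triples={Triple(int(perm[h]), r, int(perm[t])) for h, r, t in g.triples},
    )
    head, rel, tail = 3, 1, 7
    E1, R1 = forward(g, (head, rel), params, cfg)
    E2, R2 = forward(g2, (int(perm[head]), rel), params, cfg)
    p1 = score_triple(
        E1.take(np.asarray([head]), 0).reshape(-1),
        R1.take(np.asarray([rel]), 0).reshape(-1),
        E1.take(np.asarray([tail]), 0).reshape(-1), params,
    ).data
    p2 = score_triple(
        E2.take(np.asarray([int(perm[head])]), 0).reshape(-1),
        R2.take(np.asarray([rel]), 0).reshape(-1),
        E2.take(np.asarray([int(perm[tail])]), 0).reshape(-1), params,
    ).data
    assert abs(p1 - p2) <= 1e-9


def test_batched_forward_matches_single(rng=np.random.default_rng(9)):
    g = random_graph(rng, n_entities=9, n_triples=14)
    cfg = ModelConfig(dim=8, n_heads=2, n_total_layers=2, n_base_gnn_layers=1,
                      normalize_global=True, seed=2)
    params = init_params(g.n_relations, cfg)
    queries = [(0, 1), (3, 0), (5, 2)]
    EB, _ = forward_batch(g, queries, params, cfg)
    for b, q in enumerate(queries):
        E1, _ = forward(g, q, params, cfg)
        assert np.abs(EB.data[b] - E1.data).max() < 1e-10


def test_checkpoint_roundtrip(tmp_path):
    cfg = ModelConfig(dim=8, n_heads=2, seed=3)
    params = init_params(3, cfg)
    path = save_checkpoint(params, cfg, tmp_path / "ck.npz",
                           relation_labels=["a", "b", "c"])
    params2, cfg2, rels = load_checkpoint(path)
    assert cfg2 == cfg
    assert rels == ["a", "b", "c"]
    assert set(params2) == set(params)
    for k in params:
        assert np.array_equal(params[k].data, params2[k].data)


def test_relation_embedding_import(tmp_path):
    from krgai.model import read_relation_embeddings

    p = tmp_path / "rel.tsv"
    p.write_text("# pre-trained vectors\nr0\t1.0,2.0\nr1\t3.0,4.0\nextra\t9,9\n")
    table = read_relation_embeddings(p, ["r1", "r0"], 2)
    assert np.allclose(table, [[3.0, 4.0], [1.0, 2.0]])
    with pytest.raises(ValueError, match="missing"):
        read_relation_embeddings(p, ["r2"], 2)
    bad = tmp_path / "bad.tsv"
    bad.write_text("r0\t1.0\n")
    with pytest.raises(ValueError, match="expected 2"):
        read_relation_embeddings(bad, ["r0"], 2)
    cfg = ModelConfig(dim=2, n_heads=1)
    params = init_params(2, cfg, rel_embeddings=table)
    assert np.allclose(params["rel_embed"].data[:2], table)
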