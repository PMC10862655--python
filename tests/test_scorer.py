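"""Path-attention scorer contracts: shapes, attention, invariances and
gradient correctness."""

import numpy as np
import pytest

from targetpath.errors import InputError, KGLookupError, ShapeError
from targetpath.graph import Edge, KnowledgeGraph, Node
from targetpath.metapath import parse_metapath
from targetpath.pathing import enumerate_paths
from targetpath.quate import QuaternionEmbeddingSet
from targetpath.scorer import (PairScorer, ScorerConfig, ScorerParams,
                               attention_merge, encode_path, forward, predict)


def _embeddings(node_ids, k=2, seed=0):
    rng = np.random.default_rng(seed)
    return QuaternionEmbeddingSet(
        entity_ids=tuple(sorted(node_ids)),
        entities=rng.normal(size=(len(node_ids), k, 4)),
        relation_codes=("asw", "ppi"),
        relations=rng.normal(size=(2, k, 4)))


@pytest.fixture()
def toy_setup(schema):
    nodes = [Node("D1", "DI"), Node("G1", "GE"), Node("G2", "GE"),
             Node("G3", "GE")]
    edges = [Edge("D1", "asw", "G1"), Edge("G1", "ppi", "G2")]
    kg = KnowledgeGraph(schema, nodes, edges)
    emb = _embeddings([n.id for n in nodes])
    mp = parse_metapath("DI = asw = GE = ppi = GE", schema)
    cfg = ScorerConfig(input_dim=emb.dim, n_metapaths=1, channels=6,
                       mp_dim=3, attn_hidden=5, head_hidden=(7, 4), seed=3)
    params = ScorerParams.init(cfg)
    return kg, emb, mp, cfg, params


def test_encode_path_shape_and_determinism(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    p = enumerate_paths(kg, "D1", "G2", mp)[0]
    v1 = encode_path(p, emb, params)
    v2 = encode_path(p, emb, params)
    assert v1.shape == (cfg.channels,)
    assert np.isfinite(v1).all()
    assert np.array_equal(v1, v2)


def test_encode_path_zero_embeddings_gives_zero_vector(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    zero_emb = QuaternionEmbeddingSet(
        entity_ids=emb.entity_ids,
        entities=np.zeros_like(emb.entities),
        relation_codes=emb.relation_codes,
        relations=emb.relations)
    for t in params.tensors.values():
        t.data[:] = np.abs(t.data)   # keep weights, zero only biases below
    params["conv_b"].data[:] = 0.0
    p = enumerate_paths(kg, "D1", "G2", mp)[0]
    assert np.allclose(encode_path(p, zero_emb, params), 0.0)


def test_encode_path_missing_embedding(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    few = QuaternionEmbeddingSet(entity_ids=("D1",),
                                 entities=emb.entities[:1],
                                 relation_codes=emb.relation_codes,
                                 relations=emb.relations)
    p = enumerate_paths(kg, "D1", "G2", mp)[0]
    with pytest.raises(KGLookupError):
        encode_path(p, few, params)


def test_attention_singleton_and_symmetry(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    q = emb.node_vector("D1")
    t = emb.node_vector("G2")
    pv = np.random.default_rng(1).normal(size=(1, cfg.channels))
    _f, w = attention_merge(pv, np.array([0]), q, t, params)
    assert w.shape == (1,) and w[0] == pytest.approx(1.0)
    # two identical paths split the weight evenly
    pv2 = np.vstack([pv, pv])
    _f2, w2 = attention_merge(pv2, np.array([0, 0]), q, t, params)
    assert np.allclose(w2, [0.5, 0.5])


def test_attention_permutation_equivariance(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    rng = np.random.default_rng(2)
    q, t = emb.node_vector("D1"), emb.node_vector("G2")
    pv = rng.normal(size=(5, cfg.channels))
    ids = np.array([0, 0, 0, 0, 0])
    f1, w1 = attention_merge(pv, ids, q, t, params)
    perm = rng.permutation(5)
    f2, w2 = attention_merge(pv[perm], ids[perm], q, t, params)
    assert np.allclose(w2, w1[perm], atol=1e-9)
    assert np.allclose(f1, f2, atol=1e-6)
    assert w1.sum() == pytest.approx(1.0, abs=1e-9)
    assert (w1 >= 0).all()


def test_attention_errors_and_empty(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    q, t = emb.node_vector("D1"), emb.node_vector("G2")
    with pytest.raises(InputError):
        attention_merge(np.zeros((2, cfg.channels)), np.array([0]), q, t,
                        params)
    f, w = attention_merge(np.zeros((0, cfg.channels)), np.array([], dtype=int),
                           q, t, params)
    assert w.size == 0
    assert np.array_equal(f, params["no_evidence"].data)


def test_predict_contracts(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    q, t = emb.node_vector("D1"), emb.node_vector("G2")
    f = np.random.default_rng(3).normal(size=cfg.channels)
    s1 = predict(q, t, f, params)
    assert s1 == predict(q, t, f, params)
    with pytest.raises(ShapeError):
        predict(q[:-1], t, f, params)
    # all-zero parameters: score equals the final bias
    for tensor in params.tensors.values():
        tensor.data[:] = 0.0
    params["head_b3"].data[:] = 0.77
    assert predict(q, t, f, params) == pytest.approx(0.77)


def test_predict_sensitive_to_feature(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    q, t = emb.node_vector("D1"), emb.node_vector("G2")
    rng = np.random.default_rng(4)
    f1 = rng.normal(size=cfg.channels)
    f2 = rng.normal(size=cfg.channels)
    assert predict(q, t, f1, params) != predict(q, t, f2, params)


def test_forward_with_and_without_paths(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    sp = forward(kg, emb, [mp], cfg, params, "D1", "G2")
    assert len(sp.paths) == 1
    assert sp.attention.shape == (1,)
    assert sp.attention[0] == pytest.approx(1.0)
    assert np.isfinite(sp.score)
    # G3 has no paths at all: scored via the no-evidence vector
    sp3 = forward(kg, emb, [mp], cfg, params, "D1", "G3")
    assert sp3.paths == [] and sp3.attention.size == 0
    assert np.isfinite(sp3.score)
    # reproducible
    assert forward(kg, emb, [mp], cfg, params, "D1", "G2").score == sp.score


def test_score_invariant_to_path_order(toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    kg.add_edge(Edge("G1", "ppi", "G3"))
    kg.add_edge(Edge("D1", "asw", "G3"))
    kg.add_edge(Edge("G3", "ppi", "G2"))
    scorer = PairScorer(kg, emb, [mp], cfg, params)
    entries = scorer.entries("D1", "G2")
    assert len(entries) >= 2
    s1 = scorer.score("D1", "G2")
    scorer.cache._per_disease["D1"]["G2"] = list(reversed(entries))
    s2 = scorer.score("D1", "G2")
    assert s1 == pytest.approx(s2, abs=1e-6)


def test_full_forward_gradient_check(toy_setup):
    """Analytic gradients of a hinge loss through the full forward pass
    match central finite differences."""
    kg, emb, mp, cfg, params = toy_setup
    scorer = PairScorer(kg, emb, [mp], cfg, params)

    def loss_value():
        s_pos, _, _ = scorer.score_t("D1", "G2")
        s_neg, _, _ = scorer.score_t("D1", "G3")
        return (s_neg - s_pos + 1.0).relu()

    out = loss_value()
    assert out.item() > 0  # hinge active so gradients flow
    for p in params.parameters():
        p.grad = None
    out.backward()
    eps = 1e-6
    rng = np.random.default_rng(0)
    for name in sorted(params.tensors):
        tensor = params.tensors[name]
        if tensor.grad is None:
            continue
        flat = tensor.data.reshape(-1)
        gflat = tensor.grad.reshape(-1)
        idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            fp = loss_value().item()
            flat[i] = orig - eps
            fm = loss_value().item()
            flat[i] = orig
            num = (fp - fm) / (2 * eps)
            assert num == pytest.approx(gflat[i], rel=1e-4, abs=1e-7), name


def test_params_save_load(tmp_path, toy_setup):
    kg, emb, mp, cfg, params = toy_setup
    params.save(tmp_path / "p.npz", tmp_path / "cfg.json")
    loaded = ScorerParams.load(tmp_path / "p.npz",
                               config_path=tmp_path / "cfg.json")
    assert loaded.config == cfg
    for k in params.tensors:
        assert np.array_equal(loaded[k].data, params[k].data)
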