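"""Path enumeration, scoring, top-k and catalogue selection."""

import networkx as nx
import numpy as np
import pytest

from targetpath.errors import ConfigError, InputError
from targetpath.graph import Edge, KnowledgeGraph, Node
from targetpath.metapath import Metapath, parse_metapath
from targetpath.pathing import (PathScoreConfig, candidate_metapaths, enumerate_paths,
                                path_score, paths_from_source,
                                select_metapaths, top_k_paths)
from targetpath.schema import Metaedge, Schema
from targetpath.synthetic import generate

from conftest import small_config


def test_candidate_metapaths_restricted_schema():
    schema = Schema(metanodes=frozenset({"DI", "GE"}),
                    metaedges=(Metaedge("asw", "associated", "DI", "GE",
                                        causal_capable=True),
                               Metaedge("ppi", "PPI", "GE", "GE")))
    got = {mp.id for mp in candidate_metapaths(schema, max_len=2)}
    assert got == {"DI = asw = GE", "DI = asw = GE = ppi = GE"}


def test_candidate_metapaths_len1_full_schema(schema):
    got = {mp.id for mp in candidate_metapaths(schema, max_len=1)}
    # the direct disease-gene metaedges in the bundled schema
    assert got == {"DI = asw = GE", "DI = uri = GE", "DI = dri = GE"}


def test_candidate_metapaths_edge_cases(schema):
    with pytest.raises(ConfigError):
        candidate_metapaths(schema, max_len=0)
    empty = Schema(metanodes=frozenset({"DI", "GE"}), metaedges=())
    assert candidate_metapaths(empty, max_len=3) == []


def test_enumerate_toy_graph(schema):
    nodes = [Node("D1", "DI"), Node("G1", "GE"), Node("G2", "GE")]
    edges = [Edge("D1", "asw", "G1"), Edge("G1", "ppi", "G2")]
    kg = KnowledgeGraph(schema, nodes, edges)
    mp = parse_metapath("DI = asw = GE = ppi = GE", schema)
    paths = enumerate_paths(kg, "D1", "G2", mp)
    assert len(paths) == 1
    assert paths[0].node_ids == ("D1", "G1", "G2")
    # no instantiation
    assert enumerate_paths(kg, "D1", "G1", mp) == []
    # type-mismatched endpoint
    with pytest.raises(InputError):
        enumerate_paths(kg, "G1", "G2", mp)


def _random_typed_graph(seed):
    rng = np.random.default_rng(seed)
    schema = Schema(
        metanodes=frozenset({"DI", "GE", "CO"}),
        metaedges=(Metaedge("asw", "associated", "DI", "GE",
                            causal_capable=True),
                   Metaedge("ppi", "PPI", "GE", "GE"),
                   Metaedge("trt", "treats", "CO", "DI"),
                   Metaedge("bin", "binds_to", "CO", "GE"),
                   Metaedge("pdi", "PDI", "GE", "GE", directed=True)))
    nodes = ([Node(f"D{i}", "DI") for i in range(3)]
             + [Node(f"G{i}", "GE") for i in range(10)]
             + [Node(f"C{i}", "CO") for i in range(4)])
    ids = {n.id: n.metanode for n in nodes}
    all_ids = list(ids)
    edges = {}
    for me in schema.metaedges:
        heads = [n for n in all_ids if ids[n] == me.head_type]
        tails = [n for n in all_ids if ids[n] == me.tail_type]
        for _ in range(rng.integers(3, 12)):
            h = heads[rng.integers(len(heads))]
            t = tails[rng.integers(len(tails))]
            if h != t:
                edges[(h, me.code, t)] = Edge(h, me.code, t)
    return schema, KnowledgeGraph(schema, nodes, list(edges.values()))


def _nx_oracle(kg, query, target, mp):
    """Brute force: all simple paths in an untyped multigraph view, then
    filter by metapath instantiation."""
    g = nx.Graph()
    g.add_nodes_from(kg.nodes)
    for e in kg.edges:
        g.add_edge(e.head, e.tail)
    triples = {e.triple for e in kg.edges}
    found = set()
    for nodes in nx.all_simple_paths(g, query, target, cutoff=len(mp)):
        if len(nodes) != len(mp) + 1:
            continue
        if any(kg.node(n).metanode != t for n, t in zip(nodes, mp.node_types)):
            continue
        ok = True
        for (code, orient), u, v in zip(mp.steps, nodes[:-1], nodes[1:]):
            if kg.schema.metaedge(code).directed:
                want = (u, code, v) if orient == "forward" else (v, code, u)
                ok = want in triples
            else:
                ok = kg.find_edge(u, code, v) is not None
            if not ok:
                break
        if ok:
            found.add(tuple(nodes))
    return found


@pytest.mark.parametrize("seed", range(10))
def test_enumeration_matches_bruteforce_oracle(seed):
    schema, kg = _random_typed_graph(seed)
    mps = [parse_metapath(s, schema) for s in (
        "DI = asw = GE",
        "DI = asw = GE = ppi = GE",
        "DI = asw = GE > pdi > GE",
        "DI = asw = GE < pdi < GE",
        "DI = trt = CO = bin = GE = ppi = GE",
    )]
    diseases = kg.nodes_of_type("DI")
    genes = kg.nodes_of_type("GE")
    for mp in mps:
        for d in diseases:
            grouped = paths_from_source(kg, d, mp)
            for g in genes:
                got = {p.node_ids for p in enumerate_paths(kg, d, g, mp)}
                assert got == _nx_oracle(kg, d, g, mp)
                assert got == set(map(tuple, grouped.get(g, [])))


def test_path_scores(schema):
    nodes = [Node("D1", "DI"), Node("G1", "GE"), Node("G2", "GE")]
    edges = [Edge("D1", "asw", "G1"), Edge("G1", "ppi", "G2")]
    kg = KnowledgeGraph(schema, nodes, edges)
    mp = parse_metapath("DI = asw = GE = ppi = GE", schema)
    p = enumerate_paths(kg, "D1", "G2", mp)[0]
    # all step-degrees are 1
    assert path_score(p, kg, PathScoreConfig(damping=0.4)) == 1.0
    assert path_score(p, kg, PathScoreConfig(damping=0.0)) == 1.0
    with pytest.raises(ConfigError):
        path_score(p, kg, PathScoreConfig(method="nope"))


def test_degree_damped_arithmetic(schema):
    nodes = [Node("D1", "DI"), Node("G1", "GE"), Node("G2", "GE"),
             Node("G3", "GE")]
    edges = [Edge("D1", "asw", "G1"), Edge("G1", "ppi", "G2"),
             Edge("G1", "ppi", "G3"), Edge("G2", "ppi", "G3")]
    kg = KnowledgeGraph(schema, nodes, edges)
    mp = parse_metapath("DI = asw = GE = ppi = GE", schema)
    p = enumerate_paths(kg, "D1", "G2", mp)[0]
    # asw step degrees (1,1); ppi step degrees (2,2) -> (2*2)^(-0.5) = 0.5
    assert path_score(p, kg, PathScoreConfig(damping=0.5)) == pytest.approx(0.5)
    # damping monotonicity: higher-degree steps score lower for w > 0
    s_low = path_score(p, kg, PathScoreConfig(damping=0.4))
    kg2 = KnowledgeGraph(schema, nodes + [Node("G4", "GE")],
                         edges + [Edge("G2", "ppi", "G4")])
    p2 = enumerate_paths(kg2, "D1", "G2", mp)[0]
    assert path_score(p2, kg2, PathScoreConfig(damping=0.4)) < s_low


def test_top_k_paths(schema):
    mp = parse_metapath("DI = asw = GE", schema)

    def mk(nodes, score):
        from targetpath.pathing import Path
        return Path(node_ids=nodes, edges=(), metapath=mp, score=score)

    paths = [mk(("D1", "G3"), 0.1), mk(("D1", "G1"), 0.9), mk(("D1", "G2"), 0.5)]
    assert [p.score for p in top_k_paths(paths, 5)] == [0.9, 0.5, 0.1]
    assert [p.score for p in top_k_paths(paths, 2)] == [0.9, 0.5]
    ties = [mk(("D1", "G2"), 0.5), mk(("D1", "G1"), 0.5)]
    assert [p.node_ids for p in top_k_paths(ties, 2)] == \
        [("D1", "G1"), ("D1", "G2")]
    with pytest.raises(ConfigError):
        top_k_paths(paths, 0)


def test_select_metapaths_planted_recovery():
    cfg = small_config(seed=17)
    cfg.support_templates = ("DI = asw = GE = ppi = GE",)
    cfg.noise_rate = 0.0
    kg, truth = generate(cfg)
    candidates = [parse_metapath(s, kg.schema) for s in (
        "DI = asw = GE = ppi = GE",
        "DI = trt = CO = trt = DI = uri = GE",
        "DI = mnw = DI = asw = GE",
    )]
    pos = [(d, g) for d in truth.diseases for g in truth.causal[d]]
    cat = select_metapaths(kg, pos, candidates, max_count=3, seed=5)
    rel = dict(zip(cat.stats.metapath, cat.stats.relevance))
    assert rel["DI = asw = GE = ppi = GE"] > 0.9
    assert 0.4 <= rel["DI = trt = CO = trt = DI = uri = GE"] <= 0.6


def test_select_metapaths_rejects_duplicates(small_synthetic):
    kg, truth = small_synthetic
    mp = parse_metapath("DI = asw = GE = ppi = GE", kg.schema)
    other = parse_metapath("DI = mnw = DI = asw = GE", kg.schema)
    pos = [(d, g) for d in truth.diseases for g in truth.causal[d]]
    cat = select_metapaths(kg, pos, [mp, mp, other], max_count=5, seed=1)
    assert cat.ids().count(mp.id) == 1
    dup_rows = cat.stats[cat.stats.metapath == mp.id]
    assert dup_rows.accepted.sum() == 1
    assert (dup_rows.redundant_with == mp.id).sum() == 1
    # max_count=1 keeps only the single most relevant metapath
    cat1 = select_metapaths(kg, pos, [mp, other], max_count=1, seed=1)
    assert cat1.ids() == [mp.id]


def test_select_metapaths_input_errors(small_synthetic):
    kg, truth = small_synthetic
    mp = parse_metapath("DI = asw = GE = ppi = GE", kg.schema)
    with pytest.raises(InputError):
        select_metapaths(kg, [], [mp])
    with pytest.raises(InputError):
        select_metapaths(kg, [("D", "G")], [])


def test_catalogue_persistence(tmp_path, small_synthetic):
    kg, truth = small_synthetic
    mps = [parse_metapath(s, kg.schema)
           for s in ("DI = asw = GE = ppi = GE", "DI = mnw = DI = asw = GE")]
    pos = [(d, g) for d in truth.diseases for g in truth.causal[d]]
    cat = select_metapaths(kg, pos, mps, max_count=2, seed=2)
    cat.save(tmp_path / "mp.txt", tmp_path / "stats.tsv")
    from targetpath.pathing import MetapathCatalogue
    loaded = MetapathCatalogue.load(tmp_path / "mp.txt", kg.schema,
                                    tmp_path / "stats.tsv")
    assert loaded.ids() == cat.ids()
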