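"""Evidence subgraphs, secondary filters and exports."""

import json

import networkx as nx
import numpy as np
import pytest

from targetpath.errors import ConfigError, FormatError, InputError
from targetpath.evidence import (FilterCondition,
                                 build_evidence, export_evidence,
                                 filter_targets, intersect_fold_change,
                                 load_evidence, load_fold_change, top_decile)
from targetpath.graph import Edge, KnowledgeGraph, Node
from targetpath.metapath import parse_metapath
from targetpath.pathing import build_path
from targetpath.scorer import ScoredPair


@pytest.fixture()
def hub_kg(schema):
    """Two hub genes (H1, H2); targets G1, G2 interact with H1, G3 with H2,
    G4 with neither."""
    nodes = [Node("D1", "DI"), Node("H1", "GE"), Node("H2", "GE")]
    nodes += [Node(f"G{i}", "GE") for i in range(1, 5)]
    edges = [Edge("D1", "asw", "H1", causal=True), Edge("D1", "asw", "H2"),
             Edge("H1", "ppi", "G1"), Edge("H1", "ppi", "G2"),
             Edge("H2", "ppi", "G3"), Edge("D1", "asw", "G4")]
    return KnowledgeGraph(schema, nodes, edges)


def _scored_pair(kg, disease, gene, via, weight_split=None):
    mp = parse_metapath("DI = asw = GE = ppi = GE", kg.schema)
    paths = [build_path(kg, mp, (disease, v, gene), score=1.0) for v in via]
    n = len(paths)
    att = np.array(weight_split if weight_split is not None
                   else [1.0 / n] * n) if n else np.zeros(0)
    return ScoredPair(query=disease, target=gene, score=1.0, attention=att,
                      paths=paths)


def test_build_evidence_union_and_weights(hub_kg):
    sp = _scored_pair(hub_kg, "D1", "G1", ["H1"])
    sg = build_evidence(sp, hub_kg)
    assert sg.union_nodes == {"D1", "H1", "G1"}
    assert sg.union_edges == {("D1", "asw", "H1"), ("G1", "ppi", "H1")}
    assert sum(w for _p, w, _s in sg.entries) == pytest.approx(1.0)
    assert sg.node_types == {"D1": "DI", "H1": "GE", "G1": "GE"}


def test_build_evidence_union_matches_set_oracle(hub_kg):
    sp = ScoredPair(
        query="D1", target="G1", score=0.5,
        attention=np.array([0.7, 0.3]),
        paths=[build_path(hub_kg,
                          parse_metapath("DI = asw = GE = ppi = GE",
                                         hub_kg.schema),
                          ("D1", "H1", "G1"), score=1.0),
               build_path(hub_kg,
                          parse_metapath("DI = asw = GE", hub_kg.schema),
                          ("D1", "G4"), score=0.5)])
    sg = build_evidence(sp, hub_kg)
    oracle_nodes = set().union(*(set(p.node_ids) for p in sp.paths))
    assert sg.union_nodes == oracle_nodes
    # entries sorted by weight descending
    assert [w for _p, w, _s in sg.entries] == [0.7, 0.3]


def test_top_decile():
    def mk(i, score):
        return ScoredPair(query="D", target=f"G{i:03d}", score=score,
                          attention=np.zeros(0))

    scored = [mk(i, float(i)) for i in range(200)]
    kept = top_decile(scored)
    assert len(kept) == 20
    assert min(sp.score for sp in kept) >= \
        max(sp.score for sp in scored if sp not in kept)
    assert len(top_decile([mk(i, 0.1 * i) for i in range(7)])) == 1
    with pytest.raises(InputError):
        top_decile([])


def test_filter_targets_hub_condition(hub_kg):
    pairs = [_scored_pair(hub_kg, "D1", g, via)
             for g, via in (("G1", ["H1"]), ("G2", ["H1"]), ("G3", ["H2"]))]
    pairs.append(_scored_pair(hub_kg, "D1", "G4", []))
    sgs = [build_evidence(sp, hub_kg) for sp in pairs]
    kept = filter_targets(sgs, [FilterCondition("contains_gene", "H1")])
    assert {sg.target for sg in kept} == {"G1", "G2"}
    either = filter_targets(sgs, [FilterCondition("contains_gene", "H1"),
                                  FilterCondition("contains_gene", "H2")],
                            mode="OR")
    assert {sg.target for sg in either} == {"G1", "G2", "G3"}
    # condition on a node absent everywhere
    assert filter_targets(sgs, [FilterCondition("contains_gene", "NOPE")]) == []
    # AND of two conditions is a subset of each single-condition result
    both = filter_targets(sgs, [FilterCondition("contains_gene", "H1"),
                                FilterCondition("contains_gene", "D1")],
                          mode="AND")
    only_h1 = filter_targets(sgs, [FilterCondition("contains_gene", "H1")])
    assert {sg.target for sg in both} <= {sg.target for sg in only_h1}


def test_filter_targets_metapath_condition(hub_kg):
    sg = build_evidence(_scored_pair(hub_kg, "D1", "G1", ["H1"]), hub_kg)
    mp_id = "DI = asw = GE = ppi = GE"
    kept = filter_targets([sg], [FilterCondition("has_metapath", mp_id)],
                          known_metapaths={mp_id})
    assert kept == [sg]
    with pytest.raises(ConfigError):
        filter_targets([sg], [FilterCondition("has_metapath", "bogus")],
                       known_metapaths={mp_id})
    with pytest.raises(ConfigError):
        FilterCondition("contains_pathway", "x")
    with pytest.raises(InputError):
        filter_targets([sg], [])


def test_intersect_fold_change():
    fc = {"g1": 2.5, "g2": 1.8, "g3": 2.0}
    assert intersect_fold_change(["g1", "g2", "g3"], fc, 2.0, "up") == ["g1"]
    # gene missing from the table is dropped
    assert intersect_fold_change(["g1", "gX"], fc, 2.0, "up") == ["g1"]
    # reciprocal rule for direction=both
    fc2 = {"g1": 0.4, "g2": 0.6}
    assert intersect_fold_change(["g1", "g2"], fc2, 2.0, "both") == ["g1"]
    assert intersect_fold_change(["g1", "g2"], fc2, 2.0, "down") == ["g1"]
    with pytest.raises(FormatError):
        intersect_fold_change(["g1"], {"g1": "high"})
    with pytest.raises(InputError):
        intersect_fold_change(["g1"], fc, threshold=0.0)


def test_load_fold_change(tmp_path):
    p = tmp_path / "fc.tsv"
    p.write_text("gene\tfold_change\ng1\t2.5\ng2\t0.4\n")
    assert load_fold_change(p) == {"g1": 2.5, "g2": 0.4}
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\tvalue\ng1\t2.5\n")
    with pytest.raises(FormatError):
        load_fold_change(bad)


def test_export_json_round_trip(tmp_path, hub_kg):
    sg = build_evidence(_scored_pair(hub_kg, "D1", "G1", ["H1"]), hub_kg)
    p = tmp_path / "ev.json"
    export_evidence(sg, "JSON", p)
    loaded = load_evidence(p, hub_kg)
    assert loaded.query == sg.query and loaded.target == sg.target
    assert loaded.score == sg.score
    assert loaded.union_nodes == sg.union_nodes
    assert loaded.union_edges == sg.union_edges
    assert [w for _p, w, _s in loaded.entries] == \
        [w for _p, w, _s in sg.entries]


def test_export_graphml_and_empty(tmp_path, hub_kg):
    sg = build_evidence(_scored_pair(hub_kg, "D1", "G1", ["H1"]), hub_kg)
    p = tmp_path / "ev.graphml"
    export_evidence(sg, "GraphML", p)
    g = nx.read_graphml(p)
    assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
    assert g.nodes["D1"]["metanode"] == "DI"
    # empty subgraph serializes with an empty entries array
    empty = build_evidence(_scored_pair(hub_kg, "D1", "G4", []), hub_kg)
    pj = tmp_path / "empty.json"
    export_evidence(empty, "JSON", pj)
    assert json.loads(pj.read_text())["entries"] == []
    with pytest.raises(ConfigError):
        export_evidence(sg, "XML", tmp_path / "x")
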