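"""Interpretable subgraph evidence and secondary target filters.

For a scored disease-gene pair, the *evidence subgraph* is the
attention-weighted set of extracted paths together with their union graph.
Secondary triage follows the score: keep the top decile of targets, filter
evidence subgraphs by conditions ("contains a certain gene", "has a certain
metapath"), and optionally intersect with an expression fold-change table
(strictly greater than 2-fold by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx

from .errors import ConfigError, FormatError, InputError
from .graph import KnowledgeGraph
from .pathing import Path
from .scorer import ScoredPair

__all__ = ["EvidenceSubgraph", "FilterCondition", "build_evidence",
           "top_decile", "filter_targets", "intersect_fold_change",
           "export_evidence", "load_evidence", "load_fold_change",
           "EMT_CONDITION_PRESETS"]


@dataclass
class EvidenceSubgraph:
    """Attention-weighted path evidence for one disease-gene pair."""

    query: str
    target: str
    score: float
    #: (path, attention weight, path score), sorted by weight descending
    entries: list[tuple[Path, float, float]] = field(default_factory=list)
    #: node id -> metanode code for every node in the union graph
    node_types: dict[str, str] = field(default_factory=dict)

    @property
    def union_nodes(self) -> set[str]:
        return {n for p, _w, _s in self.entries for n in p.node_ids}

    @property
    def union_edges(self) -> set[tuple[str, str, str]]:
        return {e.triple for p, _w, _s in self.entries for e in p.edges}

    @property
    def metapath_ids(self) -> set[str]:
        return {p.metapath.id for p, _w, _s in self.entries}


def build_evidence(sp: ScoredPair, kg: KnowledgeGraph | None = None) -> EvidenceSubgraph:
    """Assemble the evidence subgraph of a scored pair, lossless with
    respect to its paths; entries sorted by attention weight descending."""
    entries = sorted(
        ((p, float(w), float(p.score))
         for p, w in zip(sp.paths, sp.attention)),
        key=lambda e: (-e[1], e[0].node_ids))
    node_types: dict[str, str] = {}
    if kg is not None:
        for p, _w, _s in entries:
            for n in p.node_ids:
                node_types[n] = kg.node(n).metanode
    return EvidenceSubgraph(query=sp.query, target=sp.target,
                            score=float(sp.score), entries=entries,
                            node_types=node_types)


def top_decile(scored: list[ScoredPair]) -> list[ScoredPair]:
    """Retain the ceil(10%) highest-scoring pairs, ties broken by gene id."""
    if not scored:
        raise InputError("empty scored list")
    keep = math.ceil(0.10 * len(scored))
    ranked = sorted(scored, key=lambda sp: (-sp.score, sp.target))
    return ranked[:keep]


@dataclass(frozen=True)
class FilterCondition:
    """A per-subgraph condition: the union graph contains a gene/node, or
    some evidence path instantiates a given metapath."""

    kind: str        #: contains_gene | contains_node | has_metapath
    argument: str

    def __post_init__(self) -> None:
        if self.kind not in ("contains_gene", "contains_node", "has_metapath"):
            raise ConfigError(f"unknown condition kind {self.kind!r}")

    def matches(self, sg: EvidenceSubgraph) -> bool:
        if self.kind in ("contains_gene", "contains_node"):
            return self.argument in sg.union_nodes
        return self.argument in sg.metapath_ids


#: Example condition presets for pathway-hub filtering of evidence: keep
#: targets whose evidence passes through a named hub gene (e.g. the EMT
#: regulators SNAI2 / CTNNB1 / TWIST1 / ZEB1 in a fibrosis study).
EMT_CONDITION_PRESETS = tuple(
    FilterCondition("contains_gene", g)
    for g in ("SNAI2", "CTNNB1", "TWIST1", "ZEB1")
)


def filter_targets(subgraphs: list[EvidenceSubgraph],
                   conditions: list[FilterCondition], mode: str = "OR",
                   known_metapaths: set[str] | None = None
                   ) -> list[EvidenceSubgraph]:
    """Keep subgraphs satisfying the combined conditions (set-level AND/OR).

    If *known_metapaths* is given, ``has_metapath`` arguments are validated
    against it (unknown id -> :class:`~targetpath.errors.ConfigError`).
    """
    if not conditions:
        raise InputError("conditions must be non-empty")
    if mode not in ("AND", "OR"):
        raise ConfigError(f"unknown combine mode {mode!r}")
    if known_metapaths is not None:
        for c in conditions:
            if c.kind == "has_metapath" and c.argument not in known_metapaths:
                raise ConfigError(f"unknown metapath id {c.argument!r}")
    combine = all if mode == "AND" else any
    return [sg for sg in subgraphs
            if combine(c.matches(sg) for c in conditions)]


def intersect_fold_change(targets, fc_table, threshold: float = 2.0,
                          direction: str = "up") -> list[str]:
    """Genes in *targets* whose fold change passes the strict threshold.

    ``up``: FC > threshold; ``down``: FC < 1/threshold; ``both``: either.
    Genes absent from the table are dropped.
    """
    if threshold <= 0:
        raise InputError("threshold must be > 0")
    if direction not in ("up", "down", "both"):
        raise ConfigError(f"unknown direction {direction!r}")
    try:
        table = {str(g): float(v) for g, v in dict(fc_table).items()}
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed fold-change table: {exc}") from exc
    out = []
    for g in targets:
        if g not in table:
            continue
        fc = table[g]
        up = fc > threshold
        down = fc < 1.0 / threshold
        if (direction == "up" and up) or (direction == "down" and down) \
                or (direction == "both" and (up or down)):
            out.append(g)
    return out


def load_fold_change(path) -> dict[str, float]:
    """Read a gene/fold_change TSV into a dict."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "gene" not in df.columns or "fold_change" not in df.columns:
        raise FormatError("fold-change table needs columns gene, fold_change")
    try:
        return {str(r.gene): float(r.fold_change) for r in df.itertuples()}
    except ValueError as exc:
        raise FormatError(f"non-numeric fold change: {exc}") from exc


def _entry_doc(p: Path, w: float, s: float) -> dict:
    return {
        "nodes": list(p.node_ids),
        "edges": [[e.head, e.metaedge, e.tail] for e in p.edges],
        "metapath": p.metapath.id,
        "weight": w,
        "path_score": s,
    }


def export_evidence(sg: EvidenceSubgraph, fmt: str, path) -> None:
    """Write the subgraph as JSON (round-trippable) or GraphML (node
    ``metanode`` and edge ``metaedge`` attributes)."""
    if fmt == "JSON":
        doc = {
            "query": sg.query,
            "target": sg.target,
            "score": sg.score,
            "node_types": sg.node_types,
            "entries": [_entry_doc(p, w, s) for p, w, s in sg.entries],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    elif fmt == "GraphML":
        g = nx.Graph()
        for n in sorted(sg.union_nodes):
            g.add_node(n, metanode=sg.node_types.get(n, ""))
        for h, m, t in sorted(sg.union_edges):
            g.add_edge(h, t, metaedge=m)
        nx.write_graphml(g, path)
    else:
        raise ConfigError(f"unknown export format {fmt!r}")


def load_evidence(path, kg: KnowledgeGraph, schema=None) -> EvidenceSubgraph:
    """Load a JSON evidence file back into an :class:`EvidenceSubgraph`
    (paths re-materialized against *kg*)."""
    from .metapath import parse_metapath
    from .pathing import build_path
    with open(path) as fh:
        doc = json.load(fh)
    schema = schema or kg.schema
    entries = []
    for e in doc["entries"]:
        mp = parse_metapath(e["metapath"], schema)
        p = build_path(kg, mp, tuple(e["nodes"]), score=e["path_score"])
        entries.append((p, float(e["weight"]), float(e["path_score"])))
    return EvidenceSubgraph(query=doc["query"], target=doc["target"],
                            score=float(doc["score"]), entries=entries,
                            node_types=dict(doc.get("node_types", {})))
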