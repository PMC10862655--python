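"""Typed knowledge-graph storage with adjacency indexes and TSV I/O.

The in-memory container is deliberately simple: nodes and edges are
validated against a :class:`~targetpath.schema.Schema` on construction, and
an adjacency index keyed by ``(node id, metaedge code, direction)`` supports
the metapath traversals downstream.  Duplicate ``(head, metaedge, tail)``
triples collapse to a single edge (keeping ``causal=True`` if any duplicate
has it), which is the normal situation when several sources report the same
relation.

File formats: ``nodes.tsv`` with columns ``id, metanode, label`` and
``edges.tsv`` with ``head, metaedge, tail, causal, source, weight`` --
UTF-8, tab-separated, header row mandatory, ``.`` for missing optional
fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import FormatError, IntegrityError, KGLookupError, SchemaError
from .metapath import BACKWARD, FORWARD, UNDIRECTED
from .schema import Schema

__all__ = ["Node", "Edge", "KnowledgeGraph", "load_kg", "save_kg"]

log = logging.getLogger(__name__)

# adjacency direction keys
_FWD = "f"   # outgoing along a directed metaedge
_BWD = "b"   # incoming along a directed metaedge
_UND = "u"   # either endpoint of an undirected metaedge


@dataclass(frozen=True)
class Node:
    id: str
    metanode: str
    label: str = ""


@dataclass(frozen=True)
class Edge:
    head: str
    metaedge: str
    tail: str
    causal: bool = False
    source: str = "."
    weight: float | None = None

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.head, self.metaedge, self.tail)


class KnowledgeGraph:
    """A validated typed graph.

    Parameters
    ----------
    schema : Schema
        Declared metanode/metaedge types.
    nodes : iterable of Node
    edges : iterable of Edge
        Duplicate triples are collapsed; undirected edges are normalized to
        the declared endpoint order (and lexicographically for same-type
        endpoints) before deduplication.
    """

    def __init__(self, schema: Schema, nodes=(), edges=()):
        self.schema = schema
        self.nodes: dict[str, Node] = {}
        self._edges: dict[tuple[str, str, str], Edge] = {}
        #: node id -> (metaedge code, direction) -> neighbor ids
        self._adj: dict[str, dict[tuple[str, str], list[str]]] = {}
        self._sorted = True
        self.n_duplicates = 0
        for n in nodes:
            self.add_node(n)
        unknown = []
        for e in edges:
            if e.head not in self.nodes or e.tail not in self.nodes:
                unknown.append(e)
                continue
            self.add_edge(e)
        if unknown:
            missing = sorted(
                {e.head for e in unknown if e.head not in self.nodes}
                | {e.tail for e in unknown if e.tail not in self.nodes}
            )
            raise IntegrityError(
                f"{len(unknown)} edge(s) reference missing node(s): {missing[:20]}"
            )
        if self.n_duplicates:
            log.info("collapsed %d duplicate edge triple(s)", self.n_duplicates)

    # -- construction -----------------------------------------------------

    def add_node(self, node: Node) -> None:
        if not node.id:
            raise SchemaError("node id must be non-empty")
        if node.id in self.nodes:
            raise IntegrityError(f"duplicate node id {node.id!r}")
        if not self.schema.has_metanode(node.metanode):
            raise SchemaError(f"node {node.id!r}: unknown metanode {node.metanode!r}")
        self.nodes[node.id] = node
        self._adj[node.id] = {}

    def _normalize(self, e: Edge) -> Edge:
        me = self.schema.metaedge(e.metaedge)
        ht = self.nodes[e.head].metanode
        tt = self.nodes[e.tail].metanode
        if me.directed:
            if (ht, tt) != (me.head_type, me.tail_type):
                raise SchemaError(
                    f"edge {e.triple}: endpoint types ({ht},{tt}) do not match "
                    f"directed metaedge {me.code} ({me.head_type}>{me.tail_type})"
                )
            return e
        if (ht, tt) == (me.head_type, me.tail_type):
            if me.head_type == me.tail_type and e.tail < e.head:
                return replace(e, head=e.tail, tail=e.head)
            return e
        if (ht, tt) == (me.tail_type, me.head_type):
            return replace(e, head=e.tail, tail=e.head)
        raise SchemaError(
            f"edge {e.triple}: endpoint types ({ht},{tt}) do not match "
            f"metaedge {me.code} ({me.head_type}-{me.tail_type})"
        )

    def add_edge(self, e: Edge) -> None:
        if e.head not in self.nodes or e.tail not in self.nodes:
            raise IntegrityError(f"edge {e.triple} references a missing node")
        me = self.schema.metaedge(e.metaedge)
        if e.causal and not me.causal_capable:
            raise SchemaError(
                f"edge {e.triple}: causal flag on non-causal-capable metaedge {me.code}"
            )
        if e.weight is not None and e.weight < 0:
            raise SchemaError(f"edge {e.triple}: negative weight")
        e = self._normalize(e)
        key = e.triple
        old = self._edges.get(key)
        if old is not None:
            self.n_duplicates += 1
            if e.causal and not old.causal:
                self._edges[key] = replace(old, causal=True)
            return
        self._edges[key] = e
        self._sorted = False
        if me.directed:
            self._adj[e.head].setdefault((me.code, _FWD), []).append(e.tail)
            self._adj[e.tail].setdefault((me.code, _BWD), []).append(e.head)
        else:
            self._adj[e.head].setdefault((me.code, _UND), []).append(e.tail)
            self._adj[e.tail].setdefault((me.code, _UND), []).append(e.head)

    # -- access -----------------------------------------------------------

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges.values())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> Node:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KGLookupError(f"unknown node {node_id!r}") from None

    def has_edge(self, head: str, metaedge: str, tail: str) -> bool:
        return self.find_edge(head, metaedge, tail) is not None

    def find_edge(self, head: str, metaedge: str, tail: str) -> Edge | None:
        """Edge lookup honoring undirected symmetry; None if absent."""
        e = self._edges.get((head, metaedge, tail))
        if e is None and not self.schema.metaedge(metaedge).directed:
            e = self._edges.get((tail, metaedge, head))
        return e

    def nodes_of_type(self, metanode: str) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.metanode == metanode)

    def neighbors(self, node_id: str, step: tuple[str, str]) -> list[str]:
        """Nodes one edge away via *step* = (metaedge code, orientation),
        in deterministic lexicographic order."""
        self.node(node_id)
        code, orient = step
        me = self.schema.metaedge(code)
        if orient == UNDIRECTED:
            if me.directed:
                raise SchemaError(f"{code} is directed; undirected step invalid")
            key = (code, _UND)
        elif orient == FORWARD:
            key = (code, _FWD)
        elif orient == BACKWARD:
            key = (code, _BWD)
        else:
            raise SchemaError(f"unknown orientation {orient!r}")
        if not self._sorted:
            for per_node in self._adj.values():
                for lst in per_node.values():
                    lst.sort()
            self._sorted = True
        return self._adj[node_id].get(key, [])

    def degree(self, node_id: str, metaedge: str | None = None) -> int:
        """Count of incident edges, optionally restricted to one metaedge."""
        self.node(node_id)
        if metaedge is not None:
            self.schema.metaedge(metaedge)
        return sum(len(nbrs) for (code, _d), nbrs in self._adj[node_id].items()
                   if metaedge is None or code == metaedge)

    # -- helpers ----------------------------------------------------------

    def subgraph_without_edges(self, triples) -> "KnowledgeGraph":
        """A copy of the graph with the given (head, metaedge, tail) triples
        removed (undirected symmetry honored). Nodes are kept."""
        drop = set()
        for h, m, t in triples:
            e = self.find_edge(h, m, t)
            if e is not None:
                drop.add(e.triple)
        keep = [e for e in self._edges.values() if e.triple not in drop]
        return KnowledgeGraph(self.schema, list(self.nodes.values()), keep)

    def validate(self) -> None:
        """Re-check referential integrity and index consistency."""
        for e in self._edges.values():
            if e.head not in self.nodes or e.tail not in self.nodes:
                raise IntegrityError(f"edge {e.triple} references a missing node")
        incidence = {nid: 0 for nid in self.nodes}
        for e in self._edges.values():
            incidence[e.head] += 1
            incidence[e.tail] += 1
        for nid, cnt in incidence.items():
            if self.degree(nid) != cnt:
                raise IntegrityError(f"adjacency index inconsistent at {nid!r}")


# -- I/O -------------------------------------------------------------------

_NODE_COLS = ["id", "metanode", "label"]
_EDGE_COLS = ["head", "metaedge", "tail", "causal", "source"]


def load_kg(nodes_path, edges_path, schema: Schema) -> KnowledgeGraph:
    """Load a knowledge graph from nodes/edges TSV files and validate it."""
    nodes_df = pd.read_csv(nodes_path, sep="\t", dtype=str, keep_default_na=False)
    edges_df = pd.read_csv(edges_path, sep="\t", dtype=str, keep_default_na=False)
    for col in _NODE_COLS:
        if col not in nodes_df.columns:
            raise FormatError(f"nodes file missing column {col!r}")
    for col in _EDGE_COLS:
        if col not in edges_df.columns:
            raise FormatError(f"edges file missing column {col!r}")
    nodes = [Node(r.id, r.metanode, r.label) for r in nodes_df.itertuples()]
    has_weight = "weight" in edges_df.columns
    edges = []
    for r in edges_df.itertuples():
        w = None
        if has_weight and r.weight not in (".", ""):
            try:
                w = float(r.weight)
            except ValueError:
                raise FormatError(f"non-numeric weight {r.weight!r}") from None
        if r.causal not in ("0", "1"):
            raise FormatError(f"causal must be 0/1, got {r.causal!r}")
        edges.append(Edge(r.head, r.metaedge, r.tail,
                          causal=r.causal == "1", source=r.source or ".", weight=w))
    return KnowledgeGraph(schema, nodes, edges)


def save_kg(kg: KnowledgeGraph, nodes_path, edges_path) -> None:
    """Serialize to the TSV dialect accepted by :func:`load_kg` (sorted,
    so equal graphs produce byte-identical files)."""
    nodes = sorted(kg.nodes.values(), key=lambda n: n.id)
    pd.DataFrame(
        {"id": [n.id for n in nodes],
         "metanode": [n.metanode for n in nodes],
         "label": [n.label for n in nodes]}
    ).to_csv(nodes_path, sep="\t", index=False)
    edges = sorted(kg.edges, key=lambda e: e.triple)
    pd.DataFrame(
        {"head": [e.head for e in edges],
         "metaedge": [e.metaedge for e in edges],
         "tail": [e.tail for e in edges],
         "causal": ["1" if e.causal else "0" for e in edges],
         "source": [e.source for e in edges],
         "weight": ["." if e.weight is None else repr(e.weight) for e in edges]}
    ).to_csv(edges_path, sep="\t", index=False)
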