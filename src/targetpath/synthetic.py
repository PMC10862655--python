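"""Synthetic knowledge-graph generator with planted disease-gene structure.

The generator emulates the statistical shape of a multi-source biomedical
KG at desk scale: every disease gets a *module* of causal and associated
genes connected by ``asw`` edges (causal edges flagged), causal genes
additionally receive mechanistic *support paths* instantiating catalogue
metapaths (interaction partners, pathway co-membership, compound bridges),
association genes receive support with a configurable probability, and
uniform background edges are laid over every metaedge as an exchangeable
null.  Everything is reproducible from a single seed.

The planted structure is what makes the downstream stages testable: path
extraction should find the support paths, metapath selection should rate the
support templates as relevant, and the ranking model should order
causal > associated > unlinked genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .graph import Edge, KnowledgeGraph, Node
from .metapath import BACKWARD, Metapath, parse_metapath
from .schema import Schema, default_schema

__all__ = ["SyntheticConfig", "GroundTruth", "KGSummary", "generate",
           "summarize", "save_truth", "load_truth"]

#: support-path templates planted for causal genes by default: an interaction
#: partner inside the disease module, pathway co-membership with a module gene,
#: and a treating-compound bridge onto an interaction partner.
DEFAULT_SUPPORT_TEMPLATES: tuple[str, ...] = (
    "DI = asw = GE = ppi = GE",
    "DI = asw = GE = inv = PW = inv = GE",
    "DI = trt = CO = bin = GE = ppi = GE",
)

#: baseline background edge counts per metaedge (scaled by ``noise_rate``).
DEFAULT_BACKGROUND: dict[str, int] = {
    "asw": 900, "mnw": 80, "uri": 150, "dri": 150, "urb": 200, "drb": 200,
    "trt": 150, "bin": 400, "oci": 60, "inv": 500, "ppi": 3000, "pdi": 300,
    "exl": 200, "exh": 200, "cov": 200, "cau": 100, "prs": 100, "cat": 40,
    "gbp": 400, "gcc": 300, "gmf": 300, "kdu": 100, "kdd": 100, "oxd": 100,
    "oxu": 100,
}

DEFAULT_NODE_COUNTS: dict[str, int] = {
    "DI": 40, "GE": 1500, "CO": 200, "PW": 120, "AN": 30,
    "GO": 150, "SE": 50, "PC": 20,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark KG."""

    node_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_NODE_COUNTS))
    n_causal: int = 8
    n_assoc: int = 25
    n_module_pathways: int = 3
    support_templates: tuple[str, ...] = DEFAULT_SUPPORT_TEMPLATES
    #: planted support paths per template per causal gene
    n_support_paths: int = 3
    #: probability an association gene receives support paths at all
    assoc_support_prob: float = 0.3
    background_edges: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    noise_rate: float = 1.0
    seed: int = 0

    def validate(self, schema: Schema) -> None:
        for code, n in self.node_counts.items():
            if not schema.has_metanode(code):
                raise ConfigError(f"unknown metanode {code!r} in node_counts")
            if n <= 0:
                raise ConfigError(f"node count for {code} must be positive")
        n_ge = self.node_counts.get("GE", 0)
        if self.n_causal < 0 or self.n_assoc < 0:
            raise ConfigError("module sizes must be non-negative")
        if self.n_causal + self.n_assoc > n_ge:
            raise ConfigError(
                f"disease module ({self.n_causal}+{self.n_assoc}) larger than "
                f"gene pool ({n_ge})"
            )
        if self.n_module_pathways > self.node_counts.get("PW", 0):
            raise ConfigError("more module pathways than pathway nodes")
        if not 0.0 <= self.noise_rate:
            raise ConfigError("noise_rate must be >= 0")
        if not 0.0 <= self.assoc_support_prob <= 1.0:
            raise ConfigError("assoc_support_prob must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-disease planted labels: causal genes and (merely) associated genes,
    disjoint by construction."""

    causal: dict[str, frozenset[str]]
    assoc: dict[str, frozenset[str]]

    @property
    def diseases(self) -> list[str]:
        return sorted(self.causal)

    def tier_frame(self) -> pd.DataFrame:
        rows = []
        for di in self.diseases:
            rows += [(di, g, "causal") for g in sorted(self.causal[di])]
            rows += [(di, g, "assoc") for g in sorted(self.assoc[di])]
        return pd.DataFrame(rows, columns=["disease", "gene", "tier"])


def _norm_triple(schema: Schema, code: str, u: str, u_type: str,
                 v: str, v_type: str, backward: bool) -> tuple[str, str, str]:
    me = schema.metaedge(code)
    if me.directed:
        return (v, code, u) if backward else (u, code, v)
    if (u_type, v_type) == (me.head_type, me.tail_type):
        if me.head_type == me.tail_type and v < u:
            return (v, code, u)
        return (u, code, v)
    return (v, code, u)


class _Builder:
    """Accumulates normalized, deduplicated edges."""

    def __init__(self, schema: Schema, node_types: dict[str, str]):
        self.schema = schema
        self.node_types = node_types
        self.edges: dict[tuple[str, str, str], Edge] = {}

    def add(self, code: str, u: str, v: str, causal: bool = False,
            source: str = "planted", backward: bool = False) -> None:
        key = _norm_triple(self.schema, code, u, self.node_types[u],
                           v, self.node_types[v], backward)
        old = self.edges.get(key)
        if old is not None:
            if causal and not old.causal:
                self.edges[key] = Edge(*key, causal=True, source=old.source)
            return
        self.edges[key] = Edge(*key, causal=causal, source=source)


def _plant_path(builder: _Builder, mp: Metapath, disease: str, gene: str,
                module_genes: list[str], module_pathways: list[str],
                pools: dict[str, list[str]], rng: np.random.Generator) -> None:
    """Instantiate one concrete support path for *mp* from *disease* to
    *gene*, preferring module genes/pathways for typed intermediates."""
    seq = [disease]
    used = {disease, gene}
    for t in mp.node_types[1:-1]:
        if t == "GE":
            cands = [g for g in module_genes if g not in used]
        elif t == "PW":
            cands = [p for p in module_pathways if p not in used]
        else:
            cands = [n for n in pools[t] if n not in used]
        if not cands:
            raise ConfigError(f"cannot instantiate {mp.id}: no free {t} node")
        pick = cands[rng.integers(len(cands))]
        seq.append(pick)
        used.add(pick)
    seq.append(gene)
    for (code, orient), u, v in zip(mp.steps, seq[:-1], seq[1:]):
        builder.add(code, u, v, backward=(orient == BACKWARD))


def generate(config: SyntheticConfig | None = None,
             schema: Schema | None = None) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a schema-conformant KG with planted disease modules.

    Returns the validated graph and the planted ground truth.  Byte-identical
    output for equal configs (one master seed; per-stage streams are drawn
    in a fixed order).
    """
    config = config or SyntheticConfig()
    schema = schema or default_schema()
    config.validate(schema)
    rng = np.random.default_rng(config.seed)

    pools: dict[str, list[str]] = {}
    nodes: list[Node] = []
    for code in sorted(config.node_counts):
        width = max(4, len(str(config.node_counts[code])))
        ids = [f"{code}{i:0{width}d}" for i in range(config.node_counts[code])]
        pools[code] = ids
        nodes += [Node(i, code, label=i) for i in ids]
    node_types = {n.id: n.metanode for n in nodes}

    templates = [parse_metapath(s, schema) for s in config.support_templates]
    builder = _Builder(schema, node_types)
    causal_truth: dict[str, frozenset[str]] = {}
    assoc_truth: dict[str, frozenset[str]] = {}

    for di in pools.get("DI", []):
        module = list(rng.choice(pools["GE"], size=config.n_causal + config.n_assoc,
                                 replace=False))
        causal_genes = sorted(module[: config.n_causal])
        assoc_genes = sorted(module[config.n_causal:])
        module_pathways = list(rng.choice(pools["PW"], size=config.n_module_pathways,
                                          replace=False)) if pools.get("PW") else []
        for g in causal_genes:
            builder.add("asw", di, g, causal=True, source="module")
        for g in assoc_genes:
            builder.add("asw", di, g, causal=False, source="module")
        for g in causal_genes:
            for mp in templates:
                for _ in range(config.n_support_paths):
                    _plant_path(builder, mp, di, g, module, module_pathways,
                                pools, rng)
        for g in assoc_genes:
            if rng.random() < config.assoc_support_prob:
                for mp in templates:
                    for _ in range(config.n_support_paths):
                        _plant_path(builder, mp, di, g, module, module_pathways,
                                    pools, rng)
        causal_truth[di] = frozenset(causal_genes)
        assoc_truth[di] = frozenset(assoc_genes)

    # background edges: uniform over type-valid endpoint pairs
    for me in schema.metaedges:
        base = config.background_edges.get(me.code, 0)
        count = int(round(config.noise_rate * base))
        if count <= 0:
            continue
        heads = pools.get(me.head_type, [])
        tails = pools.get(me.tail_type, [])
        if not heads or not tails:
            continue
        hi = rng.integers(len(heads), size=count)
        ti = rng.integers(len(tails), size=count)
        for h, t in zip(hi, ti):
            u, v = heads[h], tails[t]
            if u == v:
                continue
            builder.add(me.code, u, v, source="background")

    edges = [builder.edges[k] for k in sorted(builder.edges)]
    kg = KnowledgeGraph(schema, nodes, edges)
    kg.validate()
    return kg, GroundTruth(causal=causal_truth, assoc=assoc_truth)


@dataclass
class KGSummary:
    node_counts: pd.Series
    edge_counts: pd.Series
    n_causal_edges: int

    def __str__(self) -> str:
        return (
            "Nodes per metanode:\n" + self.node_counts.to_string()
            + "\n\nEdges per metaedge:\n" + self.edge_counts.to_string()
            + f"\n\nCausal edges: {self.n_causal_edges}"
        )


def summarize(kg: KnowledgeGraph) -> KGSummary:
    """Counts of nodes per metanode and edges per metaedge, plus the number
    of causal-flagged edges."""
    node_counts = pd.Series(0, index=sorted(kg.schema.metanodes), dtype=int)
    for n in kg.nodes.values():
        node_counts[n.metanode] += 1
    edge_counts = pd.Series(0, index=[m.code for m in kg.schema.metaedges], dtype=int)
    n_causal = 0
    for e in kg.edges:
        edge_counts[e.metaedge] += 1
        n_causal += bool(e.causal)
    return KGSummary(node_counts=node_counts, edge_counts=edge_counts,
                     n_causal_edges=n_causal)


def save_truth(truth: GroundTruth, path) -> None:
    truth.tier_frame().to_csv(path, sep="\t", index=False)


def load_truth(path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    causal: dict[str, set[str]] = {}
    assoc: dict[str, set[str]] = {}
    for r in df.itertuples():
        causal.setdefault(r.disease, set())
        assoc.setdefault(r.disease, set())
        (causal if r.tier == "causal" else assoc)[r.disease].add(r.gene)
    return GroundTruth(
        causal={d: frozenset(s) for d, s in causal.items()},
        assoc={d: frozenset(s) for d, s in assoc.items()},
    )
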