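"""Typed knowledge-graph schema: metanodes and metaedges.

A biomedical knowledge graph carries a *type* on every node (metanode) and
every edge (metaedge).  The bundled default schema describes a
target-discovery KG with 8 metanodes -- compounds (CO), diseases (DI), genes
(GE), gene-ontology terms (GO), pathways (PW), anatomy (AN), side effects
(SE) and pharmacologic classes (PC) -- and 25 metaedges linking them
(association, expression change, treatment, binding, protein interaction,
transcription-factor regulation, ontology annotation, ...).

Exactly one metaedge may be *causal-capable*: the disease-gene association
relation ``asw``, whose individual edges can be flagged as causal.  That flag
drives the tiered ranking objective downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError, SchemaError

__all__ = ["Metaedge", "Schema", "default_schema", "load_schema", "save_schema"]


@dataclass(frozen=True)
class Metaedge:
    """A declared edge type.

    ``head_type``/``tail_type`` are metanode codes.  Undirected metaedges are
    traversable in both directions; directed ones (e.g. transcription-factor
    regulation ``pdi``) only forward unless a metapath step says backward.
    """

    code: str
    long_name: str
    head_type: str
    tail_type: str
    directed: bool = False
    causal_capable: bool = False
    sources: tuple[str, ...] = ()


@dataclass(frozen=True)
class Schema:
    metanodes: frozenset[str]
    metaedges: tuple[Metaedge, ...]
    _by_code: dict[str, Metaedge] = field(init=False, repr=False, compare=False, hash=False, default=None)

    def __post_init__(self) -> None:
        codes = [m.code for m in self.metaedges]
        if len(set(codes)) != len(codes):
            raise SchemaError("metaedge codes must be unique")
        for m in self.metaedges:
            if m.head_type not in self.metanodes or m.tail_type not in self.metanodes:
                raise SchemaError(
                    f"metaedge {m.code!r} endpoints ({m.head_type}, {m.tail_type}) "
                    f"not declared as metanodes"
                )
        object.__setattr__(self, "_by_code", {m.code: m for m in self.metaedges})

    def metaedge(self, code: str) -> Metaedge:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemaError(f"unknown metaedge code {code!r}") from None

    def has_metaedge(self, code: str) -> bool:
        return code in self._by_code

    def has_metanode(self, code: str) -> bool:
        return code in self.metanodes

    @property
    def causal_metaedges(self) -> tuple[Metaedge, ...]:
        return tuple(m for m in self.metaedges if m.causal_capable)


#: (code, long_name, head, tail, directed, causal_capable, sources)
_DEFAULT_METAEDGES: tuple[tuple, ...] = (
    ("asw", "associated", "DI", "GE", False, True,
     ("ClinGen", "CTD", "DISEASES", "DisGeNET", "GWAS Catalog", "Open Targets")),
    ("mnw", "mentioned_with", "DI", "DI", False, False, ("MEDLINE",)),
    ("uri", "upregulated_in", "GE", "DI", False, False, ("Harmonizome", "STARGEO")),
    ("dri", "downregulated_in", "GE", "DI", False, False, ("Harmonizome", "STARGEO")),
    ("urb", "upregulated_by", "GE", "CO", False, False, ("CTD", "LINCS Connectivity Map")),
    ("drb", "downregulated_by", "GE", "CO", False, False, ("CTD", "LINCS Connectivity Map")),
    ("trt", "treats", "CO", "DI", False, False, ("CTD", "DrugCentral", "PharmacotherapyDB")),
    ("bin", "binds_to", "CO", "GE", False, False,
     ("BindingDB", "ChEMBL", "CTD", "DrugCentral", "PDSP Ki Database")),
    ("oci", "occurs_in", "DI", "AN", False, False, ("MEDLINE",)),
    ("inv", "involved_in", "GE", "PW", False, False, ("Reactome",)),
    ("ppi", "PPI", "GE", "GE", False, False,
     ("BioGRID", "IntAct", "MINT", "Pathway Commons", "Reactome", "STRING")),
    ("pdi", "PDI", "GE", "GE", True, False, ("TRRUST",)),
    ("exl", "expressed_low", "GE", "AN", False, False, ("Bgee",)),
    ("exh", "expressed_high", "GE", "AN", False, False, ("Bgee",)),
    ("cov", "covaries", "GE", "GE", False, False, ("ERC",)),
    ("cau", "causes", "CO", "SE", False, False, ("FAERS",)),
    ("prs", "presents", "DI", "SE", False, False, ("MEDLINE",)),
    ("cat", "categorized_in", "CO", "PC", False, False, ("DrugCentral",)),
    ("gbp", "biological_process", "GE", "GO", False, False, ("GO",)),
    ("gcc", "cellular_component", "GE", "GO", False, False, ("GO",)),
    ("gmf", "molecular_function", "GE", "GO", False, False, ("GO",)),
    ("kdu", "KD_upregulates", "GE", "GE", True, False, ("LINCS Connectivity Map",)),
    ("kdd", "KD_downregulates", "GE", "GE", True, False, ("LINCS Connectivity Map",)),
    ("oxu", "OX_upregulates", "GE", "GE", True, False, ("LINCS Connectivity Map",)),
    ("oxd", "OX_downregulates", "GE", "GE", True, False, ("LINCS Connectivity Map",)),
)

_DEFAULT_METANODES = frozenset({"CO", "DI", "GE", "GO", "PW", "AN", "SE", "PC"})


def default_schema() -> Schema:
    """The bundled 8-metanode / 25-metaedge target-discovery schema."""
    return Schema(
        metanodes=_DEFAULT_METANODES,
        metaedges=tuple(Metaedge(*row) for row in _DEFAULT_METAEDGES),
    )


def save_schema(schema: Schema, path) -> None:
    doc = {
        "metanodes": sorted(schema.metanodes),
        "metaedges": [
            {
                "code": m.code,
                "long_name": m.long_name,
                "head_type": m.head_type,
                "tail_type": m.tail_type,
                "directed": m.directed,
                "causal_capable": m.causal_capable,
                "sources": list(m.sources),
            }
            for m in schema.metaedges
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_schema(path) -> Schema:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        metanodes = frozenset(doc["metanodes"])
        metaedges = tuple(
            Metaedge(
                code=e["code"],
                long_name=e.get("long_name", e["code"]),
                head_type=e["head_type"],
                tail_type=e["tail_type"],
                directed=bool(e.get("directed", False)),
                causal_capable=bool(e.get("causal_capable", False)),
                sources=tuple(e.get("sources", ())),
            )
            for e in doc["metaedges"]
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed schema file {path}: {exc}") from exc
    return Schema(metanodes=metanodes, metaedges=metaedges)
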