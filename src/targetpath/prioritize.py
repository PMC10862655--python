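"""Five-criteria target assessment and global ranking.

Targets are triaged on five strategic criteria, each mapped to [0, 1]
(toxicity encoded so that higher = safer), then combined into a weighted
global score.  The default quantifications are transparent graph/model
proxies and every one of them is replaceable through
:class:`PrioritizeConfig`:

* biological relevance -- the model score, min-max normalized within the
  disease's candidate list;
* disease causality -- attention-weighted fraction of evidence-path edges
  that carry a causal flag;
* druggability -- compound-binding (``bin``) partner count, capped;
* toxicity -- one minus a capped count of side-effect liabilities reachable
  through binding compounds (``bin`` then ``cau`` edges);
* novelty -- one minus a capped normalized association-edge degree (a
  literature-knownness proxy: heavily associated genes are less novel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, InputError
from .graph import KnowledgeGraph
from .scorer import ScoredPair

__all__ = ["CriterionScores", "PrioritizeConfig", "TargetCard",
           "score_criteria", "global_score", "rank_targets", "make_cards",
           "cards_frame"]

CRITERIA = ("biological_relevance", "disease_causality", "druggability",
            "toxicity", "novelty")


@dataclass(frozen=True)
class CriterionScores:
    biological_relevance: float
    disease_causality: float
    druggability: float
    toxicity: float
    novelty: float

    def __post_init__(self) -> None:
        for name in CRITERIA:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in CRITERIA)


@dataclass
class PrioritizeConfig:
    weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    druggability_cap: int = 1     #: bin partners at which druggability saturates
    toxicity_cap: int = 10        #: distinct liability links at which safety hits 0
    novelty_cap: int = 20         #: asw degree at which novelty hits 0
    #: optional per-criterion overrides: name -> f(gene, disease, kg, scored)
    overrides: dict = field(default_factory=dict)


def _causality(scored: ScoredPair) -> float:
    if not scored.paths or scored.attention.size == 0:
        return 0.0
    total = 0.0
    for p, w in zip(scored.paths, scored.attention):
        frac = sum(1 for e in p.edges if e.causal) / len(p.edges)
        total += float(w) * frac
    return min(max(total, 0.0), 1.0)


def score_criteria(gene: str, disease: str, kg: KnowledgeGraph,
                   scored: ScoredPair, cfg: PrioritizeConfig | None = None,
                   score_bounds: tuple[float, float] | None = None
                   ) -> CriterionScores:
    """Quantify the five criteria for one candidate target.

    *score_bounds* are the (min, max) model scores within the disease's
    candidate list, used to normalize biological relevance; when omitted the
    raw score is clipped to [0, 1].
    """
    cfg = cfg or PrioritizeConfig()
    kg.node(gene)
    kg.node(disease)

    def _default(name: str) -> float:
        if name == "biological_relevance":
            if score_bounds is None:
                return min(max(scored.score, 0.0), 1.0)
            lo, hi = score_bounds
            if hi <= lo:
                return 1.0
            return min(max((scored.score - lo) / (hi - lo), 0.0), 1.0)
        if name == "disease_causality":
            return _causality(scored)
        if name == "druggability":
            return min(kg.degree(gene, "bin") / cfg.druggability_cap, 1.0)
        if name == "toxicity":
            liabilities = set()
            for comp in kg.neighbors(gene, ("bin", "undirected")):
                liabilities.update(kg.neighbors(comp, ("cau", "undirected")))
            return 1.0 - min(len(liabilities) / cfg.toxicity_cap, 1.0)
        if name == "novelty":
            return 1.0 - min(kg.degree(gene, "asw") / cfg.novelty_cap, 1.0)
        raise ConfigError(f"unknown criterion {name!r}")

    values = {}
    for name in CRITERIA:
        fn = cfg.overrides.get(name)
        values[name] = (float(fn(gene, disease, kg, scored)) if fn is not None
                        else _default(name))
    return CriterionScores(**values)


def global_score(c: CriterionScores, weights=None) -> float:
    """Weighted mean of the five criteria; monotone in each one."""
    w = tuple(weights) if weights is not None else (1.0,) * 5
    if len(w) != 5 or any(x < 0 for x in w):
        raise ConfigError("need 5 non-negative weights")
    total = sum(w)
    if total == 0:
        raise ConfigError("weights must not all be zero")
    return sum(wi * ci for wi, ci in zip(w, c.as_tuple())) / total


@dataclass
class TargetCard:
    """A ranked target with its per-criterion assessment."""

    gene: str
    disease: str
    criteria: CriterionScores
    global_score: float
    rank: int | None = None
    annotations: tuple[str, ...] = ()


def make_cards(kg: KnowledgeGraph, scored_pairs: list[ScoredPair],
               cfg: PrioritizeConfig | None = None) -> list[TargetCard]:
    """Build (unranked) target cards for a disease's scored candidates,
    normalizing biological relevance within the list."""
    cfg = cfg or PrioritizeConfig()
    if not scored_pairs:
        raise InputError("scored_pairs must be non-empty")
    lo = min(sp.score for sp in scored_pairs)
    hi = max(sp.score for sp in scored_pairs)
    cards = []
    for sp in scored_pairs:
        crit = score_criteria(sp.target, sp.query, kg, sp, cfg,
                              score_bounds=(lo, hi))
        cards.append(TargetCard(gene=sp.target, disease=sp.query,
                                criteria=crit,
                                global_score=global_score(crit, cfg.weights)))
    return cards


def rank_targets(cards: list[TargetCard], top_n: int | None = None
                 ) -> list[TargetCard]:
    """Order cards by global score descending (ties by gene id), assign
    unique ranks, optionally truncate to *top_n*."""
    if not cards:
        raise InputError("cards must be non-empty")
    ranked = sorted(cards, key=lambda c: (-c.global_score, c.gene))
    out = []
    for i, c in enumerate(ranked, start=1):
        out.append(TargetCard(gene=c.gene, disease=c.disease,
                              criteria=c.criteria,
                              global_score=c.global_score, rank=i,
                              annotations=c.annotations))
    if top_n is not None:
        out = out[:top_n]
    return out


def cards_frame(cards: list[TargetCard]) -> pd.DataFrame:
    """Heatmap-ready table: one row per card, one column per criterion."""
    rows = []
    for c in cards:
        row = {"disease": c.disease, "gene": c.gene, "rank": c.rank,
               "global_score": c.global_score}
        row.update(dict(zip(CRITERIA, c.criteria.as_tuple())))
        rows.append(row)
    return pd.DataFrame(rows)
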