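"""Model/Results facade tying the pipeline stages together.

:class:`AssociationModel` is constructed from a knowledge graph and fitted
with :meth:`AssociationModel.fit`, which runs the full protocol -- edge
split, QuatE pre-training on the training graph, metapath-catalogue
selection, WARP training of the path-attention scorer -- and returns an
:class:`AssociationResults` carrying the trained parameters, training
history, per-disease evaluation, target rankings and evidence subgraphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .evaluation import (ALL_ASSOCIATION, EvaluationResult, evaluate,
                         quate_score_fn, random_score_fn)
from .evidence import EvidenceSubgraph, build_evidence
from .graph import KnowledgeGraph, load_kg
from .metapath import DEFAULT_CATALOGUE_STRINGS, parse_metapath
from .pathing import (MetapathCatalogue, PathCache, PathScoreConfig,
                      select_metapaths)
from .prioritize import PrioritizeConfig, TargetCard, make_cards, rank_targets
from .quate import QuatEConfig, QuaternionEmbeddingSet, train_quate
from .scorer import PairScorer, ScoredPair, ScorerConfig, ScorerParams
from .synthetic import GroundTruth
from .training import (EdgeSplit, SplitConfig, WarpConfig, split_edges, train)

__all__ = ["AssociationModel", "AssociationResults"]


def _derive(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2 ** 31))


class AssociationModel:
    """Disease-gene association model over a typed knowledge graph.

    Parameters
    ----------
    kg : KnowledgeGraph
        The full graph (test edges are removed internally after splitting).
    truth : GroundTruth, optional
        Planted labels when the graph is synthetic; only used by
        diagnostics, never by training.
    catalogue : MetapathCatalogue, optional
        A pre-selected metapath catalogue.  When omitted, the bundled
        candidate metapaths are filtered by the data-driven
        relevance/redundancy selection using causal association pairs.
    """

    def __init__(self, kg: KnowledgeGraph, truth: GroundTruth | None = None,
                 catalogue: MetapathCatalogue | None = None,
                 candidate_strings: tuple[str, ...] = DEFAULT_CATALOGUE_STRINGS,
                 quate_config: QuatEConfig | None = None,
                 warp_config: WarpConfig | None = None,
                 split_config: SplitConfig | None = None,
                 path_score_config: PathScoreConfig | None = None,
                 scorer_channels: int = 64,
                 select_max_count: int = 8,
                 seed: int = 0):
        self.kg = kg
        self.truth = truth
        self.catalogue = catalogue
        self.candidate_strings = candidate_strings
        self.seed = int(seed)
        self.quate_config = quate_config or QuatEConfig(seed=_derive(seed, 1))
        self.warp_config = warp_config or WarpConfig(seed=_derive(seed, 2))
        self.split_config = split_config or SplitConfig(seed=_derive(seed, 3))
        self.path_score_config = path_score_config or PathScoreConfig()
        self.scorer_channels = scorer_channels
        self.select_max_count = select_max_count

    @classmethod
    def from_tables(cls, nodes_path, edges_path, schema, **kwargs
                    ) -> "AssociationModel":
        return cls(load_kg(nodes_path, edges_path, schema), **kwargs)

    # -- fitting ----------------------------------------------------------

    def _select_catalogue(self) -> MetapathCatalogue:
        """Data-driven catalogue selection on the full graph.

        Causal association pairs are the positives (they are the
        highest-confidence labels); all association pairs are used when no
        causal flags exist.  The catalogue is a design-time input fixed
        before the split, like the schema itself.
        """
        candidates = [parse_metapath(s, self.kg.schema)
                      for s in self.candidate_strings]
        causal_pairs = [(e.head, e.tail) for e in self.kg.edges
                        if e.metaedge == "asw" and e.causal]
        pairs = causal_pairs or [(e.head, e.tail) for e in self.kg.edges
                                 if e.metaedge == "asw"]
        if not pairs:
            raise InputError("graph has no asw edges; cannot select metapaths")
        return select_metapaths(self.kg, pairs, candidates,
                                max_count=self.select_max_count,
                                score_cfg=self.path_score_config,
                                seed=_derive(self.seed, 4))

    def fit(self) -> "AssociationResults":
        """Run split -> pre-train -> select -> train and return results."""
        split = split_edges(self.kg, self.split_config)
        train_kg = self.kg.subgraph_without_edges(
            [(d, "asw", g) for d, g, _c in split.test_edges])
        embeddings = train_quate(train_kg, self.quate_config)
        catalogue = self.catalogue or self._select_catalogue()
        scorer_cfg = ScorerConfig(input_dim=embeddings.dim,
                                  n_metapaths=len(catalogue),
                                  channels=self.scorer_channels,
                                  seed=_derive(self.seed, 5))
        cache = PathCache(train_kg, catalogue.metapaths,
                          self.path_score_config, embeddings=embeddings)
        scorer = PairScorer(train_kg, embeddings, catalogue, scorer_cfg,
                            ScorerParams.init(scorer_cfg),
                            score_cfg=self.path_score_config, cache=cache)
        params, history = train(train_kg, embeddings, catalogue, scorer_cfg,
                                self.warp_config, split, self.truth,
                                pair_scorer=scorer)
        scorer.params = params
        return AssociationResults(model=self, params=params, history=history,
                                  embeddings=embeddings, split=split,
                                  catalogue=catalogue, train_kg=train_kg,
                                  scorer=scorer)


@dataclass
class AssociationResults:
    """Fit artifacts plus evaluation, ranking and evidence accessors."""

    model: AssociationModel
    params: ScorerParams
    history: pd.DataFrame
    embeddings: QuaternionEmbeddingSet
    split: EdgeSplit
    catalogue: MetapathCatalogue
    train_kg: KnowledgeGraph
    scorer: PairScorer
    _eval_cache: dict = field(default_factory=dict)

    # -- scoring ----------------------------------------------------------

    def score(self, disease: str, gene: str) -> float:
        return self.scorer.score(disease, gene)

    def predict(self, disease: str, gene: str) -> ScoredPair:
        """Score one pair, returning the path evidence and attention."""
        return self.scorer.scored_pair(disease, gene)

    def score_frame(self, disease: str) -> pd.DataFrame:
        """Scores of every evaluation candidate gene for *disease*."""
        train_pos = self.split.train_genes().get(disease, set())
        genes = [g for g in self.train_kg.nodes_of_type("GE")
                 if g not in train_pos]
        scores = [self.scorer.score(disease, g) for g in genes]
        return (pd.DataFrame({"disease": disease, "gene": genes,
                              "score": scores})
                .sort_values(["score", "gene"], ascending=[False, True])
                .reset_index(drop=True))

    # -- evaluation -------------------------------------------------------

    def evaluate(self, mode: str = ALL_ASSOCIATION) -> EvaluationResult:
        key = ("model", mode)
        if key not in self._eval_cache:
            self._eval_cache[key] = evaluate(
                lambda d, g: self.scorer.score(d, g),
                self.train_kg, self.split, mode)
        return self._eval_cache[key]

    def baseline_evaluate(self, mode: str = ALL_ASSOCIATION) -> EvaluationResult:
        """Embedding-only (QuatE triple score) baseline under the same
        protocol and candidate filtering."""
        key = ("baseline", mode)
        if key not in self._eval_cache:
            self._eval_cache[key] = evaluate(
                quate_score_fn(self.embeddings), self.train_kg, self.split,
                mode)
        return self._eval_cache[key]

    def null_evaluate(self, mode: str = ALL_ASSOCIATION,
                      seed: int | None = None) -> EvaluationResult:
        """Random-ranking null under the same protocol."""
        s = _derive(self.model.seed, 6) if seed is None else seed
        return evaluate(random_score_fn(s), self.train_kg, self.split, mode)

    # -- triage -----------------------------------------------------------

    def rank_targets(self, disease: str, top_n: int = 20,
                     cfg: PrioritizeConfig | None = None) -> list[TargetCard]:
        """Ranked target cards for the disease's top-scoring candidates."""
        frame = self.score_frame(disease)
        lo, hi = float(frame.score.min()), float(frame.score.max())
        top = frame.head(top_n)
        pairs = [self.predict(disease, g) for g in top.gene]
        cards = make_cards(self.train_kg, pairs, cfg)
        # re-normalize biological relevance against the full candidate list
        from .prioritize import CriterionScores, global_score
        cfg = cfg or PrioritizeConfig()
        fixed = []
        for card, sp in zip(cards, pairs):
            rel = 1.0 if hi <= lo else min(max((sp.score - lo) / (hi - lo), 0.0), 1.0)
            crit = CriterionScores(
                biological_relevance=rel,
                disease_causality=card.criteria.disease_causality,
                druggability=card.criteria.druggability,
                toxicity=card.criteria.toxicity,
                novelty=card.criteria.novelty)
            fixed.append(TargetCard(gene=card.gene, disease=card.disease,
                                    criteria=crit,
                                    global_score=global_score(crit, cfg.weights)))
        return rank_targets(fixed, top_n=top_n)

    def evidence(self, disease: str, gene: str) -> EvidenceSubgraph:
        return build_evidence(self.predict(disease, gene), self.train_kg)

    # -- diagnostics ------------------------------------------------------

    def tier_separation(self, truth: GroundTruth | None = None,
                        n_random: int = 100, seed: int | None = None
                        ) -> pd.DataFrame:
        """Per-disease mean model score over causal, associated and random
        genes, plus whether the means are strictly ordered
        causal > associated > random."""
        truth = truth or self.model.truth
        if truth is None:
            raise InputError("tier separation needs ground-truth labels")
        rng = np.random.default_rng(
            _derive(self.model.seed, 7) if seed is None else seed)
        genes = self.train_kg.nodes_of_type("GE")
        rows = []
        for d in truth.diseases:
            causal = sorted(truth.causal[d])
            assoc = sorted(truth.assoc[d])
            excluded = set(causal) | set(assoc)
            pool = [g for g in genes if g not in excluded]
            rand = [pool[i] for i in rng.choice(len(pool),
                                                size=min(n_random, len(pool)),
                                                replace=False)]
            mc = float(np.mean([self.scorer.score(d, g) for g in causal]))
            ma = float(np.mean([self.scorer.score(d, g) for g in assoc]))
            mr = float(np.mean([self.scorer.score(d, g) for g in rand]))
            rows.append({"disease": d, "mean_causal": mc, "mean_assoc": ma,
                         "mean_random": mr,
                         "ordered": bool(mc > ma > mr)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Association model fit",
            "=" * 52,
            f"nodes: {self.model.kg.n_nodes}   edges: {self.model.kg.n_edges}",
            f"train asw edges: {len(self.split.train_edges)}   "
            f"test asw edges: {len(self.split.test_edges)}",
            f"retained diseases: {len(self.split.retained_diseases)}",
            f"catalogue metapaths: {len(self.catalogue)}",
            f"embedding dim: {self.embeddings.dim} "
            f"(k={self.embeddings.k} quaternions)",
            f"training epochs: {len(self.history)}   "
            f"final mean loss: {self.history.mean_loss.iloc[-1]:.4f}",
        ]
        for key, res in sorted(self._eval_cache.items()):
            lines.append(f"{key[0]} ({key[1]}): mean AveP "
                         f"{res.mean_avep:.4f}, mean Prec@20 "
                         f"{res.mean_prec_at_20:.4f}")
        return "\n".join(lines)
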