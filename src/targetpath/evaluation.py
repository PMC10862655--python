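"""Ranking evaluation: AveP, Prec@20, PR curves, baselines and paired tests.

Per retained disease the candidate list is *all* genes minus that disease's
train-positive genes (train associations are removed entirely from every
evaluation case), ranked by score descending with ties broken by gene id.
Ground truth is either every held-out association (``all_association`` mode)
or only the causal held-out edges (``causal_only`` mode; diseases without a
causal test edge are skipped because the metric is undefined for them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .errors import InputError, UndefinedMetricError, UndefinedTestError
from .graph import KnowledgeGraph
from .quate import QuaternionEmbeddingSet
from .training import EdgeSplit

__all__ = ["average_precision", "precision_at_k", "EvaluationResult",
           "evaluate", "quate_score_fn", "quate_baseline", "pr_curve",
           "compare_paired", "random_score_fn"]

ALL_ASSOCIATION = "all_association"
CAUSAL_ONLY = "causal_only"


def average_precision(ranked, relevant) -> float:
    """Average precision: mean over the ranks of retrieved relevant items of
    the precision at that rank, normalized by the number of relevant items
    present in the ranking."""
    relevant = set(relevant)
    hits = 0
    total = 0.0
    n_rel = 0
    for k, item in enumerate(ranked, start=1):
        if item in relevant:
            hits += 1
            total += hits / k
    n_rel = hits
    if n_rel == 0:
        raise UndefinedMetricError("no relevant item appears in the ranking")
    return total / n_rel


def precision_at_k(ranked, relevant, k: int = 20) -> float:
    """Fraction of relevant items among the top *k* (denominator is *k*
    even when fewer candidates exist)."""
    if k < 1:
        raise InputError("k must be >= 1")
    relevant = set(relevant)
    top = list(ranked)[:k]
    return sum(1 for g in top if g in relevant) / k


@dataclass
class EvaluationResult:
    """Per-disease metrics plus a summary."""

    per_disease: pd.DataFrame     #: columns disease, avep, prec_at_20, n_candidates
    mode: str

    @property
    def mean_avep(self) -> float:
        return float(self.per_disease["avep"].mean())

    @property
    def median_avep(self) -> float:
        return float(self.per_disease["avep"].median())

    @property
    def mean_prec_at_20(self) -> float:
        return float(self.per_disease["prec_at_20"].mean())

    def summary(self) -> pd.Series:
        return pd.Series({
            "mode": self.mode,
            "n_diseases": len(self.per_disease),
            "mean_avep": self.mean_avep,
            "median_avep": self.median_avep,
            "mean_prec_at_20": self.mean_prec_at_20,
        })

    def to_long_frame(self, method: str = "model") -> pd.DataFrame:
        """Boxplot-ready long format: one row per (disease, metric)."""
        long = self.per_disease.melt(
            id_vars=["disease"], value_vars=["avep", "prec_at_20"],
            var_name="metric", value_name="value")
        long.insert(0, "method", method)
        long.insert(1, "mode", self.mode)
        return long


def _candidates(kg: KnowledgeGraph, split: EdgeSplit, disease: str) -> list[str]:
    train_pos = split.train_genes().get(disease, set())
    return [g for g in kg.nodes_of_type("GE") if g not in train_pos]


def rank_candidates(score_fn, disease: str, candidates: list[str]) -> list[str]:
    """Rank candidates by score descending, ties broken by gene id."""
    scores = {g: score_fn(disease, g) for g in candidates}
    return sorted(candidates, key=lambda g: (-scores[g], g))


def evaluate(score_fn, kg: KnowledgeGraph, split: EdgeSplit,
             mode: str = ALL_ASSOCIATION, k: int = 20) -> EvaluationResult:
    """Evaluate a ``score_fn(disease, gene) -> float`` under the protocol.

    Train-positive genes are excluded from every candidate list, so train
    leakage into the ranking is impossible by construction.
    """
    if mode not in (ALL_ASSOCIATION, CAUSAL_ONLY):
        raise InputError(f"unknown mode {mode!r}")
    if not split.retained_diseases:
        raise InputError("no retained disease in the split")
    relevant_map = (split.test_genes if mode == ALL_ASSOCIATION
                    else split.test_genes_causal())
    rows = []
    for d in split.retained_diseases:
        relevant = relevant_map.get(d, set())
        if not relevant:
            continue  # causal_only: metric undefined without causal test edges
        cands = _candidates(kg, split, d)
        ranked = rank_candidates(score_fn, d, cands)
        rows.append({
            "disease": d,
            "avep": average_precision(ranked, relevant),
            "prec_at_20": precision_at_k(ranked, relevant, k),
            "n_candidates": len(cands),
            "n_relevant": len(relevant),
        })
    if not rows:
        raise InputError(f"no disease evaluable in mode {mode!r}")
    return EvaluationResult(per_disease=pd.DataFrame(rows), mode=mode)


def quate_score_fn(embeddings: QuaternionEmbeddingSet, relation: str = "asw"):
    """Score function of the embedding-only baseline: the QuatE triple score
    of (disease, asw, gene)."""
    def fn(disease: str, gene: str) -> float:
        return embeddings.score_triple(disease, relation, gene)
    return fn


def quate_baseline(embeddings: QuaternionEmbeddingSet, disease: str,
                   kg: KnowledgeGraph, split: EdgeSplit,
                   relation: str = "asw") -> list[str]:
    """Candidate genes ranked by the QuatE score of (disease, asw, gene),
    with the same train-positive filtering as :func:`evaluate`."""
    cands = _candidates(kg, split, disease)
    scores = dict(zip(cands, embeddings.score_one_to_many(disease, relation,
                                                          cands)))
    return sorted(cands, key=lambda g: (-scores[g], g))


def random_score_fn(seed: int = 0):
    """Null model: i.i.d. uniform scores (memoized per pair)."""
    rng = np.random.default_rng(seed)
    memo: dict[tuple[str, str], float] = {}

    def fn(disease: str, gene: str) -> float:
        key = (disease, gene)
        if key not in memo:
            memo[key] = float(rng.random())
        return memo[key]
    return fn


def pr_curve(scores, labels) -> list[tuple[float, float]]:
    """Precision-recall points at every distinct score threshold,
    ordered by increasing recall (recall is non-decreasing along the list)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise InputError("pr_curve requires at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # last index of each distinct-threshold block
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    pts = [(tp[i] / n_pos, tp[i] / (tp[i] + fp[i])) for i in distinct]
    return [(float(r), float(p)) for r, p in pts]


def compare_paired(avep_a, avep_b) -> float:
    """One-sided Wilcoxon signed-rank p-value for "b ranks higher than a"
    over paired per-disease values; zero differences are dropped."""
    a = np.asarray(avep_a, dtype=float)
    b = np.asarray(avep_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise InputError("need paired samples of equal length >= 5")
    if np.all(b - a == 0.0):
        raise UndefinedTestError("all paired differences are zero")
    res = wilcoxon(b, a, alternative="greater", zero_method="wilcox")
    return float(res.pvalue)
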