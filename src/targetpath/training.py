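"""Edge splitting, tiered ranking pairs and WARP/BPR training of the scorer.

The evaluation protocol splits disease-gene association (``asw``) edges:
each edge is independently assigned to the test set with probability 0.5;
diseases ending up with fewer than 20 sampled test edges are dropped from
the test set (their sampled edges return to training), so every retained
disease has at least 20 held-out positives.

Training is a ranking problem with two tiers of pairs:

* tier 1 (causal vs association): for a disease, a causally-linked gene
  should outscore a merely associated gene;
* tier 2 (association vs none): an associated gene should outscore a gene
  with no (train or test) association.

The default loss is WARP: negatives are sampled until one violates the
margin; the hinge penalty is weighted by Phi(rank) with
``Phi(k) = sum_{i=1..k} 1/i`` and estimated rank ``floor((N-1)/T)`` after T
sampling trials over N candidates.  BPR (``-log sigmoid(s_pos - s_neg)``) is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autograd import Adam, Tensor
from .errors import ConfigError, DomainError, InputError
from .graph import KnowledgeGraph
from .scorer import PairScorer, ScorerConfig, ScorerParams
from .synthetic import GroundTruth

__all__ = ["SplitConfig", "EdgeSplit", "split_edges", "warp_rank_weight",
           "RankingPairs", "make_ranking_pairs", "warp_step", "WarpConfig",
           "train"]


@dataclass
class SplitConfig:
    test_fraction: float = 0.5
    min_test: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.min_test < 1:
            raise ConfigError("min_test must be >= 1")


@dataclass
class EdgeSplit:
    """Train/test partition of asw edges.  ``train_edges``/``test_edges``
    are (disease, gene, causal) triples."""

    train_edges: list[tuple[str, str, bool]]
    test_edges: list[tuple[str, str, bool]]
    retained_diseases: list[str]

    @property
    def test_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {d: set() for d in self.retained_diseases}
        for d, g, _c in self.test_edges:
            out[d].add(g)
        return out

    def test_genes_causal(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {d: set() for d in self.retained_diseases}
        for d, g, c in self.test_edges:
            if c:
                out[d].add(g)
        return out

    def train_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d, g, _c in self.train_edges:
            out.setdefault(d, set()).add(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(d, g, int(c), "train") for d, g, c in self.train_edges]
        rows += [(d, g, int(c), "test") for d, g, c in self.test_edges]
        return pd.DataFrame(rows, columns=["disease", "gene", "causal", "split"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "EdgeSplit":
        df = pd.read_csv(path, sep="\t", dtype={"disease": str, "gene": str})
        train = [(r.disease, r.gene, bool(r.causal))
                 for r in df[df.split == "train"].itertuples()]
        test = [(r.disease, r.gene, bool(r.causal))
                for r in df[df.split == "test"].itertuples()]
        return cls(train_edges=train, test_edges=test,
                   retained_diseases=sorted({d for d, _g, _c in test}))


def split_edges(kg: KnowledgeGraph, cfg: SplitConfig | None = None) -> EdgeSplit:
    """Split asw edges per the evaluation protocol (see module docstring).

    Each asw edge goes to the test set independently with probability
    ``test_fraction``; diseases with fewer than ``min_test`` sampled test
    edges are dropped from the test set and their edges returned to train.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or SplitConfig()
    asw = sorted((e.head, e.tail, e.causal) for e in kg.edges
                 if e.metaedge == "asw")
    if not asw:
        raise InputError("graph has no asw edges to split")
    rng = np.random.default_rng(cfg.seed)
    picks = rng.random(len(asw)) < cfg.test_fraction
    sampled: dict[str, list[tuple[str, str, bool]]] = {}
    train: list[tuple[str, str, bool]] = []
    for (d, g, c), is_test in zip(asw, picks):
        if is_test:
            sampled.setdefault(d, []).append((d, g, c))
        else:
            train.append((d, g, c))
    test: list[tuple[str, str, bool]] = []
    retained: list[str] = []
    for d in sorted(sampled):
        if len(sampled[d]) < cfg.min_test:
            train.extend(sampled[d])
        else:
            retained.append(d)
            test.extend(sampled[d])
    return EdgeSplit(train_edges=sorted(train), test_edges=sorted(test),
                     retained_diseases=retained)


def warp_rank_weight(k: int) -> float:
    """WARP rank weight ``Phi(k) = sum_{i=1..k} 1/i`` (harmonic number)."""
    if k < 1:
        raise DomainError("rank must be >= 1")
    return float(np.sum(1.0 / np.arange(1, int(k) + 1)))


@dataclass
class RankingPairs:
    """Tiered training material for one split.

    ``tier1``: (disease, causal gene, association gene) triples.
    ``tier2_positives``: (disease, positive gene) pairs; negatives for tier 2
    are sampled at training time from ``negative_pool`` (all genes minus the
    disease's train *and* test positives, so held-out positives are never
    used as negatives).
    """

    tier1: list[tuple[str, str, str]]
    tier2_positives: list[tuple[str, str]]
    negative_pool: dict[str, list[str]]


def make_ranking_pairs(kg: KnowledgeGraph, split: EdgeSplit,
                       truth: GroundTruth | None = None) -> RankingPairs:
    """Build the two tiers of ranking pairs from the train edges.

    Causal flags come from the edges themselves (ground truth is only used
    in tests).  A graph with no causal train edges yields an empty tier 1;
    training then proceeds on tier 2 alone.
    """
    genes = kg.nodes_of_type("GE")
    by_disease: dict[str, dict[str, bool]] = {}
    for d, g, c in split.train_edges:
        by_disease.setdefault(d, {})[g] = c
    test_genes = {}
    for d, g, _c in split.test_edges:
        test_genes.setdefault(d, set()).add(g)

    tier1: list[tuple[str, str, str]] = []
    tier2_pos: list[tuple[str, str]] = []
    negative_pool: dict[str, list[str]] = {}
    for d in sorted(by_disease):
        flags = by_disease[d]
        causal = sorted(g for g, c in flags.items() if c)
        assoc = sorted(g for g, c in flags.items() if not c)
        for cg in causal:
            for ag in assoc:
                tier1.append((d, cg, ag))
        for g in sorted(flags):
            tier2_pos.append((d, g))
        excluded = set(flags) | test_genes.get(d, set())
        negative_pool[d] = [g for g in genes if g not in excluded]
    return RankingPairs(tier1=tier1, tier2_positives=tier2_pos,
                        negative_pool=negative_pool)


@dataclass
class WarpConfig:
    margin: float = 1.0
    max_trials: int = 50
    epochs: int = 5
    batch_size: int = 8        #: pairs per optimizer step
    lr: float = 1e-3
    tier_weights: tuple[float, float] = (1.0, 1.0)
    loss: str = "warp"         #: or "bpr"
    #: per-epoch cap on sampled positives per disease per tier
    max_pairs_per_disease: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ConfigError("margin must be > 0")
        if self.max_trials < 1:
            raise ConfigError("max_trials must be >= 1")
        if self.loss not in ("warp", "bpr"):
            raise ConfigError(f"unknown loss {self.loss!r}")


def warp_step(s_pos: Tensor, negatives: list, score_fn, cfg: WarpConfig,
              rng: np.random.Generator) -> Tensor | None:
    """One WARP (or BPR) loss contribution for a positive with score
    *s_pos* against *negatives* scored on demand by ``score_fn(neg)``.

    WARP samples negatives uniformly with replacement until a margin
    violator (``s_neg + margin > s_pos``) is found or ``max_trials`` is
    reached; with a violator found on trial T among N candidates the
    estimated rank is ``floor((N - 1) / T)`` and the contribution is
    ``Phi(max(rank, 1)) * max(0, margin - s_pos + s_neg)``.  Returns None if
    no violator is found (zero loss).
    """
    if not negatives:
        raise InputError("empty candidate negative set")
    n = len(negatives)
    if cfg.loss == "bpr":
        neg = negatives[rng.integers(n)]
        s_neg = score_fn(neg)
        return (-(s_pos - s_neg)).softplus()
    for trial in range(1, cfg.max_trials + 1):
        neg = negatives[rng.integers(n)]
        s_neg = score_fn(neg)
        if s_neg.item() + cfg.margin > s_pos.item():
            rank = max((n - 1) // trial, 1)
            hinge = (s_neg - s_pos + cfg.margin).relu()
            return warp_rank_weight(rank) * hinge
    return None


def train(kg: KnowledgeGraph, embeddings, catalogue, scorer_cfg: ScorerConfig,
          warp_cfg: WarpConfig | None = None, split: EdgeSplit | None = None,
          truth: GroundTruth | None = None,
          pair_scorer: PairScorer | None = None
          ) -> tuple[ScorerParams, pd.DataFrame]:
    """Train the path-attention scorer with the tiered ranking loss.

    *kg* should be the training graph (test asw edges removed).  Returns the
    trained parameters and a per-epoch loss history.  Deterministic given
    ``warp_cfg.seed``.
    """
    warp_cfg = warp_cfg or WarpConfig()
    if split is None:
        split = split_edges(kg)
    pairs = make_ranking_pairs(kg, split, truth)
    rng = np.random.default_rng(warp_cfg.seed)

    params = ScorerParams.init(scorer_cfg)
    scorer = pair_scorer or PairScorer(kg, embeddings, catalogue, scorer_cfg,
                                       params)
    scorer.params = params
    opt = Adam(params.parameters(), lr=warp_cfg.lr)

    w1, w2 = warp_cfg.tier_weights
    history_rows = []
    for epoch in range(warp_cfg.epochs):
        tasks: list[tuple[float, str, str, list[str]]] = []
        # tier 1: causal positive vs association negatives, capped per disease
        t1_by_d: dict[str, list[tuple[str, str, str]]] = {}
        for d, cg, ag in pairs.tier1:
            t1_by_d.setdefault(d, []).append((d, cg, ag))
        for d in sorted(t1_by_d):
            group = t1_by_d[d]
            assoc_pool = sorted({ag for _d, _cg, ag in group})
            causal_pool = sorted({cg for _d, cg, _ag in group})
            take = min(len(causal_pool) * 2, warp_cfg.max_pairs_per_disease)
            picks = rng.choice(len(causal_pool), size=take, replace=True)
            for pi in picks:
                tasks.append((w1, d, causal_pool[pi], assoc_pool))
        # tier 2: any positive vs unlinked negatives
        t2_by_d: dict[str, list[str]] = {}
        for d, g in pairs.tier2_positives:
            t2_by_d.setdefault(d, []).append(g)
        for d in sorted(t2_by_d):
            pool = pairs.negative_pool[d]
            if not pool:
                continue
            pos = t2_by_d[d]
            take = min(len(pos), warp_cfg.max_pairs_per_disease)
            picks = rng.choice(len(pos), size=take, replace=False)
            for pi in picks:
                tasks.append((w2, d, pos[pi], pool))

        order = rng.permutation(len(tasks))
        total, count = 0.0, 0
        batch_losses: list[Tensor] = []
        for oi in order:
            weight, d, pos_gene, neg_pool = tasks[oi]
            s_pos, _, _ = scorer.score_t(d, pos_gene)
            contrib = warp_step(
                s_pos, neg_pool,
                lambda g: scorer.score_t(d, g)[0], warp_cfg, rng)
            count += 1
            if contrib is None:
                continue
            batch_losses.append(weight * contrib)
            total += float(batch_losses[-1].item())
            if len(batch_losses) >= warp_cfg.batch_size:
                loss = batch_losses[0]
                for extra in batch_losses[1:]:
                    loss = loss + extra
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses = []
        if batch_losses:
            loss = batch_losses[0]
            for extra in batch_losses[1:]:
                loss = loss + extra
            opt.zero_grad()
            loss.backward()
            opt.step()
        history_rows.append({"epoch": epoch,
                             "mean_loss": total / max(count, 1),
                             "n_pairs": count})
    params.check_finite()
    history = pd.DataFrame(history_rows)
    return params, history
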