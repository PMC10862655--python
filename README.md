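# targetpath

Knowledge-graph path-attention models for disease–gene target
prioritization.

## The problem

Early drug discovery hinges on picking the right target gene for a disease.
A large fraction of the public evidence relevant to that choice lives in
heterogeneous *knowledge graphs* (KGs): typed networks whose nodes are
diseases (DI), genes (GE), compounds (CO), pathways (PW), anatomy (AN),
gene-ontology terms (GO), side effects (SE) and pharmacologic classes (PC),
and whose edges carry relations such as *associated* (`asw`), *treats*
(`trt`), *binds_to* (`bin`), *PPI* (`ppi`) or *upregulated_in* (`uri`).
Predicting a missing disease–gene association is then a link-prediction
problem — but a prediction a biologist can act on also needs *evidence*:
which mechanistic chains of relations support the call?

`targetpath` implements a complete, desk-scale version of this workflow:

1. **Typed KG** — an 8-metanode / 25-metaedge schema, TSV I/O, validation,
   and a metapath grammar (`DI = asw = GE = ppi = GE`).
2. **Quaternion embeddings (QuatE)** — every node/relation is a vector of
   quaternions; a triple (h, r, t) is scored as
   `Σₘ ⟨hₘ ⊗ rₘ/|rₘ|, tₘ⟩` (⊗ the Hamilton product), which can capture
   symmetric, antisymmetric and inverse relation patterns.  Embeddings are
   pre-trained with uniform negative corruption and then frozen.
3. **Metapath path evidence** — simple paths instantiating a curated
   metapath catalogue are extracted between the query disease and every
   candidate gene and scored with a degree-damped product
   `Π (deg(u)·deg(v))^(−w)`; the catalogue itself is selected from a
   candidate pool by ranking AUC (relevance) with a rank-correlation
   redundancy filter.
4. **Path-attention scorer** — each path's stacked node embeddings pass
   through a 1-D convolution and max-pool into a path vector; attention
   over paths (conditioned on query, target and metapath) merges them into
   a feature vector; a feed-forward head on [query ‖ target ‖ feature]
   emits the association score.
5. **Tiered WARP ranking** — training orders causal > associated > unlinked
   genes per disease with the weighted approximately ranked pairwise loss,
   `Φ(rank)·hinge` with `Φ(k) = Σᵢ₌₁..ₖ 1/i`; BPR is available.
6. **Evaluation** — per-disease average precision (AveP) and Prec@20 under
   a 50 % association-edge split (diseases with < 20 held-out edges are
   dropped from the test set), in *all-association* and *causal-only*
   ground-truth modes, against an embedding-only baseline and a random
   null, with PR curves and one-sided Wilcoxon comparisons.
7. **Evidence & triage** — attention-weighted evidence subgraphs (JSON /
   GraphML), top-decile cuts, per-subgraph conditions ("contains a certain
   gene", "has a certain metapath"), fold-change intersection (> 2-fold),
   and five-criteria target cards (biological relevance, disease causality,
   druggability, toxicity, novelty).

Because no public full-scale KG ships with the package, a first-class
synthetic generator (`targetpath.synthetic`) emulates the schema with
planted per-disease causal/association gene modules and mechanistic support
paths, so the whole pipeline is testable end to end.

## Worked example

```python
from targetpath import AssociationModel, QuatEConfig, WarpConfig
from targetpath.synthetic import SyntheticConfig, generate

cfg = SyntheticConfig(seed=3)               # shrink for a quick demo
cfg.node_counts = dict(cfg.node_counts, DI=8, GE=300, CO=60, PW=40,
                       AN=10, GO=30, SE=15, PC=5)
cfg.background_edges = {k: max(1, v // 5)
                        for k, v in cfg.background_edges.items()}
kg, truth = generate(cfg)

model = AssociationModel(kg, truth=truth, seed=7,
                         quate_config=QuatEConfig(epochs=5, k=8, seed=11),
                         warp_config=WarpConfig(epochs=2, seed=12),
                         select_max_count=6)
res = model.fit()
res.evaluate("all_association"); res.baseline_evaluate("all_association")
print(res.summary())
```

prints

```
Association model fit
====================================================
nodes: 468   edges: 3670
train asw edges: 196   test asw edges: 221
retained diseases: 8
catalogue metapaths: 6
embedding dim: 32 (k=8 quaternions)
training epochs: 2   final mean loss: 4.2190
baseline (all_association): mean AveP 0.1431, mean Prec@20 0.1313
model (all_association): mean AveP 0.1904, mean Prec@20 0.2062
```

The path-attention model (mean AveP 0.190) outranks the embedding-only
baseline (0.143): path evidence adds signal beyond the embeddings alone.
Ranked target cards and their evidence follow the same results object:

```python
d = res.split.retained_diseases[0]
cards = res.rank_targets(d, top_n=5)       # five-criteria target cards
sg = res.evidence(d, cards[0].gene)        # attention-weighted subgraph
```

```
evidence paths for DI0000 -> GE0075: 4
  w=0.290  DI0000 - GE0051 - PW0009 - GE0075  [DI = asw = GE = inv = PW = inv = GE]
  w=0.238  DI0000 - GE0051 - PW0028 - GE0075  [DI = asw = GE = inv = PW = inv = GE]
  ...
```

Each line is one mechanistic chain supporting the prediction — here the
candidate shares pathways with genes already associated with the disease —
with its attention weight `w`.

A `targetpath` console script exposes the same pipeline stage by stage
(`simulate`, `pretrain`, `select-metapaths`, `train`, `evaluate`, `rank`,
`prioritize`, `evidence`, `pipeline`) over an artifact directory; see
`targetpath --help`.

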