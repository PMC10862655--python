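# Methods

This note documents the models, default parameters, numerical choices and
limitations of `targetpath`.  It is written for a reader who wants to know
exactly what the package computes and why the defaults are what they are.

## Typed knowledge graph and schema

The bundled schema declares 8 metanodes (CO, DI, GE, GO, PW, AN, SE, PC)
and 25 metaedges.  The relation vocabulary mirrors what multi-source
biomedical KGs typically carry: disease–gene association (`asw`, the only
*causal-capable* relation — its individual edges may be flagged causal),
disease co-mention (`mnw`), expression changes of genes in diseases
(`uri`/`dri`) and by compounds (`urb`/`drb`), treatment (`trt`), binding
(`bin`), anatomy occurrence (`oci`), pathway membership (`inv`),
protein–protein interaction (`ppi`, undirected) and transcription-factor
regulation (`pdi`, directed), plus tissue expression, covariation,
side-effect, pharmacologic-class, three GO-annotation and four
perturbation (knockdown/overexpression) relations.  `urb`/`drb` are
declared gene–compound only; disease-side expression change is carried by
`uri`/`dri`, keeping metaedge codes unique.

Edges are deduplicated on their (head, metaedge, tail) triple — undirected
edges after normalizing endpoint order — with `causal=True` surviving
deduplication, since overlapping sources routinely report the same relation.

A *metapath* is a typed template (`DI = asw = GE = ppi = GE`); `=` marks an
undirected step, `>`/`<` a directed step traversed forward/backward.  The
parser and formatter are exact inverses on every valid metapath.

## QuatE embeddings

Every node and relation is a length-k vector of quaternions (k = 32 by
default, i.e. a 128-dimensional real feature per node).  A triple (h, r, t)
scores

    s(h, r, t) = Σ_{m=1..k} ⟨ h_m ⊗ r_m/|r_m| , t_m ⟩ ,

the 4-component inner product of the tail with the head rotated by the
unit-normalized relation.  Rotation by a unit quaternion preserves norms and
is non-commutative, which is what lets the score express symmetric,
antisymmetric and inverse relation patterns (verified by property tests:
Hamilton identities to 1e-9; a strictly antisymmetric toy relation is
ranked correctly in > 90 % of pairs after training).

Training: softplus logistic loss `softplus(−s_pos) + softplus(s_neg)` over
observed triples vs 10 uniformly corrupted negatives per positive (head or
tail replaced; corruptions that recreate an observed triple are discarded),
L2 regularization 1e-4 on batch embeddings, Adam (lr 0.02), batch 2048,
20 epochs, all seeded.  Gradients use the closed forms
`∂s/∂h = t ⊗ ū`, `∂s/∂t = h ⊗ u`, `∂s/∂u = h̄ ⊗ t` with the unit-sphere
projection `(I − uuᵀ)/|r|` for the normalization.  Embeddings are **frozen**
after pre-training; the scorer never fine-tunes them.  In the benchmark
pipeline pre-training runs on the training graph (test association edges
removed), so the embedding-only baseline is leakage-free.

## Path extraction and catalogue selection

Evidence paths are *simple* (no repeated node) instantiations of catalogue
metapaths, enumerated depth-first over the typed adjacency with
lexicographic neighbor order (deterministic).  Simple paths avoid degenerate
back-and-forth walks on undirected metaedges.

Default path score: the degree-damped product
`Π_steps (deg(u, metaedge) · deg(v, metaedge))^(−w)` with w = 0.4 —
step-degrees are restricted to the step's metaedge (type-aware damping), and
hub-mediated paths are down-weighted.  An alternative `kge_plausibility`
score multiplies `sigmoid(QuatE score)` over the path's edges.  Per
metapath, the top-k = 5 paths per pair are kept.

Catalogue selection: for each candidate metapath the per-pair feature is
the sum of its top-k path scores; *relevance* is the ranking AUC of that
feature on known positive pairs vs an equal number of uniformly sampled
negative disease–gene pairs; candidates are accepted by descending
relevance unless their feature's Spearman correlation with an
already-accepted feature exceeds 0.9 (redundancy), up to a maximum
catalogue size (20 by default; 8 in the benchmark pipeline).  Selection
runs on the full graph with causal association pairs as positives: the
catalogue is a design-time input fixed before any train/test split, like
the schema itself, and causal edges are the highest-confidence labels.
The bundled 20-template candidate pool covers co-mention,
expression-change, compound-bridge, pathway-co-membership and interaction
chains from disease to gene.

## Path-attention scorer

For one (disease, gene) pair with extracted paths p₁..p_P:

1. **Path encoding** — stack the frozen node embedding vectors of the
   path's L nodes into an L×d matrix (d = 4k), apply a width-2 1-D
   convolution along the sequence (64 channels), ReLU, and global max-pool
   over positions → one 64-vector per path, independent of L.
2. **Attention merge** — each path vector is concatenated with a learned
   16-dimensional metapath embedding (indexed by catalogue position) and
   the query/target node vectors; a one-hidden-layer ReLU network maps the
   concatenation to a logit; softmax over paths gives the attention
   weights; the feature vector is the weighted sum of a linear value
   projection of [path vector ‖ metapath embedding].  A pair with no paths
   uses a learned *no-evidence* vector.
3. **Score head** — a (128, 64) ReLU feed-forward network on
   [query ‖ target ‖ feature] outputs the scalar score.

Layer sizes, the ReLU nonlinearity, max-pooling and the projected
concatenation as the attention "value" are package choices, all
configurable through `ScorerConfig`.  Contracts verified by tests:
attention weights are non-negative and sum to 1 (1e-9); the score is
invariant to path order (1e-6); analytic gradients of the full forward pass
match central finite differences to 1e-4 relative.

All neural computation runs on a small in-house reverse-mode autodiff
engine over numpy (`targetpath.autograd`): ~15 primitive operations with
numpy-broadcasting-aware backward passes, gather/scatter-add for embedding
lookups, and an Adam optimizer.  The model sizes involved (10⁴–10⁵
parameters) do not warrant a framework dependency.

## Ranking objective (tiered WARP)

Training pairs come in two tiers per disease, built from *training* edges
only: (1) a causally linked gene should outscore a merely associated gene;
(2) an associated gene should outscore a gene with no association at all.
Held-out positives are never sampled as negatives.  Both tiers are weighted
equally by default.

For a positive with score s⁺, WARP samples negatives uniformly with
replacement until one violates the margin (s⁻ + 1 > s⁺) or 50 trials are
reached; with a violator on trial T among N candidates the estimated rank is
`floor((N−1)/T)` and the contribution is `Φ(max(rank, 1)) · max(0, 1 − s⁺ +
s⁻)` with `Φ(k) = Σ_{i=1..k} 1/i` — early violators imply a badly ranked
positive and get the large harmonic weight.  BPR
(`−log σ(s⁺ − s⁻)`) is available as an alternative.  Optimization is Adam
(lr 1e-3) over mini-batches of 8 pair losses; per epoch, positives are
subsampled to at most 30 per disease per tier to bound cost.  Defaults:
5 epochs.  Everything is seeded and reruns are bit-identical.

## Evaluation protocol

Association (`asw`) edges are split per disease: each edge goes to the test
set independently with probability 0.5; diseases with fewer than 20 sampled
test edges are dropped from the test set and their sampled edges returned
to training (the protocol retains the data; only the disease leaves the
evaluation).  Per retained disease the candidate list is all genes minus
that disease's training positives — training associations are removed
entirely from every evaluation case, so leakage into the candidate ranking
is impossible by construction.  Metrics: AveP (mean precision at the ranks
of retrieved relevant items, normalized by retrieved relevant count) and
Prec@20 (denominator fixed at 20), under *all-association* and
*causal-only* ground truth (diseases without causal test edges are skipped
in the latter — the metric is undefined for them, and scoring them zero
would conflate absence of labels with failure).  Ties are broken by gene id
for reproducibility.  Comparisons between methods use the one-sided
Wilcoxon signed-rank test on per-disease AveP with zero differences
dropped.  PR curves report precision/recall at every distinct score
threshold.

## Synthetic benchmark

The generator emulates the *structure* the method exploits, not any
particular database.  Default study conditions: 40 diseases, 1 500 genes,
200 compounds, 120 pathways, 30 anatomy, 150 GO, 50 side-effect and 20
class nodes.  Each disease receives a module of 8 causal and 25 associated
genes (`asw` edges, causal flagged); each causal gene receives 3 planted
support paths per template for three templates — an interaction partner
inside the module, pathway co-membership with a module gene, and a
treating-compound bridge; association genes receive the same support with
probability 0.3, which makes the causal/association tiers separable but not
trivially.  Three support paths per template (rather than one) keep the
planted signal detectable after the 50 % edge split removes roughly half of
the partner association edges a support path relies on.  Background edges
are drawn uniformly over type-valid endpoint pairs per metaedge (the
simplest exchangeable null; ~8 000 edges at the default rate, including
~900 background associations so that diseases average ~55 `asw` edges and
nearly all survive the 20-test-edge retention rule).  One master seed
drives node sampling, module assignment, planting and background placement
in a fixed order, so equal configs produce byte-identical TSVs.

What passing on this benchmark shows: the pipeline recovers planted
mechanistic signal (metapath selection AUC, tier ordering) and path
evidence adds ranking power over frozen embeddings alone.  What it does not
show: performance on real KGs, whose degree distributions are heavy-tailed,
whose relations are correlated in source-specific ways, and whose causal
annotations are sparse and biased — none of which the exchangeable
background emulates.

## Problem sizes and runtime

The acceptance run (`scripts/acceptance.py`) uses the default benchmark
above: QuatE k = 32 for ~2 100 nodes / ~18 000 edges, an 8-metapath
catalogue selected from the 20-template pool, 5 WARP epochs, and evaluation
over ~39 retained diseases × ~1 470 candidates; it completes in a few
minutes on one CPU.  The per-disease path cache (top-k scored paths to
every reachable gene, computed once per disease per metapath) is what keeps
training and evaluation affordable.

## Known limitations

* The five prioritization criteria are transparent graph/model proxies
  (binding-partner counts, side-effect adjacency, association-degree
  novelty, attention-weighted causal-edge mass); real deployments would
  substitute curated tractability/safety sources via the per-criterion
  override hooks.
* The degree-damped path score and the relevance/redundancy selection
  objective are reasonable defaults, kept pluggable
  (`PathScoreConfig.method`, `select_metapaths` arguments); other scoring
  choices are defensible.
* Path enumeration is exact and exhaustive per metapath with a global cap;
  on much denser graphs an approximate traversal would be needed.
* The scorer's attention merge normalizes over paths, so the *amount* of
  evidence enters only through the score head's use of the feature vector,
  not as an explicit count.
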