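"""Path-attention association scorer.

The network scores a (disease, gene) pair from its path evidence:

1. each extracted path is encoded by stacking the (frozen) embedding vectors
   of its nodes into an L x d matrix, applying a 1-D convolution along the
   sequence with ReLU, and global max-pooling over positions -> a
   fixed-length *path vector*;
2. path vectors are concatenated with a learned metapath embedding and the
   query/target node vectors, a small feed-forward map produces one logit
   per path, and a softmax over paths yields attention weights; the *feature
   vector* is the attention-weighted sum of value-projected path
   representations (a learned no-evidence vector stands in when the pair has
   no paths);
3. a feed-forward head on [query || target || feature] emits the scalar
   association score.

Query and target vectors are the pre-trained QuatE node embeddings and are
never fine-tuned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigError, InputError, ShapeError
from .graph import KnowledgeGraph
from .metapath import Metapath
from .pathing import (MetapathCatalogue, Path, PathCache, PathScoreConfig,
                      build_path, enumerate_paths, score_walk, top_k_paths)
from .quate import QuaternionEmbeddingSet

__all__ = ["ScorerConfig", "ScorerParams", "ScoredPair", "PairScorer",
           "encode_path", "attention_merge", "predict", "forward"]

_NEG_INF = -1e9


@dataclass
class ScorerConfig:
    """Architecture hyperparameters.  ``input_dim`` must equal the flattened
    embedding dimension 4k."""

    input_dim: int
    n_metapaths: int
    channels: int = 64
    filter_width: int = 2
    mp_dim: int = 16
    attn_hidden: int = 64
    head_hidden: tuple[int, int] = (128, 64)
    max_paths: int | None = None    #: P; defaults to n_metapaths * top_k
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "n_metapaths", "channels", "mp_dim",
                     "attn_hidden"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not (1 <= self.filter_width <= 2):
            raise ConfigError("filter_width must be 1 or 2 (shortest path has "
                              "2 nodes)")


def _glorot(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class ScorerParams:
    """Learnable weights; a flat name -> Tensor mapping."""

    def __init__(self, tensors: dict[str, Tensor], config: ScorerConfig):
        self.tensors = tensors
        self.config = config

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def parameters(self) -> list[Tensor]:
        return [self.tensors[k] for k in sorted(self.tensors)]

    @classmethod
    def init(cls, config: ScorerConfig) -> "ScorerParams":
        rng = np.random.default_rng(config.seed)
        d, C = config.input_dim, config.channels
        M, H = config.mp_dim, config.attn_hidden
        H1, H2 = config.head_hidden
        F = C  # feature dim after value projection
        a_in = C + M + 2 * d
        v_in = C + M
        h_in = 2 * d + F
        t = {}
        for j in range(config.filter_width):
            t[f"conv_w{j}"] = Tensor(_glorot(rng, d * config.filter_width, C, (d, C)),
                                     requires_grad=True)
        t["conv_b"] = Tensor(np.zeros(C), requires_grad=True)
        t["mp_emb"] = Tensor(rng.normal(0.0, 0.1, size=(config.n_metapaths, M)),
                             requires_grad=True)
        t["attn_w"] = Tensor(_glorot(rng, a_in, H, (a_in, H)), requires_grad=True)
        t["attn_b"] = Tensor(np.zeros(H), requires_grad=True)
        t["attn_v"] = Tensor(_glorot(rng, H, 1, (H, 1)), requires_grad=True)
        t["attn_c"] = Tensor(np.zeros(1), requires_grad=True)
        t["val_w"] = Tensor(_glorot(rng, v_in, F, (v_in, F)), requires_grad=True)
        t["val_b"] = Tensor(np.zeros(F), requires_grad=True)
        t["no_evidence"] = Tensor(rng.normal(0.0, 0.1, size=F), requires_grad=True)
        t["head_w1"] = Tensor(_glorot(rng, h_in, H1, (h_in, H1)), requires_grad=True)
        t["head_b1"] = Tensor(np.zeros(H1), requires_grad=True)
        t["head_w2"] = Tensor(_glorot(rng, H1, H2, (H1, H2)), requires_grad=True)
        t["head_b2"] = Tensor(np.zeros(H2), requires_grad=True)
        t["head_w3"] = Tensor(_glorot(rng, H2, 1, (H2, 1)), requires_grad=True)
        t["head_b3"] = Tensor(np.zeros(1), requires_grad=True)
        return cls(t, config)

    def check_finite(self) -> None:
        for name, t in self.tensors.items():
            if not np.all(np.isfinite(t.data)):
                raise ShapeError(f"non-finite values in parameter {name!r}")

    def save(self, path, config_path=None) -> None:
        np.savez(path, **{k: v.data for k, v in self.tensors.items()})
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump({"input_dim": self.config.input_dim,
                           "n_metapaths": self.config.n_metapaths,
                           "channels": self.config.channels,
                           "filter_width": self.config.filter_width,
                           "mp_dim": self.config.mp_dim,
                           "attn_hidden": self.config.attn_hidden,
                           "head_hidden": list(self.config.head_hidden),
                           "max_paths": self.config.max_paths,
                           "seed": self.config.seed,
                           "format_version": 1}, fh, indent=1)

    @classmethod
    def load(cls, path, config: ScorerConfig | None = None,
             config_path=None) -> "ScorerParams":
        if config is None:
            with open(config_path) as fh:
                doc = json.load(fh)
            doc.pop("format_version", None)
            doc["head_hidden"] = tuple(doc["head_hidden"])
            config = ScorerConfig(**doc)
        with np.load(path) as z:
            tensors = {k: Tensor(z[k], requires_grad=True) for k in z.files}
        return cls(tensors, config)


@dataclass
class ScoredPair:
    """Model output for one disease-gene pair: score, per-path attention
    weights (non-negative, summing to 1 when paths exist) and the paths."""

    query: str
    target: str
    score: float
    attention: np.ndarray
    paths: list[Path] = field(default_factory=list)


# -- building blocks (autograd) --------------------------------------------

def _encode_batch(node_mats: np.ndarray, lengths: np.ndarray,
                  params: ScorerParams) -> Tensor:
    """Encode padded path node matrices (P, Lmax, d) into path vectors (P, C)."""
    P, Lmax, d = node_mats.shape
    width = params.config.filter_width
    n_pos = Lmax - width + 1
    pos_list = []
    for t in range(n_pos):
        h = Tensor(node_mats[:, t, :]) @ params["conv_w0"]
        for j in range(1, width):
            h = h + Tensor(node_mats[:, t + j, :]) @ params[f"conv_w{j}"]
        h = h + params["conv_b"]
        pos_list.append(h.reshape(P, 1, -1))
    stacked = ag.concatenate(pos_list, axis=1).relu()    # (P, n_pos, C)
    mask = np.zeros((P, n_pos, 1))
    for i, L in enumerate(lengths):
        mask[i, max(L - width + 1, 1):, :] = _NEG_INF
    return (stacked + Tensor(mask)).max(axis=1)          # (P, C)


def _attention_t(path_vecs: Tensor, mp_ids: np.ndarray, query_vec: np.ndarray,
                 target_vec: np.ndarray, params: ScorerParams
                 ) -> tuple[Tensor, Tensor]:
    """(feature vector (F,), attention weights (P,)) for a non-empty path set."""
    P = path_vecs.shape[0]
    mp_e = ag.take(params["mp_emb"], mp_ids)                       # (P, M)
    q = np.broadcast_to(query_vec, (P, query_vec.size))
    t = np.broadcast_to(target_vec, (P, target_vec.size))
    ctx = ag.concatenate([path_vecs, mp_e, Tensor(q), Tensor(t)], axis=1)
    hidden = (ctx @ params["attn_w"] + params["attn_b"]).relu()
    logits = hidden @ params["attn_v"] + params["attn_c"]          # (P, 1)
    weights = ag.softmax(logits, axis=0)                           # (P, 1)
    vals = ag.concatenate([path_vecs, mp_e], axis=1) @ params["val_w"] \
        + params["val_b"]                                          # (P, F)
    feature = (weights * vals).sum(axis=0)                         # (F,)
    return feature, weights.reshape(P)


def _predict_t(query_vec: np.ndarray, target_vec: np.ndarray,
               feature: Tensor, params: ScorerParams) -> Tensor:
    x = ag.concatenate(
        [Tensor(query_vec), Tensor(target_vec), feature], axis=0)
    x = x.reshape(1, -1)
    h = (x @ params["head_w1"] + params["head_b1"]).relu()
    h = (h @ params["head_w2"] + params["head_b2"]).relu()
    out = h @ params["head_w3"] + params["head_b3"]
    return out.reshape(())


# -- public single-shot operations -----------------------------------------

def encode_path(path: Path, embeddings: QuaternionEmbeddingSet,
                params: ScorerParams) -> np.ndarray:
    """Path vector of a single path (conv + ReLU + global max-pool)."""
    mat = np.stack([embeddings.node_vector(n) for n in path.node_ids])
    out = _encode_batch(mat[None], np.array([len(path.node_ids)]), params)
    return out.data[0]


def attention_merge(path_vectors: np.ndarray, metapath_ids: np.ndarray,
                    query_vec: np.ndarray, target_vec: np.ndarray,
                    params: ScorerParams) -> tuple[np.ndarray, np.ndarray]:
    """Merge path vectors into one feature vector by context attention.

    Returns ``(feature, weights)``; an empty path list yields the learned
    no-evidence vector and an empty weight array.
    """
    path_vectors = np.asarray(path_vectors, dtype=float)
    metapath_ids = np.asarray(metapath_ids, dtype=int)
    if len(path_vectors) != len(metapath_ids):
        raise InputError("path_vectors and metapath_ids length mismatch")
    if len(path_vectors) == 0:
        return params["no_evidence"].data.copy(), np.zeros(0)
    feature, weights = _attention_t(Tensor(path_vectors), metapath_ids,
                                    np.asarray(query_vec, dtype=float),
                                    np.asarray(target_vec, dtype=float), params)
    return feature.data, weights.data


def predict(query_vec: np.ndarray, target_vec: np.ndarray,
            feature_vec: np.ndarray, params: ScorerParams) -> float:
    """Scalar association score from query, target and feature vectors."""
    d = params.config.input_dim
    q = np.asarray(query_vec, dtype=float)
    t = np.asarray(target_vec, dtype=float)
    f = np.asarray(feature_vec, dtype=float)
    if q.size != d or t.size != d or f.size != params.config.channels:
        raise ShapeError(
            f"expected dims (q={d}, t={d}, f={params.config.channels}), got "
            f"({q.size}, {t.size}, {f.size})")
    return float(_predict_t(q, t, Tensor(f), params).item())


class PairScorer:
    """Binds graph, embeddings, catalogue and parameters into a pair-scoring
    callable; reuses a :class:`~targetpath.pathing.PathCache` so each
    disease's path extraction runs once."""

    def __init__(self, kg: KnowledgeGraph, embeddings: QuaternionEmbeddingSet,
                 catalogue: MetapathCatalogue | list[Metapath],
                 config: ScorerConfig, params: ScorerParams,
                 score_cfg: PathScoreConfig | None = None,
                 cache: PathCache | None = None):
        self.kg = kg
        self.embeddings = embeddings
        self.metapaths = (catalogue.metapaths
                          if isinstance(catalogue, MetapathCatalogue)
                          else list(catalogue))
        self.config = config
        self.params = params
        self.score_cfg = score_cfg or PathScoreConfig()
        self.cache = cache or PathCache(kg, self.metapaths, self.score_cfg,
                                        embeddings=embeddings)
        self._vec_cache: dict[str, np.ndarray] = {}

    def _vec(self, node_id: str) -> np.ndarray:
        v = self._vec_cache.get(node_id)
        if v is None:
            v = self.embeddings.node_vector(node_id)
            self._vec_cache[node_id] = v
        return v

    @property
    def max_paths(self) -> int:
        if self.config.max_paths is not None:
            return self.config.max_paths
        return len(self.metapaths) * self.score_cfg.top_k

    def entries(self, query: str, target: str) -> list[tuple[int, tuple[str, ...], float]]:
        return self.cache.get(query, target)[: self.max_paths]

    def score_t(self, query: str, target: str) -> tuple[Tensor, Tensor | None,
                                                        list[tuple[int, tuple[str, ...], float]]]:
        """Differentiable score; returns (score Tensor, attention Tensor or
        None, path entries)."""
        entries = self.entries(query, target)
        q = self._vec(query)
        tv = self._vec(target)
        if not entries:
            feature: Tensor = self.params["no_evidence"]
            weights = None
        else:
            Lmax = max(len(e[1]) for e in entries)
            mats = np.zeros((len(entries), Lmax, self.config.input_dim))
            lengths = np.zeros(len(entries), dtype=int)
            for i, (_mi, nodes, _s) in enumerate(entries):
                for j, n in enumerate(nodes):
                    mats[i, j] = self._vec(n)
                lengths[i] = len(nodes)
            path_vecs = _encode_batch(mats, lengths, self.params)
            mp_ids = np.array([e[0] for e in entries], dtype=int)
            feature, weights = _attention_t(path_vecs, mp_ids, q, tv, self.params)
        score = _predict_t(q, tv, feature, self.params)
        return score, weights, entries

    def score(self, query: str, target: str) -> float:
        score, _, _ = self.score_t(query, target)
        return float(score.item())

    def scored_pair(self, query: str, target: str) -> ScoredPair:
        """Full forward pass returning the evidence-carrying result."""
        score, weights, entries = self.score_t(query, target)
        attention = weights.data.copy() if weights is not None else np.zeros(0)
        paths = [build_path(self.kg, self.metapaths[mi], nodes, score=s)
                 for mi, nodes, s in entries]
        return ScoredPair(query=query, target=target, score=float(score.item()),
                          attention=attention, paths=paths)


def forward(kg: KnowledgeGraph, embeddings: QuaternionEmbeddingSet,
            catalogue: MetapathCatalogue | list[Metapath], cfg: ScorerConfig,
            params: ScorerParams, query: str, target: str,
            score_cfg: PathScoreConfig | None = None) -> ScoredPair:
    """One-shot forward pass: extract paths (top-k per catalogue metapath),
    encode, attention-merge and score.  For repeated calls construct a
    :class:`PairScorer` instead."""
    return PairScorer(kg, embeddings, catalogue, cfg, params,
                      score_cfg=score_cfg).scored_pair(query, target)
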