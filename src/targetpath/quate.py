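"""Quaternion knowledge-graph embeddings (QuatE).

Entities and relations are represented as vectors of quaternions.  A triple
``(h, r, t)`` is scored by rotating the head by the unit-normalized relation
(Hamilton product) and taking the 4-component inner product with the tail,

    score(h, r, t) = sum_m < h_m (x) r_m / |r_m| , t_m >,

which can express symmetric, antisymmetric and inverse relation patterns.
Training maximizes observed-triple scores against uniformly corrupted
negatives under a softplus logistic loss with L2 regularization.

Embeddings are *frozen* after pre-training: the downstream path-attention
scorer consumes them as fixed node features and never fine-tunes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Adam, Tensor
from .errors import DomainError, InputError, KGLookupError, ShapeError
from .graph import KnowledgeGraph

__all__ = ["hamilton", "normalize", "quate_score", "QuatEConfig",
           "QuaternionEmbeddingSet", "train_quate"]


def _check_quat(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 4:
        raise ShapeError(f"{name} must have last dimension 4, got {x.shape}")
    return x


def hamilton(p, q) -> np.ndarray:
    """Hamilton product of quaternion arrays with shape ``(..., 4)``.

    Components are ``(a, b, c, d)`` for ``a + b i + c j + d k``.  The product
    is non-commutative: ``i (x) j = k`` but ``j (x) i = -k``.
    """
    p = _check_quat(p, "p")
    q = _check_quat(q, "q")
    a1, b1, c1, d1 = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    a2, b2, c2, d2 = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    out = np.empty(np.broadcast_shapes(p.shape, q.shape))
    out[..., 0] = a1 * a2 - b1 * b2 - c1 * c2 - d1 * d2
    out[..., 1] = a1 * b2 + b1 * a2 + c1 * d2 - d1 * c2
    out[..., 2] = a1 * c2 - b1 * d2 + c1 * a2 + d1 * b2
    out[..., 3] = a1 * d2 + b1 * c2 - c1 * b2 + d1 * a2
    return out


def normalize(q) -> np.ndarray:
    """Scale quaternions to unit norm.  Zero quaternions are a domain error."""
    q = _check_quat(q, "q")
    norm = np.sqrt((q * q).sum(axis=-1, keepdims=True))
    if np.any(norm == 0.0):
        raise DomainError("cannot normalize a zero quaternion")
    return q / norm


def quate_score(h, r, t) -> np.ndarray | float:
    """QuatE triple score: ``sum_m <h_m (x) r_m/|r_m|, t_m>``.

    Accepts ``(k, 4)`` arrays or batches ``(..., k, 4)``; returns a scalar or
    an array of batch shape.
    """
    h = _check_quat(h, "h")
    r = _check_quat(r, "r")
    t = _check_quat(t, "t")
    if not (h.shape == t.shape and h.shape[-2:] == r.shape[-2:]):
        raise ShapeError(f"shape mismatch: h{h.shape} r{r.shape} t{t.shape}")
    rotated = hamilton(h, normalize(r))
    out = (rotated * t).sum(axis=(-2, -1))
    return float(out) if out.ndim == 0 else out


# -- fused autograd op used in training ------------------------------------

def _conj(q: np.ndarray) -> np.ndarray:
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def _score_t(h: Tensor, r: Tensor, t: Tensor) -> Tensor:
    """Differentiable batched QuatE score with analytic gradients.

    Uses <p (x) q, s> = <p, s (x) conj(q)> = <q, conj(p) (x) s> to express the
    gradients as Hamilton products, and the unit-sphere projection
    (I - u u^T)/|r| for the relation normalization.
    """
    norm = np.sqrt((r.data ** 2).sum(axis=-1, keepdims=True)) + 1e-12
    u = r.data / norm
    rotated = hamilton(h.data, u)
    score = (rotated * t.data).sum(axis=(-2, -1))

    def bw(g):
        gg = g[..., None, None]     # broadcast over (k, 4)
        if h.requires_grad:
            h._accum(gg * hamilton(t.data, _conj(u)))
        if t.requires_grad:
            t._accum(gg * rotated)
        if r.requires_grad:
            gu = gg * hamilton(_conj(h.data), t.data)
            gr = (gu - (gu * u).sum(axis=-1, keepdims=True) * u) / norm
            r._accum(gr)
    return Tensor._make(score, (h, r, t), bw)


@dataclass
class QuatEConfig:
    """Pre-training hyperparameters (standard QuatE recipe)."""

    k: int = 32                 #: quaternions per entity (feature dim = 4k)
    lr: float = 0.02
    epochs: int = 20
    negatives: int = 10         #: corrupted triples per observed triple
    reg: float = 1e-4           #: L2 weight on batch embeddings
    batch_size: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be >= 1")
        if self.negatives < 1:
            raise InputError("negatives must be >= 1")


@dataclass
class QuaternionEmbeddingSet:
    """Frozen per-node and per-relation quaternion vectors."""

    entity_ids: tuple[str, ...]
    entities: np.ndarray          #: (n_entities, k, 4)
    relation_codes: tuple[str, ...]
    relations: np.ndarray         #: (n_relations, k, 4)
    history: list[float] = field(default_factory=list)
    _eindex: dict = field(init=False, repr=False, default=None)
    _rindex: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._eindex = {e: i for i, e in enumerate(self.entity_ids)}
        self._rindex = {r: i for i, r in enumerate(self.relation_codes)}

    @property
    def k(self) -> int:
        return self.entities.shape[1]

    @property
    def dim(self) -> int:
        """Flattened per-node feature dimension (4k)."""
        return 4 * self.k

    def has_node(self, node_id: str) -> bool:
        return node_id in self._eindex

    def node_index(self, node_id: str) -> int:
        try:
            return self._eindex[node_id]
        except KeyError:
            raise KGLookupError(f"no embedding for node {node_id!r}") from None

    def node_quaternions(self, node_id: str) -> np.ndarray:
        return self.entities[self.node_index(node_id)]

    def node_vector(self, node_id: str) -> np.ndarray:
        return self.node_quaternions(node_id).reshape(-1)

    def relation_quaternions(self, code: str) -> np.ndarray:
        try:
            return self.relations[self._rindex[code]]
        except KeyError:
            raise KGLookupError(f"no embedding for relation {code!r}") from None

    def score_triple(self, head: str, code: str, tail: str) -> float:
        return quate_score(self.node_quaternions(head),
                           self.relation_quaternions(code),
                           self.node_quaternions(tail))

    def score_one_to_many(self, head: str, code: str, tails) -> np.ndarray:
        """Vectorized scores of (head, code, tail) over many tails."""
        h = self.node_quaternions(head)[None]
        r = self.relation_quaternions(code)[None]
        idx = [self.node_index(t) for t in tails]
        t = self.entities[idx]
        return quate_score(np.broadcast_to(h, t.shape), r, t)

    def save(self, path) -> None:
        np.savez(
            path,
            entity_ids=np.array(self.entity_ids),
            entities=self.entities.astype(np.float32),
            relation_codes=np.array(self.relation_codes),
            relations=self.relations.astype(np.float32),
        )

    @classmethod
    def load(cls, path) -> "QuaternionEmbeddingSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                entity_ids=tuple(str(e) for e in z["entity_ids"]),
                entities=z["entities"].astype(np.float64),
                relation_codes=tuple(str(r) for r in z["relation_codes"]),
                relations=z["relations"].astype(np.float64),
            )


def train_quate(kg: KnowledgeGraph,
                config: QuatEConfig | None = None) -> QuaternionEmbeddingSet:
    """Pre-train QuatE embeddings on all edges of *kg*.

    Negatives are drawn by uniformly corrupting the head or the tail of each
    observed triple; the loss is ``softplus(-s_pos) + softplus(s_neg)`` plus
    L2 regularization.  Deterministic given ``config.seed``.
    """
    config = config or QuatEConfig()
    if kg.n_edges == 0:
        raise InputError("cannot train embeddings on an empty graph")
    rng = np.random.default_rng(config.seed)

    entity_ids = tuple(sorted(kg.nodes))
    relation_codes = tuple(m.code for m in kg.schema.metaedges)
    eindex = {e: i for i, e in enumerate(entity_ids)}
    rindex = {r: i for i, r in enumerate(relation_codes)}
    triples = np.array(
        sorted((eindex[e.head], rindex[e.metaedge], eindex[e.tail])
               for e in kg.edges),
        dtype=np.int64,
    )
    n_ent = len(entity_ids)
    k = config.k

    scale = 0.5 / np.sqrt(k)
    E = Tensor(rng.normal(0.0, scale, size=(n_ent, k, 4)), requires_grad=True)
    R = Tensor(rng.normal(0.0, scale, size=(len(relation_codes), k, 4)),
               requires_grad=True)
    opt = Adam([E, R], lr=config.lr)

    history: list[float] = []
    n = len(triples)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = triples[order[start:start + config.batch_size]]
            b = len(batch)
            orig = np.repeat(batch, config.negatives, axis=0)
            neg = orig.copy()
            corrupt_head = rng.random(len(neg)) < 0.5
            rand_ent = rng.integers(n_ent, size=len(neg))
            neg[corrupt_head, 0] = rand_ent[corrupt_head]
            neg[~corrupt_head, 2] = rand_ent[~corrupt_head]
            # discard corruptions that recreate the observed triple
            neg = neg[(neg != orig).any(axis=1)]
            if len(neg) == 0:
                continue

            h = ag.take(E, batch[:, 0])
            r = ag.take(R, batch[:, 1])
            t = ag.take(E, batch[:, 2])
            hn = ag.take(E, neg[:, 0])
            rn = ag.take(R, neg[:, 1])
            tn = ag.take(E, neg[:, 2])
            s_pos = _score_t(h, r, t)
            s_neg = _score_t(hn, rn, tn)
            loss = (
                (-s_pos).softplus().mean()
                + s_neg.softplus().mean()
                + config.reg * ((h * h).sum() + (t * t).sum()
                                + (r * r).sum()) * (1.0 / b)
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * b
        history.append(epoch_loss / n)

    return QuaternionEmbeddingSet(
        entity_ids=entity_ids,
        entities=E.data.copy(),
        relation_codes=relation_codes,
        relations=R.data.copy(),
        history=history,
    )
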