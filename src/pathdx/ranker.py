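"""Recursive path embeddings and attention-based path scoring.

A path ``p = {v_1, e_1, v_2, ...}`` starts as its source node's
embedding and is extended hop by hop through a feedforward aggregator
over ``[previous path embedding ; relation one-hot ; next node
embedding]``.  Two scorers rate a path against the patient context
(note embedding ``h_x`` and source-concept-list embedding ``h_v``):

* **MultiAttn** — builds the context relevancy matrix
  ``H = [h_x; p; h_x - p; h_x * p]`` and the concept relevancy matrix
  ``Z = [h_v; p; h_v - p; h_v * p]`` (concatenation / difference /
  elementwise product encode neutrality, contradiction and entailment),
  runs multihead self-attention over the four blocks of ``H * Z``, and
  maps the pooled output through a learned projection, a rectifier and
  a final linear layer to a scalar.
* **TriAttn** — the trilinear form
  ``alpha = sum_abc (h_x)_a (h_v)_b (p)_c W_abc`` with a D^3 tensor,
  followed by the same projection / rectifier / linear head.

Per-terminal scores ``beta`` aggregate (sum by default) over all paths
ending at a node; the top-N nodes are selected with lexicographic
tie-breaking for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import nn
from .nn import Linear, MLP, Tensor

ScorerKind = Literal["multiattn", "triattn"]
Aggregate = Literal["sum", "max", "mean"]


@dataclass(frozen=True)
class PathState:
    """A (partial) knowledge path with its embedding and provenance.

    ``hops`` starts with ``(source_cui, None)`` and appends
    ``(next_cui, relation_index)`` per hop.  A self-loop hop terminates
    the path; terminated paths are never extended again.
    """

    hops: tuple[tuple[str, int | None], ...]
    embedding: Tensor
    score: float | None = None
    terminated: bool = False

    @property
    def terminal_cui(self) -> str:
        return self.hops[-1][0]

    @property
    def n_hops(self) -> int:
        return len(self.hops) - 1

    @property
    def visited(self) -> frozenset[str]:
        return frozenset(cui for cui, _ in self.hops)


@dataclass
class ScorerParams:
    """Learnable parameters of the path FFN and the chosen scorer."""

    dim: int
    onehot_size: int              # |relation vocabulary| + 1 (self-loop)
    kind: ScorerKind
    heads: int
    path_ffn: MLP                 # (2D + onehot) -> D
    sigma: Linear                 # projection before the rectifier
    phi: Linear                   # final linear head -> scalar
    # multiattn
    Wq: Linear | None = None
    Wk: Linear | None = None
    Wv: Linear | None = None
    Wo: Linear | None = None
    # triattn
    W_abc: Tensor | None = None

    @classmethod
    def init(cls, dim: int, onehot_size: int, kind: ScorerKind,
             rng: np.random.Generator, heads: int = 4,
             hidden: int | None = None) -> "ScorerParams":
        if kind not in ("multiattn", "triattn"):
            raise ValueError(f"unknown scorer kind {kind!r}")
        hidden = hidden or dim
        ffn = MLP(2 * dim + onehot_size, dim, dim, rng)
        if kind == "multiattn":
            if dim % heads:
                raise ValueError("dim must be divisible by the head count")
            return cls(dim=dim, onehot_size=onehot_size, kind=kind, heads=heads,
                       path_ffn=ffn,
                       sigma=Linear(dim, hidden, rng),
                       phi=Linear(hidden, 1, rng),
                       Wq=Linear(dim, dim, rng), Wk=Linear(dim, dim, rng),
                       Wv=Linear(dim, dim, rng), Wo=Linear(dim, dim, rng))
        scale = 1.0 / dim
        W = Tensor(rng.normal(0.0, scale, size=(dim, dim, dim)),
                   requires_grad=True)
        return cls(dim=dim, onehot_size=onehot_size, kind=kind, heads=heads,
                   path_ffn=ffn,
                   sigma=Linear(1, hidden, rng),
                   phi=Linear(hidden, 1, rng),
                   W_abc=W)

    def parameters(self) -> list[Tensor]:
        out = self.path_ffn.parameters() + self.sigma.parameters() + \
            self.phi.parameters()
        if self.kind == "multiattn":
            for lin in (self.Wq, self.Wk, self.Wv, self.Wo):
                out.extend(lin.parameters())
        else:
            out.append(self.W_abc)
        return out


# ----------------------------------------------------------------------
# path construction
# ----------------------------------------------------------------------

def init_path(cui: str, node_embedding: Tensor | np.ndarray) -> PathState:
    """Single-node path: the embedding is the node embedding itself."""
    emb = nn.as_tensor(node_embedding)
    return PathState(hops=((cui, None),), embedding=emb)


def relation_onehot(relation_index: int, onehot_size: int) -> np.ndarray:
    if not (0 <= relation_index < onehot_size):
        raise ValueError(f"relation index {relation_index} out of range")
    v = np.zeros(onehot_size)
    v[relation_index] = 1.0
    return v


def extend_path(path: PathState, relation_index: int,
                next_cui: str, next_node_embedding: Tensor | np.ndarray,
                params: ScorerParams, max_hops: int | None = None) -> PathState:
    """Append one hop: new embedding = FFN([p_prev ; onehot(rel) ; h_next])."""
    if path.terminated:
        raise ValueError(
            f"path ending at {path.terminal_cui} is self-loop terminated"
        )
    if max_hops is not None and path.n_hops >= max_hops:
        raise ValueError(f"path already has {path.n_hops} hops (max {max_hops})")
    onehot = relation_onehot(relation_index, params.onehot_size)
    x = nn.concat([
        path.embedding.reshape(1, params.dim),
        Tensor(onehot.reshape(1, -1)),
        nn.as_tensor(next_node_embedding).reshape(1, params.dim),
    ], axis=1)
    emb = params.path_ffn(x).reshape(params.dim)
    is_self = relation_index == params.onehot_size - 1
    return PathState(hops=path.hops + ((next_cui, relation_index),),
                     embedding=emb, terminated=is_self)


def extend_paths_batch(P: Tensor, expansions: Sequence[tuple[int, int, int]],
                       node_states: Tensor, params: ScorerParams) -> Tensor:
    """Vectorised extension: each expansion is (path_row, relation_index,
    node_row); returns the (n_new, D) matrix of extended embeddings."""
    rows = [e[0] for e in expansions]
    rels = np.zeros((len(expansions), params.onehot_size))
    for i, (_, r, _) in enumerate(expansions):
        rels[i, r] = 1.0
    tgts = [e[2] for e in expansions]
    x = nn.concat([P.gather(rows), Tensor(rels), node_states.gather(tgts)],
                  axis=1)
    return params.path_ffn(x)


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _context_blocks(h: Tensor, P: Tensor) -> Tensor:
    """Relevancy matrix [h; p; h - p; h * p] per path -> (n, 4, D)."""
    n, d = P.shape
    hb = h.reshape(1, d) + Tensor(np.zeros((n, d)))  # broadcast to (n, D)
    return nn.stack([hb, P, hb - P, hb * P], axis=1)


def _head(params: ScorerParams, alpha: Tensor) -> Tensor:
    """Shared score head: phi(ReLU(sigma(alpha))) -> (n, 1)."""
    return params.phi(params.sigma(alpha).relu())


def score_multiattn_batch(h_x: Tensor | np.ndarray, h_v: Tensor | np.ndarray,
                          P: Tensor, params: ScorerParams) -> Tensor:
    """MultiAttn scores for a batch of path embeddings -> (n, 1)."""
    h_x, h_v = nn.as_tensor(h_x), nn.as_tensor(h_v)
    n, d = P.shape
    if d != params.dim or h_x.data.size != d or h_v.data.size != d:
        raise ValueError("h_x, h_v and path embeddings must share dimension D")
    H = _context_blocks(h_x, P)
    Z = _context_blocks(h_v, P)
    X = H * Z                                    # (n, 4, D)
    nh, dh = params.heads, d // params.heads
    q = params.Wq(X).reshape(n, 4, nh, dh).swapaxes(1, 2)   # (n, nh, 4, dh)
    k = params.Wk(X).reshape(n, 4, nh, dh).swapaxes(1, 2)
    v = params.Wv(X).reshape(n, 4, nh, dh).swapaxes(1, 2)
    att = nn.softmax((q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(dh)), axis=-1)
    mixed = (att @ v).swapaxes(1, 2).reshape(n, 4, d)
    pooled = params.Wo(mixed).mean(axis=1)       # (n, D)
    return _head(params, pooled)


def score_triattn_batch(h_x: Tensor | np.ndarray, h_v: Tensor | np.ndarray,
                        P: Tensor, params: ScorerParams) -> Tensor:
    """Trilinear scores alpha_j = sum_abc (h_x)_a (h_v)_b (P_j)_c W_abc,
    through the shared head -> (n, 1)."""
    h_x, h_v = nn.as_tensor(h_x), nn.as_tensor(h_v)
    n, d = P.shape
    if d != params.dim or h_x.data.size != d or h_v.data.size != d:
        raise ValueError("h_x, h_v and path embeddings must share dimension D")
    outer = (h_x.reshape(d, 1) @ h_v.reshape(1, d)).reshape(1, d * d)
    w2 = outer @ params.W_abc.reshape(d * d, d)  # (1, D)
    alpha = P @ w2.reshape(d, 1)                 # (n, 1)
    return _head(params, alpha)


def score_paths_batch(h_x, h_v, P: Tensor, params: ScorerParams) -> Tensor:
    if params.kind == "multiattn":
        return score_multiattn_batch(h_x, h_v, P, params)
    return score_triattn_batch(h_x, h_v, P, params)


def score_multiattn(h_x, h_v, path: PathState, params: ScorerParams) -> float:
    """Convenience scalar form of :func:`score_multiattn_batch`."""
    P = path.embedding.reshape(1, params.dim)
    return float(score_multiattn_batch(h_x, h_v, P, params).data[0, 0])


def score_triattn(h_x, h_v, path: PathState, params: ScorerParams) -> float:
    P = path.embedding.reshape(1, params.dim)
    return float(score_triattn_batch(h_x, h_v, P, params).data[0, 0])


# ----------------------------------------------------------------------
# aggregation and selection
# ----------------------------------------------------------------------

def aggregate_scores(paths: Sequence[PathState], scores: np.ndarray,
                     aggregate: Aggregate = "sum") -> dict[str, float]:
    """Per-terminal-node score beta over all paths ending at that node."""
    groups: dict[str, list[float]] = {}
    for p, s in zip(paths, scores):
        groups.setdefault(p.terminal_cui, []).append(float(s))
    if aggregate == "sum":
        return {c: float(np.sum(v)) for c, v in groups.items()}
    if aggregate == "max":
        return {c: float(np.max(v)) for c, v in groups.items()}
    if aggregate == "mean":
        return {c: float(np.mean(v)) for c, v in groups.items()}
    raise ValueError(f"unknown aggregate {aggregate!r}")


def aggregate_and_select(
    paths: Sequence[PathState], n: int,
    scores: np.ndarray | None = None,
    aggregate: Aggregate = "sum",
) -> tuple[list[str], dict[str, PathState]]:
    """Top-N terminal CUIs by aggregated score, ties broken
    lexicographically by CUI; each selected node carries its
    highest-scoring path (first in path order on a tie).

    ``scores`` defaults to the ``score`` attribute stored on each path.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not paths:
        return [], {}
    if scores is None:
        scores = np.array([p.score for p in paths], dtype=float)
    beta = aggregate_scores(paths, scores, aggregate)
    ranked = sorted(beta, key=lambda c: (-beta[c], c))[:n]
    best: dict[str, PathState] = {}
    for cui in ranked:
        idxs = [i for i, p in enumerate(paths) if p.terminal_cui == cui]
        top = max(idxs, key=lambda i: (scores[i], -i))
        best[cui] = replace(paths[top], score=float(scores[top]))
    return ranked, best
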