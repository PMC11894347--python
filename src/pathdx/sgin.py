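"""Stacked graph isomorphism network over retrieved 1-hop subgraphs.

One GIN layer updates each node as

    h_i^(k) = MLP^(k)( (1 + eps^(k)) * h_i^(k-1) + sum_{u in N(v_i)} h_u^(k-1) )

with sum aggregation (permutation-invariant by construction) over the
subgraph's out-neighbors by default (in-neighbors can be included via a
flag, matching forward path traversal otherwise).  The stacked network
concatenates the K per-layer outputs into a K*D vector per node; a
learned linear projection K*D -> D reconciles that with the D-dimensional
path scorers.  Edge relation types are not consumed here — relations
feed the path encoder, not the node aggregator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import nn
from .kg import Subgraph
from .nn import Linear, MLP, Tensor


@dataclass
class GINLayerParams:
    """One layer: learnable scalar eps and a D->D two-layer perceptron."""

    epsilon: Tensor
    mlp: MLP

    @classmethod
    def init(cls, dim: int, rng: np.random.Generator) -> "GINLayerParams":
        return cls(epsilon=Tensor(0.0, requires_grad=True),
                   mlp=MLP(dim, dim, dim, rng))

    @classmethod
    def identity(cls, dim: int) -> "GINLayerParams":
        """eps = 0, MLP acting as identity on nonnegative inputs."""
        return cls(epsilon=Tensor(0.0, requires_grad=True),
                   mlp=MLP.identity(dim))

    def parameters(self) -> list[Tensor]:
        return [self.epsilon] + self.mlp.parameters()


@dataclass
class SGINParams:
    """K stacked layers plus the K*D -> D output projection."""

    layers: list[GINLayerParams]
    projection: Linear

    @classmethod
    def init(cls, dim: int, n_layers: int, rng: np.random.Generator) -> "SGINParams":
        if n_layers < 1:
            raise ValueError("at least one GIN layer is required")
        layers = [GINLayerParams.init(dim, rng) for _ in range(n_layers)]
        return cls(layers=layers, projection=Linear(n_layers * dim, dim, rng))

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out + self.projection.parameters()


def _neighbor_matrix(order: Mapping[str, int], subgraph: Subgraph,
                     include_in_neighbors: bool) -> np.ndarray:
    """0/1 matrix A with A[i, j] = 1 iff v_j is a neighbor of v_i.

    Parallel edges contribute once: the neighborhood is a set of nodes.
    """
    n = len(order)
    A = np.zeros((n, n))
    for u, _, w in subgraph.edges:
        if u == w:
            continue
        A[order[u], order[w]] = 1.0          # w is an out-neighbor of u
        if include_in_neighbors:
            A[order[w], order[u]] = 1.0
    return A


def gin_layer(states: Mapping[str, Tensor | np.ndarray], subgraph: Subgraph,
              params: GINLayerParams,
              include_in_neighbors: bool = False) -> dict[str, Tensor]:
    """One GIN update over every subgraph member; error on a missing state."""
    for cui in subgraph.member_cuis:
        if cui not in states:
            raise KeyError(f"no state vector for CUI {cui}")
    order = {cui: i for i, cui in enumerate(subgraph.member_cuis)}
    H = nn.stack([nn.as_tensor(states[c]) for c in subgraph.member_cuis], axis=0)
    out = _gin_layer_matrix(H, order, subgraph, params, include_in_neighbors)
    return {cui: out.gather([order[cui]]).reshape(H.shape[1])
            for cui in subgraph.member_cuis}


def _gin_layer_matrix(H: Tensor, order: Mapping[str, int], subgraph: Subgraph,
                      params: GINLayerParams,
                      include_in_neighbors: bool) -> Tensor:
    A = _neighbor_matrix(order, subgraph, include_in_neighbors)
    agg = H * (params.epsilon + 1.0) + Tensor(A) @ H
    return params.mlp(agg)


def sgin_forward(states: Mapping[str, Tensor | np.ndarray], subgraph: Subgraph,
                 params: SGINParams,
                 include_in_neighbors: bool = False) -> dict[str, Tensor]:
    """Stacked forward pass: per-node concatenation of all K layer outputs
    (dimension K*D).  Use :func:`project_states` to map back to D."""
    order = {cui: i for i, cui in enumerate(subgraph.member_cuis)}
    H = nn.stack([nn.as_tensor(states[c]) for c in subgraph.member_cuis], axis=0)
    stacked = _sgin_matrix(H, order, subgraph, params, include_in_neighbors)
    kd = stacked.shape[1]
    return {cui: stacked.gather([order[cui]]).reshape(kd)
            for cui in subgraph.member_cuis}


def _sgin_matrix(H: Tensor, order: Mapping[str, int], subgraph: Subgraph,
                 params: SGINParams, include_in_neighbors: bool) -> Tensor:
    per_layer: list[Tensor] = []
    cur = H
    for layer in params.layers:
        cur = _gin_layer_matrix(cur, order, subgraph, layer, include_in_neighbors)
        per_layer.append(cur)
    return nn.concat(per_layer, axis=1)


def encode_subgraph(base_states: Mapping[str, np.ndarray], subgraph: Subgraph,
                    params: SGINParams,
                    include_in_neighbors: bool = False
                    ) -> tuple[dict[str, int], Tensor]:
    """Matrix-form node encoding used by the path pipeline.

    Returns (cui -> row index, projected node-state matrix of shape
    (n_members, D)).
    """
    for cui in subgraph.member_cuis:
        if cui not in base_states:
            raise KeyError(f"no base embedding for CUI {cui}")
    order = {cui: i for i, cui in enumerate(subgraph.member_cuis)}
    H = Tensor(np.stack([np.asarray(base_states[c], dtype=np.float64)
                         for c in subgraph.member_cuis]))
    stacked = _sgin_matrix(H, order, subgraph, params, include_in_neighbors)
    return order, params.projection(stacked)
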