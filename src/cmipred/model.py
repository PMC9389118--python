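"""NGCF-style embedding propagation over the circRNA-miRNA bipartite graph.

The model assigns every circRNA u and miRNA v a trainable D-dimensional
embedding e0. K propagation layers then refine the embeddings by message
passing over the interaction graph: at layer k each node aggregates

    e_u^k = LeakyReLU( W1_k e_u^{k-1}
                       + sum_{v in N(u)} (1/sqrt(|N(u)||N(v)|))
                         * ( W1_k e_v^{k-1} + W2_k (e_v^{k-1} * e_u^{k-1}) ) )

(elementwise product *), and symmetrically on the miRNA side. The
self-message carries no Laplacian decay. The per-layer embeddings
e^0 .. e^K are concatenated into e* and a pair (u, v) is scored by the
inner product <e_u*, e_v*>.

Embeddings are stored as matrix rows; transformations act by right
multiplication (rows @ W), which is the same parameterisation as W e for
column vectors up to transposition of the learned matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ._rng import substream
from .graph_data import InteractionGraph, normalized_adjacency

__all__ = [
    "ModelConfig",
    "ModelParams",
    "EmbeddingStack",
    "init_params",
    "apply_dropout",
    "propagate_layer",
    "forward",
    "final_embeddings",
    "score_pairs",
    "score_matrix",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    K is the number of propagation layers (how many hops of interaction
    information each embedding absorbs) and D the embedding size; K=2,
    D=256 are the best-performing settings on the real benchmark. The
    transformation size equals D at every layer. LeakyReLU slope 0.2
    follows the collaborative-filtering convention this architecture is
    based on. Dropout rates apply only while training.
    """

    K: int = 2
    D: int = 256
    leaky_slope: float = 0.2
    message_dropout: float = 0.1
    node_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        for r in (self.message_dropout, self.node_dropout):
            if not 0.0 <= r < 1.0:
                raise ValueError("dropout rates must lie in [0, 1)")


@dataclass
class ModelParams:
    """All trainable parameters: initial embeddings + per-layer transforms."""

    E0_u: np.ndarray            # n x D
    E0_v: np.ndarray            # m x D
    W1: list[np.ndarray]        # K matrices, D x D
    W2: list[np.ndarray]        # K matrices, D x D

    def tensors(self) -> dict[str, np.ndarray]:
        out = {"E0_u": self.E0_u, "E0_v": self.E0_v}
        for k, (w1, w2) in enumerate(zip(self.W1, self.W2)):
            out[f"W1_{k}"] = w1
            out[f"W2_{k}"] = w2
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            E0_u=self.E0_u.copy(), E0_v=self.E0_v.copy(),
            W1=[w.copy() for w in self.W1], W2=[w.copy() for w in self.W2],
        )

    def squared_norm(self) -> float:
        return float(sum((t ** 2).sum() for t in self.tensors().values()))


@dataclass
class EmbeddingStack:
    """Per-layer embeddings e^0 .. e^K for both node sides."""

    layers_u: list[np.ndarray]  # K+1 matrices, n x D
    layers_v: list[np.ndarray]  # K+1 matrices, m x D

    @property
    def n_layers(self) -> int:
        return len(self.layers_u)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_in, fan_out))


def init_params(graph: InteractionGraph, config: ModelConfig) -> ModelParams:
    """Glorot-uniform initialisation of embeddings and transforms.

    Deterministic under ``config.seed``: two calls with the same seed give
    bitwise-identical parameters.
    """
    rng = substream(config.seed, "model/init")
    E0_u = _glorot(rng, graph.n, config.D)
    E0_v = _glorot(rng, graph.m, config.D)
    W1 = [_glorot(rng, config.D, config.D) for _ in range(config.K)]
    W2 = [_glorot(rng, config.D, config.D) for _ in range(config.K)]
    return ModelParams(E0_u=E0_u, E0_v=E0_v, W1=W1, W2=W2)


def apply_dropout(
    x: np.ndarray, rate: float, training: bool,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverted dropout: zero entries with prob ``rate``, rescale the rest.

    Identity when not training or when ``rate == 0``; retained entries are
    scaled by 1/(1-rate) so the expected value matches evaluation mode.
    """
    masked, _ = _dropout(x, rate, training, rng)
    return masked


def _dropout(
    x: np.ndarray, rate: float, training: bool, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray | None]:
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    if not training or rate == 0.0:
        return x, None
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


@dataclass
class _LayerCache:
    """Intermediates of one propagation layer, kept for backpropagation."""

    prev_u: np.ndarray
    prev_v: np.ndarray
    S_u: np.ndarray          # aggregated neighbour messages (post mask)
    S_v: np.ndarray
    H_u: np.ndarray          # pre-activations
    H_v: np.ndarray
    msg_mask_u: np.ndarray | None
    msg_mask_v: np.ndarray | None


@dataclass
class _ForwardCache:
    A_u: sp.spmatrix         # adjacency used for circRNA-side aggregation
    A_v: sp.spmatrix         # adjacency used for miRNA-side aggregation
    layers: list[_LayerCache]


def _layer_forward(
    prev_u: np.ndarray, prev_v: np.ndarray,
    A_u: sp.spmatrix, A_v: sp.spmatrix,
    W1k: np.ndarray, W2k: np.ndarray, slope: float,
    message_dropout: float = 0.0, training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, _LayerCache]:
    S_u = A_u @ prev_v
    S_v = A_v.T @ prev_u
    S_u, mask_u = _dropout(S_u, message_dropout, training, rng)
    S_v, mask_v = _dropout(S_v, message_dropout, training, rng)
    H_u = (prev_u + S_u) @ W1k + (S_u * prev_u) @ W2k
    H_v = (prev_v + S_v) @ W1k + (S_v * prev_v) @ W2k
    cache = _LayerCache(prev_u, prev_v, S_u, S_v, H_u, H_v, mask_u, mask_v)
    return _leaky(H_u, slope), _leaky(H_v, slope), cache


def propagate_layer(
    prev_u: np.ndarray, prev_v: np.ndarray, graph: InteractionGraph,
    W1k: np.ndarray, W2k: np.ndarray, slope: float = 0.2,
    message_dropout: float = 0.0, training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One embedding-propagation layer over ``graph``.

    Degrees for the Laplacian decay are taken from ``graph`` itself, which
    during cross-validation is the training-split graph. Dropout is active
    only with ``training=True``.
    """
    D = W1k.shape[0]
    if prev_u.shape != (graph.n, D) or prev_v.shape != (graph.m, D):
        raise ValueError(
            f"embedding shapes {prev_u.shape}/{prev_v.shape} inconsistent with "
            f"graph ({graph.n},{graph.m}) and transform size {D}"
        )
    A = normalized_adjacency(graph)
    next_u, next_v, _ = _layer_forward(
        prev_u, prev_v, A, A, W1k, W2k, slope, message_dropout, training, rng
    )
    return next_u, next_v


def _node_dropped_adjacency(
    A: sp.spmatrix, rate: float, rng: np.random.Generator
) -> tuple[sp.spmatrix, sp.spmatrix]:
    """Drop each node's outgoing messages with prob ``rate``.

    A message v->u is lost when v is dropped, so the circRNA-side
    aggregation matrix loses columns; symmetrically the miRNA side loses
    rows. Retained messages are rescaled by 1/(1-rate). The masks are
    sampled once and shared by every layer of the forward pass.
    """
    n, m = A.shape
    keep_u = (rng.random(n) >= rate) / (1.0 - rate)
    keep_v = (rng.random(m) >= rate) / (1.0 - rate)
    A_u = A.multiply(keep_v[None, :]).tocsr()   # v's outgoing messages
    A_v = A.multiply(keep_u[:, None]).tocsr()   # u's outgoing messages
    return A_u, A_v


def _forward_cached(
    params: ModelParams, graph: InteractionGraph, config: ModelConfig,
    training: bool = False, rng: np.random.Generator | None = None,
    A: sp.spmatrix | None = None,
) -> tuple[EmbeddingStack, _ForwardCache]:
    if params.E0_u.shape != (graph.n, config.D) or params.E0_v.shape != (graph.m, config.D):
        raise ValueError("parameter shapes inconsistent with graph/config")
    if A is None:
        A = normalized_adjacency(graph)
    if training and config.node_dropout > 0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng")
        A_u, A_v = _node_dropped_adjacency(A, config.node_dropout, rng)
    else:
        A_u = A_v = A
    layers_u = [params.E0_u]
    layers_v = [params.E0_v]
    caches: list[_LayerCache] = []
    for k in range(config.K):
        next_u, next_v, cache = _layer_forward(
            layers_u[-1], layers_v[-1], A_u, A_v,
            params.W1[k], params.W2[k], config.leaky_slope,
            config.message_dropout, training, rng,
        )
        layers_u.append(next_u)
        layers_v.append(next_v)
        caches.append(cache)
    stack = EmbeddingStack(layers_u=layers_u, layers_v=layers_v)
    return stack, _ForwardCache(A_u=A_u, A_v=A_v, layers=caches)


def forward(
    params: ModelParams, graph: InteractionGraph, config: ModelConfig,
    training: bool = False, rng: np.random.Generator | None = None,
) -> EmbeddingStack:
    """Run the full K-layer propagation; layer 0 is the E0 tables.

    With ``training=False`` the pass is deterministic (no dropout). The
    node-dropout mask, when active, is sampled once per call and shared by
    all layers.
    """
    stack, _ = _forward_cached(params, graph, config, training=training, rng=rng)
    return stack


def final_embeddings(stack: EmbeddingStack) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate e^0 .. e^K row-wise into e* (width (K+1) * D)."""
    return np.hstack(stack.layers_u), np.hstack(stack.layers_v)


def score_pairs(
    star_u: np.ndarray, star_v: np.ndarray, pairs: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Inner-product scores <e_u*, e_v*> for the requested pairs."""
    if len(pairs) == 0:
        return np.zeros(0)
    idx = np.asarray(pairs, dtype=np.int64)
    if idx.ndim != 2 or idx.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (u, v) index pairs")
    u, v = idx[:, 0], idx[:, 1]
    if u.min() < 0 or u.max() >= star_u.shape[0] or v.min() < 0 or v.max() >= star_v.shape[0]:
        raise IndexError("pair index out of range")
    return np.einsum("ij,ij->i", star_u[u], star_v[v])


def score_matrix(star_u: np.ndarray, star_v: np.ndarray) -> np.ndarray:
    """All-pairs score matrix, used for ranking candidates."""
    return star_u @ star_v.T
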