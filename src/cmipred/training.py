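"""Pairwise (BPR) training of the propagation model.

The objective is Bayesian Personalized Ranking over triples (u, i, j) where
(u, i) is a known interaction and (u, j) an unobserved one:

    L(Theta) = sum_{(u,i,j)} -ln sigmoid(y_ui - y_uj) + lambda * ||Theta||^2

with Theta = {E0_u, E0_v, W1_k, W2_k}. Gradients are computed analytically:
the score gradients are scattered onto every layer's embeddings (the final
embedding is a concatenation, so each layer contributes an independent inner
product) and then backpropagated through the propagation recursion.
Optimisation uses Adam (beta1=0.9, beta2=0.999, eps=1e-8). One negative j
is drawn per positive per epoch, resampled every epoch.

Early stopping monitors ranking AUC on a held-out slice of the *training*
positives (test folds are never touched); the best-validation snapshot is
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from ._rng import substream
from .graph_data import (
    BprTriple,
    InteractionGraph,
    normalized_adjacency,
    sample_bpr_triples,
    sample_negative_pairs,
    subgraph_with_edges,
)
from .model import (
    EmbeddingStack,
    ModelConfig,
    ModelParams,
    _forward_cached,
    _ForwardCache,
    _leaky_grad,
    final_embeddings,
    init_params,
    score_pairs,
)

__all__ = [
    "TrainConfig",
    "TrainState",
    "bpr_loss",
    "bpr_loss_and_grads",
    "AdamState",
    "adam_step",
    "train_epoch",
    "fit",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    lambda_reg is the L2 strength applied to all model parameters;
    val_fraction of the training positives is held out (with matched
    sampled negatives) purely to drive early stopping.
    """

    lr: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 400
    lambda_reg: float = 1e-5
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class TrainState:
    """Trajectory of one fit: loss/validation history + best snapshot."""

    epoch: int = 0
    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_params: ModelParams | None = None
    best_epoch: int = -1
    best_val_auc: float = -np.inf


def _softplus(x: np.ndarray) -> np.ndarray:
    # -ln sigmoid(x) = ln(1 + exp(-x)), numerically stable
    return np.logaddexp(0.0, -x)


def bpr_loss(
    scores_pos: np.ndarray,
    scores_neg: np.ndarray,
    params: ModelParams | None = None,
    lambda_reg: float = 0.0,
) -> float:
    """BPR objective: sum of -ln sigmoid(gap) plus L2 penalty.

    Depends on the scores only through the gaps y_ui - y_uj; with
    lambda_reg = 0 and all-equal scores it equals (number of triples) * ln 2.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.shape != scores_neg.shape:
        raise ValueError("positive and negative score vectors must have equal length")
    loss = float(_softplus(scores_pos - scores_neg).sum())
    if lambda_reg != 0.0:
        if params is None:
            raise ValueError("lambda_reg > 0 requires the parameters")
        loss += lambda_reg * params.squared_norm()
    return loss


def _score_layer_grads(
    stack: EmbeddingStack, triples: np.ndarray, coef: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the BPR data term w.r.t. every layer's embeddings.

    The pair score decomposes over layers, score(u,v) = sum_k <e_u^k, e_v^k>,
    so for each triple (u, i, j) with gap-gradient ``coef``:
    d/de_u^k += coef * (e_i^k - e_j^k), d/de_i^k += coef * e_u^k,
    d/de_j^k -= coef * e_u^k.
    """
    u, i, j = triples[:, 0], triples[:, 1], triples[:, 2]
    c = coef[:, None]
    d_layers_u, d_layers_v = [], []
    for eu, ev in zip(stack.layers_u, stack.layers_v):
        gu = np.zeros_like(eu)
        gv = np.zeros_like(ev)
        np.add.at(gu, u, c * (ev[i] - ev[j]))
        np.add.at(gv, i, c * eu[u])
        np.add.at(gv, j, -c * eu[u])
        d_layers_u.append(gu)
        d_layers_v.append(gv)
    return d_layers_u, d_layers_v


def _backward(
    params: ModelParams,
    config: ModelConfig,
    cache: _ForwardCache,
    d_layers_u: list[np.ndarray],
    d_layers_v: list[np.ndarray],
) -> dict[str, np.ndarray]:
    """Backpropagate per-layer embedding gradients through the recursion."""
    grads: dict[str, np.ndarray] = {}
    carry_u = np.zeros_like(d_layers_u[-1])
    carry_v = np.zeros_like(d_layers_v[-1])
    slope = config.leaky_slope
    for k in range(config.K - 1, -1, -1):
        lc = cache.layers[k]
        g_u = d_layers_u[k + 1] + carry_u
        g_v = d_layers_v[k + 1] + carry_v
        dH_u = g_u * _leaky_grad(lc.H_u, slope)
        dH_v = g_v * _leaky_grad(lc.H_v, slope)
        W1, W2 = params.W1[k], params.W2[k]
        grads[f"W1_{k}"] = (
            (lc.prev_u + lc.S_u).T @ dH_u + (lc.prev_v + lc.S_v).T @ dH_v
        )
        grads[f"W2_{k}"] = (
            (lc.S_u * lc.prev_u).T @ dH_u + (lc.S_v * lc.prev_v).T @ dH_v
        )
        dS_u = dH_u @ W1.T + (dH_u @ W2.T) * lc.prev_u
        dS_v = dH_v @ W1.T + (dH_v @ W2.T) * lc.prev_v
        if lc.msg_mask_u is not None:
            dS_u = dS_u * lc.msg_mask_u
        if lc.msg_mask_v is not None:
            dS_v = dS_v * lc.msg_mask_v
        carry_u = dH_u @ W1.T + (dH_u @ W2.T) * lc.S_u + cache.A_v @ dS_v
        carry_v = dH_v @ W1.T + (dH_v @ W2.T) * lc.S_v + cache.A_u.T @ dS_u
    grads["E0_u"] = d_layers_u[0] + carry_u
    grads["E0_v"] = d_layers_v[0] + carry_v
    return grads


def bpr_loss_and_grads(
    params: ModelParams,
    graph: InteractionGraph,
    config: ModelConfig,
    triples: list[BprTriple] | np.ndarray,
    lambda_reg: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    A: sp.spmatrix | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Full objective and analytic gradients for one batch of triples."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    stack, cache = _forward_cached(params, graph, config, training=training, rng=rng, A=A)
    star_u, star_v = final_embeddings(stack)
    s_pos = score_pairs(star_u, star_v, triples[:, [0, 1]])
    s_neg = score_pairs(star_u, star_v, triples[:, [0, 2]])
    gap = s_pos - s_neg
    loss = float(_softplus(gap).sum())
    coef = -expit(-gap)  # d/dgap of -ln sigmoid(gap)
    d_layers_u, d_layers_v = _score_layer_grads(stack, triples, coef)
    grads = _backward(params, config, cache, d_layers_u, d_layers_v)
    if lambda_reg != 0.0:
        loss += lambda_reg * params.squared_norm()
        for name, tensor in params.tensors().items():
            grads[name] = grads[name] + 2.0 * lambda_reg * tensor
    return loss, grads


@dataclass
class AdamState:
    """First/second-moment accumulators, one pair per parameter tensor."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    @classmethod
    def for_params(cls, params: ModelParams) -> "AdamState":
        return cls(
            m={k: np.zeros_like(t) for k, t in params.tensors().items()},
            v={k: np.zeros_like(t) for k, t in params.tensors().items()},
        )


def adam_step(
    params: ModelParams, grads: dict[str, np.ndarray], state: AdamState, lr: float
) -> None:
    """In-place Adam update of every parameter tensor."""
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    for name, tensor in params.tensors().items():
        g = grads[name]
        state.m[name] = b1 * state.m[name] + (1 - b1) * g
        state.v[name] = b2 * state.v[name] + (1 - b2) * g * g
        m_hat = state.m[name] / (1 - b1 ** state.t)
        v_hat = state.v[name] / (1 - b2 ** state.t)
        tensor -= lr * m_hat / (np.sqrt(v_hat) + state.eps)


def train_epoch(
    params: ModelParams,
    adam: AdamState,
    graph: InteractionGraph,
    train_pos: frozenset[Edge] | set[Edge],
    model_config: ModelConfig,
    train_config: TrainConfig,
    rng: np.random.Generator,
    A: sp.spmatrix | None = None,
) -> float:
    """One pass over the training positives in seeded mini-batches.

    Returns the epoch mean loss per triple (including the L2 term applied
    per batch). Dropout is active; the negative j of every triple is freshly
    sampled for this epoch.
    """
    triples = sample_bpr_triples(train_pos, graph, rng=rng)
    if not triples:
        raise ValueError("no usable training triples")
    arr = np.asarray(triples, dtype=np.int64)
    arr = arr[rng.permutation(len(arr))]
    if A is None:
        A = normalized_adjacency(graph)
    total = 0.0
    for start in range(0, len(arr), train_config.batch_size):
        batch = arr[start:start + train_config.batch_size]
        loss, grads = bpr_loss_and_grads(
            params, graph, model_config, batch,
            lambda_reg=train_config.lambda_reg, training=True, rng=rng, A=A,
        )
        adam_step(params, grads, adam, train_config.lr)
        total += loss
    return total / len(arr)


def _ranking_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from .evaluation import ScoredPairs, auc_score  # deferred: avoids cycle

    return auc_score(ScoredPairs(pairs=[], scores=scores, labels=labels))


def fit(
    graph: InteractionGraph,
    train_pos: frozenset[Edge] | set[Edge],
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[ModelParams, TrainState]:
    """End-to-end training on one split of positives.

    A val_fraction slice of ``train_pos`` (plus matched sampled negatives)
    is held out for validation AUC; propagation degrees and BPR triples use
    only the remaining positives. Training stops at max_epochs or when
    ``patience`` epochs pass without a validation improvement, returning the
    best-validation parameter snapshot (with val_fraction = 0, the final
    parameters after max_epochs).
    """
    train_pos = frozenset(train_pos)
    if not train_pos:
        raise ValueError("train_pos must be non-empty")
    rng = substream(train_config.seed, "train/fit")

    pos_list = sorted(train_pos)
    n_val = int(round(train_config.val_fraction * len(pos_list)))
    val_pos: list[Edge] = []
    fit_pos = train_pos
    if train_config.val_fraction > 0 and n_val >= 1:
        order = rng.permutation(len(pos_list))
        val_pos = [pos_list[i] for i in order[:n_val]]
        fit_pos = frozenset(pos_list[i] for i in order[n_val:])
        if not fit_pos:
            raise ValueError("val_fraction leaves no training positives")

    train_graph = subgraph_with_edges(graph, fit_pos)
    A = normalized_adjacency(train_graph)

    val_pairs: list[Edge] = []
    val_labels = np.zeros(0)
    loss_based = False
    if val_pos:
        val_neg = sorted(sample_negative_pairs(graph, len(val_pos), rng=rng))
        val_pairs = list(val_pos) + list(val_neg)
        val_labels = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])
        if len(set(val_labels.tolist())) < 2:
            logger.warning("degenerate validation set; falling back to loss-based stopping")
            loss_based = True
    else:
        loss_based = train_config.val_fraction > 0
        if loss_based:
            logger.warning(
                "val_fraction %.3g yields an empty validation set; using loss-based stopping",
                train_config.val_fraction,
            )

    params = init_params(train_graph, model_config)
    adam = AdamState.for_params(params)
    state = TrainState()
    stall = 0
    monitor_validation = bool(val_pairs) and not loss_based

    for epoch in range(train_config.max_epochs):
        mean_loss = train_epoch(
            params, adam, train_graph, fit_pos, model_config, train_config, rng, A=A
        )
        state.train_loss.append(mean_loss)
        state.epoch = epoch + 1

        if monitor_validation:
            stack, _ = _forward_cached(params, train_graph, model_config, training=False, A=A)
            star_u, star_v = final_embeddings(stack)
            scores = score_pairs(star_u, star_v, val_pairs)
            criterion = _ranking_auc(scores, val_labels)
            state.val_auc.append(criterion)
        elif loss_based:
            criterion = -mean_loss
        else:
            continue  # val_fraction == 0: run every epoch, keep final params

        if criterion > state.best_val_auc:
            state.best_val_auc = criterion
            state.best_epoch = epoch
            state.best_params = params.copy()
            stall = 0
        else:
            stall += 1
            if stall > train_config.patience:
                logger.info("early stop at epoch %d (best epoch %d)", epoch, state.best_epoch)
                break

    if state.best_params is None:
        state.best_params = params.copy()
        state.best_epoch = state.epoch - 1
    return state.best_params, state
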