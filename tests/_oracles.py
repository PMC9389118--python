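"""Independent brute-force oracles used to check the vectorised code paths.

Everything here is written as explicit loops over dense structures, on
purpose: these implementations share no code with the package internals
they verify.
"""

from __future__ import annotations

import numpy as np


def dense_propagation_oracle(prev_u, prev_v, graph, W1, W2, slope):
    """Explicit-loop message passing over the materialised adjacency.

    For each node: self-message W1 e, plus for every neighbour the
    Laplacian-decayed W1 e_nb + W2 (e_nb * e_self), then LeakyReLU.
    """
    R = graph.dense_matrix()
    next_u = np.zeros_like(prev_u)
    next_v = np.zeros_like(prev_v)
    for u in range(graph.n):
        h = prev_u[u] @ W1
        for v in range(graph.m):
            if R[u, v]:
                c = 1.0 / np.sqrt(graph.deg_u[u] * graph.deg_v[v])
                h = h + c * (prev_v[v] @ W1 + (prev_v[v] * prev_u[u]) @ W2)
        next_u[u] = np.where(h >= 0, h, slope * h)
    for v in range(graph.m):
        h = prev_v[v] @ W1
        for u in range(graph.n):
            if R[u, v]:
                c = 1.0 / np.sqrt(graph.deg_u[u] * graph.deg_v[v])
                h = h + c * (prev_u[u] @ W1 + (prev_u[u] * prev_v[v]) @ W2)
        next_v[v] = np.where(h >= 0, h, slope * h)
    return next_u, next_v


def pairwise_auc_oracle(scores, labels):
    """Fraction of (positive, negative) pairs ordered correctly; ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def step_sum_ap_oracle(scores, labels):
    """Average precision by explicit enumeration of distinct thresholds."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    ap = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def finite_difference_grads(objective, params, eps=1e-6):
    """Central finite differences of ``objective()`` w.r.t. every tensor."""
    grads = {}
    for name, tensor in params.tensors().items():
        num = np.zeros_like(tensor)
        it = np.nditer(tensor, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = tensor[idx]
            tensor[idx] = orig + eps
            lp = objective()
            tensor[idx] = orig - eps
            lm = objective()
            tensor[idx] = orig
            num[idx] = (lp - lm) / (2 * eps)
        grads[name] = num
    return grads


def random_bipartite_graph(rng, max_n=10, max_m=10):
    """A small random graph for oracle-equivalence sweeps."""
    from cmipred.graph_data import graph_from_edges

    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(2, max_m + 1))
    n_edges = int(rng.integers(1, n * m + 1))
    flat = rng.choice(n * m, size=n_edges, replace=False)
    return graph_from_edges(n, m, [(int(f) // m, int(f) % m) for f in flat])
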