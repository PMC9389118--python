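"""Evaluation: ranking metrics, five-fold cross-validation, sweeps, ranking.

AUC is the rank-based (Mann-Whitney) statistic with midranks for tied
scores: the probability that a random known interaction outscores a random
unlabeled pair, ties counting one half. AUPR is average precision by the
step-sum over recall increments (trapezoidal interpolation overestimates
precision-recall area and is deliberately avoided). Threshold metrics
(accuracy, precision, recall, F1) follow the usual confusion-count
definitions; the default decision rule is raw inner-product score >= 0,
i.e. sigmoid(score) >= 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph_data import (
    FoldSplit,
    InteractionGraph,
    make_folds,
    subgraph_with_edges,
)
from .model import (
    ModelConfig,
    ModelParams,
    final_embeddings,
    forward,
    score_matrix,
    score_pairs,
)
from .training import TrainConfig, fit

__all__ = [
    "ScoredPairs",
    "MetricsReport",
    "CVResult",
    "auc_score",
    "aupr_score",
    "confusion_metrics",
    "compute_metrics",
    "score_split",
    "cross_validate",
    "sweep",
    "rank_candidates",
    "degree_baseline_scores",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]


@dataclass
class ScoredPairs:
    """Model scores joined with ground-truth labels for a set of pairs."""

    pairs: Sequence[Edge]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")


@dataclass
class MetricsReport:
    """Metric bundle for one evaluation (None where undefined)."""

    auc: float | None = None
    aupr: float | None = None
    acc: float | None = None
    pre: float | None = None
    recall: float | None = None
    f1: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "aupr": self.aupr, "acc": self.acc, "pre": self.pre,
            "recall": self.recall, "f1": self.f1,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
        }


def auc_score(scored: ScoredPairs) -> float:
    """Mann-Whitney AUC with midranks for ties.

    Equals the fraction of (positive, negative) pairs ordered correctly,
    counting ties as one half; invariant under any strictly monotone
    transform of the scores.
    """
    labels = scored.labels.astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scored.scores)  # midranks
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr_score(scored: ScoredPairs) -> float:
    """Average precision: sum over recall steps of step size times precision.

    Scores are swept in descending order; tied scores enter as one
    threshold group.
    """
    labels = scored.labels.astype(bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive pairs")
    order = np.argsort(-scored.scores, kind="stable")
    s = scored.scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # last index of each tied-score group = the achievable operating points
    group_end = np.flatnonzero(np.append(np.diff(s) != 0, True))
    tp_g = tp[group_end]
    fp_g = fp[group_end]
    precision = tp_g / (tp_g + fp_g)
    recall = tp_g / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def confusion_metrics(scored: ScoredPairs, threshold: float = 0.0) -> MetricsReport:
    """Threshold metrics: predict interaction iff score >= threshold.

    Acc = (TP+TN)/total, Pre = TP/(TP+FP), Recall = TP/(TP+FN),
    F1 = 2*Pre*Recall/(Pre+Recall). Any metric with a zero denominator is
    reported as None; the counts are always filled in.
    """
    pred = scored.scores >= threshold
    truth = scored.labels.astype(bool)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else None
    pre = tp / (tp + fp) if (tp + fp) else None
    rec = tp / (tp + fn) if (tp + fn) else None
    f1 = None
    if pre is not None and rec is not None and (pre + rec) > 0:
        f1 = 2 * pre * rec / (pre + rec)
    return MetricsReport(acc=acc, pre=pre, recall=rec, f1=f1, tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(scored: ScoredPairs, threshold: float = 0.0) -> MetricsReport:
    """Full report: ranking metrics plus confusion metrics at ``threshold``."""
    report = confusion_metrics(scored, threshold)
    report.auc = auc_score(scored)
    report.aupr = aupr_score(scored)
    return report


def score_split(
    params: ModelParams,
    train_graph: InteractionGraph,
    config: ModelConfig,
    pos: Sequence[Edge],
    neg: Sequence[Edge],
) -> ScoredPairs:
    """Score test positives and negatives with a trained model.

    Propagation runs on the training graph (its degrees, its edges); the
    test pairs themselves contribute nothing to message passing.
    """
    stack = forward(params, train_graph, config, training=False)
    star_u, star_v = final_embeddings(stack)
    pairs = list(pos) + list(neg)
    scores = score_pairs(star_u, star_v, pairs)
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return ScoredPairs(pairs=pairs, scores=scores, labels=labels)


@dataclass
class CVResult:
    """Per-fold reports, their arithmetic means, and the folds used."""

    per_fold: list[MetricsReport]
    averages: dict[str, float]
    folds: list[FoldSplit]
    roc_points: list[pd.DataFrame] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.per_fold]
        df = pd.DataFrame(rows)
        df.insert(0, "fold", range(1, len(rows) + 1))
        return df


def _averages(reports: list[MetricsReport]) -> dict[str, float]:
    keys = ["auc", "aupr", "acc", "pre", "recall", "f1"]
    out = {}
    for key in keys:
        vals = [getattr(r, key) for r in reports]
        if all(v is not None for v in vals):
            out[key] = float(np.mean(vals))
    return out


def _roc_points(scored: ScoredPairs) -> pd.DataFrame:
    order = np.argsort(-scored.scores, kind="stable")
    y = scored.labels.astype(bool)[order]
    tpr = np.cumsum(y) / max(y.sum(), 1)
    fpr = np.cumsum(~y) / max((~y).sum(), 1)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def cross_validate(
    graph: InteractionGraph,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.0,
    collect_roc: bool = False,
) -> CVResult:
    """K-fold cross-validation of the full pipeline.

    Per fold: fit on the training positives (the fold's training graph
    supplies the propagation degrees), score test positives plus the
    fold's balanced sampled negatives, and compute all metrics. Averages
    are arithmetic means across folds.
    """
    folds = make_folds(graph, k=k, seed=seed)
    reports: list[MetricsReport] = []
    roc: list[pd.DataFrame] = []
    for fs in folds:
        fold_train_cfg = replace(train_config, seed=train_config.seed + 1000 * (fs.fold_index + 1))
        params, _state = fit(graph, fs.train_pos, model_config, fold_train_cfg)
        train_graph = subgraph_with_edges(graph, fs.train_pos)
        scored = score_split(
            params, train_graph, model_config, sorted(fs.test_pos), sorted(fs.test_neg)
        )
        reports.append(compute_metrics(scored, threshold))
        if collect_roc:
            roc.append(_roc_points(scored))
        logger.info(
            "fold %d: AUC=%.4f AUPR=%.4f", fs.fold_index, reports[-1].auc, reports[-1].aupr
        )
    return CVResult(per_fold=reports, averages=_averages(reports), folds=folds,
                    roc_points=roc)


def sweep(
    parameter: Literal["K", "D"],
    values: Sequence[int],
    graph: InteractionGraph,
    model_config: ModelConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate once per hyperparameter value with shared fold seed.

    Returns one row per value with the averaged metrics, mirroring the
    layer-count and embedding-size tables of the original study design.
    """
    if parameter not in ("K", "D"):
        raise ValueError("parameter must be 'K' or 'D'")
    if len(values) == 0:
        raise ValueError("values must be non-empty")
    rows = []
    for value in values:
        cfg = replace(model_config, **{parameter: int(value)})
        result = cross_validate(graph, cfg, train_config, k=k, seed=seed)
        row = {parameter: int(value)}
        row.update({key.upper() if key in ("auc", "aupr") else key.capitalize(): v
                    for key, v in result.averages.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def degree_baseline_scores(
    train_graph: InteractionGraph, pairs: Sequence[Edge]
) -> np.ndarray:
    """Popularity baseline: score(u, v) = training deg(u) * deg(v)."""
    idx = np.asarray(list(pairs), dtype=np.int64)
    return (train_graph.deg_u[idx[:, 0]] * train_graph.deg_v[idx[:, 1]]).astype(float)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def rank_candidates(
    params: ModelParams,
    graph: InteractionGraph,
    query_id: str,
    config: ModelConfig,
    top_k: int = 10,
    exclude_known: bool = True,
    normalization: Literal["minmax", "sigmoid"] = "minmax",
) -> list[tuple[str, float]]:
    """Top-k cross-side candidates for one circRNA or miRNA, by score.

    The query may be either a circRNA or a miRNA identifier. With
    ``exclude_known`` the partners already present in ``graph`` (the
    training-known interactions) are removed before ranking, matching the
    case-study protocol. Scores are normalised over the scored candidate
    set (min-max by default, sigmoid optionally) and returned in descending
    order, ties broken by candidate index ascending.
    """
    stack = forward(params, graph, config, training=False)
    star_u, star_v = final_embeddings(stack)
    cm = graph.index_map
    if query_id in cm.circ_index:
        q = cm.circ_index[query_id]
        scores = score_matrix(star_u[q:q + 1], star_v)[0]
        known = {v for (u, v) in graph.edges if u == q}
        ids = cm.mir_ids
    elif query_id in cm.mir_index:
        q = cm.mir_index[query_id]
        scores = star_u @ star_v[q]
        known = {u for (u, v) in graph.edges if v == q}
        ids = cm.circ_ids
    else:
        raise KeyError(f"unknown identifier: {query_id!r}")
    candidates = np.arange(len(ids))
    if exclude_known and known:
        keep = ~np.isin(candidates, sorted(known))
        candidates = candidates[keep]
        scores = scores[keep]
    if candidates.size == 0:
        return []
    if normalization == "minmax":
        norm = _minmax(scores)
    elif normalization == "sigmoid":
        from scipy.special import expit

        norm = expit(scores)
    else:
        raise ValueError("normalization must be 'minmax' or 'sigmoid'")
    order = np.lexsort((candidates, -norm))
    top = order[: min(top_k, len(order))]
    return [(ids[int(candidates[t])], float(norm[t])) for t in top]
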