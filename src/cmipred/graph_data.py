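"""Bipartite interaction graphs from circRNA-miRNA edge lists.

This module owns the plumbing between raw two-column edge lists and the
indexed bipartite graph the model operates on: loading and de-duplicating
interaction records, assigning stable 0-based indices (first-appearance
order), degree bookkeeping, Laplacian normalisation coefficients, seeded
cross-validation splits with balanced negative sampling, and the pairwise
(u, i, j) triples consumed by the BPR objective.

Identifiers are matched by exact, case-sensitive string equality: circRNA
and miRNA accessions that differ in case or whitespace are deliberately
treated as distinct rather than silently merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "InteractionTable",
    "IndexMap",
    "InteractionGraph",
    "FoldSplit",
    "BprTriple",
    "ParseError",
    "load_edge_list",
    "build_graph",
    "graph_from_edges",
    "subgraph_with_edges",
    "norm_coefficient",
    "normalized_adjacency",
    "make_folds",
    "sample_negative_pairs",
    "sample_bpr_triples",
    "write_edge_list",
    "write_fold_manifest",
]

logger = logging.getLogger(__name__)

Edge = tuple[int, int]

#: Header tokens recognised (case-insensitively) when auto-detecting a
#: non-data first line in an edge list.
_HEADER_TOKENS = {
    "circrna", "circrna_id", "circ", "circ_id", "source",
    "mirna", "mirna_id", "mir", "mir_id", "target",
}


class ParseError(ValueError):
    """A malformed line in an interaction edge list."""


@dataclass
class InteractionTable:
    """Ordered, de-duplicated (circRNA id, miRNA id) interaction records."""

    records: list[tuple[str, str]]
    source_path: str = "in-memory"

    def __post_init__(self) -> None:
        for c, m in self.records:
            if not c or not m:
                raise ValueError("interaction ids must be non-empty strings")
        if len(set(self.records)) != len(self.records):
            raise ValueError("interaction table contains duplicate pairs")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class IndexMap:
    """Bijection between RNA identifiers and 0-based matrix indices.

    Index order is first-appearance order in the input, which makes the map
    deterministic without assuming anything about identifier lexicography.
    """

    circ_ids: tuple[str, ...]
    mir_ids: tuple[str, ...]

    @property
    def circ_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.circ_ids)}

    @property
    def mir_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.mir_ids)}


@dataclass(frozen=True)
class InteractionGraph:
    """Indexed bipartite graph of known circRNA-miRNA interactions.

    Holds the binary interaction structure R as an edge set over
    ``[0, n) x [0, m)`` plus per-side degree vectors (|N(u)|, |N(v)|).
    """

    n: int
    m: int
    edges: frozenset[Edge]
    deg_u: np.ndarray
    deg_v: np.ndarray
    index_map: IndexMap

    def __post_init__(self) -> None:
        if int(self.deg_u.sum()) != len(self.edges) or int(self.deg_v.sum()) != len(self.edges):
            raise ValueError("degree vectors inconsistent with edge set")
        for u, v in self.edges:
            if not (0 <= u < self.n and 0 <= v < self.m):
                raise ValueError(f"edge ({u}, {v}) outside [0,{self.n})x[0,{self.m})")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def dense_matrix(self) -> np.ndarray:
        """The interaction matrix R as a dense n x m {0,1} array."""
        r = np.zeros((self.n, self.m))
        for u, v in self.edges:
            r[u, v] = 1.0
        return r


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: positive partition plus sampled negatives."""

    fold_index: int
    train_pos: frozenset[Edge]
    test_pos: frozenset[Edge]
    train_neg: frozenset[Edge]
    test_neg: frozenset[Edge]


class BprTriple(NamedTuple):
    """Pairwise ranking sample: (u, i) observed, (u, j) unobserved."""

    u: int
    i: int
    j: int


def load_edge_list(path: str | Path, delimiter: str | None = None) -> InteractionTable:
    """Read a two-column interaction edge list.

    Lines starting with ``#`` and blank lines are skipped; a first line whose
    fields all look like column headers is skipped too. Duplicate pairs are
    collapsed, keeping first-appearance order. ``delimiter=None`` tries tab
    first, then comma.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ParseError
        For any data line with fewer than two fields (the line number is
        included in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")

    records: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    first_data_line = True
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            sep = delimiter
            if sep is None:
                sep = "\t" if "\t" in line else ","
            fields = line.split(sep)
            if first_data_line:
                first_data_line = False
                if all(f.strip().lower() in _HEADER_TOKENS for f in fields[:2]):
                    continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}: {line!r}"
                )
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                records.append(pair)
    logger.info("loaded %d unique interaction pairs from %s", len(records), path)
    return InteractionTable(records=records, source_path=str(path))


def build_graph(table: InteractionTable) -> InteractionGraph:
    """Index an interaction table into a bipartite graph.

    circRNAs and miRNAs are numbered by first appearance; degrees count
    incident known interactions on each side.
    """
    if len(table) == 0:
        raise ValueError("cannot build a graph from an empty interaction table")
    circ_ids: list[str] = []
    mir_ids: list[str] = []
    circ_index: dict[str, int] = {}
    mir_index: dict[str, int] = {}
    edges: set[Edge] = set()
    for c, m in table.records:
        if c not in circ_index:
            circ_index[c] = len(circ_ids)
            circ_ids.append(c)
        if m not in mir_index:
            mir_index[m] = len(mir_ids)
            mir_ids.append(m)
        edges.add((circ_index[c], mir_index[m]))
    n, m_ = len(circ_ids), len(mir_ids)
    deg_u = np.zeros(n, dtype=np.int64)
    deg_v = np.zeros(m_, dtype=np.int64)
    for u, v in edges:
        deg_u[u] += 1
        deg_v[v] += 1
    return InteractionGraph(
        n=n,
        m=m_,
        edges=frozenset(edges),
        deg_u=deg_u,
        deg_v=deg_v,
        index_map=IndexMap(tuple(circ_ids), tuple(mir_ids)),
    )


def graph_from_edges(n: int, m: int, edges: Iterable[Edge],
                     index_map: IndexMap | None = None) -> InteractionGraph:
    """Build an :class:`InteractionGraph` directly from index pairs."""
    edge_set = frozenset((int(u), int(v)) for u, v in edges)
    deg_u = np.zeros(n, dtype=np.int64)
    deg_v = np.zeros(m, dtype=np.int64)
    for u, v in edge_set:
        deg_u[u] += 1
        deg_v[v] += 1
    if index_map is None:
        index_map = IndexMap(
            tuple(f"circ_{i}" for i in range(n)),
            tuple(f"mir_{j}" for j in range(m)),
        )
    return InteractionGraph(n=n, m=m, edges=edge_set, deg_u=deg_u, deg_v=deg_v,
                            index_map=index_map)


def subgraph_with_edges(graph: InteractionGraph, edges: Iterable[Edge]) -> InteractionGraph:
    """Same node universe and index map, restricted edge set.

    Used per CV fold so that propagation degrees come from the training
    split only. Nodes whose every interaction fell into the test split are
    kept with degree 0 (cold start); they receive only self-messages.
    """
    return graph_from_edges(graph.n, graph.m, edges, index_map=graph.index_map)


def norm_coefficient(graph: InteractionGraph, u: int, v: int) -> float:
    """Graph Laplacian decay 1/sqrt(|N(u)| |N(v)|) for the message u<-v.

    Defined only when both endpoints have at least one known interaction
    (it is only ever evaluated on existing edges).
    """
    du, dv = int(graph.deg_u[u]), int(graph.deg_v[v])
    if du < 1 or dv < 1:
        raise ValueError(
            f"normalisation undefined for zero-degree endpoint (deg_u={du}, deg_v={dv})"
        )
    return 1.0 / float(np.sqrt(du * dv))


def normalized_adjacency(graph: InteractionGraph) -> sp.csr_matrix:
    """Sparse n x m matrix A with A[u, v] = 1/sqrt(|N(u)| |N(v)|) on edges."""
    if not graph.edges:
        return sp.csr_matrix((graph.n, graph.m))
    rows, cols = zip(*sorted(graph.edges))
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    vals = 1.0 / np.sqrt(graph.deg_u[rows] * graph.deg_v[cols])
    return sp.csr_matrix((vals, (rows, cols)), shape=(graph.n, graph.m))


def sample_negative_pairs(
    graph: InteractionGraph,
    count: int,
    exclude: Iterable[Edge] = (),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> frozenset[Edge]:
    """Sample ``count`` non-interacting pairs uniformly without replacement.

    Pairs are drawn from the complement of the known edge set, additionally
    excluding ``exclude`` (e.g. negatives already assigned to another role in
    the same fold). Sampling is uniform over the remaining pairs and
    deterministic under ``seed``/``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return frozenset()
    total = graph.n * graph.m
    forbidden = {u * graph.m + v for u, v in graph.edges}
    forbidden.update(u * graph.m + v for u, v in exclude)
    available = total - len(forbidden)
    if count > available:
        raise ValueError(
            f"requested {count} negative pairs but only {available} non-edges available"
        )
    chosen: set[int] = set()
    if count / max(available, 1) > 0.25:
        # dense regime: enumerate the complement and choose directly
        allowed = np.setdiff1d(
            np.arange(total), np.fromiter(forbidden, dtype=np.int64, count=len(forbidden)),
            assume_unique=True,
        )
        picks = rng.choice(allowed, size=count, replace=False)
        chosen.update(int(p) for p in picks)
    else:
        while len(chosen) < count:
            batch = rng.integers(0, total, size=2 * (count - len(chosen)) + 8)
            for flat in batch:
                flat = int(flat)
                if flat not in forbidden and flat not in chosen:
                    chosen.add(flat)
                    if len(chosen) == count:
                        break
    return frozenset((flat // graph.m, flat % graph.m) for flat in chosen)


def make_folds(
    graph: InteractionGraph, k: int = 5, seed: int | None = None
) -> list[FoldSplit]:
    """Partition the known interactions into ``k`` cross-validation folds.

    Positives are shuffled once (seeded) and split into near-equal parts;
    each fold takes one part as test positives and the rest as training
    positives. Per fold, an equal number of unlabeled (non-interacting)
    pairs is sampled for each role, never overlapping any known positive,
    and the four sets within a fold are pairwise disjoint. Negatives are
    drawn independently per fold.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if graph.n_edges < k:
        raise ValueError(f"cannot split {graph.n_edges} edges into {k} folds")
    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    order = rng.permutation(len(edges))
    parts = np.array_split(order, k)
    folds: list[FoldSplit] = []
    for fold_index, part in enumerate(parts):
        test_pos = frozenset(edges[i] for i in part)
        train_pos = frozenset(graph.edges - test_pos)
        train_neg = sample_negative_pairs(graph, len(train_pos), rng=rng)
        test_neg = sample_negative_pairs(graph, len(test_pos), exclude=train_neg, rng=rng)
        folds.append(
            FoldSplit(fold_index, train_pos, test_pos, train_neg, test_neg)
        )
    return folds


def sample_bpr_triples(
    train_pos: Iterable[Edge],
    graph: InteractionGraph,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[BprTriple]:
    """Draw one pairwise ranking triple per training positive.

    For every observed (u, i) a miRNA j is drawn uniformly from the miRNAs u
    is *not* known (in training) to interact with, by rejection sampling. A
    circRNA adjacent to every miRNA yields no triples and is skipped with a
    warning.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pos = sorted(train_pos)
    if not pos:
        raise ValueError("train_pos must be non-empty")
    pos_by_u: dict[int, set[int]] = {}
    for u, i in pos:
        pos_by_u.setdefault(u, set()).add(i)
    saturated = {u for u, s in pos_by_u.items() if len(s) >= graph.m}
    for u in sorted(saturated):
        logger.warning(
            "circRNA index %d interacts with all %d miRNAs in training; "
            "no ranking triples generated for it", u, graph.m
        )
    kept = [(u, i) for u, i in pos if u not in saturated]
    if not kept:
        return []
    us = np.array([u for u, _ in kept])
    is_ = np.array([i for _, i in kept])
    js = rng.integers(0, graph.m, size=len(kept))
    bad = np.array([j in pos_by_u[u] for u, j in zip(us, js)])
    while bad.any():
        js[bad] = rng.integers(0, graph.m, size=int(bad.sum()))
        bad_idx = np.flatnonzero(bad)
        still = np.array([js[t] in pos_by_u[us[t]] for t in bad_idx])
        bad = np.zeros(len(kept), dtype=bool)
        bad[bad_idx[still]] = True
    return [BprTriple(int(u), int(i), int(j)) for u, i, j in zip(us, is_, js)]


def write_edge_list(graph: InteractionGraph, path: str | Path, delimiter: str = "\t") -> None:
    """Write the graph's edges as a two-column id edge list (sorted by index)."""
    path = Path(path)
    cm = graph.index_map
    with path.open("w") as fh:
        for u, v in sorted(graph.edges):
            fh.write(f"{cm.circ_ids[u]}{delimiter}{cm.mir_ids[v]}\n")


def write_fold_manifest(
    folds: Sequence[FoldSplit], graph: InteractionGraph, path: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write all folds as (circRNA, miRNA, label, fold, role) rows."""
    path = Path(path)
    cm = graph.index_map
    with path.open("w") as fh:
        fh.write(delimiter.join(["circrna_id", "mirna_id", "label", "fold", "role"]) + "\n")
        for fs in folds:
            for edges, label, role in [
                (fs.train_pos, 1, "train"), (fs.test_pos, 1, "test"),
                (fs.train_neg, 0, "train"), (fs.test_neg, 0, "test"),
            ]:
                for u, v in sorted(edges):
                    fh.write(delimiter.join(
                        [cm.circ_ids[u], cm.mir_ids[v], str(label), str(fs.fold_index), role]
                    ) + "\n")
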