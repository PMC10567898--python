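"""Core containers and plain-text I/O.

The three objects every other module works with:

* :class:`ConstraintGraph` — the topological constraint ``G = (V, E)``: which
  directed interactions are possible at all.  Per node ``i`` it exposes the
  ordered successor set ``S(i)``.
* :class:`InteractionCounts` — the observed multiset of directed interactions,
  aggregated to counts ``n_ij`` with total ``m``.
* :class:`TransitionMatrix` — a row-stochastic matrix over a fixed node order.
  Rows of nodes with no defined distribution (sinks, or unobserved sources in
  the frequentist estimate) are stored as zeros and flagged in ``defined``;
  they are materialised as uniform rows only when a downstream consumer needs
  a fully stochastic matrix.

Node identifiers are opaque strings; integer-looking labels are never coerced.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from typing import IO

import numpy as np

__all__ = [
    "ConstraintGraph",
    "InteractionCounts",
    "TransitionMatrix",
    "ParseError",
    "ConstraintViolationError",
    "read_interactions",
    "read_constraint",
    "constraint_from_weights",
    "write_transition_matrix",
    "read_transition_matrix",
]

ROW_SUM_TOL = 1e-9


class ParseError(ValueError):
    """Raised for malformed lines in edge-list or matrix files."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ConstraintViolationError(ValueError):
    """An observation falls on a pair outside the topological constraint."""

    def __init__(self, pair: tuple[str, str]):
        super().__init__(
            f"observed interaction {pair!r} is outside the constraint "
            "(its prior probability is exactly zero)"
        )
        self.pair = pair


class ConstraintGraph:
    """Directed possible-edge set with per-node successor lists.

    Node order is the insertion order of ``nodes`` (deduplicated); successor
    lists are ordered by node index, so matrix indexing is reproducible across
    runs for the same input.
    """

    __slots__ = ("nodes", "index", "_succ", "_edge_keys")

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        ordered: list[str] = []
        index: dict[str, int] = {}
        for v in nodes:
            v = str(v)
            if v not in index:
                index[v] = len(ordered)
                ordered.append(v)
        self.nodes: tuple[str, ...] = tuple(ordered)
        self.index: dict[str, int] = index
        n = len(ordered)
        pair_set: set[tuple[int, int]] = set()
        for i, j in edges:
            i, j = str(i), str(j)
            if i not in index or j not in index:
                raise ValueError(f"edge ({i!r}, {j!r}) references unknown node")
            pair_set.add((index[i], index[j]))
        succ: list[list[int]] = [[] for _ in range(n)]
        for i, j in pair_set:
            succ[i].append(j)
        self._succ: list[np.ndarray] = [
            np.array(sorted(s), dtype=np.intp) for s in succ
        ]
        keys = np.array([i * n + j for i, j in pair_set], dtype=np.int64)
        keys.sort()
        self._edge_keys = keys

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "ConstraintGraph":
        """Build a graph whose node set is exactly the nodes seen on edges."""
        edges = [(str(i), str(j)) for i, j in edges]
        nodes: list[str] = []
        for i, j in edges:
            nodes.append(i)
            nodes.append(j)
        return cls(nodes, edges)

    @classmethod
    def complete(
        cls, nodes: Iterable[str], self_loops: bool = False
    ) -> "ConstraintGraph":
        """Complete directed graph on ``nodes`` (self-loops optional)."""
        nodes = [str(v) for v in nodes]
        edges = [
            (i, j) for i in nodes for j in nodes if self_loops or i != j
        ]
        return cls(nodes, edges)

    # -- queries --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self._edge_keys.size)

    @property
    def edges(self) -> list[tuple[str, str]]:
        n = self.n_nodes
        return [
            (self.nodes[int(k) // n], self.nodes[int(k) % n])
            for k in self._edge_keys
        ]

    def successors(self, node: str) -> tuple[str, ...]:
        idx = self._succ[self.index[str(node)]]
        return tuple(self.nodes[j] for j in idx)

    def successor_indices(self, i: int) -> np.ndarray:
        """Successor node indices of node index ``i`` (sorted, read-only)."""
        return self._succ[i]

    @property
    def out_degrees(self) -> np.ndarray:
        return np.array([s.size for s in self._succ], dtype=np.intp)

    def has_edge(self, i: str, j: str) -> bool:
        key = self.index[str(i)] * self.n_nodes + self.index[str(j)]
        pos = np.searchsorted(self._edge_keys, key)
        return pos < self._edge_keys.size and self._edge_keys[pos] == key

    def contains_pairs(self, src_idx: np.ndarray, dst_idx: np.ndarray) -> np.ndarray:
        """Vectorised membership test on index pairs."""
        keys = src_idx.astype(np.int64) * self.n_nodes + dst_idx
        pos = np.searchsorted(self._edge_keys, keys)
        pos = np.clip(pos, 0, max(self._edge_keys.size - 1, 0))
        if self._edge_keys.size == 0:
            return np.zeros(keys.shape, dtype=bool)
        return self._edge_keys[pos] == keys

    def edge_index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """All edges as parallel (src, dst) index arrays in key order."""
        n = self.n_nodes
        return (self._edge_keys // n).astype(np.intp), (
            self._edge_keys % n
        ).astype(np.intp)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ConstraintGraph)
            and self.nodes == other.nodes
            and np.array_equal(self._edge_keys, other._edge_keys)
        )

    def __hash__(self):  # pragma: no cover - identity hashing is fine here
        return id(self)

    def __repr__(self) -> str:
        return f"ConstraintGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class InteractionCounts:
    """Aggregated observation counts ``n_ij`` over directed node pairs."""

    __slots__ = ("counts", "total")

    def __init__(self, counts: Mapping[tuple[str, str], int] | None = None):
        agg: dict[tuple[str, str], int] = {}
        total = 0
        if counts:
            for (i, j), n in counts.items():
                n = int(n)
                if n < 0:
                    raise ValueError(f"negative count for pair ({i!r}, {j!r})")
                if n == 0:
                    continue
                key = (str(i), str(j))
                agg[key] = agg.get(key, 0) + n
                total += n
        self.counts: dict[tuple[str, str], int] = agg
        self.total: int = total

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionCounts":
        agg: dict[tuple[str, str], int] = {}
        for i, j in pairs:
            key = (str(i), str(j))
            agg[key] = agg.get(key, 0) + 1
        return cls(agg)

    @classmethod
    def from_arrays(
        cls,
        nodes: Sequence[str],
        src_idx: np.ndarray,
        dst_idx: np.ndarray,
        values: np.ndarray,
    ) -> "InteractionCounts":
        """Build from parallel index arrays against a fixed node order."""
        obj = cls.__new__(cls)
        pos = values > 0
        obj.counts = {
            (nodes[int(s)], nodes[int(d)]): int(v)
            for s, d, v in zip(src_idx[pos], dst_idx[pos], values[pos])
        }
        obj.total = int(values[pos].sum())
        return obj

    def get(self, pair: tuple[str, str]) -> int:
        return self.counts.get((str(pair[0]), str(pair[1])), 0)

    def items(self):
        return self.counts.items()

    def merged(self, other: "InteractionCounts") -> "InteractionCounts":
        agg = dict(self.counts)
        for k, n in other.counts.items():
            agg[k] = agg.get(k, 0) + n
        return InteractionCounts(agg)

    def source_nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for i, _ in self.counts:
            seen.setdefault(i)
        return list(seen)

    def all_nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for i, j in self.counts:
            seen.setdefault(i)
            seen.setdefault(j)
        return list(seen)

    def __len__(self) -> int:
        return len(self.counts)

    def __repr__(self) -> str:
        return f"InteractionCounts(n_pairs={len(self.counts)}, total={self.total})"


class TransitionMatrix:
    """Row-stochastic matrix over an explicit node order.

    Parameters
    ----------
    values
        ``(N, N)`` array.  Rows flagged ``defined`` must sum to one within
        ``1e-9``; undefined rows must be all zero.
    nodes
        Node labels in row/column order.
    defined
        Boolean row mask; by default inferred as "row sums to ~1".
    support
        Optional :class:`ConstraintGraph`; when given, entries outside its
        edge set must be exactly zero.
    """

    __slots__ = ("values", "nodes", "index", "defined", "support")

    def __init__(
        self,
        values: np.ndarray,
        nodes: Sequence[str],
        defined: np.ndarray | None = None,
        support: ConstraintGraph | None = None,
        validate: bool = True,
    ):
        values = np.asarray(values, dtype=float)
        nodes = tuple(str(v) for v in nodes)
        if values.shape != (len(nodes), len(nodes)):
            raise ValueError("matrix shape does not match node list")
        if defined is None:
            defined = np.abs(values.sum(axis=1) - 1.0) <= ROW_SUM_TOL
        defined = np.asarray(defined, dtype=bool)
        self.values = values
        self.nodes = nodes
        self.index = {v: k for k, v in enumerate(nodes)}
        self.defined = defined
        self.support = support
        if validate:
            self._validate()

    def _validate(self) -> None:
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums[self.defined] - 1.0) > ROW_SUM_TOL):
            raise ValueError("a defined row does not sum to 1")
        if np.any(sums[~self.defined] != 0.0):
            raise ValueError("an undefined row is not all zero")
        if self.support is not None:
            mask = np.zeros_like(self.values, dtype=bool)
            src, dst = self.support.edge_index_arrays()
            mask[src, dst] = True
            if np.any(self.values[~mask] != 0.0):
                raise ValueError("nonzero entry outside the declared support")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def materialized(self) -> np.ndarray:
        """Dense stochastic matrix with undefined rows set uniform over V."""
        out = self.values.copy()
        if not self.defined.all():
            out[~self.defined] = 1.0 / self.n_nodes
        return out

    def reindexed(self, nodes: Sequence[str]) -> "TransitionMatrix":
        """Same matrix under a different node order (a permutation of ours)."""
        nodes = [str(v) for v in nodes]
        if sorted(nodes) != sorted(self.nodes):
            raise ValueError("node sets differ")
        perm = np.array([self.index[v] for v in nodes], dtype=np.intp)
        return TransitionMatrix(
            self.values[np.ix_(perm, perm)],
            nodes,
            defined=self.defined[perm],
            validate=False,
        )

    def __repr__(self) -> str:
        return (
            f"TransitionMatrix(n_nodes={self.n_nodes}, "
            f"defined_rows={int(self.defined.sum())})"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _data_lines(stream: IO[str] | str):
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def read_interactions(
    stream: IO[str] | str,
    dialect: str = "pairs",
    delimiter: str | None = None,
) -> InteractionCounts:
    """Read an interaction edge list.

    ``dialect="pairs"`` expects ``i j`` per line (repeats accumulate);
    ``dialect="counts"`` expects ``i j n`` with a nonnegative integer count.
    ``delimiter=None`` splits on any whitespace.
    """
    if dialect not in ("pairs", "counts"):
        raise ValueError(f"unknown dialect {dialect!r}")
    want = 2 if dialect == "pairs" else 3
    agg: dict[tuple[str, str], int] = {}
    for lineno, line in _data_lines(stream):
        fields = line.split(delimiter)
        if len(fields) != want:
            raise ParseError(
                f"expected {want} fields, got {len(fields)}", line=lineno
            )
        i, j = fields[0], fields[1]
        if dialect == "pairs":
            n = 1
        else:
            try:
                n = int(fields[2])
            except ValueError:
                raise ParseError(
                    f"count field {fields[2]!r} is not an integer", line=lineno
                ) from None
            if n < 0:
                raise ValueError(
                    f"line {lineno}: negative count {n} for pair ({i!r}, {j!r})"
                )
        if n:
            agg[(i, j)] = agg.get((i, j), 0) + n
    return InteractionCounts(agg)


def read_constraint(
    stream: IO[str] | str, delimiter: str | None = None
) -> ConstraintGraph:
    """Read a directed edge list into a constraint graph (edges deduplicated)."""
    edges: list[tuple[str, str]] = []
    for lineno, line in _data_lines(stream):
        fields = line.split(delimiter)
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 fields, got {len(fields)}", line=lineno
            )
        edges.append((fields[0], fields[1]))
    return ConstraintGraph.from_edges(edges)


def constraint_from_weights(
    adjacency: np.ndarray, nodes: Sequence[str] | None = None
) -> tuple[ConstraintGraph, TransitionMatrix]:
    """Constraint and ground-truth transition matrix from a weighted adjacency.

    Edges are the strictly positive entries; each row with positive sum is
    normalised to a transition distribution.  All-zero rows are retained as
    sinks with an undefined transition row.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be nonnegative")
    n = A.shape[0]
    if nodes is None:
        nodes = [str(k) for k in range(n)]
    nodes = [str(v) for v in nodes]
    src, dst = np.nonzero(A > 0)
    graph = ConstraintGraph(nodes, [(nodes[i], nodes[j]) for i, j in zip(src, dst)])
    sums = A.sum(axis=1)
    defined = sums > 0
    T = np.zeros_like(A)
    T[defined] = A[defined] / sums[defined, None]
    return graph, TransitionMatrix(T, nodes, defined=defined, support=graph)


def write_transition_matrix(
    matrix: TransitionMatrix, stream: IO[str], fmt: str = "dense"
) -> None:
    """Write a transition matrix as dense CSV or sparse triplet TSV.

    Dense CSV carries node labels in the first row and column; the triplet
    format writes one ``i<TAB>j<TAB>value`` line per nonzero entry.
    """
    if fmt == "dense":
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(["", *matrix.nodes])
        for i, node in enumerate(matrix.nodes):
            writer.writerow([node, *(repr(float(x)) for x in matrix.values[i])])
    elif fmt == "triplet":
        src, dst = np.nonzero(matrix.values)
        for i, j in zip(src, dst):
            stream.write(
                f"{matrix.nodes[i]}\t{matrix.nodes[j]}\t{float(matrix.values[i, j])!r}\n"
            )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_transition_matrix(
    stream: IO[str] | str,
    fmt: str = "dense",
    nodes: Sequence[str] | None = None,
) -> TransitionMatrix:
    """Inverse of :func:`write_transition_matrix`.

    For the triplet format the node order cannot be recovered from the file
    alone when rows are missing, so an explicit ``nodes`` sequence may be
    given; otherwise first-appearance order is used.
    """
    if fmt == "dense":
        text = stream if isinstance(stream, str) else stream.read()
        rows = list(csv.reader(text.splitlines()))
        header = rows[0][1:]
        values = np.array(
            [[float(x) for x in row[1:]] for row in rows[1:]], dtype=float
        )
        labels = [row[0] for row in rows[1:]]
        if labels != header:
            raise ParseError("row labels do not match column header")
        return TransitionMatrix(values, header)
    if fmt == "triplet":
        entries: list[tuple[str, str, float]] = []
        for lineno, line in _data_lines(stream):
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(
                    f"expected 3 fields, got {len(fields)}", line=lineno
                )
            entries.append((fields[0], fields[1], float(fields[2])))
        if nodes is None:
            seen: dict[str, None] = {}
            for i, j, _ in entries:
                seen.setdefault(i)
                seen.setdefault(j)
            nodes = list(seen)
        nodes = [str(v) for v in nodes]
        index = {v: k for k, v in enumerate(nodes)}
        values = np.zeros((len(nodes), len(nodes)))
        for i, j, x in entries:
            values[index[i], index[j]] = x
        return TransitionMatrix(values, nodes)
    raise ValueError(f"unknown format {fmt!r}")
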