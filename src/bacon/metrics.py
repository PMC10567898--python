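"""Evaluation metrics and random-walk downstream tasks.

Matrix recovery is scored by the Frobenius distance
``||A - B|| = sqrt(sum_ij (A_ij - B_ij)^2)``.  Downstream tasks compare an
inferred transition matrix against the ground truth through the analyses a
practitioner would actually run on it: PageRank node ranking (agreement via
Kendall tau-b) and map-equation community detection (agreement via adjusted
mutual information).  The data-requirement machinery (:class:`ErrorCurve`,
:func:`data_requirement_ratio`) turns error-versus-sample-size sweeps into
"method A needs r times more data than method B" statements.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau as _kendalltau
from sklearn.metrics import adjusted_mutual_info_score as _ami

from .graph import TransitionMatrix
from .mapequation import optimize_map_equation

__all__ = [
    "ScoreVector",
    "ErrorCurve",
    "NotReachedError",
    "frobenius_distance",
    "pagerank",
    "kendall_tau",
    "detect_clusters",
    "adjusted_mutual_information",
    "count_clusters",
    "threshold_crossing",
    "data_requirement_ratio",
]


class NotReachedError(RuntimeError):
    """An error curve never drops below the requested threshold."""

    def __init__(self, threshold: float, last_mean: float):
        super().__init__(
            f"mean error never reached {threshold} (last mean {last_mean:.4g})"
        )
        self.threshold = threshold
        self.last_mean = last_mean


@dataclass
class ScoreVector:
    """Per-node real scores; the induced ranking is by descending score."""

    nodes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.nodes = tuple(str(v) for v in self.nodes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.nodes),):
            raise ValueError("scores must align with nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.nodes, map(float, self.values)))

    def aligned(self, nodes) -> np.ndarray:
        index = {v: k for k, v in enumerate(self.nodes)}
        try:
            perm = [index[str(v)] for v in nodes]
        except KeyError as exc:
            raise ValueError(f"node {exc.args[0]!r} missing from scores") from None
        return self.values[perm]


def _check_same_nodes(a_nodes, b_nodes):
    if set(a_nodes) != set(b_nodes):
        raise ValueError("node sets differ")


def frobenius_distance(a: TransitionMatrix, b: TransitionMatrix) -> float:
    """``sqrt(sum_ij (a_ij - b_ij)^2)`` over a shared node order.

    Undefined rows enter as their stored zeros, so an unobserved frequentist
    row contributes the full mass of the reference row.
    """
    _check_same_nodes(a.nodes, b.nodes)
    if a.nodes != b.nodes:
        b = b.reindexed(a.nodes)
    return float(np.linalg.norm(a.values - b.values))


def pagerank(
    matrix: TransitionMatrix,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> ScoreVector:
    """Stationary scores of ``s = d T' s + (1 - d) u`` by power iteration.

    Undefined rows are materialised as uniform teleport rows first; the
    returned scores sum to one.  Convergence is declared at L1 change below
    ``tol``; exceeding ``max_iter`` raises with the residual reported.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    P = matrix.materialized()
    n = P.shape[0]
    s = np.full(n, 1.0 / n)
    base = (1.0 - damping) / n
    for _ in range(max_iter):
        s_new = damping * (P.T @ s) + base
        delta = float(np.abs(s_new - s).sum())
        s = s_new
        if delta < tol:
            s = s / s.sum()
            return ScoreVector(matrix.nodes, s)
    raise RuntimeError(
        f"PageRank did not converge in {max_iter} iterations (residual {delta:.3g})"
    )


def kendall_tau(a: ScoreVector, b: ScoreVector) -> float:
    """Tie-aware Kendall rank correlation (tau-b) between two score vectors.

    A completely tied score vector induces no ranking; its correlation with
    anything is reported as 0 (the "uncorrelated" value).
    """
    _check_same_nodes(a.nodes, b.nodes)
    if len(a.nodes) < 2:
        raise ValueError("Kendall tau needs at least 2 nodes")
    tau = _kendalltau(a.values, b.aligned(a.nodes)).statistic
    return 0.0 if np.isnan(tau) else float(tau)


def _flow_edges(matrix: TransitionMatrix, flow_weights: bool, damping: float):
    """Directed weighted edges handed to community detection.

    With ``flow_weights`` the transition probabilities are scaled by the
    source node's PageRank visit rate (the flow form of the map equation);
    otherwise the raw probabilities are used.  Undefined rows contribute no
    edges either way.
    """
    src, dst = np.nonzero(matrix.values)
    w = matrix.values[src, dst]
    if flow_weights:
        visit = pagerank(matrix, damping=damping).values
        w = visit[src] * w
    return src, dst, w


def detect_clusters(
    matrix: TransitionMatrix,
    backend: str = "igraph",
    seed: int = 0,
    flow_weights: bool = True,
    damping: float = 0.85,
) -> dict[str, int]:
    """Map-equation community detection on an inferred transition matrix.

    ``backend="igraph"`` runs igraph's InfoMap implementation;
    ``backend="builtin"`` runs the bundled two-level optimizer
    (:mod:`bacon.mapequation`).  Nodes without edges become singleton
    clusters.  Deterministic for a fixed seed.
    """
    src, dst, w = _flow_edges(matrix, flow_weights, damping)
    n = matrix.n_nodes
    if src.size == 0:
        return {v: k for k, v in enumerate(matrix.nodes)}
    if backend == "igraph":
        import igraph as ig

        state = _random.Random(int(seed))
        ig.set_random_number_generator(state)
        g = ig.Graph(n=n, edges=list(zip(src.tolist(), dst.tolist())), directed=True)
        membership = g.community_infomap(edge_weights=w.tolist(), trials=3).membership
        labels = np.asarray(membership)
    elif backend == "builtin":
        labels = optimize_map_equation(n, src, dst, w, seed=seed)
    else:
        raise ValueError(
            f"unknown backend {backend!r}; use 'igraph' or the bundled 'builtin'"
        )
    # canonical labelling by first appearance, singletons included
    seen: dict[int, int] = {}
    out: dict[str, int] = {}
    for i, v in enumerate(matrix.nodes):
        out[v] = seen.setdefault(int(labels[i]), len(seen))
    return out


def adjusted_mutual_information(a: dict[str, int], b: dict[str, int]) -> float:
    """AMI between two labelings, chance-corrected (permutation model)."""
    _check_same_nodes(a.keys(), b.keys())
    nodes = sorted(a)
    return float(_ami([a[v] for v in nodes], [b[v] for v in nodes]))


def count_clusters(labeling: dict[str, int]) -> int:
    return len(set(labeling.values()))


@dataclass
class ErrorCurve:
    """Replicated metric values over a grid of sample sizes.

    ``values`` has shape (replicates, len(sample_sizes)); summaries are the
    mean and the 2.5th/97.5th percentiles (linear interpolation convention).
    """

    sample_sizes: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.sample_sizes = np.asarray(self.sample_sizes)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.sample_sizes) <= 0):
            raise ValueError("sample sizes must be strictly increasing")
        if self.values.shape[1] != self.sample_sizes.size:
            raise ValueError("values must have one column per sample size")

    @property
    def mean(self) -> np.ndarray:
        # nan-aware: failed replicate cells are excluded from summaries
        return np.nanmean(self.values, axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = np.sum(~np.isnan(self.values), axis=0)
        if self.values.shape[0] < 2:
            return np.zeros(self.sample_sizes.size)
        return np.nanstd(self.values, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))

    def percentiles(self, lo: float = 2.5, hi: float = 97.5):
        return (
            np.nanpercentile(self.values, lo, axis=0),
            np.nanpercentile(self.values, hi, axis=0),
        )


def threshold_crossing(curve: ErrorCurve, threshold: float) -> float:
    """Sample size at which the mean error first drops below ``threshold``.

    Located by log-linear interpolation on the (log m, mean) segment that
    brackets the crossing; if the very first grid point is already below,
    that size is returned.  Never crossing raises :class:`NotReachedError`.
    """
    means = curve.mean
    below = means < threshold
    if not below.any():
        raise NotReachedError(threshold, float(means[-1]))
    i = int(np.argmax(below))
    if i == 0:
        return float(curve.sample_sizes[0])
    m0, m1 = curve.sample_sizes[i - 1], curve.sample_sizes[i]
    e0, e1 = means[i - 1], means[i]
    frac = (e0 - threshold) / (e0 - e1)
    return float(np.exp(np.log(m0) + frac * (np.log(m1) - np.log(m0))))


def data_requirement_ratio(
    curve_a: ErrorCurve, curve_b: ErrorCurve, threshold: float
) -> float:
    """How many times more data curve A needs than curve B to hit ``threshold``."""
    if not np.array_equal(curve_a.sample_sizes, curve_b.sample_sizes):
        raise ValueError("curves must share the sample-size grid")
    return threshold_crossing(curve_a, threshold) / threshold_crossing(
        curve_b, threshold
    )
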