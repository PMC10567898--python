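"""Transition-matrix estimators: frequentist, noninformative Bayes, BaCon.

The three estimators share one statistical setting.  A random walker at node
``i`` picks a successor ``j`` with probability ``pi_ij``; we observe ``n_ij``
interactions and want the row-stochastic matrix ``T``.

* **Frequentist (MLE)** — ``pi_ij = n_ij / sum_k n_ik``.  Rows of nodes never
  observed as a source are undefined.
* **Noninformative Bayes** — symmetric Dirichlet prior with concentration
  ``alpha`` (default 1, the uniform prior) on *every* possible successor,
  i.e. the complete graph: no topological knowledge.
* **BaCon** — the same conjugate machinery, but the prior lives only on the
  successors allowed by a topological constraint ``G=(V,E)``; pairs outside
  ``E`` carry a Dirac delta at zero.  The posterior for row ``i`` is
  ``Dir(alpha * 1_{|S(i)|} + n_i)`` and its mean is
  ``E[T_ij] = alpha_ij / sum_k alpha_ik``.

The evidence (log marginal likelihood) of the observations given ``alpha``
is analytic and is used to select the shape hyperparameter from a candidate
grid by maximum a posteriori under a flat hyperprior.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .graph import (
    ConstraintGraph,
    ConstraintViolationError,
    InteractionCounts,
    TransitionMatrix,
)

__all__ = [
    "DirichletPosterior",
    "EvidenceTable",
    "fit_frequentist",
    "fit_bacon",
    "fit_noninformative",
    "posterior_mean",
    "topology_baseline",
    "log_marginal_likelihood",
    "select_alpha",
    "default_alpha_grid",
    "per_successor_alpha",
    "FrequentistTransitionModel",
    "BayesTransitionModel",
    "TransitionResults",
    "BayesTransitionResults",
]


def default_alpha_grid(
    low: float = 1e-2, high: float = 1e2, size: int = 50
) -> np.ndarray:
    """Candidate shape parameters: ``size`` points log-spaced on [low, high]."""
    if low <= 0 or high <= 0 or size < 1:
        raise ValueError("grid bounds must be positive and size >= 1")
    return np.logspace(np.log10(low), np.log10(high), size)


def per_successor_alpha(constraint: ConstraintGraph) -> np.ndarray:
    """Per-node shape ``1/|S(i)|`` (Schurmann–Grassberger-style preset).

    Nodes without successors get alpha 1; their rows carry no prior anyway.
    """
    deg = constraint.out_degrees.astype(float)
    out = np.ones_like(deg)
    np.divide(1.0, deg, out=out, where=deg > 0)
    return out


def _node_alphas(constraint: ConstraintGraph, alpha) -> np.ndarray:
    """Normalise the ``alpha`` argument to a per-node array of shapes."""
    if isinstance(alpha, str):
        if alpha == "sg":
            return per_successor_alpha(constraint)
        raise ValueError(f"unknown alpha preset {alpha!r}")
    arr = np.asarray(alpha, dtype=float)
    if arr.ndim == 0:
        arr = np.full(constraint.n_nodes, float(arr))
    elif arr.shape != (constraint.n_nodes,):
        raise ValueError("per-node alpha must have one entry per node")
    if np.any(arr <= 0):
        raise ValueError("alpha must be strictly positive")
    return arr


def _counts_on_constraint(
    counts: InteractionCounts, constraint: ConstraintGraph
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed counts as (src, dst, n) index arrays, validated against E."""
    if not counts.counts:
        e = np.empty(0, dtype=np.intp)
        return e, e, np.empty(0, dtype=np.int64)
    src, dst, val = [], [], []
    for (i, j), n in counts.items():
        if i not in constraint.index or j not in constraint.index:
            raise ConstraintViolationError((i, j))
        src.append(constraint.index[i])
        dst.append(constraint.index[j])
        val.append(n)
    src = np.array(src, dtype=np.intp)
    dst = np.array(dst, dtype=np.intp)
    val = np.array(val, dtype=np.int64)
    ok = constraint.contains_pairs(src, dst)
    if not ok.all():
        k = int(np.argmin(ok))
        raise ConstraintViolationError(
            (constraint.nodes[src[k]], constraint.nodes[dst[k]])
        )
    return src, dst, val


class DirichletPosterior:
    """Per-node Dirichlet concentrations over the constrained successors.

    With zero data this is the prior itself: ``alpha * 1_{|S(i)|}`` per node.
    """

    __slots__ = ("constraint", "alpha0", "concentrations")

    def __init__(
        self,
        constraint: ConstraintGraph,
        alpha0,
        concentrations: list[np.ndarray],
    ):
        self.constraint = constraint
        self.alpha0 = alpha0
        self.concentrations = concentrations
        for i, c in enumerate(concentrations):
            if c.size != constraint.successor_indices(i).size:
                raise ValueError(f"concentration length mismatch at node {i}")
            if np.any(c <= 0):
                raise ValueError("concentrations must be strictly positive")

    def row(self, node: str) -> tuple[tuple[str, ...], np.ndarray]:
        """Successor labels and concentration vector for one node."""
        i = self.constraint.index[str(node)]
        return self.constraint.successors(node), self.concentrations[i].copy()

    def updated(self, counts: InteractionCounts) -> "DirichletPosterior":
        """Conjugate update: add new observation counts to the concentrations."""
        src, dst, val = _counts_on_constraint(counts, self.constraint)
        conc = [c.copy() for c in self.concentrations]
        for s, d, n in zip(src, dst, val):
            succ = self.constraint.successor_indices(int(s))
            conc[int(s)][np.searchsorted(succ, d)] += n
        return DirichletPosterior(self.constraint, self.alpha0, conc)

    def mean(self) -> TransitionMatrix:
        return posterior_mean(self)

    def __repr__(self) -> str:
        return (
            f"DirichletPosterior(n_nodes={self.constraint.n_nodes}, "
            f"alpha0={self.alpha0!r})"
        )


def fit_frequentist(
    counts: InteractionCounts, nodes: Sequence[str] | None = None
) -> TransitionMatrix:
    """Maximum-likelihood rows ``n_ij / n_i``; unobserved sources undefined."""
    if nodes is None:
        nodes = counts.all_nodes()
    nodes = [str(v) for v in nodes]
    index = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    C = np.zeros((n, n))
    for (i, j), c in counts.items():
        if i not in index or j not in index:
            raise ValueError(f"counts mention unknown node in pair ({i!r}, {j!r})")
        C[index[i], index[j]] += c
    sums = C.sum(axis=1)
    defined = sums > 0
    T = np.zeros_like(C)
    T[defined] = C[defined] / sums[defined, None]
    return TransitionMatrix(T, nodes, defined=defined)


def fit_bacon(
    counts: InteractionCounts,
    constraint: ConstraintGraph,
    alpha=1.0,
) -> DirichletPosterior:
    """Conjugate posterior under the topological prior.

    ``alpha`` may be a scalar, a per-node array, or the preset ``"sg"``
    (``1/|S(i)|``).  Observations outside the constraint raise
    :class:`~bacon.graph.ConstraintViolationError`.
    """
    alphas = _node_alphas(constraint, alpha)
    src, dst, val = _counts_on_constraint(counts, constraint)
    conc = [
        np.full(constraint.successor_indices(i).size, alphas[i])
        for i in range(constraint.n_nodes)
    ]
    for s, d, n in zip(src, dst, val):
        succ = constraint.successor_indices(int(s))
        conc[int(s)][np.searchsorted(succ, d)] += n
    a0 = float(alpha) if np.ndim(alpha) == 0 and not isinstance(alpha, str) else alphas
    return DirichletPosterior(constraint, a0, conc)


def fit_noninformative(
    counts: InteractionCounts,
    nodes: Sequence[str],
    alpha: float = 1.0,
    self_loops: bool = False,
) -> DirichletPosterior:
    """Uniform Dirichlet prior on the complete graph — no topological input.

    Identical to :func:`fit_bacon` with the complete directed graph on
    ``nodes`` as constraint.  Self-loops are excluded by default so the
    successor spaces match the synthetic generators; pass
    ``self_loops=True`` to put prior mass on them as well.
    """
    complete = ConstraintGraph.complete(nodes, self_loops=self_loops)
    return fit_bacon(counts, complete, alpha)


def posterior_mean(posterior: DirichletPosterior) -> TransitionMatrix:
    """Expected transition matrix ``E[T_ij] = alpha_ij / sum_k alpha_ik``."""
    g = posterior.constraint
    n = g.n_nodes
    T = np.zeros((n, n))
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        succ = g.successor_indices(i)
        if succ.size == 0:
            continue
        c = posterior.concentrations[i]
        if np.all(c == c[0]):
            # symmetric row: the mean is exactly uniform (alpha cancels)
            T[i, succ] = 1.0 / succ.size
        else:
            T[i, succ] = c / c.sum()
        defined[i] = True
    return TransitionMatrix(T, g.nodes, defined=defined, support=g)


def topology_baseline(constraint: ConstraintGraph) -> TransitionMatrix:
    """Uniform rows over ``S(i)``: the zero-data limit of BaCon for any alpha."""
    n = constraint.n_nodes
    T = np.zeros((n, n))
    defined = np.zeros(n, dtype=bool)
    for i in range(n):
        succ = constraint.successor_indices(i)
        if succ.size:
            T[i, succ] = 1.0 / succ.size
            defined[i] = True
    return TransitionMatrix(T, constraint.nodes, defined=defined, support=constraint)


def _evidence_terms(
    counts: InteractionCounts, constraint: ConstraintGraph
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Sufficient statistics for the evidence: per-observation and per-node.

    Returns (obs counts n_ij, source index of each observation, per-node
    totals n_i, per-node successor counts K_i, log multinomial coefficient).
    """
    src, _dst, val = _counts_on_constraint(counts, constraint)
    n_i = np.zeros(constraint.n_nodes)
    np.add.at(n_i, src, val)
    K = constraint.out_degrees.astype(float)
    log_z = float(np.sum(gammaln(n_i + 1)) - np.sum(gammaln(val + 1)))
    return val.astype(float), src, n_i, K, log_z


def log_marginal_likelihood(
    counts: InteractionCounts,
    constraint: ConstraintGraph,
    alpha=1.0,
) -> float:
    """Log evidence ``log p(E | alpha, G)`` of the observed interactions.

    Per node the multinomial likelihood integrates against the Dirichlet
    prior to ``Z_i * B(alpha_i0 + n_i) / B(alpha_i0)`` with ``B`` the
    multivariate beta function and ``Z_i`` the multinomial coefficient;
    everything is evaluated in log space via log-gamma.  Zero data gives 0.
    """
    alphas = _node_alphas(constraint, alpha)
    val, src, n_i, K, log_z = _evidence_terms(counts, constraint)
    a = alphas[src]
    obs_term = float(np.sum(gammaln(a + val) - gammaln(a)))
    active = n_i > 0
    node_term = float(
        np.sum(
            gammaln(K[active] * alphas[active])
            - gammaln(K[active] * alphas[active] + n_i[active])
        )
    )
    return log_z + obs_term + node_term


@dataclass
class EvidenceTable:
    """Log evidence per candidate alpha and the MAP choice.

    Ties are broken toward the smallest candidate — the safer default when
    the constraint may contain spurious edges.
    """

    alphas: np.ndarray
    log_evidence: np.ndarray
    selected: float = field(init=False)

    def __post_init__(self):
        order = np.argsort(self.alphas)
        self.alphas = np.asarray(self.alphas, dtype=float)[order]
        self.log_evidence = np.asarray(self.log_evidence, dtype=float)[order]
        best = self.log_evidence.max()
        self.selected = float(
            self.alphas[np.flatnonzero(self.log_evidence >= best - 1e-12)[0]]
        )


def select_alpha(
    counts: InteractionCounts,
    constraint: ConstraintGraph,
    grid: np.ndarray | None = None,
) -> EvidenceTable:
    """MAP selection of the shared shape alpha over a candidate grid.

    With a flat hyperprior over the candidates the posterior over alpha is
    proportional to the evidence, so the argmax of the log marginal
    likelihood is returned.
    """
    if grid is None:
        grid = default_alpha_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid must be nonempty")
    if np.any(grid <= 0):
        raise ValueError("candidate alphas must be strictly positive")
    val, src, n_i, K, log_z = _evidence_terms(counts, constraint)
    active = n_i > 0
    logev = np.empty(grid.size)
    for k, a in enumerate(grid):
        obs = np.sum(gammaln(a + val) - gammaln(a))
        node = np.sum(gammaln(K[active] * a) - gammaln(K[active] * a + n_i[active]))
        logev[k] = log_z + obs + node
    return EvidenceTable(alphas=grid, log_evidence=logev)


# ---------------------------------------------------------------------------
# Model / Results layer
# ---------------------------------------------------------------------------


class TransitionResults:
    """Fit results: the estimated transition matrix plus metadata."""

    def __init__(self, model, transition_matrix: TransitionMatrix, method: str):
        self.model = model
        self.transition_matrix = transition_matrix
        self.method = method

    def summary(self) -> str:
        tm = self.transition_matrix
        lines = [
            "Transition matrix estimation",
            "=" * 44,
            f"Method:            {self.method}",
            f"Nodes:             {tm.n_nodes}",
            f"Defined rows:      {int(tm.defined.sum())}",
            f"Observations (m):  {self.model.counts.total}",
        ]
        return "\n".join(lines)


class BayesTransitionResults(TransitionResults):
    """Results of a Dirichlet-multinomial fit.

    Attributes
    ----------
    posterior : DirichletPosterior
        Analytic posterior; ``posterior.row(node)`` exposes per-row
        uncertainty via the concentration vectors.
    alpha : float | ndarray
        The shape hyperparameter used (after selection, if requested).
    log_evidence : float
        Log marginal likelihood of the data at ``alpha``.
    evidence_table : EvidenceTable | None
        Full per-candidate table when alpha was selected from a grid.
    """

    def __init__(
        self,
        model,
        posterior: DirichletPosterior,
        method: str,
        alpha,
        log_evidence: float,
        evidence_table: EvidenceTable | None = None,
    ):
        super().__init__(model, posterior.mean(), method)
        self.posterior = posterior
        self.alpha = alpha
        self.log_evidence = log_evidence
        self.evidence_table = evidence_table

    def summary(self) -> str:
        alpha = self.alpha
        alpha_txt = f"{alpha:g}" if np.ndim(alpha) == 0 else "per-node (1/|S(i)|)"
        lines = [
            super().summary(),
            f"alpha:             {alpha_txt}",
            f"log evidence:      {self.log_evidence:.6g}",
        ]
        if self.evidence_table is not None:
            lines.append(
                f"alpha selected from {self.evidence_table.alphas.size} candidates"
            )
        return "\n".join(lines)


class FrequentistTransitionModel:
    """MLE model: relative observation frequencies per source node."""

    def __init__(
        self, counts: InteractionCounts, nodes: Sequence[str] | None = None
    ):
        self.counts = counts
        self.nodes = list(nodes) if nodes is not None else counts.all_nodes()

    def fit(self) -> TransitionResults:
        tm = fit_frequentist(self.counts, self.nodes)
        return TransitionResults(self, tm, "frequentist (MLE)")


class BayesTransitionModel:
    """Dirichlet-multinomial model with an optional topological constraint.

    With ``constraint`` given this is BaCon; with ``constraint=None`` the
    prior lives on the complete graph over ``nodes`` and the model reduces
    to the noninformative Bayesian baseline.
    """

    def __init__(
        self,
        counts: InteractionCounts,
        constraint: ConstraintGraph | None = None,
        nodes: Sequence[str] | None = None,
        self_loops: bool = False,
    ):
        self.counts = counts
        if constraint is None:
            if nodes is None:
                nodes = counts.all_nodes()
            constraint = ConstraintGraph.complete(nodes, self_loops=self_loops)
            self.method = "noninformative Bayes"
        else:
            self.method = "BaCon (topological prior)"
        self.constraint = constraint

    def fit(self, alpha=1.0, grid: np.ndarray | None = None) -> BayesTransitionResults:
        """Fit at a fixed ``alpha``, the ``"sg"`` preset, or ``alpha="select"``.

        ``"select"`` maximises the log evidence over ``grid`` (default: 50
        log-spaced candidates on [1e-2, 1e2]).
        """
        table = None
        if isinstance(alpha, str) and alpha == "select":
            table = select_alpha(self.counts, self.constraint, grid)
            alpha = table.selected
        posterior = fit_bacon(self.counts, self.constraint, alpha)
        logev = log_marginal_likelihood(self.counts, self.constraint, alpha)
        return BayesTransitionResults(
            self, posterior, self.method, posterior.alpha0, logev, table
        )
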