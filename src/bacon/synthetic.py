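"""Synthetic study systems: topologies, ground-truth walks, sampled interactions.

The generators emulate the study conditions used throughout the evaluation:

* **Topology** — an undirected graph from one of three families, made
  connected by bridging every non-largest component to the largest one, then
  doubled into a directed constraint (each undirected edge becomes both
  directions).  Families: Erdős–Rényi ``G(N=500, M=5000)``; soft random
  geometric graphs in the unit square; soft RGGs in a hyperbolic disk of
  radius ``R=1`` with curvature ``-zeta^2`` (``zeta=1``).  Geometric models
  connect ``i, j`` with probability ``exp(-d_ij / sigma)`` (``sigma=0.1``).
* **Ground truth** — per-node transition rows drawn from a Dirichlet: flat
  ``Dir(1)`` for matrix/ranking studies, or community-biased
  (``alpha=10`` within the community, ``1`` across) for clustering studies.
* **Interactions** — ``m`` independent draws of (start node, successor),
  with start probabilities themselves drawn once from ``Dir(1_N)``.

Every generator is a pure function of its arguments and a seed; RNG streams
are derived from ``(seed, operation tag)`` so composed pipelines stay
reproducible piece by piece.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph import ConstraintGraph, InteractionCounts, TransitionMatrix

__all__ = [
    "GeneratorConfig",
    "SyntheticSystem",
    "CapacityError",
    "generate_topology",
    "assign_communities",
    "sample_ground_truth",
    "sample_start_probabilities",
    "sample_interactions",
    "sample_from_weighted",
    "add_spurious_edges",
    "generate_system",
]

KINDS = ("erdos_renyi", "euclidean_rgg", "hyperbolic_rgg")

# RNG stream tags (seed, tag) -> independent stream per generated object
_TAG_TOPOLOGY = 1
_TAG_COMMUNITIES = 2
_TAG_GROUND_TRUTH = 3
_TAG_START = 4
_TAG_SPURIOUS = 5
_TAG_INTERACTIONS = 6


class CapacityError(ValueError):
    """Requested more spurious edges than the complement can hold."""


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *tags])


@dataclass
class GeneratorConfig:
    """Parameters of one topology family.

    ``n_edges`` applies to the Erdős–Rényi model only; ``sigma`` (edge-decay
    scale), ``radius`` and ``curvature`` to the geometric models.
    """

    kind: str
    n_nodes: int = 500
    n_edges: int = 5000
    sigma: float = 0.1
    radius: float = 1.0
    curvature: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if self.kind == "erdos_renyi":
            cap = self.n_nodes * (self.n_nodes - 1) // 2
            if not (0 < self.n_edges <= cap):
                raise ValueError(f"n_edges must be in (0, {cap}]")
        if min(self.sigma, self.radius, self.curvature) <= 0:
            raise ValueError("sigma, radius and curvature must be positive")


@dataclass
class SyntheticSystem:
    """A complete ground truth: constraint, walk probabilities, metadata."""

    kind: str
    constraint: ConstraintGraph
    t_gt: TransitionMatrix
    start_probs: np.ndarray
    labeling: dict[str, int] | None = None
    latent: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        if abs(self.start_probs.sum() - 1.0) > 1e-9:
            raise ValueError("start probabilities must sum to 1")
        if np.any(self.constraint.out_degrees == 0):
            raise ValueError("synthetic constraint must have no sink nodes")


def _hyperbolic_distance(
    r1, theta1, r2, theta2, zeta: float
) -> np.ndarray:
    """Distance in the disk of curvature ``-zeta^2`` from polar coordinates."""
    arg = np.cosh(zeta * r1) * np.cosh(zeta * r2) - np.sinh(zeta * r1) * np.sinh(
        zeta * r2
    ) * np.cos(theta1 - theta2)
    return np.arccosh(np.maximum(arg, 1.0)) / zeta


def _undirected_edges(config: GeneratorConfig, rng: np.random.Generator):
    """Raw undirected edge list plus latent coordinates (None for ER)."""
    n = config.n_nodes
    if config.kind == "erdos_renyi":
        g = nx.gnm_random_graph(n, config.n_edges, seed=int(rng.integers(2**31)))
        return sorted(tuple(sorted(e)) for e in g.edges()), None
    iu, ju = np.triu_indices(n, k=1)
    if config.kind == "euclidean_rgg":
        coords = rng.random((n, 2))
        d = np.hypot(coords[iu, 0] - coords[ju, 0], coords[iu, 1] - coords[ju, 1])
        latent = {str(i): (float(x), float(y)) for i, (x, y) in enumerate(coords)}
    else:  # hyperbolic_rgg: uniform w.r.t. hyperbolic area, angles uniform
        zeta, R = config.curvature, config.radius
        theta = rng.uniform(0.0, 2 * np.pi, n)
        u = rng.random(n)
        r = np.arccosh(1.0 + u * (np.cosh(zeta * R) - 1.0)) / zeta
        d = _hyperbolic_distance(r[iu], theta[iu], r[ju], theta[ju], zeta)
        latent = {str(i): (float(a), float(b)) for i, (a, b) in enumerate(zip(r, theta))}
    keep = rng.random(d.size) < np.exp(-d / config.sigma)
    edges = [(int(a), int(b)) for a, b in zip(iu[keep], ju[keep])]
    return edges, latent


def generate_topology(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[ConstraintGraph, dict[str, tuple[float, float]] | None]:
    """Generate a directed constraint graph (and latent coordinates).

    After the raw undirected graph is drawn, one undirected bridge is added
    from a uniformly random node of every non-largest connected component to
    a uniformly random node of the largest component, then every undirected
    edge is converted to the two directed edges.  The result is a single
    strongly connected-by-construction component with minimum out-degree 1.
    """
    if seed is None:
        seed = config.seed
    rng = _rng(seed, _TAG_TOPOLOGY)
    n = config.n_nodes
    edges, latent = _undirected_edges(config, rng)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    largest = comps[0]
    for comp in comps[1:]:
        u = int(rng.choice(comp))
        v = int(rng.choice(largest))
        edges.append((u, v))

    nodes = [str(i) for i in range(n)]
    directed = []
    for a, b in edges:
        directed.append((nodes[a], nodes[b]))
        directed.append((nodes[b], nodes[a]))
    return ConstraintGraph(nodes, directed), latent


def assign_communities(
    constraint: ConstraintGraph,
    kind: str,
    latent: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Ground-truth community labels per topology family.

    ER: each node uniform over three groups.  Euclidean: the unit square is
    cut by one random vertical and one random horizontal line (quadrant
    label).  Hyperbolic: the disk is cut by two random geodesics, each the
    perpendicular bisector of a chord between two uniform boundary angles;
    the 2-bit side pattern is the label.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    rng = _rng(seed, _TAG_COMMUNITIES)
    nodes = constraint.nodes
    if kind == "erdos_renyi":
        labels = rng.integers(0, 3, len(nodes))
        return {v: int(c) for v, c in zip(nodes, labels)}
    if latent is None:
        raise ValueError(f"{kind} community assignment requires latent coordinates")
    if kind == "euclidean_rgg":
        tx, ty = rng.random(2)
        return {
            v: int(2 * (latent[v][0] > tx) + (latent[v][1] > ty)) for v in nodes
        }
    # hyperbolic: side w.r.t. each geodesic = which of its two boundary
    # anchor points is nearer in the hyperbolic metric
    labels = {v: 0 for v in nodes}
    for bit in range(2):
        phi = rng.uniform(0.0, 2 * np.pi, 2)
        for v in nodes:
            r, theta = latent[v]
            d1 = _hyperbolic_distance(r, theta, 1.0, phi[0], 1.0)
            d2 = _hyperbolic_distance(r, theta, 1.0, phi[1], 1.0)
            labels[v] |= int(d1 < d2) << bit
    return labels


def sample_ground_truth(
    constraint: ConstraintGraph,
    labeling: dict[str, int] | None = None,
    alpha_within: float = 10.0,
    alpha_between: float = 1.0,
    concentration: float = 1.0,
    seed: int = 0,
) -> TransitionMatrix:
    """Draw ground-truth rows ``pi_i ~ Dir(alpha_i)`` on the constraint.

    With a labeling, the concentration is ``alpha_within`` toward same-label
    successors and ``alpha_between`` otherwise; without one, every successor
    gets ``concentration`` (flat ``Dir(1)`` by default).
    """
    if np.any(constraint.out_degrees == 0):
        raise ValueError("constraint has sink nodes; ground truth undefined")
    rng = _rng(seed, _TAG_GROUND_TRUTH)
    n = constraint.n_nodes
    T = np.zeros((n, n))
    label_arr = None
    if labeling is not None:
        label_arr = np.array([labeling[v] for v in constraint.nodes])
    for i in range(n):
        succ = constraint.successor_indices(i)
        if label_arr is not None:
            a = np.where(label_arr[succ] == label_arr[i], alpha_within, alpha_between)
        else:
            a = np.full(succ.size, float(concentration))
        T[i, succ] = rng.dirichlet(a)
    return TransitionMatrix(T, constraint.nodes, support=constraint)


def sample_start_probabilities(n_nodes: int, seed: int = 0) -> np.ndarray:
    """One draw of starting-node probabilities from the flat ``Dir(1_N)``."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    return _rng(seed, _TAG_START).dirichlet(np.ones(n_nodes))


def sample_interactions(
    system: SyntheticSystem, m: int, seed: int = 0
) -> InteractionCounts:
    """Sample ``m`` interactions: start ~ start_probs, successor ~ T_gt row.

    The two-stage draw is performed as one multinomial over the joint edge
    distribution ``p_ij = s_i * T_ij`` — the same distribution, one call.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    rng = _rng(seed, _TAG_INTERACTIONS)
    src, dst = system.constraint.edge_index_arrays()
    p = system.start_probs[src] * system.t_gt.values[src, dst]
    p = p / p.sum()
    draws = rng.multinomial(m, p)
    return InteractionCounts.from_arrays(system.constraint.nodes, src, dst, draws)


def sample_from_weighted(
    adjacency: np.ndarray,
    m: int,
    seed: int = 0,
    nodes: Sequence[str] | None = None,
) -> InteractionCounts:
    """Sample ``m`` edges i.i.d. with probability proportional to ``A_ij``.

    The empirical-network protocol: all weighted edges go in one bin.
    """
    A = np.asarray(adjacency, dtype=float)
    if np.any(A < 0):
        raise ValueError("adjacency entries must be nonnegative")
    src, dst = np.nonzero(A > 0)
    if src.size == 0:
        raise ValueError("adjacency has no positive entries")
    if nodes is None:
        nodes = [str(k) for k in range(A.shape[0])]
    nodes = [str(v) for v in nodes]
    w = A[src, dst]
    draws = _rng(seed, _TAG_INTERACTIONS).multinomial(m, w / w.sum())
    return InteractionCounts.from_arrays(nodes, src, dst, draws)


def add_spurious_edges(
    constraint: ConstraintGraph, k: int, seed: int = 0
) -> ConstraintGraph:
    """Add ``k`` uniformly random directed non-self-loop edges not in ``E``.

    Models partial knowledge of the topology: falsely assumed possible
    transitions.  Sampling is without replacement from the complement;
    ``k`` larger than the complement raises :class:`CapacityError`.
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    n = constraint.n_nodes
    taken = np.zeros(n * n, dtype=bool)
    src, dst = constraint.edge_index_arrays()
    taken[src * n + dst] = True
    taken[np.arange(n) * n + np.arange(n)] = True  # exclude self-loops
    free = np.flatnonzero(~taken)
    if k > free.size:
        raise CapacityError(
            f"requested {k} spurious edges but only {free.size} pairs remain"
        )
    if k == 0:
        return ConstraintGraph(constraint.nodes, constraint.edges)
    chosen = _rng(seed, _TAG_SPURIOUS).choice(free, size=k, replace=False)
    nodes = constraint.nodes
    new_edges = constraint.edges + [
        (nodes[int(e) // n], nodes[int(e) % n]) for e in chosen
    ]
    return ConstraintGraph(nodes, new_edges)


def generate_system(
    config: GeneratorConfig,
    communities: bool = False,
    alpha_within: float = 10.0,
    alpha_between: float = 1.0,
    concentration: float = 1.0,
    seed: int | None = None,
) -> SyntheticSystem:
    """Convenience bundle: topology + (labels) + ground truth + start probs."""
    if seed is None:
        seed = config.seed
    constraint, latent = generate_topology(config, seed=seed)
    labeling = None
    if communities:
        labeling = assign_communities(constraint, config.kind, latent, seed=seed)
    t_gt = sample_ground_truth(
        constraint,
        labeling=labeling,
        alpha_within=alpha_within,
        alpha_between=alpha_between,
        concentration=concentration,
        seed=seed,
    )
    start = sample_start_probabilities(config.n_nodes, seed=seed)
    return SyntheticSystem(
        kind=config.kind,
        constraint=constraint,
        t_gt=t_gt,
        start_probs=start,
        labeling=labeling,
        latent=latent,
    )
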