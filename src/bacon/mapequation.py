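"""Two-level map-equation optimizer (bundled InfoMap-style backend).

The map equation scores a hard partition M of a directed flow network by the
expected description length (in bits) of a random walk under a two-level
codebook:

    L(M) = plogp(Q) - 2 * sum_m plogp(q_m) + sum_m plogp(q_m + p_m)
           - sum_i plogp(p_i)

with ``plogp(x) = x log2 x``, ``p_i`` the node visit rates, ``q_m`` the exit
flow of module m (flow from members to non-members) and ``Q = sum_m q_m``.
Lower is better.  Optimization is Louvain-style: sweeps of greedy single-node
moves followed by aggregation of modules into supernodes, repeated until no
move improves the objective.  Deterministic for a fixed seed (move order is
the only randomized ingredient).

This is a compact reference optimizer meant for moderate graphs; the igraph
InfoMap backend in :mod:`bacon.metrics` is the faster default.
"""

from __future__ import annotations

import numpy as np

__all__ = ["map_equation_cost", "optimize_map_equation"]


def _plogp(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def _normalise(src, dst, weight):
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    weight = np.asarray(weight, dtype=float)
    if np.any(weight < 0):
        raise ValueError("flows must be nonnegative")
    total = weight.sum()
    if total <= 0:
        raise ValueError("total flow must be positive")
    return src, dst, weight / total


def map_equation_cost(labels, src, dst, weight, n_nodes: int) -> float:
    """Description length (bits) of the partition ``labels`` for given flows.

    ``weight`` is normalised internally; node visit rates are the out-flows
    ``p_i = sum_j w_ij``.
    """
    labels = np.asarray(labels)
    src, dst, w = _normalise(src, dst, weight)
    p = np.zeros(n_nodes)
    np.add.at(p, src, w)
    exit_flow: dict[int, float] = {}
    p_mod: dict[int, float] = {}
    for i in range(n_nodes):
        m = int(labels[i])
        p_mod[m] = p_mod.get(m, 0.0) + p[i]
        exit_flow.setdefault(m, 0.0)
    cross = labels[src] != labels[dst]
    for s, x in zip(src[cross], w[cross]):
        exit_flow[int(labels[s])] += x
    Q = sum(exit_flow.values())
    L = _plogp(Q) - sum(p * np.log2(p, where=p > 0, out=np.zeros_like(p)))
    for m, q in exit_flow.items():
        L += -2.0 * _plogp(q) + _plogp(q + p_mod[m])
    return L


class _Level:
    """One aggregation level: flow adjacency and module statistics."""

    def __init__(self, n, src, dst, w):
        self.n = n
        self.p = np.zeros(n)
        np.add.at(self.p, src, w)
        self.out: list[dict[int, float]] = [dict() for _ in range(n)]
        self.in_: list[dict[int, float]] = [dict() for _ in range(n)]
        self.self_flow = np.zeros(n)
        for s, d, x in zip(src, dst, w):
            s, d = int(s), int(d)
            if s == d:
                self.self_flow[s] += x
                continue
            self.out[s][d] = self.out[s].get(d, 0.0) + x
            self.in_[d][s] = self.in_[d].get(s, 0.0) + x
        self.module = np.arange(n)
        self.exit = np.array([sum(o.values()) for o in self.out])
        self.p_mod = self.p.copy()
        self.Q = float(self.exit.sum())

    def _delta(self, u: int, a: int, b: int, w_ua, w_au, w_ub, w_bu) -> float:
        """Change in L when node u moves from module a to module b."""
        out_u = sum(self.out[u].values())
        in_u = sum(self.in_[u].values())
        ex_a, ex_b = self.exit[a], self.exit[b]
        pa, pb = self.p_mod[a], self.p_mod[b]
        pu = self.p[u]
        ex_a2 = ex_a - (out_u - w_ua) + w_au
        ex_b2 = ex_b + (out_u - w_ub) - w_bu
        q2 = self.Q - ex_a - ex_b + ex_a2 + ex_b2
        old = (
            _plogp(self.Q)
            - 2 * (_plogp(ex_a) + _plogp(ex_b))
            + _plogp(ex_a + pa)
            + _plogp(ex_b + pb)
        )
        new = (
            _plogp(q2)
            - 2 * (_plogp(ex_a2) + _plogp(ex_b2))
            + _plogp(ex_a2 + (pa - pu))
            + _plogp(ex_b2 + (pb + pu))
        )
        return new - old

    def _apply(self, u, a, b, w_ua, w_au, w_ub, w_bu):
        out_u = sum(self.out[u].values())
        in_u = sum(self.in_[u].values())
        self.Q += (
            -(out_u - w_ua)
            + w_au
            + (out_u - w_ub)
            - w_bu
        )
        self.exit[a] += -(out_u - w_ua) + w_au
        self.exit[b] += (out_u - w_ub) - w_bu
        self.p_mod[a] -= self.p[u]
        self.p_mod[b] += self.p[u]
        self.module[u] = b
        del in_u  # in-flow enters through the neighbour sums only

    def sweep(self, rng: np.random.Generator) -> bool:
        """One pass of greedy single-node moves; True if anything moved."""
        moved = False
        order = rng.permutation(self.n)
        for u in order:
            a = int(self.module[u])
            # flow between u and each neighbouring module
            to_mod: dict[int, float] = {}
            from_mod: dict[int, float] = {}
            for v, x in self.out[u].items():
                m = int(self.module[v])
                to_mod[m] = to_mod.get(m, 0.0) + x
            for v, x in self.in_[u].items():
                m = int(self.module[v])
                from_mod[m] = from_mod.get(m, 0.0) + x
            w_ua = to_mod.get(a, 0.0)
            w_au = from_mod.get(a, 0.0)
            best_b, best_delta = a, -1e-15
            for b in sorted(set(to_mod) | set(from_mod)):
                if b == a:
                    continue
                d = self._delta(
                    u, a, b, w_ua, w_au, to_mod.get(b, 0.0), from_mod.get(b, 0.0)
                )
                if d < best_delta:
                    best_b, best_delta = b, d
            if best_b != a:
                self._apply(
                    u, a, best_b, w_ua, w_au,
                    to_mod.get(best_b, 0.0), from_mod.get(best_b, 0.0),
                )
                moved = True
        return moved


def optimize_map_equation(
    n_nodes: int,
    src,
    dst,
    weight,
    seed: int = 0,
    max_levels: int = 20,
) -> np.ndarray:
    """Greedy two-level map-equation partition of a directed flow network.

    Returns integer module labels (consecutive, ordered by first node).
    Nodes without any flow become singleton modules.
    """
    src, dst, w = _normalise(src, dst, weight)
    rng = np.random.default_rng(seed)
    labels = np.arange(n_nodes)
    cur_src, cur_dst, cur_w, cur_n = src, dst, w, n_nodes
    for _ in range(max_levels):
        level = _Level(cur_n, cur_src, cur_dst, cur_w)
        improved = False
        while level.sweep(rng):
            improved = True
        # map fine labels through this level's assignment
        labels = level.module[labels]
        mods, inv = np.unique(labels, return_inverse=True)
        labels = inv
        if not improved or mods.size == cur_n:
            break
        # aggregate: one supernode per module
        agg_src = level.module[cur_src]
        agg_dst = level.module[cur_dst]
        remap = {int(m): k for k, m in enumerate(np.unique(level.module))}
        agg_src = np.array([remap[int(m)] for m in agg_src], dtype=np.intp)
        agg_dst = np.array([remap[int(m)] for m in agg_dst], dtype=np.intp)
        cur_n = len(remap)
        cur_src, cur_dst, cur_w = agg_src, agg_dst, cur_w
    # canonical labels: first appearance order
    seen: dict[int, int] = {}
    out = np.empty(n_nodes, dtype=int)
    for i, m in enumerate(labels):
        out[i] = seen.setdefault(int(m), len(seen))
    return out
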