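"""Independent brute-force oracles used by the test suite.

Deliberately implemented with different machinery than the package:
distances via boolean matrix powers (path-length enumeration) instead
of networkx BFS, regressions via explicit normal equations instead of
least-squares solvers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bf_distance_matrix(adj: np.ndarray) -> np.ndarray:
    """Directed geodesic distances by matrix-power reachability.

    d(i, j) = smallest k with (A^k)[i, j] > 0; inf when unreachable.
    """
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    power = np.eye(n, dtype=bool)
    for k in range(1, n):
        power = (power.astype(int) @ a.astype(int)) > 0
        newly = power & ~np.isfinite(dist)
        dist[newly] = k
    return dist


def bf_metrics(adj: np.ndarray) -> dict:
    """All five whole-network statistics from first principles."""
    a = np.asarray(adj, dtype=int)
    n = a.shape[0]
    und = ((a + a.T) > 0).astype(int)
    d_dir = bf_distance_matrix(a)
    d_und = bf_distance_matrix(und)
    off = ~np.eye(n, dtype=bool)

    # components of the undirected graph from the reachability closure
    reach = np.isfinite(d_und)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = set(np.flatnonzero(reach[i]))
        comps.append(comp)
        seen |= comp
    sizes = [len(c) for c in comps]

    l_und = int(np.triu(und, 1).sum())
    v_req = sum(s - 1 for s in sizes)
    m_max = sum(s * (s - 1) // 2 for s in sizes)
    eff = 1.0 if m_max == v_req else 1.0 - (l_und - v_req) / (m_max - v_req)

    reach_pairs = sum(s * (s - 1) // 2 for s in sizes)
    conn = reach_pairs / (n * (n - 1) // 2)

    finite = d_dir[off][np.isfinite(d_dir[off])]
    avg_dist = float(finite.mean()) if finite.size else float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d_dir[off]), 1.0 / d_dir[off], 0.0)
    cohesion = float(inv.sum() / (n * (n - 1)))

    return {
        "density": a.sum() / (n * (n - 1)),
        "efficiency": eff,
        "connectedness": conn,
        "average_distance": avg_dist,
        "cohesion_index": cohesion,
        "n_components": len(comps),
    }


def bf_granger_f(x: np.ndarray, y: np.ndarray, lag: int) -> tuple[float, float]:
    """Granger F test by explicit normal equations (two regressions)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t = len(y)
    dep = y[lag:]
    cols_r = [np.ones(t - lag)] + [y[lag - i : t - i] for i in range(1, lag + 1)]
    cols_u = cols_r + [x[lag - i : t - i] for i in range(1, lag + 1)]

    def ssr(cols):
        X = np.column_stack(cols)
        beta = np.linalg.solve(X.T @ X, X.T @ dep)
        r = dep - X @ beta
        return float(r @ r)

    ssr_r, ssr_u = ssr(cols_r), ssr(cols_u)
    df_den = len(dep) - 2 * lag - 1
    f = ((ssr_r - ssr_u) / lag) / (ssr_u / df_den)
    return f, float(stats.f.sf(f, lag, df_den))


def partitions_equal(labels_a, labels_b) -> bool:
    """True when two labelings induce the same partition (any relabeling)."""
    groups_a = {}
    groups_b = {}
    for i, (la, lb) in enumerate(zip(labels_a, labels_b)):
        groups_a.setdefault(la, set()).add(i)
        groups_b.setdefault(lb, set()).add(i)
    return {frozenset(g) for g in groups_a.values()} == {
        frozenset(g) for g in groups_b.values()
    }
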