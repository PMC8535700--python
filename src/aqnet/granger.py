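"""Directed association networks from pairwise Granger-causality tests.

For an ordered city pair (x, y) and lag order p, the test compares the
restricted regression

    y_t = a + sum_{i=1..p} g_i y_{t-i} + e_t

with the unrestricted one that adds x's lags 1..p, via the standard
joint F statistic on the added coefficients:

    F = ((SSR_r - SSR_u) / p) / (SSR_u / (T - 2p - 1)).

An edge x -> y is drawn when the tests across the configured lag range
reject according to the aggregation rule (any / majority / all lags).
The network over all ordered pairs is the pollutant's spatial
association network: a binary directed adjacency with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .preprocess import StationaryPanel

__all__ = [
    "GrangerConfig",
    "PairTestResult",
    "AssociationNetwork",
    "granger_pair",
    "GrangerNetwork",
    "build_network",
]

AGGREGATIONS = ("any", "majority", "all")


@dataclass(frozen=True)
class GrangerConfig:
    """Pair-test configuration: lag range, level and lag aggregation."""

    lag_min: int = 1
    lag_max: int = 10
    alpha: float = 0.10
    aggregation: str = "majority"
    require_reciprocal: bool = False
    correction: str | None = None  # None | "bonferroni" | "bh"

    def __post_init__(self) -> None:
        if self.lag_min < 1 or self.lag_min > self.lag_max:
            raise ValueError("need 1 <= lag_min <= lag_max")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
        if self.correction not in (None, "bonferroni", "bh"):
            raise ValueError("correction must be None, 'bonferroni' or 'bh'")


@dataclass
class PairTestResult:
    """Evidence for one ordered pair: per-lag F tests and the edge call."""

    source: str
    target: str
    per_lag: list[dict] = field(default_factory=list)
    edge: bool = False


@dataclass
class AssociationNetwork:
    """Binary directed city network for one pollutant."""

    nodes: list[str]
    adjacency: np.ndarray
    pollutant: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = len(self.nodes)
        if a.shape != (n, n):
            raise ValueError("adjacency shape must match node count")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def _lag_matrix(z: np.ndarray, lag: int) -> np.ndarray:
    """Columns z_{t-1}..z_{t-lag} for t = lag..T-1."""
    return np.column_stack([z[lag - i : len(z) - i] for i in range(1, lag + 1)])


def granger_pair(
    x: np.ndarray, y: np.ndarray, lag: int, alpha: float = 0.10
) -> dict:
    """Test whether x Granger-causes y at a single lag order.

    Returns ``{"f_statistic", "p_value", "reject", "df_num", "df_den"}``.

    Raises
    ------
    ValueError
        If the series are unequal length, too short (need
        ``len > 3 * lag + 2``), or the regression is degenerate
        (rank-deficient design or an exactly-fitting unrestricted
        model, e.g. constant series).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be equal-length 1-D series")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if len(y) <= 3 * lag + 2:
        raise ValueError(
            f"series of length {len(y)} too short for lag {lag} "
            f"(need length > {3 * lag + 2})"
        )
    y_dep = y[lag:]
    ylags = _lag_matrix(y, lag)
    xlags = _lag_matrix(x, lag)
    n_obs = len(y_dep)
    const = np.ones((n_obs, 1))
    X_r = np.hstack([const, ylags])
    X_u = np.hstack([const, ylags, xlags])

    beta_r, _, rank_r, _ = np.linalg.lstsq(X_r, y_dep, rcond=None)
    beta_u, _, rank_u, _ = np.linalg.lstsq(X_u, y_dep, rcond=None)
    if rank_u < X_u.shape[1] or rank_r < X_r.shape[1]:
        raise ValueError(
            "degenerate Granger regression (collinear or constant series) "
            f"for pair at lag {lag}"
        )
    ssr_r = float(np.sum((y_dep - X_r @ beta_r) ** 2))
    ssr_u = float(np.sum((y_dep - X_u @ beta_u) ** 2))
    df_den = n_obs - 2 * lag - 1
    if ssr_u <= 0 or df_den <= 0:
        raise ValueError(f"degenerate Granger regression (zero residual) at lag {lag}")
    f_stat = ((ssr_r - ssr_u) / lag) / (ssr_u / df_den)
    f_stat = max(f_stat, 0.0)
    p_value = float(stats.f.sf(f_stat, lag, df_den))
    return {
        "f_statistic": float(f_stat),
        "p_value": p_value,
        "reject": p_value < alpha,
        "df_num": lag,
        "df_den": df_den,
    }


def _aggregate(rejections: list[bool], rule: str) -> bool:
    k = sum(rejections)
    if rule == "any":
        return k >= 1
    if rule == "all":
        return k == len(rejections)
    return k > len(rejections) / 2  # majority


class GrangerNetwork(BaseEstimator):
    """Estimator that infers a directed association network.

    Runs the pairwise Granger F-test for every ordered city pair at each
    lag in ``lag_min..lag_max`` and sets edge i -> j by the aggregation
    rule.  With ``require_reciprocal=True`` an edge is kept only when
    both directions reject (undirected-style association); the default
    keeps one-way edges so out- versus in-degree bookkeeping (spillover
    vs receiver roles) stays meaningful.

    Parameters
    ----------
    lag_min, lag_max : int
        Lag range tested per pair (defaults 1..10).
    alpha : float
        Per-test significance level (default 0.10).
    aggregation : {"any", "majority", "all"}
        How per-lag rejections combine into one edge call.
    require_reciprocal : bool
        Keep an edge only if both directions reject.
    correction : {None, "bonferroni", "bh"}
        Optional multiple-testing adjustment applied to the pooled
        per-lag p-values across all pairs before edge calls.

    Attributes
    ----------
    nodes_ : list of city labels (ordered).
    adjacency_ : binary ndarray, entry (i, j) = 1 iff i -> j.
    results_ : list of PairTestResult with full per-lag evidence.
    network_ : AssociationNetwork.
    """

    def __init__(
        self,
        lag_min: int = 1,
        lag_max: int = 10,
        alpha: float = 0.10,
        aggregation: str = "majority",
        require_reciprocal: bool = False,
        correction: str | None = None,
    ):
        self.lag_min = lag_min
        self.lag_max = lag_max
        self.alpha = alpha
        self.aggregation = aggregation
        self.require_reciprocal = require_reciprocal
        self.correction = correction

    def _config(self) -> GrangerConfig:
        return GrangerConfig(
            lag_min=self.lag_min,
            lag_max=self.lag_max,
            alpha=self.alpha,
            aggregation=self.aggregation,
            require_reciprocal=self.require_reciprocal,
            correction=self.correction,
        )

    def fit(self, X, y=None, pollutant: str = ""):
        """Infer the network from per-city stationary series.

        ``X`` is either a mapping ``{city: 1-D array}`` or a
        ``StationaryPanel`` (then ``pollutant`` selects the series and
        city pairs are aligned at the max of their differencing orders).
        """
        cfg = self._config()
        if isinstance(X, StationaryPanel):
            if not pollutant:
                raise ValueError("pollutant label required with a StationaryPanel")
            nodes = X.cities(pollutant)
            if len(nodes) < 2:
                raise ValueError(f"need >= 2 cities with pollutant {pollutant!r}")
            get_pair = lambda cx, cy: X.aligned_pair(cx, cy, pollutant)
        else:
            series = {k: np.asarray(v, dtype=float) for k, v in dict(X).items()}
            nodes = sorted(series)
            if len(nodes) < 2:
                raise ValueError("need >= 2 cities")
            get_pair = lambda cx, cy: (series[cx], series[cy])

        lags = range(cfg.lag_min, cfg.lag_max + 1)
        results: dict[tuple[str, str], PairTestResult] = {}
        for sx in nodes:
            for sy in nodes:
                if sx == sy:
                    continue
                xs, ys = get_pair(sx, sy)
                res = PairTestResult(source=sx, target=sy)
                for lag in lags:
                    try:
                        t = granger_pair(xs, ys, lag, cfg.alpha)
                    except ValueError as err:
                        raise ValueError(f"pair {sx} -> {sy}: {err}") from err
                    res.per_lag.append({"lag": lag, **t})
                results[(sx, sy)] = res

        if cfg.correction is not None:
            from statsmodels.stats.multitest import multipletests

            flat = [(key, i) for key, r in results.items()
                    for i in range(len(r.per_lag))]
            pvals = np.array([results[k].per_lag[i]["p_value"] for k, i in flat])
            method = "bonferroni" if cfg.correction == "bonferroni" else "fdr_bh"
            rej, p_adj, *_ = multipletests(pvals, alpha=cfg.alpha, method=method)
            for (key, i), r, p in zip(flat, rej, p_adj):
                results[key].per_lag[i]["p_value_adj"] = float(p)
                results[key].per_lag[i]["reject"] = bool(r)

        for r in results.values():
            r.edge = _aggregate([t["reject"] for t in r.per_lag], cfg.aggregation)
        if cfg.require_reciprocal:
            for (sx, sy), r in results.items():
                r.edge = r.edge and _aggregate(
                    [t["reject"] for t in results[(sy, sx)].per_lag], cfg.aggregation
                )

        n = len(nodes)
        adj = np.zeros((n, n), dtype=int)
        idx = {c: i for i, c in enumerate(nodes)}
        for (sx, sy), r in results.items():
            if r.edge:
                adj[idx[sx], idx[sy]] = 1

        self.nodes_ = nodes
        self.adjacency_ = adj
        self.results_ = list(results.values())
        self.network_ = AssociationNetwork(nodes=nodes, adjacency=adj,
                                           pollutant=pollutant)
        return self


def build_network(
    panel: StationaryPanel, pollutant: str, cfg: GrangerConfig | None = None
) -> tuple[AssociationNetwork, list[PairTestResult]]:
    """Functional wrapper over :class:`GrangerNetwork`."""
    cfg = cfg or GrangerConfig()
    est = GrangerNetwork(
        lag_min=cfg.lag_min,
        lag_max=cfg.lag_max,
        alpha=cfg.alpha,
        aggregation=cfg.aggregation,
        require_reciprocal=cfg.require_reciprocal,
        correction=cfg.correction,
    ).fit(panel, pollutant=pollutant)
    return est.network_, est.results_


def pair_results_frame(results: list[PairTestResult]) -> pd.DataFrame:
    """Flatten pair evidence to a tidy frame (one row per pair x lag)."""
    rows = []
    for r in results:
        for t in r.per_lag:
            rows.append({"source": r.source, "target": r.target, "edge": r.edge, **t})
    return pd.DataFrame(rows)
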