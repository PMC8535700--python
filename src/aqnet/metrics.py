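"""Whole-network and per-node statistics of an association network.

Conventions (the standard Krackhardt/Freeman ones for binary networks):

* density — directed edge count over ``n (n - 1)``;
* efficiency — Krackhardt efficiency of the *underlying undirected*
  graph: 1 minus the share of redundant undirected links beyond the
  minimum needed to keep each component connected (low efficiency =
  many redundant transmission paths = a stable network);
* connectedness — fraction of unordered node pairs joined by some path
  in the underlying undirected graph;
* average distance — mean directed geodesic over ordered reachable
  pairs (unreachable pairs excluded; NaN when nothing is reachable);
* cohesion index — mean reciprocal directed geodesic over ordered
  pairs, counting unreachable pairs as 0 (compactness);
* node roles — a city with more outgoing than incoming ties is a
  "spillover" city, the converse a "receiver", equal counts
  "equivalent".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .granger import AssociationNetwork

__all__ = [
    "NetworkSummary",
    "NodeSummary",
    "density",
    "efficiency",
    "connectedness",
    "average_distance",
    "cohesion_index",
    "node_summaries",
    "summarize",
    "summary_table",
    "node_table",
]


@dataclass(frozen=True)
class NetworkSummary:
    density: float
    efficiency: float
    connectedness: float
    average_distance: float  # NaN when no ordered pair is reachable
    cohesion_index: float
    n_components: int  # weak components


@dataclass(frozen=True)
class NodeSummary:
    city: str
    out_degree: int
    in_degree: int
    degree_centrality: float  # percent of possible alters, 0..100
    betweenness: float  # Freeman betweenness, normalized to [0, 1]
    role: str  # spillover | receiver | equivalent


def _digraph(net: AssociationNetwork) -> nx.DiGraph:
    g = nx.from_numpy_array(net.adjacency, create_using=nx.DiGraph)
    return nx.relabel_nodes(g, dict(enumerate(net.nodes)))


def _require_size(net: AssociationNetwork) -> int:
    n = net.n_nodes
    if n < 2:
        raise ValueError("network must have >= 2 nodes")
    return n


def density(net: AssociationNetwork) -> float:
    """Directed edge count / n(n-1)."""
    n = _require_size(net)
    return net.n_edges / (n * (n - 1))


def efficiency(net: AssociationNetwork) -> float:
    """Krackhardt efficiency on the underlying undirected graph."""
    _require_size(net)
    und = nx.Graph(_digraph(net))
    sizes = [len(c) for c in nx.connected_components(und)]
    v_req = sum(s - 1 for s in sizes)
    m_max = sum(s * (s - 1) // 2 for s in sizes)
    if m_max == v_req:
        return 1.0
    return 1.0 - (und.number_of_edges() - v_req) / (m_max - v_req)


def connectedness(net: AssociationNetwork) -> float:
    """Share of unordered pairs with an undirected path between them."""
    n = _require_size(net)
    und = nx.Graph(_digraph(net))
    reachable = sum(
        len(c) * (len(c) - 1) // 2 for c in nx.connected_components(und)
    )
    return reachable / (n * (n - 1) // 2)


def _directed_distances(net: AssociationNetwork) -> list[int]:
    g = _digraph(net)
    return [
        d
        for _, lengths in nx.all_pairs_shortest_path_length(g)
        for tgt, d in lengths.items()
        if d > 0
    ]


def average_distance(net: AssociationNetwork) -> float:
    """Mean directed geodesic over reachable ordered pairs; NaN if none."""
    _require_size(net)
    dists = _directed_distances(net)
    if not dists:
        return float("nan")
    return float(np.mean(dists))


def cohesion_index(net: AssociationNetwork) -> float:
    """Mean reciprocal directed geodesic (0 for unreachable pairs)."""
    n = _require_size(net)
    return float(sum(1.0 / d for d in _directed_distances(net)) / (n * (n - 1)))


def summarize(net: AssociationNetwork) -> NetworkSummary:
    und = nx.Graph(_digraph(net))
    return NetworkSummary(
        density=density(net),
        efficiency=efficiency(net),
        connectedness=connectedness(net),
        average_distance=average_distance(net),
        cohesion_index=cohesion_index(net),
        n_components=nx.number_connected_components(und),
    )


def _role(out_deg: int, in_deg: int) -> str:
    if out_deg > in_deg:
        return "spillover"
    if in_deg > out_deg:
        return "receiver"
    return "equivalent"


def node_summaries(net: AssociationNetwork) -> list[NodeSummary]:
    """Degrees, centralities and spillover/receiver role per city.

    Degree centrality is the percentage of the other n-1 cities that
    are neighbours in either direction (max 100); betweenness is
    Freeman betweenness on the directed graph, normalized to [0, 1].
    """
    n = _require_size(net)
    a = net.adjacency
    g = _digraph(net)
    btw = nx.betweenness_centrality(g, normalized=True)
    out = []
    either = (a + a.T) > 0
    for i, city in enumerate(net.nodes):
        od = int(a[i].sum())
        ind = int(a[:, i].sum())
        out.append(
            NodeSummary(
                city=city,
                out_degree=od,
                in_degree=ind,
                degree_centrality=100.0 * either[i].sum() / (n - 1),
                betweenness=float(btw[city]),
                role=_role(od, ind),
            )
        )
    return out


def summary_table(summaries: dict[str, NetworkSummary]) -> pd.DataFrame:
    """Whole-network statistics, pollutants as columns."""
    rows = ["density", "efficiency", "connectedness", "average_distance",
            "cohesion_index", "n_components"]
    return pd.DataFrame(
        {pol: [getattr(s, r) for r in rows] for pol, s in summaries.items()},
        index=rows,
    )


def node_table(nodes: list[NodeSummary]) -> pd.DataFrame:
    """Per-city statistics, one row per city, sorted by out-degree."""
    df = pd.DataFrame([vars(s) for s in nodes])
    return df.sort_values(["out_degree", "city"], ascending=[False, True],
                          ignore_index=True)
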