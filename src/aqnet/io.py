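"""Readers and writers for panels and association networks.

Supported network formats: dense CSV adjacency matrix, edge-list CSV
(with the node universe recorded in a header comment so isolated nodes
survive a round trip), GraphML (via networkx), and the UCINET DL
full-matrix dialect.  CSV matrix, edge list and DL all round-trip to an
identical adjacency.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .granger import AssociationNetwork

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "export_network",
    "import_network",
    "NETWORK_FORMATS",
]

NETWORK_FORMATS = ("csv_matrix", "edgelist", "graphml", "dl")


def read_panel_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format (city, date, pollutant, value) panel CSV."""
    panel = pd.read_csv(path, parse_dates=["date"])
    from .preprocess import validate_panel

    return validate_panel(panel)


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _to_digraph(net: AssociationNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    src, tgt = np.nonzero(net.adjacency)
    g.add_edges_from((net.nodes[i], net.nodes[j]) for i, j in zip(src, tgt))
    return g


def export_network(
    net: AssociationNetwork, path: str | Path, format: str = "csv_matrix"
) -> Path:
    """Write a network in one of :data:`NETWORK_FORMATS`."""
    path = Path(path)
    if format == "csv_matrix":
        pd.DataFrame(net.adjacency, index=net.nodes, columns=net.nodes).to_csv(path)
    elif format == "edgelist":
        lines = ["# nodes: " + ",".join(net.nodes), "source,target"]
        src, tgt = np.nonzero(net.adjacency)
        lines += [f"{net.nodes[i]},{net.nodes[j]}" for i, j in zip(src, tgt)]
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(_to_digraph(net), path)
    elif format == "dl":
        n = net.n_nodes
        rows = "\n".join(" ".join(str(v) for v in row) for row in net.adjacency)
        path.write_text(
            f"dl n={n}\nformat = fullmatrix\nlabels:\n"
            + ",".join(net.nodes)
            + "\ndata:\n"
            + rows
            + "\n"
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")
    return path


def import_network(
    path: str | Path, format: str = "csv_matrix", pollutant: str = ""
) -> AssociationNetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if format == "csv_matrix":
        df = pd.read_csv(path, index_col=0)
        return AssociationNetwork(
            nodes=[str(c) for c in df.index],
            adjacency=df.to_numpy(dtype=int),
            pollutant=pollutant,
        )
    if format == "edgelist":
        lines = path.read_text().splitlines()
        if not lines or not lines[0].startswith("# nodes:"):
            raise ValueError("edgelist file missing '# nodes:' header")
        nodes = lines[0].split(":", 1)[1].strip().split(",")
        idx = {c: i for i, c in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=int)
        for line in lines[2:]:
            if not line.strip():
                continue
            s, t = line.split(",")
            adj[idx[s], idx[t]] = 1
        return AssociationNetwork(nodes=nodes, adjacency=adj, pollutant=pollutant)
    if format == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        idx = {c: i for i, c in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)), dtype=int)
        for s, t in g.edges:
            adj[idx[s], idx[t]] = 1
        return AssociationNetwork(nodes=nodes, adjacency=adj, pollutant=pollutant)
    if format == "dl":
        return _read_dl(path, pollutant)
    raise ValueError(f"unknown network format: {format!r}")


def _read_dl(path: Path, pollutant: str) -> AssociationNetwork:
    text = path.read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].lower().startswith("dl"):
        raise ValueError("not a DL file")
    n = None
    for tok in lines[0].replace(",", " ").split():
        if tok.lower().startswith("n="):
            n = int(tok[2:])
    if n is None:
        raise ValueError("DL header missing n=")
    labels: list[str] = []
    data_rows: list[list[int]] = []
    mode = None
    for ln in lines[1:]:
        low = ln.lower()
        if low.startswith("format"):
            if "fullmatrix" not in low.replace(" ", ""):
                raise ValueError("only the fullmatrix DL dialect is supported")
            continue
        if low.startswith("labels"):
            mode = "labels"
            continue
        if low.startswith("data"):
            mode = "data"
            continue
        if mode == "labels":
            labels += [t for t in ln.replace(",", " ").split() if t]
        elif mode == "data":
            data_rows.append([int(float(t)) for t in ln.split()])
    if len(data_rows) != n or any(len(r) != n for r in data_rows):
        raise ValueError(f"DL data block is not an {n} x {n} matrix")
    if not labels:
        labels = [f"n{i}" for i in range(n)]
    return AssociationNetwork(
        nodes=labels, adjacency=np.array(data_rows, dtype=int), pollutant=pollutant
    )
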