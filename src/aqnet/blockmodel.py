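"""CONCOR blockmodelling: cohesive subgroups by iterated correlations.

CONCOR (CONvergence of iterated CORrelations) partitions the cities of
a directed network into structurally similar blocks.  Each node's
profile is the concatenation of its adjacency row and column; the
node-by-node Pearson correlation matrix of these profiles is then
itself correlated, repeatedly, until every off-diagonal entry converges
to +/-1.  The sign pattern splits the nodes in two; applying the split
recursively to depth d yields up to 2**d subgroups (depth 2 gives the
classical four-subgroup solution).

Subgroups are then labelled by their aggregate flow balance: a block
whose members mostly export ties is a "spillover" subgroup, one that
mostly absorbs them a "receiver", anything in between an
"intermediary".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .granger import AssociationNetwork
from .metrics import NodeSummary

__all__ = [
    "ConcorConfig",
    "BlockPartition",
    "concor_split",
    "CONCOR",
    "concor",
    "subgroup_roles",
]

MAX_DEPTH = 4


@dataclass(frozen=True)
class ConcorConfig:
    depth: int = 2
    max_iterations: int = 200
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= MAX_DEPTH:
            raise ValueError(f"depth must be in [1, {MAX_DEPTH}]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class BlockPartition:
    """Subgroup assignment plus the binary split tree."""

    nodes: list[str]
    assignment: dict[str, int]
    tree: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.assignment[c] for c in self.nodes])

    @property
    def n_subgroups(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, group: int) -> list[str]:
        return [c for c in self.nodes if self.assignment[c] == group]


def _safe_corr(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson correlation; returns (corr, zero_var mask)."""
    sd = m.std(axis=0)
    zero = sd < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(m, rowvar=False)
    c = np.atleast_2d(c)
    return c, zero


def concor_split(
    profiles: np.ndarray,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
) -> tuple[list[int], list[int], bool]:
    """One CONCOR bisection of nodes by profile similarity.

    ``profiles`` has one row per node.  Returns (indices_a, indices_b,
    converged); ``indices_b`` may be empty when all profiles are
    positively correlated (the block is indivisible).  Nodes with a
    constant (zero-variance) profile cannot be correlated and are
    assigned to the larger sibling block, with a warning.
    """
    profiles = np.asarray(profiles, dtype=float)
    m = profiles.shape[0]
    if m < 2:
        raise ValueError("need >= 2 nodes to split")
    c0, zero = _safe_corr(profiles.T)
    aside = list(np.flatnonzero(zero))
    active = list(np.flatnonzero(~zero))
    if aside:
        warnings.warn(
            f"{len(aside)} constant profile(s) set aside during CONCOR split",
            stacklevel=2,
        )
    if len(active) < 2:
        return list(range(m)), [], True

    c = c0[np.ix_(active, active)]
    converged = False
    for _ in range(max_iterations):
        off = c[~np.eye(len(active), dtype=bool)]
        if np.all(np.abs(np.abs(off) - 1.0) < tolerance):
            converged = True
            break
        c_next, zero_it = _safe_corr(c)
        if zero_it.any() or not np.isfinite(c_next).all():
            # a column went constant (perfect agreement): current signs final
            break
        # keep exact symmetry and unit diagonal against float drift
        c = (c_next + c_next.T) / 2.0
        np.fill_diagonal(c, 1.0)

    signs = c[0] >= 0
    group_a = [active[i] for i in range(len(active)) if signs[i]]
    group_b = [active[i] for i in range(len(active)) if not signs[i]]
    if aside:
        (group_a if len(group_a) >= len(group_b) else group_b).extend(aside)
    return sorted(group_a), sorted(group_b), converged


class CONCOR(BaseEstimator, ClusterMixin):
    """Recursive CONCOR bisection to a fixed depth.

    Parameters
    ----------
    depth : int
        Number of recursive bisection levels (default 2 -> up to four
        subgroups); capped at 4.
    max_iterations : int
        Iteration cap per split before falling back to the sign
        pattern of the last iterate (reported via ``converged_``).
    tolerance : float
        Convergence tolerance on |corr| - 1.

    Attributes
    ----------
    labels_ : ndarray of subgroup ids, numbered by first-node index.
    tree_ : nested dict describing every binary split.
    converged_ : bool, True when every split converged.
    """

    def __init__(self, depth: int = 2, max_iterations: int = 200,
                 tolerance: float = 1e-6):
        self.depth = depth
        self.max_iterations = max_iterations
        self.tolerance = tolerance

    def fit(self, X, y=None):
        cfg = ConcorConfig(self.depth, self.max_iterations, self.tolerance)
        a = np.asarray(X, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("X must be a square adjacency matrix")
        n = a.shape[0]
        if n < 2 ** cfg.depth:
            raise ValueError(f"need >= {2 ** cfg.depth} nodes for depth {cfg.depth}")
        profiles = np.hstack([a, a.T])

        self.converged_ = True

        def split_block(members: list[int], level: int) -> dict:
            node: dict = {"members": members}
            if level >= cfg.depth or len(members) < 2:
                return node
            ga, gb, conv = concor_split(
                profiles[members], cfg.max_iterations, cfg.tolerance
            )
            node["converged"] = conv
            if not conv:
                self.converged_ = False
            if not gb:  # indivisible block: stop recursing
                return node
            left = [members[i] for i in ga]
            right = [members[i] for i in gb]
            node["children"] = [split_block(left, level + 1),
                                split_block(right, level + 1)]
            return node

        self.tree_ = split_block(list(range(n)), 0)

        leaves: list[list[int]] = []

        def collect(node: dict) -> None:
            if "children" in node:
                for ch in node["children"]:
                    collect(ch)
            else:
                leaves.append(node["members"])

        collect(self.tree_)
        leaves.sort(key=min)  # deterministic ids: order by first node index
        labels = np.empty(n, dtype=int)
        for gid, mem in enumerate(leaves):
            labels[mem] = gid
        self.labels_ = labels
        return self


def concor(
    net: AssociationNetwork, cfg: ConcorConfig | None = None
) -> BlockPartition:
    """Partition a network's cities into cohesive subgroups."""
    cfg = cfg or ConcorConfig()
    est = CONCOR(cfg.depth, cfg.max_iterations, cfg.tolerance).fit(net.adjacency)

    def name_tree(node: dict) -> dict:
        out = {"members": [net.nodes[i] for i in node["members"]]}
        if "converged" in node:
            out["converged"] = node["converged"]
        if "children" in node:
            out["children"] = [name_tree(ch) for ch in node["children"]]
        return out

    assignment = {net.nodes[i]: int(g) for i, g in enumerate(est.labels_)}
    return BlockPartition(
        nodes=list(net.nodes),
        assignment=assignment,
        tree=name_tree(est.tree_),
        converged=est.converged_,
    )


def subgroup_roles(
    partition: BlockPartition,
    nodes: list[NodeSummary],
    lam: float = 1.2,
) -> dict[int, str]:
    """Label each subgroup spillover / intermediary / receiver.

    A subgroup with total member out-degree O and in-degree I is a
    spillover block when ``O > lam * I``, a receiver when
    ``I > lam * O``, and an intermediary otherwise (``lam >= 1``).
    """
    if lam < 1:
        raise ValueError("lam must be >= 1")
    by_city = {s.city: s for s in nodes}
    if set(by_city) != set(partition.nodes):
        raise ValueError("node summaries and partition cover different cities")
    roles: dict[int, str] = {}
    for gid in sorted(set(partition.assignment.values())):
        members = partition.members(gid)
        if not members:
            raise ValueError(f"subgroup {gid} is empty")
        o = sum(by_city[c].out_degree for c in members)
        i = sum(by_city[c].in_degree for c in members)
        if o > lam * i:
            roles[gid] = "spillover"
        elif i > lam * o:
            roles[gid] = "receiver"
        else:
            roles[gid] = "intermediary"
    return roles


def partition_table(partition: BlockPartition, roles: dict[int, str] | None = None
                    ) -> pd.DataFrame:
    """Tidy (city, subgroup, role) table."""
    rows = [
        {"city": c, "subgroup": g,
         "role": (roles or {}).get(g, "")}
        for c, g in partition.assignment.items()
    ]
    return pd.DataFrame(rows).sort_values(["subgroup", "city"], ignore_index=True)
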