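"""lncRNA–mRNA coexpression network and Markov clustering.

Edges are lncRNA × mRNA pairs whose expression profiles correlate with
|r| >= 0.8 and p < 0.05 across samples (p from the exact t transform with
n-2 df); the 500 most significant pairs form the network, which Markov
clustering (MCL) partitions into highly interconnected modules.

The MCL implementation is self-contained and deterministic: alternate
expansion (matrix power of the column-stochastic transition matrix) and
inflation (entrywise power followed by column renormalization) with
pruning of tiny entries, until the matrix stops changing; clusters are
the connected components of the attractor support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix


@dataclass(frozen=True)
class CoexpressionEdge:
    lnc_id: str
    mrna_id: str
    r: float
    p: float


def correlate_pairs(
    mat: ExpressionMatrix,
    lnc_ids: list[str],
    mrna_ids: list[str],
    r_min: float = 0.8,
    alpha: float = 0.05,
    positive_only: bool = False,
) -> list[CoexpressionEdge]:
    """All lncRNA × mRNA pairs with |r| >= r_min and p < alpha.

    Pearson r is computed on log2(x+1); the two-sided p-value comes from
    t = r sqrt((n-2)/(1-r^2)) with n-2 df. Zero-variance genes cannot be
    correlated and are excluded with a warning. ``positive_only``
    restricts the screen to r >= r_min (discarding strong negative
    correlations).
    """
    if set(lnc_ids) & set(mrna_ids):
        raise ValueError("lnc and mRNA id sets must be disjoint")
    logx = mat.log2p1()
    n = logx.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")

    def usable(ids):
        keep = []
        for g in ids:
            if logx.loc[g].std() == 0.0:
                warnings.warn(f"excluding zero-variance gene {g}", stacklevel=2)
            else:
                keep.append(g)
        return keep

    lnc_ids = usable(lnc_ids)
    mrna_ids = usable(mrna_ids)
    if not lnc_ids or not mrna_ids:
        return []
    a = logx.loc[lnc_ids].to_numpy()
    b = logx.loc[mrna_ids].to_numpy()
    a = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    b = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = a @ b.T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    mask = (r >= r_min) if positive_only else (np.abs(r) >= r_min)
    mask &= p < alpha
    edges = [
        CoexpressionEdge(lnc_ids[i], mrna_ids[j], float(r[i, j]), float(p[i, j]))
        for i, j in zip(*np.nonzero(mask))
    ]
    return edges


def select_top_edges(edges: list[CoexpressionEdge], k: int = 500) -> list[CoexpressionEdge]:
    """Deterministic top-k by (p asc, |r| desc, lnc_id, mrna_id)."""
    ranked = sorted(edges, key=lambda e: (e.p, -abs(e.r), e.lnc_id, e.mrna_id))
    return ranked[:k]


def edges_to_graph(edges: list[CoexpressionEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_node(e.lnc_id, kind="lncRNA")
        g.add_node(e.mrna_id, kind="mRNA")
        g.add_edge(e.lnc_id, e.mrna_id, weight=abs(e.r), r=e.r, p=e.p)
    return g


@dataclass(frozen=True)
class MclParams:
    expansion: int = 2
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-8
    add_self_loops: bool = True

    def __post_init__(self):
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


@dataclass
class ClusterAssignment:
    assignments: dict[str, int]
    converged: bool = True
    n_iter: int = 0
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sizes:
            sizes: dict[int, int] = {}
            for c in self.assignments.values():
                sizes[c] = sizes.get(c, 0) + 1
            self.sizes = sizes

    def members(self, cluster_id: int) -> set[str]:
        return {n for n, c in self.assignments.items() if c == cluster_id}


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0, keepdims=True)
    colsum[colsum == 0.0] = 1.0
    return m / colsum


class MarkovClustering:
    """From-scratch dense MCL with canonical defaults (e=2, i=2.0)."""

    def __init__(self, params: MclParams | None = None):
        self.params = params or MclParams()

    def fit_predict(self, graph: nx.Graph) -> ClusterAssignment:
        p = self.params
        nodes = sorted(graph.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        if n == 0:
            raise ValueError("empty graph")
        adj = np.zeros((n, n))
        for u, v, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0))
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
        if p.add_self_loops:
            loops = adj.max(axis=0)
            loops[loops == 0.0] = 1.0  # isolated nodes
            adj[np.diag_indices(n)] = loops
        m = _column_normalize(adj)
        converged = False
        it = 0
        for it in range(1, p.max_iter + 1):
            prev = m
            m = np.linalg.matrix_power(m, p.expansion)
            m = _column_normalize(m**p.inflation)
            m[m < p.prune_threshold] = 0.0
            m = _column_normalize(m)
            if np.abs(m - prev).max() < p.tol:
                converged = True
                break
        if not converged:
            warnings.warn("MCL did not converge within max_iter", stacklevel=2)

        # attractors: rows with a nonzero diagonal; clusters = connected
        # components of the attractor support
        attractors = np.nonzero(np.diag(m) > 0.0)[0]
        support = nx.Graph()
        support.add_nodes_from(attractors.tolist())
        for i in attractors:
            for j in np.nonzero(m[i])[0]:
                if j in set(attractors.tolist()):
                    support.add_edge(int(i), int(j))
        comps = sorted(
            (sorted(c) for c in nx.connected_components(support)), key=lambda c: c[0]
        )
        cluster_of_attractor = {}
        for cid, comp in enumerate(comps):
            for i in comp:
                cluster_of_attractor[i] = cid
        assignments: dict[str, int] = {}
        for j in range(n):
            # mass flowing from node j towards each attractor cluster
            masses: dict[int, float] = {}
            for i in attractors:
                masses[cluster_of_attractor[int(i)]] = (
                    masses.get(cluster_of_attractor[int(i)], 0.0) + m[i, j]
                )
            if masses:
                best = max(masses.values())
                cid = min(c for c, v in masses.items() if v >= best - 1e-12)
            else:  # pathological: no attractor reached; isolate the node
                cid = len(comps) + j
            assignments[nodes[j]] = cid
        return ClusterAssignment(assignments, converged=converged, n_iter=it)


def mcl(edges: list[CoexpressionEdge], params: MclParams | None = None) -> ClusterAssignment:
    """Cluster a coexpression edge list (weights = |r|) with MCL."""
    if not edges:
        raise ValueError("empty edge list")
    return MarkovClustering(params).fit_predict(edges_to_graph(edges))


def edges_to_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.lnc_id, e.mrna_id, e.r, e.p) for e in edges],
        columns=["lnc_id", "mrna_id", "r", "p"],
    )


__all__ = [
    "ClusterAssignment",
    "CoexpressionEdge",
    "MarkovClustering",
    "MclParams",
    "correlate_pairs",
    "edges_to_frame",
    "edges_to_graph",
    "mcl",
    "select_top_edges",
]
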