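"""Social-network centrality: eigenvector, Burt constraint/brokerage,
and the PCA composite.

Friendship nominations form a simple directed graph (an edge means the
source named the target).  By default both metrics are computed on the
symmetrized (union) graph: directed eigenvector centrality is unstable
for sink nodes of nomination graphs, and Burt's proportional tie
strengths are conventionally built from mutual ties.  A ``directed``
flag retains the digraph treatment for sensitivity analyses.

Brokerage is defined as ``constraint ** -0.5``: low constraint marks
nodes whose contacts are not connected to each other (brokers), so the
transform makes brokerage increase with brokerage opportunity and is
strictly decreasing in constraint.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "SocialNetwork", "read_edge_list", "write_edge_list",
    "eigenvector_centrality", "burt_constraint", "pca_centrality",
    "centrality_table",
]

#: A social network is any networkx directed graph of nominations.
SocialNetwork = nx.DiGraph


def read_edge_list(path) -> nx.DiGraph:
    """Read a two/three-column TSV ``source<TAB>target[<TAB>weight]``."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        w = float(row[2]) if len(row) > 2 and row[2] is not None else 1.0
        if row[0] == row[1]:
            continue
        g.add_edge(row[0], row[1], weight=w)
    return g


def write_edge_list(g: nx.DiGraph, path) -> None:
    with open(path, "w") as fh:
        for u, v in g.edges:
            fh.write(f"{u}\t{v}\n")


def _validate(net: nx.DiGraph):
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(u == v for u, v in net.edges):
        raise ValueError("self-loops are not allowed")


def _adjacency(net, directed: bool) -> tuple[np.ndarray, list]:
    nodes = list(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    if not directed:
        a = np.maximum(a, a.T)      # union symmetrization
    return a, nodes


def eigenvector_centrality(net: SocialNetwork,
                           directed: bool = False) -> pd.Series:
    """Principal-eigenvector scores, non-negative, max-normalized to 1.

    Computed on the symmetrized adjacency by default (``directed=True``
    uses the right eigenvector of the digraph's adjacency).
    """
    _validate(net)
    a, nodes = _adjacency(net, directed)
    if directed:
        w, v = np.linalg.eig(a.T)
        vec = np.real(v[:, np.argmax(np.real(w))])
    else:
        w, v = np.linalg.eigh(a)
        vec = v[:, -1]
    vec = np.abs(vec)
    m = vec.max()
    if m > 0:
        vec = vec / m
    return pd.Series(vec, index=nodes, name="eigenvector")


def burt_constraint(net: SocialNetwork,
                    directed: bool = False) -> pd.DataFrame:
    """Burt's constraint and brokerage per node.

    Constraint is ``c_i = sum_j (p_ij + sum_q p_iq * p_qj)^2`` over i's
    neighbors j != i, with ``p_ij`` the proportional tie strength
    (row-normalized adjacency; union-symmetrized unless ``directed``,
    in which case strengths combine out- and in-ties as
    ``(a_ij + a_ji) / sum_k (a_ik + a_ki)``).  Brokerage is
    ``constraint ** -0.5``.  Isolated nodes get NaN for both.
    """
    _validate(net)
    a, nodes = _adjacency(net, directed)
    if directed:
        a = a + a.T                 # Burt's directed convention pools ties
    deg = a.sum(axis=1)
    iso = deg == 0
    p = np.divide(a, np.where(iso, 1.0, deg)[:, None])
    m = p + p @ p
    neighbor = a > 0
    c = np.where(iso, np.nan, ((m * neighbor) ** 2).sum(axis=1))
    out = pd.DataFrame({"constraint": c}, index=nodes)
    out["brokerage"] = out["constraint"] ** -0.5
    return out


def pca_centrality(eigen: pd.Series, brokerage: pd.Series) -> pd.Series:
    """First-principal-component composite of the two centrality metrics.

    Both inputs are z-scored, then projected onto the first principal
    component of their 2-column matrix; the sign is oriented so the
    loading on eigenvector centrality is positive.  Nodes with an
    undefined metric are dropped.  The composite has zero mean over the
    included nodes and is invariant to affine rescaling of either input.
    """
    df = pd.concat({"eigenvector": eigen, "brokerage": brokerage},
                   axis=1).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 nodes with defined metrics")
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = [c for c, s in zip(df.columns, sd) if s == 0]
        raise ValueError(f"constant metric, PCA degenerate: {bad}")
    z = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    proj = pca.fit_transform(z)[:, 0]
    if pca.components_[0, 0] < 0:
        proj = -proj
    return pd.Series(proj, index=df.index, name="pca")


def centrality_table(net: SocialNetwork,
                     directed: bool = False,
                     pca_nodes=None) -> pd.DataFrame:
    """Per-node eigenvector, constraint, brokerage and PCA composite.

    ``pca_nodes`` restricts the PCA fit to a node subset (e.g. study
    participants within a larger cohort network); by default it is
    fitted over all nodes with defined metrics.
    """
    eig = eigenvector_centrality(net, directed=directed)
    cons = burt_constraint(net, directed=directed)
    tab = cons.copy()
    tab.insert(0, "eigenvector", eig)
    nodes = list(pca_nodes) if pca_nodes is not None else list(tab.index)
    tab["pca"] = pca_centrality(tab.loc[nodes, "eigenvector"],
                                tab.loc[nodes, "brokerage"])
    return tab
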