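"""High-stringency interaction graphs and Markov clustering (MCL).

Edges survive only strictly above the stringency threshold (default 0.9, the
conventional "high confidence" STRING cutoff).  Clustering alternates
expansion (matrix power) and inflation (entrywise power with column
renormalization) of the column-stochastic transition matrix until the matrix
stops changing; attractor rows then define the clusters.  The procedure is
fully deterministic: nodes are processed in sorted order and overlapping
attractor assignments resolve to the largest cluster, ties to the
lexicographically smallest attractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import EdgeList


@dataclass
class InteractionGraph:
    """Filtered interaction graph plus (optionally) its MCL partition."""

    graph: nx.Graph
    stringency: float
    clusters: list = field(default_factory=list)   # list of frozensets
    converged: bool = True

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def components(self) -> list[frozenset]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def build_graph(edges: EdgeList, gene_set, stringency: float = 0.9,
                include_isolated: bool = False) -> InteractionGraph:
    """Subgraph over ``gene_set`` keeping only edges with weight > stringency.

    Nodes are gene-set members with at least one surviving edge; with
    ``include_isolated`` every member becomes a node regardless.
    """
    gene_set = set(gene_set)
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(sorted(gene_set))
    df = edges.data
    keep = (
        (df["weight"] > stringency)
        & df["node_a"].isin(gene_set)
        & df["node_b"].isin(gene_set)
    )
    for a, b, w in df[keep].itertuples(index=False):
        g.add_edge(a, b, weight=float(w))
    return InteractionGraph(graph=g, stringency=stringency)


def _column_normalize(m: np.ndarray) -> np.ndarray:
    colsum = m.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return m / colsum


def mcl_cluster(graph: InteractionGraph, inflation: float = 2.0,
                expansion: int = 2, prune: float = 1e-5,
                tol: float = 1e-6, max_iter: int = 200) -> list[frozenset]:
    """Markov clustering of the filtered graph (in place on ``graph.clusters``).

    Self-loops are added at each node's maximum incident edge weight before
    normalization.  Non-convergence within ``max_iter`` returns the current
    partition with ``graph.converged = False`` and a warning.
    """
    nodes = graph.nodes
    if not nodes:
        graph.clusters = []
        return []
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, data in graph.graph.edges(data=True):
        w = data.get("weight", 1.0)
        A[index[a], index[b]] = A[index[b], index[a]] = w
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0   # isolated nodes self-loop at unit weight
    np.fill_diagonal(A, loop)

    M = _column_normalize(A)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M ** inflation
        M[M < prune] = 0.0
        M = _column_normalize(M)
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning current "
                      "partition", stacklevel=2)

    # attractors: rows with a positive diagonal entry
    attractors = [i for i in range(n) if M[i, i] > 0]
    raw = {i: set(np.flatnonzero(M[i] > 0)) | {i} for i in attractors}
    # unify attractor rows that overlap (they describe one cluster)
    merged: list[tuple[set, set]] = []   # (attractor ids, member ids)
    for i in attractors:
        members = raw[i]
        hit = [mc for mc in merged if mc[0] & members or mc[1] & members]
        if hit:
            keep = hit[0]
            for other in hit[1:]:
                keep[0].update(other[0])
                keep[1].update(other[1])
                merged.remove(other)
            keep[0].add(i)
            keep[1].update(members)
        else:
            merged.append(({i}, set(members)))

    # deterministic resolution of nodes claimed by several clusters
    clusters = [(sorted(attr), set(members)) for attr, members in merged]
    claimed: dict[int, list] = {}
    for ci, (_, members) in enumerate(clusters):
        for node in members:
            claimed.setdefault(node, []).append(ci)
    for node, cis in claimed.items():
        if len(cis) > 1:
            cis.sort(key=lambda ci: (-len(clusters[ci][1]),
                                     nodes[clusters[ci][0][0]]))
            for ci in cis[1:]:
                clusters[ci][1].discard(node)
    # any node never claimed joins its strongest attractor column entry
    assigned = set().union(*(m for _, m in clusters)) if clusters else set()
    for j in range(n):
        if j not in assigned:
            col = M[:, j]
            best = int(np.argmax(col))
            for ci, (attr, members) in enumerate(clusters):
                if best in members:
                    members.add(j)
                    break
            else:
                clusters.append(([j], {j}))

    out = [frozenset(nodes[i] for i in members) for _, members in clusters
           if members]
    out.sort(key=lambda c: (-len(c), sorted(c)))
    graph.clusters = out
    graph.converged = converged
    return out


def network_summary(graph: InteractionGraph) -> dict:
    """Deterministic summary: counts plus component and cluster sizes
    (descending)."""
    comps = graph.components
    return {
        "node_count": graph.graph.number_of_nodes(),
        "edge_count": graph.graph.number_of_edges(),
        "component_sizes": [len(c) for c in comps],
        "cluster_sizes": [len(c) for c in graph.clusters],
    }


def write_clusters(graph: InteractionGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcluster\n")
        for ci, cluster in enumerate(graph.clusters, start=1):
            for gene in sorted(cluster):
                fh.write(f"{gene}\tC{ci}\n")


def write_graphml(graph: InteractionGraph, path) -> None:
    nx.write_graphml(graph.graph, path)
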