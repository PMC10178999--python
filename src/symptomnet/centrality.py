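"""Node centralities and the per-node summary table for sparsified networks.

Three centralities are reported per node, mirroring the standard
symptom-network summary: degree (number of retained incident edges, split
by partial-correlation sign), eigenvector centrality on the
absolute-weight adjacency (normalized so the maximum node scores 1), and
unweighted shortest-path betweenness with fractional credit for tied
shortest paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sparsify import SparseNetwork


def degree_centrality(net: SparseNetwork) -> pd.DataFrame:
    """Per-node retained-edge counts, split by edge sign.

    Returns a frame indexed by node with columns degree / positive /
    negative; degree = positive + negative always.
    """
    pos = {n: 0 for n in net.nodes}
    neg = {n: 0 for n in net.nodes}
    for e in net.edges:
        bucket = pos if e.sign > 0 else neg
        bucket[e.pair[0]] += 1
        bucket[e.pair[1]] += 1
    return pd.DataFrame(
        {
            "degree": [pos[n] + neg[n] for n in net.nodes],
            "positive": [pos[n] for n in net.nodes],
            "negative": [neg[n] for n in net.nodes],
        },
        index=pd.Index(net.nodes, name="node"),
    )


def eigenvector_centrality(
    net: SparseNetwork,
    absolute: bool = True,
    tol: float = 1e-12,
    max_iter: int = 200_000,
) -> pd.Series:
    """Leading-eigenvector importance on the weighted adjacency.

    Power iteration on A + sigma*I (sigma = max absolute row sum), which
    shares eigenvectors with A but makes the dominant eigenvalue strictly
    largest in magnitude even on bipartite components. The default uses
    absolute weights so the iteration is a Perron problem and scores are
    nonnegative; ``absolute=False`` switches to the signed adjacency.
    Scores are scaled so the maximum is 1; isolated nodes score 0.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless network")
    A = net.adjacency(absolute=absolute)
    sigma = np.abs(A).sum(axis=1).max()
    M = A + sigma * np.eye(len(net.nodes))

    v = np.ones(len(net.nodes))
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = M @ v
        w /= np.linalg.norm(w)
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    else:
        raise RuntimeError("power iteration did not converge")

    v = np.abs(v) if absolute else v * np.sign(v[np.argmax(np.abs(v))])
    v[v < 1e-9] = 0.0
    v /= v.max()
    return pd.Series(v, index=pd.Index(net.nodes, name="node"), name="eigenvector")


def betweenness_centrality(net: SparseNetwork, weighted: bool = False) -> pd.Series:
    """Shortest-path betweenness on the retained-edge graph.

    Unweighted by default (hop-count shortest paths, Brandes accumulation
    with fractional credit for ties, each unordered pair counted once);
    ``weighted=True`` uses 1/|partial correlation| as edge length instead.
    """
    import networkx as nx

    G = net.to_graph()
    if weighted:
        for _, _, d in G.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        scores = nx.betweenness_centrality(G, normalized=False, weight="length")
    else:
        scores = nx.betweenness_centrality(G, normalized=False)
    return pd.Series(
        [float(scores[n]) for n in net.nodes],
        index=pd.Index(net.nodes, name="node"),
        name="betweenness",
    )


def summary_table(
    net: SparseNetwork,
    stability: "pd.DataFrame | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node centrality table plus the per-pair edge report.

    The node table has one row per node — eigenvector, betweenness,
    degree, positive and negative connection counts — sorted by
    eigenvector centrality descending. The edge report lists every node
    pair with its saturated partial correlation, Fisher z, lfdr and
    retention flag; if a stability report is supplied its
    selection_frequency and median_partial_correlation columns are merged
    in.
    """
    deg = degree_centrality(net)
    if net.n_edges > 0:
        eig = eigenvector_centrality(net)
        bet = betweenness_centrality(net)
    else:
        zeros = pd.Series(0.0, index=deg.index)
        eig, bet = zeros.rename("eigenvector"), zeros.rename("betweenness")

    table = pd.concat([eig, bet, deg], axis=1)
    table = table.sort_values(["eigenvector", "degree"], ascending=False, kind="stable")

    edge_rows = [
        {
            "node_a": t.pair[0],
            "node_b": t.pair[1],
            "partial_correlation": t.r,
            "z": t.z,
            "lfdr": t.lfdr,
            "retained": t.retained,
            "sign": t.sign,
        }
        for t in net.tests
    ]
    edges = pd.DataFrame(
        edge_rows,
        columns=["node_a", "node_b", "partial_correlation", "z", "lfdr", "retained", "sign"],
    )
    if stability is not None:
        edges = edges.merge(
            stability[["node_a", "node_b", "selection_frequency", "median_partial_correlation"]],
            on=["node_a", "node_b"],
            how="left",
        )
    return table, edges
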