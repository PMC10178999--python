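"""Centrality table, stability-annotated edge report, GraphML and layout.

Produces the per-node summary (eigenvector / betweenness / degree with
signed connection counts, sorted by eigenvector centrality), merges the
stability metrics into the edge report, and writes the network as GraphML
plus deterministic Fruchterman-Reingold coordinates. A PNG figure is
rendered when matplotlib is available.
"""

from pathlib import Path

import pandas as pd

from symptomnet import layout_fr, sparsify_network, summary_table
from symptomnet.io import read_matrix, write_graphml, write_layout

SEED = 20
OUT = Path("results/study")


def main() -> None:
    partials, names = read_matrix(OUT / "partials.csv")
    net = sparsify_network(partials, cutoff=0.80, nodes=names)
    stability = pd.read_csv(OUT / "stability.csv", float_precision="round_trip")

    table, edges = summary_table(net, stability)
    table.to_csv(OUT / "centrality.csv")
    edges.to_csv(OUT / "edges.csv", index=False)

    write_graphml(net, OUT / "network.graphml")
    layout = layout_fr(net, seed=SEED + 4)
    write_layout(layout, OUT / "layout.csv")

    print(f"network: {net.n_edges} edges over {len(net.nodes)} nodes")
    print("top nodes by eigenvector centrality:")
    print(table.head(5).to_string(float_format=lambda v: f"{v:.3f}"))

    try:
        from symptomnet.io import plot_network

        plot_network(net, layout, OUT / "network.png")
        print(f"figure written to {OUT}/network.png")
    except ImportError:
        print("matplotlib not available; skipped the figure")


if __name__ == "__main__":
    main()
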