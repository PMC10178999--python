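"""File formats: data CSV, labeled matrices, edge tables, GraphML, layouts.

All artifacts are plain text. Data tables are CSV with a header row, one
subject per row and an empty cell for a missing value; matrices are
labeled CSV; networks round-trip through GraphML with node order and edge
attributes preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layout import LayoutResult
from .preprocess import DataMatrix
from .schema import VariableSchema, read_schema, write_schema  # noqa: F401  (re-export)
from .sparsify import EdgeTest, SparseNetwork


def write_data(data: DataMatrix, path) -> None:
    data.frame.to_csv(path, index=False, na_rep="")


def read_data(path, schema: list[VariableSchema], allow_subset: bool = False) -> DataMatrix:
    """Read a data CSV against its schema.

    With ``allow_subset`` the schema is restricted to the columns actually
    present (e.g. after missingness screening); otherwise every schema
    column must exist in the file.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if allow_subset:
        schema = [s for s in schema if s.name in frame.columns]
    frame = frame[[s.name for s in schema]]
    return DataMatrix(frame, list(schema))


def write_matrix(M: np.ndarray, names, path) -> None:
    pd.DataFrame(M, index=list(names), columns=list(names)).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns)


def write_graphml(net: SparseNetwork, path) -> None:
    """Write the retained network (nodes, signed weighted edges) as GraphML."""
    import networkx as nx

    G = net.to_graph()
    G.graph["cutoff"] = float(net.cutoff)
    nx.write_graphml(G, path)


def read_graphml(path) -> SparseNetwork:
    """Rebuild a SparseNetwork (retained edges only) from a GraphML file."""
    import networkx as nx

    G = nx.read_graphml(path)
    nodes = list(G.nodes())
    tests = [
        EdgeTest(
            pair=(a, b),
            r=float(d["r"]),
            z=float(np.arctanh(np.clip(d["r"], -1 + 1e-12, 1 - 1e-12))),
            lfdr=float(d.get("lfdr", 0.0)),
            retained=True,
        )
        for a, b, d in G.edges(data=True)
    ]
    return SparseNetwork(nodes=nodes, tests=tests, cutoff=float(G.graph.get("cutoff", 0.8)))


def write_layout(layout: LayoutResult, path) -> None:
    pd.DataFrame(
        {"node": layout.nodes, "x": layout.coordinates[:, 0], "y": layout.coordinates[:, 1]}
    ).to_csv(path, index=False)


def plot_network(net: SparseNetwork, layout: LayoutResult, path,
                 edge_scale: float = 8.0) -> None:
    """Optional figure: nodes at layout coordinates, edge thickness
    proportional to |partial correlation|, dashed lines for negative edges.

    Requires matplotlib; everything else in the package runs headless
    without it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = layout.as_dict()
    fig, ax = plt.subplots(figsize=(7, 7))
    for e in net.edges:
        (x0, y0), (x1, y1) = coords[e.pair[0]], coords[e.pair[1]]
        ax.plot(
            [x0, x1], [y0, y1],
            lw=edge_scale * abs(e.r),
            ls="-" if e.sign > 0 else "--",
            color="tab:blue" if e.sign > 0 else "tab:red",
            zorder=1, alpha=0.8,
        )
    xs = layout.coordinates[:, 0]
    ys = layout.coordinates[:, 1]
    ax.scatter(xs, ys, s=450, c="white", edgecolors="black", zorder=2)
    for n, (x, y) in coords.items():
        ax.annotate(n, (x, y), ha="center", va="center", fontsize=7, zorder=3)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
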