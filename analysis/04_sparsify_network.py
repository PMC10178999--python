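"""Sparsify the saturated network with the local-FDR 80% retention rule.

Fits the empirical-null mixture to the 190 Fisher-transformed partial
correlations and keeps the pairs whose posterior non-null probability
reaches 80%. Compares the retained set against the generator truth.
"""

from pathlib import Path

import pandas as pd

from symptomnet import sparsify_network
from symptomnet.io import read_matrix

OUT = Path("results/study")
CUTOFF = 0.80


def main() -> None:
    partials, names = read_matrix(OUT / "partials.csv")
    net = sparsify_network(partials, cutoff=CUTOFF, nodes=names)

    rows = [
        {"node_a": t.pair[0], "node_b": t.pair[1], "partial_correlation": t.r,
         "z": t.z, "lfdr": t.lfdr, "retained": t.retained, "sign": t.sign}
        for t in net.tests
    ]
    pd.DataFrame(rows).to_csv(OUT / "edge_tests.csv", index=False)

    truth_edges = pd.read_csv(OUT / "truth_edges.csv")
    true_pairs = {tuple(sorted(p)) for p in
                  zip(truth_edges["node_a"], truth_edges["node_b"])}
    kept = {tuple(sorted(e.pair)) for e in net.edges}
    tp = len(kept & true_pairs)
    print(f"retained {net.n_edges} of {len(net.tests)} pairs at the "
          f"{int(CUTOFF * 100)}% cut-off "
          f"(eta0 = {net.fdr_fit.eta0:.3f}, sigma0 = {net.fdr_fit.sigma0:.3f})")
    print(f"against truth ({len(true_pairs)} edges): "
          f"{tp} true positives, {net.n_edges - tp} false positives, "
          f"sensitivity {tp / len(true_pairs):.2f}")


if __name__ == "__main__":
    main()
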