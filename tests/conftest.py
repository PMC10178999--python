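import numpy as np
import pytest

from symptomnet import (
    DataMatrix,
    EdgeTest,
    SparseNetwork,
    default_schema,
    make_true_graph,
    sample_dataset,
)


@pytest.fixture(scope="session")
def study_schema():
    return default_schema()


@pytest.fixture(scope="session")
def study_dataset(study_schema):
    """One mixed-type dataset at the study scale (n=215, p=20, 26 edges)."""
    truth = make_true_graph(p=20, n_edges=26, magnitude_range=(0.15, 0.4), seed=11)
    return sample_dataset(truth, study_schema, n=215, seed=12)


def build_network(nodes, signed_edges, cutoff=0.8) -> SparseNetwork:
    """Hand-build a SparseNetwork from (a, b, r) triples for graph tests."""
    edge_map = {tuple(sorted((a, b))): r for a, b, r in signed_edges}
    tests = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            key = tuple(sorted((a, b)))
            if key in edge_map:
                r = edge_map[key]
                tests.append(EdgeTest(pair=(a, b), r=r, z=float(np.arctanh(r)),
                                      lfdr=0.0, retained=True))
            else:
                tests.append(EdgeTest(pair=(a, b), r=0.0, z=0.0, lfdr=1.0,
                                      retained=False))
    return SparseNetwork(nodes=list(nodes), tests=tests, cutoff=cutoff)


@pytest.fixture
def net_builder():
    return build_network


def complete_data(frame_values, schema) -> DataMatrix:
    import pandas as pd

    frame = pd.DataFrame(frame_values, columns=[s.name for s in schema])
    return DataMatrix(frame, list(schema))
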