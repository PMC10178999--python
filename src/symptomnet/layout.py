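"""Fruchterman-Reingold force-directed layout for network figures.

Classic spring-embedder: every node pair repels with force k^2/d, every
edge attracts with force d^2/k, and displacements are capped by a linearly
cooling temperature. k is the ideal spring length; two nodes joined by a
single edge settle near distance k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sparsify import SparseNetwork


@dataclass
class LayoutResult:
    nodes: list[str]
    coordinates: np.ndarray  # (n, 2)
    k: float
    seed: int

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {n: (float(x), float(y)) for n, (x, y) in zip(self.nodes, self.coordinates)}


def layout_fr(
    net: SparseNetwork,
    seed: int = 0,
    iterations: int = 200,
    k: float | None = None,
) -> LayoutResult:
    """Deterministic Fruchterman-Reingold coordinates for a sparse network.

    Nodes start at seeded uniform positions in the unit square; ``k``
    defaults to sqrt(1 / n). Isolated nodes feel only repulsion and drift
    to the periphery but always receive finite coordinates.
    """
    n = len(net.nodes)
    if n < 1:
        raise ValueError("layout requires at least one node")
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    if n == 1:
        return LayoutResult(list(net.nodes), pos, 1.0, seed)

    if k is None:
        k = float(np.sqrt(1.0 / n))
    idx = {name: i for i, name in enumerate(net.nodes)}
    edges = np.array(
        [[idx[e.pair[0]], idx[e.pair[1]]] for e in net.edges], dtype=int
    ).reshape(-1, 2)

    t0 = 0.1
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.maximum(dist, 1e-9)
        # repulsion k^2 / d between all pairs
        disp = (delta / dist[..., None]) * (k * k / dist)[..., None]
        np.fill_diagonal(disp[..., 0], 0.0)
        np.fill_diagonal(disp[..., 1], 0.0)
        disp = disp.sum(axis=1)
        # attraction d^2 / k along edges
        for a, b in edges:
            d = pos[a] - pos[b]
            dlen = max(np.linalg.norm(d), 1e-9)
            f = (dlen * dlen / k) * (d / dlen)
            disp[a] -= f
            disp[b] += f
        t = t0 * (1.0 - it / iterations)
        lengths = np.maximum(np.linalg.norm(disp, axis=1), 1e-9)
        pos += disp / lengths[:, None] * np.minimum(lengths, t)[:, None]

    if not np.isfinite(pos).all():
        raise FloatingPointError("layout produced non-finite coordinates")
    return LayoutResult(list(net.nodes), pos, k, seed)
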