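"""GraphHopper core: shortest-path position counting and hop weights.

The GraphHopper construction rewrites the sum over pairs of equal-length
shortest paths as a weighted sum over node pairs,

    K(G, G') = sum_{v in V} sum_{v' in V'} w(v, v') k_n(v, v'),

where the weight ``w(v, v') = <M(v), M(v')>`` is the Frobenius inner product
of two occurrence matrices: ``M(v)`` is a delta x delta integer table whose
``(i, j)`` entry counts how often ``v`` sits at position ``i`` of a shortest
path of discrete length ``j`` (lengths count NODES, so a single edge has
length 2; ``delta`` is the diameter in node count).

All shortest paths between every ordered node pair are counted — ties are
never broken.  The counting never enumerates paths: with ``D`` the distance
matrix and ``sigma`` the all-pairs shortest-path counts, the number of
shortest s->w paths holding ``v`` at position ``D(s,v)+1`` is
``sigma(s,v) * sigma(v,w)`` whenever ``D(s,v) + D(v,w) = D(s,w)``, which is a
handful of masked matrix products per node.  A literal path-enumeration
oracle (:func:`brute_force_weights`) is kept for small graphs.

Trivial single-node paths (length 1) are excluded by default — they carry no
hop structure — and restored with ``include_trivial=True``, which adds 1 to
entry (1, 1) of every occurrence matrix.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "adjacency_of",
    "discrete_diameter",
    "occurrence_matrices",
    "hop_weights",
    "brute_force_weights",
    "weighted_kernel_sum",
]


def adjacency_of(g) -> np.ndarray:
    """Boolean adjacency matrix of anything with ``neighbor_lists()``."""
    if isinstance(g, np.ndarray):
        a = g.astype(bool)
        if a.shape[0] != a.shape[1] or (a != a.T).any() or a.diagonal().any():
            raise ValueError("adjacency must be square, symmetric, hollow")
        return a
    nbrs = g.neighbor_lists()
    n = len(nbrs)
    a = np.zeros((n, n), dtype=bool)
    for u, lst in enumerate(nbrs):
        a[u, lst] = True
    return a


def _distances_and_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs BFS distances D (-1 if unreachable) and shortest-path counts sigma."""
    n = adj.shape[0]
    dist = np.full((n, n), -1, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    sigma = np.eye(n, dtype=float)
    level = np.eye(n, dtype=float)  # counts restricted to the current level
    af = adj.astype(float)
    d = 0
    while level.any():
        d += 1
        t = level @ af
        new = (dist < 0) & (t > 0)
        np.fill_diagonal(new, False)
        if not new.any():
            break
        dist[new] = d
        level = np.where(new, t, 0.0)
        sigma += level
    return dist, sigma


def discrete_diameter(g) -> int:
    """Diameter in node count: the longest shortest path, counting nodes.

    Per connected component; an isolated node has diameter 1 (the trivial
    path), an empty graph 0.
    """
    adj = adjacency_of(g)
    if adj.shape[0] == 0:
        return 0
    dist, _ = _distances_and_counts(adj)
    return int(dist.max()) + 1


def occurrence_matrices(
    g, delta: int | None = None, include_trivial: bool = False
) -> np.ndarray:
    """Stack of occurrence matrices M(v), shape ``(n, delta, delta)``.

    ``delta`` defaults to the graph's own diameter (node count); passing a
    larger value zero-pads, a smaller one is an error.  Entry ``(v, i, j)``
    (0-based) counts shortest paths of discrete length ``j + 1`` holding ``v``
    at position ``i + 1``, over all ordered endpoint pairs within ``v``'s
    connected component.
    """
    adj = adjacency_of(g)
    n = adj.shape[0]
    own = discrete_diameter(adj) if n else 0
    if delta is None:
        delta = own
    elif delta < own:
        raise ValueError(f"delta={delta} is smaller than the graph diameter {own}")
    m = np.zeros((n, delta, delta), dtype=np.int64)
    if n == 0:
        return m
    dist, sigma = _distances_and_counts(adj)
    maxd = int(dist.max())
    # pair (s, w) contributes sigma(s,v) * sigma(v,w) to M(v)[D(s,v), D(s,w)]
    # whenever v lies on a shortest s->w path: D(s,v) + D(v,w) = D(s,w) >= 1
    reach = dist >= 0
    for v in range(n):
        a = dist[:, v]  # D(s, v)
        b = dist[v, :]  # D(v, w)
        ok = reach[:, v][:, None] & reach[v, :][None, :]
        on_path = ok & (a[:, None] + b[None, :] == dist) & (dist >= 1)
        if not on_path.any():
            continue
        contrib = sigma[:, v][:, None] * sigma[v, :][None, :]
        flat = a[:, None] * delta + (a[:, None] + b[None, :])
        m[v] += np.bincount(
            flat[on_path], weights=contrib[on_path], minlength=delta * delta
        ).reshape(delta, delta).astype(np.int64)
    if include_trivial:
        m[:, 0, 0] += 1
    return m


def _cropped_inner(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Inner products of zero-padded occurrence stacks without padding them."""
    k = min(m1.shape[1], m2.shape[1])
    f1 = m1[:, :k, :k].reshape(m1.shape[0], -1).astype(float)
    f2 = m2[:, :k, :k].reshape(m2.shape[0], -1).astype(float)
    return f1 @ f2.T


def hop_weights(g, g2, include_trivial: bool = False) -> np.ndarray:
    """Weight table ``w(v, v') = <M(v), M(v')>`` for a graph pair.

    The padding dimension is the larger of the two diameters; since padding is
    zero, the inner product only runs over the overlapping block.
    """
    m1 = occurrence_matrices(g, include_trivial=include_trivial)
    m2 = occurrence_matrices(g2, include_trivial=include_trivial)
    return _cropped_inner(m1, m2)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _enumerated_occurrences(g, delta: int, include_trivial: bool) -> np.ndarray:
    """Occurrence matrices by literal enumeration of every shortest path."""
    import networkx as nx

    adj = adjacency_of(g)
    n = adj.shape[0]
    gx = nx.from_numpy_array(adj)
    m = np.zeros((n, delta, delta), dtype=np.int64)
    for s in range(n):
        for w in range(n):
            if s == w:
                continue
            if not nx.has_path(gx, s, w):
                continue
            for path in nx.all_shortest_paths(gx, s, w):
                j = len(path)
                for i, v in enumerate(path):
                    m[v, i, j - 1] += 1
    if include_trivial:
        m[:, 0, 0] += 1
    return m


def brute_force_weights(g, g2, include_trivial: bool = False) -> np.ndarray:
    """Oracle weight table via explicit shortest-path enumeration.

    Exponential in the worst case; refuses graphs with more than 10 nodes.
    """
    a1, a2 = adjacency_of(g), adjacency_of(g2)
    if a1.shape[0] > 10 or a2.shape[0] > 10:
        raise ValueError("brute-force oracle is limited to graphs with <= 10 nodes")
    delta = max(discrete_diameter(a1), discrete_diameter(a2), 1)
    m1 = _enumerated_occurrences(a1, delta, include_trivial)
    m2 = _enumerated_occurrences(a2, delta, include_trivial)
    return _cropped_inner(m1, m2)


def weighted_kernel_sum(
    w: np.ndarray, node_kernel: Callable[[int, int], float] | np.ndarray
) -> float:
    """The GraphHopper double sum ``sum_{v, v'} w(v, v') k_n(v, v')``.

    ``node_kernel`` is either a callable on index pairs or a precomputed
    matrix of the same shape as ``w``.
    """
    w = np.asarray(w, dtype=float)
    if isinstance(node_kernel, np.ndarray):
        if node_kernel.shape != w.shape:
            raise ValueError("node kernel matrix shape must match the weight table")
        return float((w * node_kernel).sum())
    total = 0.0
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            if w[i, j]:
                total += w[i, j] * node_kernel(i, j)
    return total
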