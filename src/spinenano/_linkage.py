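"""Single-linkage connected components of a planar point set."""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


def link_components(points: np.ndarray, link_distance: float) -> np.ndarray:
    """Label points by connected component at ``link_distance``.

    Two points are linked when their Euclidean distance is <= the linking
    distance; labels are contiguous integers starting at 0.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    if link_distance <= 0:
        raise ValueError("link distance must be > 0")
    pairs = cKDTree(points).query_pairs(link_distance, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels
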