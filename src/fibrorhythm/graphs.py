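"""Small helpers for k-nearest-neighbour graphs on a 2-D embedding."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_adjacency"]


def knn_adjacency(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Binary kNN adjacency on ``coords``, symmetrised by max (an edge
    exists if either endpoint lists the other among its k neighbours);
    no self-edges.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return sp.csr_matrix((n, n))
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k_eff)
    cols = idx[:, 1:].ravel()  # drop self
    a = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    a = a.maximum(a.T)
    a.data[:] = 1.0
    return a
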