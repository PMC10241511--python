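"""Geodesic Gaussian smoothing operators on triangle meshes.

Geodesic distances are approximated by shortest paths along mesh edges
(weighted by Euclidean edge length).  The Gaussian kernel is truncated at
three standard deviations and row-normalized, so constant fields are exact
fixed points of the operator.  Smoothing never mixes hemispheres: the edge
graph of a two-hemisphere mesh is disconnected across hemispheres.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def edge_graph(vertices: np.ndarray, triangles: np.ndarray) -> sparse.csr_matrix:
    """Symmetric sparse matrix of Euclidean edge lengths."""
    i = np.concatenate([triangles[:, 0], triangles[:, 1], triangles[:, 2]])
    j = np.concatenate([triangles[:, 1], triangles[:, 2], triangles[:, 0]])
    w = np.linalg.norm(vertices[i] - vertices[j], axis=1)
    n = len(vertices)
    g = sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    return g.maximum(g.T)


def truncated_geodesic_distances(
    graph: sparse.csr_matrix, cutoff_mm: float
) -> sparse.csr_matrix:
    """All-pairs shortest-path distances up to ``cutoff_mm`` (sparse).

    Diagonal entries (distance zero) are stored explicitly so the kernel
    builder can include each vertex in its own neighbourhood.
    """
    dist = dijkstra(graph, directed=False, limit=cutoff_mm)
    dist[~np.isfinite(dist)] = -1.0
    rows, cols = np.nonzero(dist >= 0)
    keep = dist[rows, cols] <= cutoff_mm
    rows, cols = rows[keep], cols[keep]
    out = sparse.coo_matrix(
        (dist[rows, cols], (rows, cols)), shape=dist.shape
    ).tocsr()
    out.setdiag(0.0)
    return out


def gaussian_operator(
    vertices: np.ndarray, triangles: np.ndarray, fwhm_mm: float
) -> sparse.csr_matrix:
    """Row-normalized geodesic Gaussian smoothing matrix for one mesh patch."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    n = len(vertices)
    if fwhm_mm == 0:
        return sparse.identity(n, format="csr")
    sd = fwhm_mm / FWHM_TO_SD
    graph = edge_graph(vertices, triangles)
    dist = truncated_geodesic_distances(graph, cutoff_mm=3.0 * sd)
    kernel = dist.copy()
    kernel.data = np.exp(-0.5 * (dist.data / sd) ** 2)
    # vertices reachable at distance 0 (the diagonal) were stored explicitly,
    # exp(0)=1, so every row has at least one entry
    row_sums = np.asarray(kernel.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / row_sums)
    return (inv @ kernel).tocsr()
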