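"""Geometric reformatting: cortical mesh <-> regular 2-D grid.

Image convolutions need data on a regular grid, but cortical activity lives
on a triangulated sphere.  Each hemisphere is therefore flattened with a
Lambert azimuthal equal-area projection centred on its lateral (outer) pole
and every non-medial vertex is assigned to its own grid cell, nearest free
cell first.  Because the assignment is injective, the inverse reformatting
recovers the original vertex values exactly: the forward/backward pair loses
nothing on the vertices that carry data.

The two hemispheres occupy the two channels of the grid image.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import CorticalTimeseries, DimensionError
from .synthetic import CorticalMesh

__all__ = ["GridMapping", "GridSequence", "build_grid_mapping", "to_grid", "from_grid",
           "save_mapping", "load_mapping"]


class CapacityError(ValueError):
    """Grid too small to hold every non-medial vertex."""


@dataclass
class GridMapping:
    """Injective vertex -> (channel, row, col) assignment for one mesh.

    ``cell_index[v]`` is the flat row*W + col cell of vertex ``v`` within its
    hemisphere's channel, or -1 for unassigned (medial) vertices.
    ``validity`` is an (H, W, 2) boolean mask of occupied cells.
    """

    cell_index: np.ndarray  # (V,) int, -1 if unassigned
    channel: np.ndarray  # (V,) int, 0=L, 1=R
    grid_shape: tuple  # (H, W)
    validity: np.ndarray  # (H, W, 2) bool
    mesh_id: str

    @property
    def n_assigned(self) -> int:
        return int((self.cell_index >= 0).sum())

    @property
    def assigned_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.cell_index >= 0)


@dataclass
class GridSequence:
    """T frames of two-channel grid images plus the validity mask."""

    frames: np.ndarray  # (T, H, W, 2)
    validity: np.ndarray  # (H, W, 2) bool
    mapping_id: str = "mapping"

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def _lambert_plane(vertices: np.ndarray, center: np.ndarray, pole: np.ndarray,
                   radius: float) -> np.ndarray:
    """Project sphere points to the plane, equal-area, centred on ``pole``."""
    local = (vertices - center) / radius
    p = pole / np.linalg.norm(pole)
    # orthonormal tangent basis at the pole
    helper = np.array([0.0, 0.0, 1.0]) if abs(p[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(p, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    cos_theta = np.clip(local @ p, -1.0, 1.0)
    rho = 2.0 * np.sin(0.5 * np.arccos(cos_theta))  # equal-area radial law
    az = np.arctan2(local @ e2, local @ e1)
    return radius * rho[:, None] * np.column_stack([np.cos(az), np.sin(az)])


def build_grid_mapping(mesh: CorticalMesh, grid_shape: tuple = (32, 32)) -> GridMapping:
    """Assign every non-medial vertex of each hemisphere to its own grid cell.

    Vertices are projected to the plane (area-preserving), scaled into the
    grid, then assigned greedily: the globally closest (vertex, free cell)
    pair is fixed first, ties broken by lower vertex index.  Deterministic.

    Raises
    ------
    CapacityError
        If a hemisphere has more non-medial vertices than grid cells; the
        message states the required minimum.
    """
    H, W = grid_shape
    cell_index = np.full(mesh.n_vertices, -1, dtype=np.int64)
    channel = np.where(mesh.hemisphere == "L", 0, 1).astype(np.int64)
    validity = np.zeros((H, W, 2), dtype=bool)

    # grid cell centres, shared by both hemispheres
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    centers = np.column_stack([rr.ravel() + 0.5, cc.ravel() + 0.5])
    tree = cKDTree(centers)
    n_cells = H * W

    for ch, hemi in enumerate(("L", "R")):
        idx = mesh.hemi_indices(hemi)
        keep = idx[~mesh.medial_mask[idx]]
        if len(keep) > n_cells:
            raise CapacityError(
                f"hemisphere {hemi}: {len(keep)} vertices need at least "
                f"{len(keep)} cells, grid has {n_cells}"
            )
        center = mesh.vertices[idx].mean(axis=0)
        # outer pole: away from the other hemisphere (L: -x, R: +x)
        pole = np.array([-1.0, 0.0, 0.0]) if hemi == "L" else np.array([1.0, 0.0, 0.0])
        plane = _lambert_plane(mesh.vertices[keep], center, pole, mesh.radius_mm)
        # scale the projected disk into the grid rectangle
        rmax = np.abs(plane).max()
        scale = 0.5 * (min(H, W) - 1e-6) / max(rmax, 1e-12)
        pts = plane * scale + np.array([H / 2.0, W / 2.0])

        # global greedy nearest-free-cell assignment via an incremental heap
        k0 = min(8, n_cells)
        dists, cells = tree.query(pts, k=k0)
        dists, cells = np.atleast_2d(dists), np.atleast_2d(cells)
        heap = [(dists[i, 0], int(keep[i]), i, 0) for i in range(len(keep))]
        heapq.heapify(heap)
        ranks = {i: (dists[i], cells[i]) for i in range(len(keep))}
        taken = np.zeros(n_cells, dtype=bool)
        n_done = 0
        while heap:
            d, v, i, rank = heapq.heappop(heap)
            dlist, clist = ranks[i]
            cell = int(clist[rank])
            if taken[cell]:
                nxt = rank + 1
                if nxt >= len(clist):  # widen this vertex's candidate list
                    kk = min(len(clist) * 2, n_cells)
                    dlist, clist = tree.query(pts[i], k=kk)
                    ranks[i] = (np.atleast_1d(dlist), np.atleast_1d(clist))
                    dlist, clist = ranks[i]
                heapq.heappush(heap, (float(dlist[nxt]), v, i, nxt))
                continue
            taken[cell] = True
            cell_index[v] = cell
            validity[cell // W, cell % W, ch] = True
            n_done += 1
        assert n_done == len(keep)

    return GridMapping(
        cell_index=cell_index,
        channel=channel,
        grid_shape=(H, W),
        validity=validity,
        mesh_id=mesh.mesh_id,
    )


def to_grid(ts: CorticalTimeseries, mapping: GridMapping) -> GridSequence:
    """Forward reformatting: vertex values into grid cells; linear in the data."""
    if ts.mesh_id != mapping.mesh_id:
        raise DimensionError(
            f"timeseries mesh {ts.mesh_id!r} does not match mapping mesh "
            f"{mapping.mesh_id!r}"
        )
    H, W = mapping.grid_shape
    T = ts.n_frames
    frames = np.zeros((T, H, W, 2), dtype=np.float64)
    v = mapping.assigned_vertices
    cells = mapping.cell_index[v]
    frames[:, cells // W, cells % W, mapping.channel[v]] = ts.values[v].T
    return GridSequence(frames=frames, validity=mapping.validity,
                        mapping_id=mapping.mesh_id)


def from_grid(grid: GridSequence, mapping: GridMapping) -> CorticalTimeseries:
    """Inverse reformatting; unassigned (medial) vertices are set to zero."""
    H, W = mapping.grid_shape
    if grid.frames.shape[1:] != (H, W, 2):
        raise DimensionError(
            f"grid frames shape {grid.frames.shape[1:]} does not match "
            f"mapping grid {(H, W, 2)}"
        )
    v = mapping.assigned_vertices
    cells = mapping.cell_index[v]
    values = np.zeros((len(mapping.cell_index), grid.n_frames))
    values[v] = grid.frames[:, cells // W, cells % W, mapping.channel[v]].T
    return CorticalTimeseries(values=values, mesh_id=mapping.mesh_id)


def save_mapping(mapping: GridMapping, path) -> None:
    payload = {
        "cell_index": mapping.cell_index.tolist(),
        "channel": mapping.channel.tolist(),
        "grid_shape": list(mapping.grid_shape),
        "mesh_id": mapping.mesh_id,
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def load_mapping(path) -> GridMapping:
    with open(path) as f:
        payload = json.load(f)
    H, W = payload["grid_shape"]
    cell_index = np.array(payload["cell_index"], dtype=np.int64)
    channel = np.array(payload["channel"], dtype=np.int64)
    validity = np.zeros((H, W, 2), dtype=bool)
    v = np.flatnonzero(cell_index >= 0)
    validity[cell_index[v] // W, cell_index[v] % W, channel[v]] = True
    return GridMapping(cell_index=cell_index, channel=channel, grid_shape=(H, W),
                       validity=validity, mesh_id=payload["mesh_id"])
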