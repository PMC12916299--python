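"""Spherical surface meshes and per-vertex scalar maps.

All maps in this package live on a triangulated unit sphere, the synthetic
stand-in for a registered cortical surface template. A per-vertex boolean
validity mask plays the role of the medial-wall exclusion: invalid vertices
never enter smoothing averages, correlations or cluster searches.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import trimesh
from nibabel.freesurfer import io as fsio
from scipy import sparse
from scipy.spatial import cKDTree


class SphereMesh:
    """Closed triangle mesh with every vertex on the unit sphere.

    Parameters
    ----------
    vertices : (n, 3) array
        Vertex coordinates; each row must have unit norm (tolerance 1e-9).
    faces : (m, 3) int array
        Counter-clockwise vertex index triples.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        norms = np.linalg.norm(vertices, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("all vertices must lie on the unit sphere (|v| = 1)")
        n = len(vertices)
        if faces.min(initial=0) < 0 or faces.max(initial=-1) >= n:
            raise ValueError("face indices out of range")
        if np.any(
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        ):
            raise ValueError("degenerate face (repeated vertex index)")
        self.vertices = vertices
        self.faces = faces
        self._adjacency: sparse.csr_matrix | None = None
        self._tree: cKDTree | None = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + len(self.faces)

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 vertex adjacency (two vertices adjacent iff they
        share a mesh edge)."""
        if self._adjacency is None:
            f = self.faces
            rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
            cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
            a = sparse.coo_matrix(
                (np.ones(len(rows)), (rows, cols)),
                shape=(self.n_vertices, self.n_vertices),
            ).tocsr()
            a.data[:] = 1.0  # collapse duplicate entries
            self._adjacency = a
        return self._adjacency

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def is_closed(self) -> bool:
        return self.euler_characteristic == 2

    def __repr__(self) -> str:  # pragma: no cover
        return f"SphereMesh(n_vertices={self.n_vertices}, n_faces={len(self.faces)})"


@dataclass
class VertexMap:
    """Per-vertex scalar field with a validity mask.

    ``values`` at invalid vertices are carried along but never used by any
    statistical operation.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    mesh: SphereMesh = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).copy()
        n = self.mesh.n_vertices
        if self.values.shape != (n,) or self.valid_mask.shape != (n,):
            raise ValueError("values/valid_mask length must equal mesh.n_vertices")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite value at a valid vertex")

    @classmethod
    def full(cls, mesh: SphereMesh, values: np.ndarray) -> "VertexMap":
        """Map with all vertices valid."""
        return cls(values, np.ones(mesh.n_vertices, bool), mesh)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def copy_with(self, values: np.ndarray) -> "VertexMap":
        return VertexMap(values, self.valid_mask, self.mesh)


def build_icosphere(subdivisions: int) -> SphereMesh:
    """Icosahedron subdivided ``subdivisions`` times and reprojected to the
    unit sphere; vertex count is 10·4**s + 2.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 not supported (mesh would be huge)")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(tm.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SphereMesh(v, np.asarray(tm.faces))


def smooth_map(
    mesh: SphereMesh, vmap: VertexMap, iterations: int, weight: float = 1.0
) -> VertexMap:
    """Iterative neighbor-averaging diffusion on valid vertices.

    Each iteration updates valid vertex i by
    ``x_i += (weight / d_max) * sum_{j in valid neighbors}(x_j - x_i)``,
    where ``d_max`` is the maximum valid-neighbor count. At a regular
    (degree-``d_max``) vertex with ``weight=1`` this replaces the value by the
    plain mean of its neighbors; the symmetric normalization conserves the
    mean over valid vertices exactly on a closed mesh. Invalid vertices, and
    valid vertices with no valid neighbor, keep their values; the mask is
    unchanged.
    """
    if iterations < 0:
        raise ValueError("iterations must be non-negative")
    if not (0.0 < weight <= 1.0):
        raise ValueError("weight must be in (0, 1]")
    mask = vmap.valid_mask
    if not mask.any():
        raise ValueError("cannot smooth an all-invalid map")
    if iterations == 0:
        return vmap.copy_with(vmap.values)

    idx = np.flatnonzero(mask)
    sub = mesh.adjacency[idx][:, idx].tocsr()  # adjacency of the valid submesh
    deg = np.asarray(sub.sum(axis=1)).ravel()
    d_max = deg.max()
    x_full = vmap.values.copy()
    if d_max == 0:  # isolated valid vertices: nothing moves
        return vmap.copy_with(x_full)
    x = x_full[idx]
    c = weight / d_max
    for _ in range(iterations):
        x = x + c * (sub @ x - deg * x)
    x_full[idx] = x
    return vmap.copy_with(x_full)


def connected_clusters(
    mesh: SphereMesh, mask: np.ndarray, min_size: int
) -> np.ndarray:
    """Label connected components of a vertex mask under edge adjacency.

    Components with fewer than ``min_size`` vertices are relabeled 0; the
    survivors get labels 1..K in order of decreasing size (ties broken by the
    smallest contained vertex index). Returns a per-vertex int array, 0
    meaning "no cluster".
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_vertices,):
        raise ValueError("mask length must equal mesh.n_vertices")
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return labels
    sub = mesh.adjacency[idx][:, idx]
    n_comp, comp = sparse.csgraph.connected_components(sub, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    keep = np.flatnonzero(sizes >= min_size)
    # order: descending size, then smallest member vertex index
    first_vertex = np.full(n_comp, mesh.n_vertices, dtype=np.int64)
    np.minimum.at(first_vertex, comp, idx)
    order = sorted(keep, key=lambda k: (-sizes[k], first_vertex[k]))
    relabel = np.zeros(n_comp, dtype=np.int64)
    for new, old in enumerate(order, start=1):
        relabel[old] = new
    labels[idx] = relabel[comp]
    return labels


# ---------------------------------------------------------------------------
# I/O


def write_vertex_map(vmap: VertexMap, path, fmt: str = "csv") -> None:
    """Write per-vertex values to ``csv`` (one value per line, one-line
    header) or FreeSurfer new-style binary ``curv`` (float32)."""
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["value"])
            for v in vmap.values:
                w.writerow([repr(float(v))])
    elif fmt == "freesurfer-curv":
        fsio.write_morph_data(path, vmap.values.astype(np.float32),
                              fnum=len(vmap.mesh.faces))
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'freesurfer-curv')")


def read_vertex_map(
    path, mesh: SphereMesh, fmt: str = "csv", valid_mask: np.ndarray | None = None
) -> VertexMap:
    """Read a per-vertex map written by :func:`write_vertex_map`.

    The file holds values only; the validity mask is supplied by the caller
    (default: all valid). Length mismatch with the mesh, or a NaN at a valid
    vertex, is an error.
    """
    if fmt == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        values = np.array([float(r[0]) for r in rows[1:]], dtype=np.float64)
    elif fmt == "freesurfer-curv":
        values = np.asarray(fsio.read_morph_data(path), dtype=np.float64)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv' or 'freesurfer-curv')")
    if len(values) != mesh.n_vertices:
        raise ValueError(
            f"map has {len(values)} values but mesh has {mesh.n_vertices} vertices"
        )
    if valid_mask is None:
        valid_mask = np.ones(mesh.n_vertices, bool)
    return VertexMap(values, valid_mask, mesh)


def write_mesh(mesh: SphereMesh, path, fmt: str | None = None) -> None:
    """Export the mesh as ASCII OFF or PLY (inferred from the extension)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    name = str(path)
    if fmt == "ply" or (fmt is None and name.endswith(".ply")):
        tm.export(path, file_type="ply", encoding="ascii")
    else:
        tm.export(path, file_type=fmt)


def read_mesh(path) -> SphereMesh:
    tm = trimesh.load(path, process=False, force="mesh")
    v = np.asarray(tm.vertices, dtype=np.float64)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SphereMesh(v, np.asarray(tm.faces))
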