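"""Isosurface reconstruction of the cortex.

The cortical surface is recovered from a masked scalar volume as the
level set of an automatically chosen isovalue, triangulated by marching
cubes, and carried as a :class:`TriMesh` in world (mm) coordinates with
outward vertex normals.  Enclosed volumes are computed exactly for the
polyhedral mesh by the divergence theorem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from skimage import measure

from .volume_io import VolumeGrid

logger = logging.getLogger(__name__)


@dataclass
class TriMesh:
    """Triangulated isosurface: world-mm vertices, faces, outward normals."""

    vertices: np.ndarray  # N×3, mm
    faces: np.ndarray  # M×3 vertex indices
    vertex_normals: np.ndarray = field(default=None)
    component_ids: np.ndarray = field(default=None)  # per-vertex component label

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        keep = (
            (self.faces[:, 0] != self.faces[:, 1])
            & (self.faces[:, 1] != self.faces[:, 2])
            & (self.faces[:, 0] != self.faces[:, 2])
        )
        # zero-area faces from lattice-coincident crossings are dropped
        if keep.size:
            v = self.vertices
            n = np.cross(
                v[self.faces[:, 1]] - v[self.faces[:, 0]],
                v[self.faces[:, 2]] - v[self.faces[:, 0]],
            )
            keep &= (n ** 2).sum(axis=1) > 1e-24
        self.faces = self.faces[keep]
        if self.vertex_normals is None:
            self.vertex_normals = area_weighted_vertex_normals(self.vertices, self.faces)
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float).reshape(-1, 3)
        if self.component_ids is None:
            self.component_ids = vertex_components(len(self.vertices), self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_components(self) -> int:
        return int(self.component_ids.max()) + 1 if len(self.component_ids) else 0

    def edges(self) -> np.ndarray:
        """Undirected unique edges (K×2, sorted pairs)."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def boundary_edge_count(self) -> int:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int((counts != 2).sum())

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + len(self.faces)

    def submesh(self, vertex_mask: np.ndarray) -> "TriMesh":
        """Mesh restricted to faces whose three vertices are all kept."""
        vertex_mask = np.asarray(vertex_mask, dtype=bool)
        fmask = vertex_mask[self.faces].all(axis=1)
        old = np.flatnonzero(vertex_mask)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[old] = np.arange(len(old))
        return TriMesh(
            self.vertices[old],
            remap[self.faces[fmask]],
            self.vertex_normals[old],
            self.component_ids[old],
        )

    def translated(self, t) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(t, dtype=float),
                       self.faces.copy(), self.vertex_normals.copy(),
                       self.component_ids.copy())


def area_weighted_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit vertex normals as the area-weighted mean of incident face normals."""
    vn = np.zeros_like(vertices)
    if len(faces):
        fn = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )  # |fn| = 2·area → area weighting is built in
        for k in range(3):
            np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1)
    nz = norm > 0
    vn[nz] /= norm[nz, None]
    return vn


def vertex_components(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    if n_vertices == 0:
        return np.zeros(0, dtype=np.int64)
    if len(faces) == 0:
        return np.arange(n_vertices, dtype=np.int64)
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    g = sparse.coo_matrix((np.ones_like(i), (i, j)), shape=(n_vertices, n_vertices))
    _, labels = _cc(g, directed=False)
    return labels.astype(np.int64)


def select_isovalue(vol: VolumeGrid, n_bins: int = 64) -> float:
    """Histogram-based isovalue for a masked (background = 0) volume.

    Builds an ``n_bins`` histogram of all voxels, removes the dominant
    (background) mode — the modal bin together with the contiguous run
    of heavily populated bins around it, so a noisy background peak is
    removed whole — discards remaining bins holding < 1% of the
    remaining voxels, and returns the midpoint between the background
    mode and the count-median surviving bin — a deterministic
    mid-intensity threshold between background and tissue.
    """
    data = np.asarray(vol.data, dtype=float).ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        raise ValueError("no isosurface exists: volume is constant")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = int(np.argmax(counts))
    rest = counts.copy()
    # remove the background peak: the modal bin plus its contiguous
    # neighbors still holding >= 1% of all voxels
    heavy = 0.01 * counts.sum()
    left = mode
    while left > 0 and counts[left - 1] >= heavy:
        left -= 1
    right = mode
    while right < n_bins - 1 and counts[right + 1] >= heavy:
        right += 1
    rest[left:right + 1] = 0
    total = rest.sum()
    if total == 0:
        # two-valued degenerate case collapsed into one bin: fall back to midpoint
        return 0.5 * (lo + hi)
    small = rest < 0.01 * total
    rest[small] = 0
    cum = np.cumsum(rest)
    median_bin = int(np.searchsorted(cum, cum[-1] / 2.0))
    alpha = 0.5 * (centers[mode] + centers[median_bin])
    # keep strictly inside the data range
    return float(np.clip(alpha, np.nextafter(lo, hi), np.nextafter(hi, lo)))


def marching_cubes(vol: VolumeGrid, alpha: float) -> TriMesh:
    """Extract the α-level set of a volume as a world-space triangle mesh.

    Edge crossings are located by linear interpolation between the
    marked (≥ α) and unmarked corner of each active lattice edge; the
    standard marching-cubes case table resolves the intersection
    topology (saddle-cube ambiguities follow the case table and are not
    re-decided).  Faces are wound so normals point outward, i.e. away
    from the ≥ α side.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    if not (data.min() < alpha < data.max()):
        raise ValueError(
            f"isovalue {alpha} outside data range [{data.min()}, {data.max()}]"
        )
    verts, faces, normals, _ = measure.marching_cubes(data, level=alpha)
    world = vol.voxel_to_world(verts)
    mesh = TriMesh(world, faces)
    # orient against the interpolated gradient normals (outward = toward
    # lower intensity for a bright-tissue volume); mapped through the
    # inverse-transpose of the affine's linear part
    g_world = normals @ np.linalg.inv(vol.affine[:3, :3])
    agree = float((mesh.vertex_normals * g_world).sum())
    if agree < 0:
        mesh = TriMesh(world, faces[:, ::-1])
    # `descent` normals point toward decreasing values = outward already;
    # as a final guard make any closed mesh enclose positive signed volume
    if mesh.is_closed():
        sv = _signed_volume(mesh.vertices, mesh.faces)
        if sv < 0:
            mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def mesh_signed_volume(mesh: TriMesh) -> float:
    """Enclosed volume (mm³) of a closed mesh via the divergence theorem.

    volume = |Σ_faces det(v0, v1, v2) / 6|; exact for polyhedra.
    """
    nb = mesh.boundary_edge_count()
    if nb:
        raise ValueError(f"mesh is not closed: {nb} boundary edge(s)")
    return abs(_signed_volume(mesh.vertices, mesh.faces))


def component_volumes(mesh: TriMesh) -> list[float]:
    """Per-connected-component enclosed volume; open components are skipped."""
    out = []
    for c in range(mesh.n_components):
        sub = mesh.submesh(mesh.component_ids == c)
        if len(sub.faces) and sub.is_closed():
            out.append(abs(_signed_volume(sub.vertices, sub.faces)))
    return out


def save_mesh(mesh: TriMesh, path: str | Path,
              vertex_scalars: dict[str, np.ndarray] | None = None) -> Path:
    """Export as PLY (binary little-endian) or OBJ by extension."""
    import trimesh as _tm

    path = Path(path)
    tm = _tm.Trimesh(mesh.vertices, mesh.faces, process=False)
    if vertex_scalars:
        for name, vals in vertex_scalars.items():
            tm.vertex_attributes[name] = np.asarray(vals, dtype=np.float32)
    tm.export(str(path))
    return path


def load_mesh(path: str | Path) -> TriMesh:
    import trimesh as _tm

    tm = _tm.load(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
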