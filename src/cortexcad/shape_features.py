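"""Per-vertex curvature descriptors from local quadric fits.

At every mesh vertex the surface patch around it is rotated into the
vertex's normal frame, a least-squares quadric f(x,y) = ax² + by² + cxy
+ dx + ey + f is fitted to the neighborhood heights, and the principal
curvatures λ1 ≥ λ2 are read off the shape operator at the origin.  Four
rotation-invariant descriptors follow:

    gaussian   = λ1·λ2          (1/mm²)
    mean       = (λ1 + λ2)/2    (1/mm)
    sharpness  = (λ1 − λ2)²     (1/mm²)
    curvedness = √((λ1² + λ2²)/2)  (1/mm)

Sign convention: normals point outward from tissue and heights are
measured toward the inside, so a convex region (a ball of radius R) has
positive principal curvatures +1/R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .surface_recon import TriMesh

logger = logging.getLogger(__name__)

#: beyond this residual tilt of the fitted tangent plane the full
#: first-fundamental-form correction is applied
TILT_THRESHOLD = 0.05

DESCRIPTOR_NAMES = ("gaussian", "mean", "sharpness", "curvedness")


@dataclass
class VertexShape:
    """Per-vertex principal curvatures and the four shape descriptors."""

    lambda1: np.ndarray  # 1/mm, λ1 ≥ λ2
    lambda2: np.ndarray
    dir1: np.ndarray  # N×3 unit world vectors
    dir2: np.ndarray
    gaussian: np.ndarray
    mean: np.ndarray
    sharpness: np.ndarray
    curvedness: np.ndarray

    def descriptor_matrix(self) -> np.ndarray:
        """N×4 array in the fixed order (gaussian, mean, sharpness, curvedness)."""
        return np.column_stack([self.gaussian, self.mean, self.sharpness, self.curvedness])


def vertex_adjacency(mesh: TriMesh) -> list[np.ndarray]:
    """Sorted one-ring neighbor indices for every vertex."""
    nbrs: list[set] = [set() for _ in range(mesh.n_vertices)]
    for f in mesh.faces:
        a, b, c = int(f[0]), int(f[1]), int(f[2])
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return [np.array(sorted(s), dtype=np.int64) for s in nbrs]


def vertex_neighborhood(
    mesh: TriMesh, v: int, rings: int = 2,
    adjacency: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Indices of all vertices within ``rings`` edge hops of ``v``.

    Excludes ``v`` itself; returned in ascending index order.
    """
    if rings < 1:
        raise ValueError("rings must be >= 1")
    adj = adjacency if adjacency is not None else vertex_adjacency(mesh)
    if len(adj[v]) == 0:
        raise ValueError(f"vertex {v} is isolated (no incident faces)")
    seen = {v}
    frontier = {v}
    for _ in range(rings):
        nxt = set()
        for u in frontier:
            nxt.update(adj[u].tolist())
        frontier = nxt - seen
        seen |= nxt
        if not frontier:
            break
    seen.discard(v)
    return np.array(sorted(seen), dtype=np.int64)


def normal_frame(normal: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows t1, t2, n) with n = ``normal``."""
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("zero normal")
    n = n / nn
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(n)))] = 1.0
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.vstack([t1, t2, n])


def rotate_to_normal_frame(
    points: np.ndarray, origin: np.ndarray, normal: np.ndarray
) -> np.ndarray:
    """Rigidly map points into the local frame of a vertex.

    The origin maps to (0,0,0) and the normal to the local +z (height)
    axis; the two tangent axes complete a right-handed orthonormal
    frame, so distances are preserved.
    """
    R = normal_frame(normal)
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(origin, dtype=float)
    return pts @ R.T


def fit_quadric_patch(local_points: np.ndarray) -> np.ndarray:
    """Least-squares quadric f(x,y) = ax²+by²+cxy+dx+ey+f to (x,y,h) samples.

    Exact when the points lie on a quadric; raises on rank deficiency
    (too few or degenerate neighborhoods — enlarge the ring radius).
    """
    pts = np.atleast_2d(np.asarray(local_points, dtype=float))
    if pts.shape[0] < 6:
        raise ValueError(
            f"need at least 6 points to fit a quadric, got {pts.shape[0]}; "
            "increase the neighborhood rings"
        )
    x, y, h = pts[:, 0], pts[:, 1], pts[:, 2]
    A = np.column_stack([x * x, y * y, x * y, x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError(
            "quadric design matrix is rank deficient; increase the neighborhood rings"
        )
    coeffs, *_ = np.linalg.lstsq(A, h, rcond=None)
    return coeffs


def principal_curvatures(coeffs: np.ndarray):
    """Principal curvatures (λ1 ≥ λ2) and tangent-plane directions.

    With the frame anchored at the vertex the first-order terms d, e are
    near zero and the shape operator reduces to the Hessian
    [[2a, c], [c, 2b]].  When the fitted tangent plane is appreciably
    tilted (√(d²+e²) > 0.05 — a rotation-invariant criterion) the full
    Weingarten map I⁻¹·II of the graph is used instead.

    Returns (λ1, λ2, u1, u2) with u1, u2 unit 2-vectors in the local
    tangent coordinates.
    """
    a, b, c, d, e, _ = np.asarray(coeffs, dtype=float)
    H = np.array([[2 * a, c], [c, 2 * b]])
    if np.hypot(d, e) > TILT_THRESHOLD:
        w = np.sqrt(1.0 + d * d + e * e)
        II = H / w
        I = np.array([[1 + d * d, d * e], [d * e, 1 + e * e]])
        W = np.linalg.solve(I, II)
        # symmetrize in the metric: eigvals of I^-1 II are real
        lam, vec = np.linalg.eig(W)
        lam = lam.real
        vec = vec.real
    else:
        lam, vec = np.linalg.eigh(H)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    u1 = vec[:, 0] / np.linalg.norm(vec[:, 0])
    u2 = vec[:, 1] / np.linalg.norm(vec[:, 1])
    return float(lam[0]), float(lam[1]), u1, u2


def shape_descriptors(lambda1, lambda2):
    """The four curvature descriptors (gaussian, mean, sharpness, curvedness)."""
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    gaussian = l1 * l2
    mean = 0.5 * (l1 + l2)
    sharpness = (l1 - l2) ** 2
    curvedness = np.sqrt((l1 * l1 + l2 * l2) / 2.0)
    return gaussian, mean, sharpness, curvedness


def compute_vertex_shapes(mesh: TriMesh, rings: int = 2, max_rings: int = 4) -> VertexShape:
    """Fit a quadric patch at every vertex and evaluate the descriptors.

    Rank-deficient neighborhoods escalate ``rings`` one step at a time
    up to ``max_rings``; vertices that still fail (isolated or tiny
    components) get NaN curvatures and are excluded downstream.
    """
    n = mesh.n_vertices
    adj = vertex_adjacency(mesh)
    l1 = np.full(n, np.nan)
    l2 = np.full(n, np.nan)
    d1 = np.full((n, 3), np.nan)
    d2 = np.full((n, 3), np.nan)
    n_failed = 0
    for v in range(n):
        if len(adj[v]) == 0:
            n_failed += 1
            continue
        normal = mesh.vertex_normals[v]
        if np.linalg.norm(normal) < 1e-12:
            n_failed += 1
            continue
        R = normal_frame(normal)
        fitted = None
        r = rings
        while r <= max_rings:
            nbr = vertex_neighborhood(mesh, v, r, adjacency=adj)
            pts = np.vstack([mesh.vertices[nbr], mesh.vertices[v][None, :]])
            local = (pts - mesh.vertices[v]) @ R.T
            # height measured toward the inside so convexity is positive
            sample = np.column_stack([local[:, 0], local[:, 1], -local[:, 2]])
            try:
                fitted = fit_quadric_patch(sample)
                break
            except ValueError:
                r += 1
        if fitted is None:
            n_failed += 1
            continue
        lam1, lam2, u1, u2 = principal_curvatures(fitted)
        l1[v], l2[v] = lam1, lam2
        d1[v] = u1[0] * R[0] + u1[1] * R[1]
        d2[v] = u2[0] * R[0] + u2[1] * R[1]
    if n_failed:
        logger.warning("curvature fit failed at %d of %d vertices", n_failed, n)
    g, m, s, c = shape_descriptors(l1, l2)
    return VertexShape(l1, l2, d1, d2, g, m, s, c)


def vertex_shape_table(mesh: TriMesh, shapes: VertexShape):
    """Per-vertex feature dump as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "vertex_id": np.arange(mesh.n_vertices),
            "x": mesh.vertices[:, 0],
            "y": mesh.vertices[:, 1],
            "z": mesh.vertices[:, 2],
            "lambda1": shapes.lambda1,
            "lambda2": shapes.lambda2,
            "gaussian": shapes.gaussian,
            "mean": shapes.mean,
            "sharpness": shapes.sharpness,
            "curvedness": shapes.curvedness,
        }
    )
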