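"""Triangle-mesh construction primitives and metrology.

All geometry in this package is carried by :class:`TriMesh`, an indexed
triangle surface mesh in millimetres.  The two constructors used by the
valve and ventricle builders are :func:`loft_ellipses` (stitching a stack of
planar elliptical cross-sections along the long axis) and
:func:`revolve_with_bulge` (a surface of revolution whose radius may be
perturbed per ``(z, theta)``, used for the sinuses of Valsalva).

Conventions: the long axis is +Z, units are mm, faces are counter-clockwise
when seen from outside, so a watertight mesh has positive signed volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class EllipseSection:
    """A planar elliptical cross-section at axial position ``z`` (mm).

    ``cx, cy`` shift the centre within the section plane; ``ax, ay`` are the
    semi-axes.  Circular sections have ``ax == ay``.
    """

    z: float
    cx: float = 0.0
    cy: float = 0.0
    ax: float = 1.0
    ay: float = 1.0

    def __post_init__(self) -> None:
        if self.ax <= 0 or self.ay <= 0:
            raise ValueError(f"semi-axes must be positive, got ax={self.ax}, ay={self.ay}")

    def ring(self, n_theta: int) -> np.ndarray:
        """Sample the ellipse at ``n_theta`` equally spaced angles -> (n, 3)."""
        theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
        return np.column_stack(
            [
                self.cx + self.ax * np.cos(theta),
                self.cy + self.ay * np.sin(theta),
                np.full(n_theta, float(self.z)),
            ]
        )


@dataclass
class TriMesh:
    """Indexed triangle surface mesh (vertices in mm, 0-based faces).

    ``lateral_mask`` marks vertices belonging to the lateral (non-cap)
    surface; builders set it so that radius statistics can exclude cap
    centroids.  It is optional: metrology infers a mask when absent.
    """

    vertices: np.ndarray
    faces: np.ndarray
    lateral_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        if self.faces.min(initial=0) < 0:
            raise ValueError("negative face index")
        if self.lateral_mask is not None:
            self.lateral_mask = np.asarray(self.lateral_mask, dtype=bool).reshape(-1)
            if self.lateral_mask.shape[0] != self.vertices.shape[0]:
                raise ValueError("lateral_mask length must match vertex count")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        """Return a rigidly moved copy (rotation applied before translation)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces.copy(), None if self.lateral_mask is None else self.lateral_mask.copy())

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        return np.cross(b - a, c - a)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())


def _undirected_edges(faces: np.ndarray) -> np.ndarray:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    return np.sort(edges, axis=1)


def is_watertight(mesh: TriMesh) -> bool:
    """Every undirected edge shared by exactly two faces."""
    if mesh.n_faces == 0:
        return False
    edges = _undirected_edges(mesh.faces)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume (mm^3) of a watertight mesh via the divergence theorem.

    The signed sum of tetrahedra spanned by each face and the origin is
    orientation-corrected to a positive value.
    """
    if not is_watertight(mesh):
        raise ValueError("mesh_volume requires a watertight mesh (2 faces per edge)")
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    signed = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return float(abs(signed))


def polygon_correction(n_theta: int) -> float:
    """Area ratio of the inscribed regular n-gon to its circumcircle.

    A lofted ring sampled at ``n`` angles is an n-gon, so discrete volumes
    equal the analytic solid-of-revolution value times this factor.
    """
    return n_theta * np.sin(2.0 * np.pi / n_theta) / (2.0 * np.pi)


def _stitch_rings(
    rings: Sequence[np.ndarray],
    cap_bottom: bool,
    cap_top: bool,
) -> TriMesh:
    """Stitch same-size vertex rings (ordered bottom -> top) into a TriMesh."""
    n = rings[0].shape[0]
    verts = [np.concatenate(rings, axis=0)]
    n_ring_verts = len(rings) * n
    faces = []
    j = np.arange(n)
    j1 = (j + 1) % n
    for i in range(len(rings) - 1):
        a = i * n + j
        b = i * n + j1
        c = (i + 1) * n + j1
        d = (i + 1) * n + j
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, d]))
    extra = 0
    if cap_bottom:
        centroid = rings[0].mean(axis=0, keepdims=True)
        ci = n_ring_verts + extra
        verts.append(centroid)
        faces.append(np.column_stack([np.full(n, ci), j1, j]))
        extra += 1
    if cap_top:
        centroid = rings[-1].mean(axis=0, keepdims=True)
        ci = n_ring_verts + extra
        base = (len(rings) - 1) * n
        verts.append(centroid)
        faces.append(np.column_stack([np.full(n, ci), base + j, base + j1]))
        extra += 1
    lateral = np.ones(n_ring_verts + extra, dtype=bool)
    if extra:
        lateral[n_ring_verts:] = False
    return TriMesh(np.concatenate(verts, axis=0), np.concatenate(faces, axis=0), lateral)


def loft_ellipses(
    sections: Sequence[EllipseSection],
    n_theta: int = 128,
    cap_ends: bool = True,
) -> TriMesh:
    """Loft a stack of elliptical cross-sections into a triangle surface.

    Sections must be strictly ordered by increasing ``z``.  Vertex ``j`` of
    ring ``i`` connects to vertex ``j`` of ring ``i+1`` (no twist
    minimisation); caps are triangle fans to the section centroid, so the
    capped loft is watertight.
    """
    if len(sections) < 2:
        raise ValueError("loft_ellipses needs at least 2 sections")
    if n_theta < 8:
        raise ValueError("n_theta must be >= 8")
    z = np.array([s.z for s in sections], dtype=float)
    if np.any(np.diff(z) <= 0):
        raise ValueError("sections must be strictly ordered by increasing z")
    rings = [s.ring(n_theta) for s in sections]
    return _stitch_rings(rings, cap_bottom=cap_ends, cap_top=cap_ends)


def revolve_with_bulge(
    profile: np.ndarray,
    n_theta: int = 128,
    bulge: Callable[[float, np.ndarray], np.ndarray] | None = None,
    cap_ends: bool = False,
) -> TriMesh:
    """Revolve a planar ``(radius, z)`` polyline about +Z with an optional
    radial bulge.

    ``bulge(z, theta)`` returns a non-negative radial increment (mm) for each
    angle of the ring at height ``z``; with ``bulge=None`` the result is a
    plain surface of revolution.
    """
    profile = np.asarray(profile, dtype=float).reshape(-1, 2)
    if profile.shape[0] < 2:
        raise ValueError("profile needs at least 2 (radius, z) pairs")
    if np.any(profile[:, 0] <= 0):
        raise ValueError("profile radii must be positive")
    if n_theta < 8:
        raise ValueError("n_theta must be >= 8")
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    rings = []
    for r0, z in profile:
        r = np.full(n_theta, r0)
        if bulge is not None:
            inc = np.asarray(bulge(z, theta), dtype=float)
            inc = np.broadcast_to(inc, theta.shape)
            if np.any(inc < -1e-12):
                raise ValueError("bulge must be non-negative")
            r = r + inc
        if np.any(r <= 0):
            raise ValueError("bulge produced a non-positive radius")
        rings.append(np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(n_theta, z)]))
    return _stitch_rings(rings, cap_bottom=cap_ends, cap_top=cap_ends)


@dataclass
class MeshMetrics:
    height: float
    radius_min: float
    radius_max: float
    radius_avg: float


def _infer_lateral_mask(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Heuristic cap exclusion for meshes without builder metadata.

    Vertices lying on an end plane but radially inside its outermost ring
    (cap-fan centroids of re-imported meshes) are treated as cap vertices.
    """
    mask = np.ones(t.shape[0], dtype=bool)
    scale = max(np.ptp(t), 1.0)
    for t_end in (t.min(), t.max()):
        on_plane = np.abs(t - t_end) < 1e-9 * scale
        if np.any(on_plane):
            r_edge = r[on_plane].max()
            mask[on_plane & (r < r_edge - 1e-6)] = False
    return mask


def mesh_metrics(
    mesh: TriMesh,
    axis=(0.0, 0.0, 1.0),
    apex_exclusion: float = 2.0,
) -> MeshMetrics:
    """Height and radius statistics of a mesh about an axis through the origin.

    Height is the extent of vertex projections on the axis.  Radii are
    distances of lateral-surface vertices from the axis; cap vertices and an
    apex-exclusion band (``apex_exclusion`` mm below the maximal projection,
    where a rounded apex would otherwise drive ``radius_min`` to zero) are
    excluded.  ``radius_avg`` is the area-weighted mean over the remaining
    lateral vertices, each weighted by one third of its incident
    lateral-face area.
    """
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must have non-zero length")
    axis = axis / norm
    t = mesh.vertices @ axis
    radial = mesh.vertices - np.outer(t, axis)
    r = np.linalg.norm(radial, axis=1)
    lateral = mesh.lateral_mask if mesh.lateral_mask is not None else _infer_lateral_mask(t, r)
    band = t <= t.max() - apex_exclusion
    sel = lateral & band
    if not np.any(sel):
        raise ValueError("no lateral vertices left after cap/apex exclusion")
    # vertex weights from faces whose three corners are all lateral
    w = np.zeros(mesh.n_vertices)
    face_lateral = lateral[mesh.faces].all(axis=1)
    if np.any(face_lateral):
        areas = mesh.face_areas()[face_lateral]
        for k in range(3):
            np.add.at(w, mesh.faces[face_lateral, k], areas / 3.0)
    if w[sel].sum() <= 0:
        w[sel] = 1.0
    r_avg = float(np.average(r[sel], weights=w[sel]))
    return MeshMetrics(
        height=float(np.ptp(t)),
        radius_min=float(r[sel].min()),
        radius_max=float(r[sel].max()),
        radius_avg=r_avg,
    )


def _closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Distance from each point ``p[i]`` to triangle ``(a[i], b[i], c[i])``.

    Vectorised barycentric region classification (Ericson's real-time
    collision detection algorithm).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m

    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    v = d1 / denom
    closest[m] = a[m] + v[m, None] * ab[m]
    done |= m

    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    w = d2 / denom
    closest[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom != 0, denom, 1.0)
    w = (d4 - d3) / denom
    closest[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(p - closest, axis=1)


def points_to_surface_distance(
    points: np.ndarray,
    mesh: TriMesh,
    face_mask: np.ndarray | None = None,
    k: int = 16,
) -> np.ndarray:
    """Unsigned nearest distance from each point to (a subset of) the mesh.

    Candidate triangles per point are the ``k`` faces with nearest centroids;
    exact point-triangle distances are then minimised over candidates.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    faces = mesh.faces if face_mask is None else mesh.faces[np.asarray(face_mask, dtype=bool)]
    if len(faces) == 0:
        raise ValueError("no target faces")
    tri = mesh.vertices[faces]  # (m, 3, 3)
    centroids = tri.mean(axis=1)
    k = min(k, len(faces))
    _, idx = cKDTree(centroids).query(points, k=k)
    idx = np.atleast_2d(idx.reshape(len(points), k))
    cand = tri[idx]  # (n, k, 3, 3)
    p_rep = np.repeat(points, k, axis=0)
    d = _closest_point_on_triangles(
        p_rep,
        cand[:, :, 0].reshape(-1, 3),
        cand[:, :, 1].reshape(-1, 3),
        cand[:, :, 2].reshape(-1, 3),
    ).reshape(len(points), k)
    return d.min(axis=1)
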