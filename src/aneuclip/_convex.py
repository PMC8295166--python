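"""Convex solid queries: containment, first segment crossing, surface distance.

The clip blades are closed convex solids, so every collision/distance query
the deformation loop needs has an exact form: containment is a conjunction of
halfspace tests, the first crossing of a motion segment comes from clipping
the segment against the halfspaces (Liang–Barsky style), and the unsigned
surface distance is a minimum of point–triangle distances over the boundary
triangles.  All queries are vectorised over points/segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConvexSolid", "box_solid", "point_triangle_closest"]

# canonical unit-box topology: 8 corners (± half extents, z-fastest order),
# 12 outward-CCW triangles
_BOX_CORNERS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
    dtype=np.float64,
)
_BOX_FACES = np.array(
    [
        [0, 1, 3], [0, 3, 2],  # -x
        [4, 6, 7], [4, 7, 5],  # +x
        [0, 4, 5], [0, 5, 1],  # -y
        [2, 3, 7], [2, 7, 6],  # +y
        [0, 2, 6], [0, 6, 4],  # -z
        [1, 5, 7], [1, 7, 3],  # +z
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class ConvexSolid:
    """Closed convex solid given by hull triangles and bounding halfspaces.

    ``normals @ x <= offsets`` (all rows) iff x is inside or on the surface.
    """

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) outward CCW
    normals: np.ndarray  # (k, 3) unit outward plane normals
    offsets: np.ndarray  # (k,)

    @classmethod
    def from_points(cls, points: np.ndarray) -> "ConvexSolid":
        """Convex hull of a point cloud (used for imported blade meshes)."""
        from scipy.spatial import ConvexHull

        hull = ConvexHull(np.asarray(points, dtype=np.float64))
        verts = hull.points[hull.vertices]
        remap = np.full(len(hull.points), -1, dtype=np.int64)
        remap[hull.vertices] = np.arange(len(hull.vertices))
        faces = remap[hull.simplices]
        normals = hull.equations[:, :3]
        offsets = -hull.equations[:, 3]
        # Qhull does not guarantee simplex winding; fix against the outward
        # plane normal of each facet
        a, b, c = (verts[faces[:, i]] for i in range(3))
        fn = np.cross(b - a, c - a)
        flip = np.einsum("ij,ij->i", fn, normals) < 0
        faces[flip] = faces[flip][:, ::-1]
        return cls(verts, faces, normals, offsets)

    def transformed(self, transform: np.ndarray) -> "ConvexSolid":
        """Apply a rigid transform (4x4 homogeneous)."""
        R, t = transform[:3, :3], transform[:3, 3]
        verts = self.vertices @ R.T + t
        normals = self.normals @ R.T
        offsets = self.offsets + normals @ t
        return ConvexSolid(verts, self.faces, normals, offsets)

    # -- queries -----------------------------------------------------------

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """True where a point is inside or within ``tol`` of the surface."""
        p = np.atleast_2d(points)
        d = p @ self.normals.T - self.offsets
        return (d <= tol).all(axis=1)

    def depth(self, points: np.ndarray) -> np.ndarray:
        """Penetration depth: -max plane distance; positive strictly inside."""
        p = np.atleast_2d(points)
        d = p @ self.normals.T - self.offsets
        return -d.max(axis=1)

    def segment_entry(self, p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """First crossing of segments p0->p1 into the solid.

        Returns ``(hit, t_entry)`` with t in [0, 1] along each segment.  The
        segment is open at its start: a segment leaving the surface does not
        count as a hit, while an endpoint exactly on the surface does.
        """
        p0 = np.atleast_2d(p0)
        p1 = np.atleast_2d(p1)
        d0 = p0 @ self.normals.T - self.offsets  # (n, k)
        d1 = p1 @ self.normals.T - self.offsets
        miss = ((d0 > 0) & (d1 > 0)).any(axis=1)
        denom = d0 - d1
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(np.abs(denom) > 0, d0 / np.where(denom == 0, 1.0, denom), 0.0)
        entering = d0 > 0  # start outside this halfspace
        exiting = (d1 > 0) & ~entering
        t_enter = np.where(entering, t, -np.inf).max(axis=1)
        t_enter = np.maximum(t_enter, 0.0)
        t_exit = np.where(exiting, t, np.inf).min(axis=1)
        t_exit = np.minimum(t_exit, 1.0)
        hit = (~miss) & (t_enter <= t_exit) & (t_exit > 0.0)
        return hit, np.where(hit, t_enter, np.nan)

    def surface_closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest point on the boundary surface and its (unsigned) distance.

        Valid for points inside and outside alike; brute force over the hull
        triangles (their count is small by construction).
        """
        p = np.atleast_2d(points)
        tri = self.vertices[self.faces]  # (m, 3, 3)
        closest, dist = point_triangle_closest(p, tri)
        best = dist.argmin(axis=1)
        idx = np.arange(len(p))
        return closest[idx, best], dist[idx, best]

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance to the solid: 0 on or inside, else to surface."""
        _, d = self.surface_closest(points)
        return np.where(self.contains(points), 0.0, d)


def point_triangle_closest(points: np.ndarray, triangles: np.ndarray):
    """Closest points on triangles for every (point, triangle) pair.

    points: (n, 3); triangles: (m, 3, 3).  Returns closest (n, m, 3) and
    distances (n, m).  Standard barycentric region classification.
    """
    p = points[:, None, :]  # (n, 1, 3)
    a = triangles[None, :, 0, :]
    b = triangles[None, :, 1, :]
    c = triangles[None, :, 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_face = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = vb / denom_face
        w_face = vc / denom_face
        v_ab = np.clip(d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0, 1.0)
        w_ac = np.clip(d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0, 1.0)
        t_bc = np.clip(
            (d4 - d3) / np.where((d4 - d3) + (d5 - d6) == 0, 1.0, (d4 - d3) + (d5 - d6)),
            0.0,
            1.0,
        )

    closest = a + v_face[..., None] * ab + w_face[..., None] * ac  # interior default
    # edge BC region
    in_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(in_bc[..., None], b + t_bc[..., None] * (c - b), closest)
    # edge AC region
    in_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(in_ac[..., None], a + w_ac[..., None] * ac, closest)
    # edge AB region
    in_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(in_ab[..., None], a + v_ab[..., None] * ab, closest)
    # vertex regions
    in_a = (d1 <= 0) & (d2 <= 0)
    closest = np.where(in_a[..., None], a, closest)
    in_b = (d3 >= 0) & (d4 <= d3)
    closest = np.where(in_b[..., None], b, closest)
    in_c = (d6 >= 0) & (d5 <= d6)
    closest = np.where(in_c[..., None], c, closest)

    dist = np.linalg.norm(p - closest, axis=-1)
    return closest, dist


def box_solid(transform: np.ndarray, half_extents: np.ndarray) -> ConvexSolid:
    """Axis-aligned box of given half extents posed by a rigid transform."""
    h = np.asarray(half_extents, dtype=np.float64)
    verts = _BOX_CORNERS * h
    normals = np.vstack([-np.eye(3), np.eye(3)])
    offsets = np.concatenate([h, h])
    return ConvexSolid(verts, _BOX_FACES.copy(), normals, offsets).transformed(transform)
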