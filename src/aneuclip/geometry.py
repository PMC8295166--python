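"""Synthetic vessel, aneurysm and clip geometry.

All other modules are testable against the meshes produced here: open-ended
tubes standing in for vessel segments, a parametric bifurcation-with-dome
aneurysm standing in for expert-built MCA bifurcation cases, and hinged
two-blade clip models.  Units are millimetres throughout; the coordinate
convention is right-handed with the mesh-local origin at the parent-vessel
inlet centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "TriangleMesh",
    "MeshValidationError",
    "make_tube",
    "make_bifurcation_aneurysm",
    "make_clip",
    "mesh_edges",
    "boundary_vertices",
    "ANEURYSM_PRESETS",
]

_ZERO_AREA_TOL = 1e-12  # mm^2


class MeshValidationError(ValueError):
    """A mesh violated a structural invariant; the message names the first."""


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    Faces are vertex-index triples with counter-clockwise winding, so face
    normals point out of the enclosed solid (or away from the vessel lumen).
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def validate(self) -> "TriangleMesh":
        """Check structural invariants; raise naming the first violation.

        Invariants: face indices valid, no degenerate faces (repeated vertex
        or area below 1e-12 mm^2), and edge-manifoldness (every undirected
        edge borders at most two faces).
        """
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= self.n_vertices):
            raise MeshValidationError("face references a vertex index out of range")
        if f.size:
            repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if repeated.any():
                raise MeshValidationError(
                    f"face {int(np.argmax(repeated))} repeats a vertex index"
                )
            areas = self.face_areas()
            if (areas < _ZERO_AREA_TOL).any():
                raise MeshValidationError(
                    f"face {int(np.argmin(areas))} has (near-)zero area"
                )
            edges = _directed_edges(f)
            uniq, counts = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
            if (counts > 2).any():
                i, j = uniq[np.argmax(counts > 2)]
                raise MeshValidationError(
                    f"edge ({int(i)}, {int(j)}) borders more than two faces"
                )
        return self

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def mesh_edges(mesh: TriangleMesh) -> np.ndarray:
    """Unique undirected edges of the mesh as an (e, 2) array with i < j.

    This is the spring topology: one entry per unique mesh edge, sorted
    lexicographically for determinism.
    """
    e = np.sort(_directed_edges(mesh.faces), axis=1)
    uniq = np.unique(e, axis=0)
    return uniq


def boundary_vertices(mesh: TriangleMesh) -> np.ndarray:
    """Vertex ids on open boundaries (edges bordering exactly one face).

    Used as the default anchor set: vessels are held fixed at their cut
    ends, mirroring arteries clamped at the edge of the surgical field.
    """
    e = np.sort(_directed_edges(mesh.faces), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    rim = uniq[counts == 1]
    return np.unique(rim)


# ---------------------------------------------------------------------------
# tube generator
# ---------------------------------------------------------------------------


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangent + two normals along a polyline, twist-minimising."""
    tangents = np.zeros_like(points)
    seg = np.diff(points, axis=0)
    seg_dir = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    tangents[:-1] = seg_dir
    tangents[-1] = seg_dir[-1]
    # interior tangents: average of adjacent segment directions
    if len(points) > 2:
        mid = seg_dir[:-1] + seg_dir[1:]
        tangents[1:-1] = mid / np.linalg.norm(mid, axis=1, keepdims=True)

    # initial normal: any vector not parallel to the first tangent
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    n = np.cross(t0, ref)
    n /= np.linalg.norm(n)
    normals = np.empty_like(points)
    binormals = np.empty_like(points)
    normals[0] = n
    binormals[0] = np.cross(t0, n)
    for i in range(1, len(points)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_cur)
        s = np.linalg.norm(axis)
        c = float(np.dot(t_prev, t_cur))
        if s < 1e-14:
            normals[i] = normals[i - 1]
        else:
            axis = axis / s
            ang = np.arctan2(s, c)
            normals[i] = _rotate_about(normals[i - 1], axis, ang)
        normals[i] -= tangents[i] * np.dot(normals[i], tangents[i])
        normals[i] /= np.linalg.norm(normals[i])
        binormals[i] = np.cross(tangents[i], normals[i])
    return tangents, normals, binormals


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def make_tube(
    centerline: np.ndarray | Iterable,
    radius: float,
    n_radial: int,
    n_axial: int,
) -> TriangleMesh:
    """Open-ended tube of given radius around a polyline centerline.

    Vertices come in ``n_axial + 1`` rings of ``n_radial`` points each
    (ring-major order), so the vertex count is ``n_radial * (n_axial + 1)``
    and the face count ``2 * n_radial * n_axial``.  Rings are spaced
    uniformly in arc length; frames are parallel-transported so the surface
    does not twist around bends.
    """
    pts = np.asarray(centerline, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("centerline must contain at least two 3-D points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_radial < 3:
        raise ValueError("n_radial must be at least 3")
    if n_axial < 1:
        raise ValueError("n_axial must be at least 1")
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if (seg_len < 1e-12).any():
        raise ValueError("degenerate centerline: repeated consecutive points")

    # resample uniformly in arc length to n_axial + 1 stations
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    stations = np.linspace(0.0, arc[-1], n_axial + 1)
    centers = np.empty((n_axial + 1, 3))
    for d in range(3):
        centers[:, d] = np.interp(stations, arc, pts[:, d])
    _, normals, binormals = _parallel_transport_frames(centers)

    theta = 2 * np.pi * np.arange(n_radial) / n_radial
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    verts = (
        centers[:, None, :]
        + radius * (cos_t[None, :, None] * normals[:, None, :]
                    + sin_t[None, :, None] * binormals[:, None, :])
    ).reshape(-1, 3)

    faces = []
    for a in range(n_axial):
        base = a * n_radial
        nxt = base + n_radial
        for j in range(n_radial):
            j2 = (j + 1) % n_radial
            # outward CCW winding (verified against signed volume of the
            # capped solid during development)
            faces.append((base + j, nxt + j2, nxt + j))
            faces.append((base + j, base + j2, nxt + j2))
    return TriangleMesh(verts, np.array(faces, dtype=np.int64)).validate()


# ---------------------------------------------------------------------------
# bifurcation aneurysm generator (SDF union + marching cubes)
# ---------------------------------------------------------------------------


def _sdf_capsule(p: np.ndarray, a: np.ndarray, b: np.ndarray, r: float) -> np.ndarray:
    """Signed distance to a capsule (cylinder with spherical caps) a-b."""
    ab = b - a
    t = np.clip(((p - a) @ ab) / float(ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1) - r


def _sdf_sphere(p: np.ndarray, c: np.ndarray, r: float) -> np.ndarray:
    return np.linalg.norm(p - c, axis=1) - r


def make_bifurcation_aneurysm(
    parent_radius: float = 1.4,
    daughter_radius: float = 1.0,
    bifurcation_angle: float = 70.0,
    dome_radius: float = 2.5,
    neck_radius: float = 1.2,
    parent_length: float = 8.0,
    daughter_length: float = 7.0,
    voxel_pitch: float | None = None,
) -> TriangleMesh:
    """Parametric bifurcation with a dome aneurysm at the apex.

    A parent tube splits at the apex into two daughter tubes separated by
    ``bifurcation_angle``; a spherical dome of ``dome_radius`` sits above the
    apex, joined through a neck of ``neck_radius``.  ``dome_radius = 0`` is
    the degenerate no-aneurysm case (a plain bifurcation).  The surface is
    extracted from a signed-distance union on a regular grid and the three
    tube ends are cut open, so the result is a single connected, edge-
    manifold surface open only at the inlet and the two outlets.

    This is a geometric stand-in for bifurcation aneurysms of the middle
    cerebral artery, not a replica of any specific case.
    """
    if parent_radius <= 0 or daughter_radius <= 0:
        raise ValueError("radii must be positive")
    if dome_radius < 0:
        raise ValueError("dome_radius must be non-negative")
    if dome_radius > 0 and neck_radius > dome_radius:
        raise ValueError("neck_radius must not exceed dome_radius")
    if not 0.0 < bifurcation_angle < 180.0:
        raise ValueError("bifurcation_angle must be in (0, 180) degrees")

    from skimage import measure

    apex = np.array([0.0, 0.0, parent_length])
    inlet = np.zeros(3)
    half = np.deg2rad(bifurcation_angle) / 2.0
    d1 = np.array([np.sin(half), 0.0, np.cos(half)])
    d2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    out1 = apex + daughter_length * d1
    out2 = apex + daughter_length * d2
    # neck rises perpendicular to the daughter plane bisector (+z here) —
    # the dome sits on top of the flow divider, the classic bifurcation type
    dome_dir = np.array([0.0, 1.0, 0.0])
    neck_len = max(dome_radius * 0.8, parent_radius)
    dome_centre = apex + (neck_len + 0.6 * dome_radius) * dome_dir

    # extend tubes beyond their nominal ends so the end caps can be cut away
    margin = 2.0 * max(parent_radius, daughter_radius)
    inlet_ext = inlet - np.array([0.0, 0.0, margin])
    out1_ext = out1 + margin * d1
    out2_ext = out2 + margin * d2

    if voxel_pitch is None:
        voxel_pitch = 0.22 * min(parent_radius, daughter_radius,
                                 dome_radius if dome_radius > 0 else parent_radius)

    pts_all = np.vstack([inlet_ext, out1_ext, out2_ext, apex, dome_centre])
    rmax = max(parent_radius, daughter_radius, dome_radius, neck_radius)
    lo = pts_all.min(axis=0) - rmax - 2 * voxel_pitch
    hi = pts_all.max(axis=0) + rmax + 2 * voxel_pitch
    nx, ny, nz = (np.ceil((hi - lo) / voxel_pitch).astype(int) + 1)
    xs = lo[0] + voxel_pitch * np.arange(nx)
    ys = lo[1] + voxel_pitch * np.arange(ny)
    zs = lo[2] + voxel_pitch * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    sdf = _sdf_capsule(grid, inlet_ext, apex, parent_radius)
    sdf = np.minimum(sdf, _sdf_capsule(grid, apex, out1_ext, daughter_radius))
    sdf = np.minimum(sdf, _sdf_capsule(grid, apex, out2_ext, daughter_radius))
    if dome_radius > 0:
        sdf = np.minimum(sdf, _sdf_capsule(grid, apex, dome_centre, neck_radius))
        sdf = np.minimum(sdf, _sdf_sphere(grid, dome_centre, dome_radius))
    vol = sdf.reshape(nx, ny, nz)

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(voxel_pitch,) * 3)
    verts = verts + lo
    # marching_cubes orients normals along the gradient (inward for SDF<0
    # inside); flip to outward CCW
    faces = faces[:, ::-1].copy()

    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=True)  # welds + drops degenerates

    # open the three tube ends: drop faces beyond each nominal end plane
    keep = np.ones(len(tm.faces), dtype=bool)
    centroids = tm.triangles_center
    for origin, outward in (
        (inlet, np.array([0.0, 0.0, -1.0])),
        (out1, d1),
        (out2, d2),
    ):
        keep &= (centroids - origin) @ outward <= 0.0
    tm.update_faces(keep)
    tm.remove_unreferenced_vertices()

    # keep only the largest connected component (cut residue can detach)
    comps = tm.split(only_watertight=False)
    if len(comps) > 1:
        tm = max(comps, key=lambda c: len(c.faces))

    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    return _drop_degenerate_faces(mesh).validate()


def _drop_degenerate_faces(mesh: TriangleMesh) -> TriangleMesh:
    areas = mesh.face_areas()
    f = mesh.faces
    ok = (
        (areas >= _ZERO_AREA_TOL)
        & (f[:, 0] != f[:, 1])
        & (f[:, 1] != f[:, 2])
        & (f[:, 0] != f[:, 2])
    )
    return TriangleMesh(mesh.vertices, f[ok])


#: Named parameter presets standing in for a small menu of bifurcation
#: aneurysm cases of graded size and geometry (implementer-chosen values).
ANEURYSM_PRESETS: dict[str, dict[str, float]] = {
    "small-narrow-neck": dict(parent_radius=1.4, daughter_radius=1.0,
                              bifurcation_angle=70.0, dome_radius=1.8, neck_radius=0.8),
    "small-wide-neck": dict(parent_radius=1.4, daughter_radius=1.0,
                            bifurcation_angle=70.0, dome_radius=1.8, neck_radius=1.6),
    "medium": dict(parent_radius=1.4, daughter_radius=1.0,
                   bifurcation_angle=80.0, dome_radius=2.5, neck_radius=1.2),
    "large": dict(parent_radius=1.5, daughter_radius=1.1,
                  bifurcation_angle=90.0, dome_radius=3.5, neck_radius=1.8),
    "wide-angle": dict(parent_radius=1.4, daughter_radius=1.0,
                       bifurcation_angle=120.0, dome_radius=2.5, neck_radius=1.2),
}


def make_clip(
    blade_length: float,
    blade_width: float,
    blade_thickness: float,
    opening_angle: float,
):
    """Hinged two-blade clip with rectangular-box blades.

    Convenience re-export; see :func:`aneuclip.clip.make_clip`.
    """
    from .clip import make_clip as _make_clip

    return _make_clip(blade_length, blade_width, blade_thickness, opening_angle)
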