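"""Rigid hinged clip: kinematics, collision queries and collision response.

The clip is the moving obstacle of the simulation: two rigid blades on a
common hinge, driven kinematically (the surgeon's hand; no reaction force).
A vessel mass point is only moved to its integrated position if the motion
does not cross a blade; on collision the point stops a fraction (default
0.9) of the collision distance along its motion, i.e. directly in front of
the contact point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._convex import ConvexSolid, box_solid
from .geometry import TriangleMesh

__all__ = [
    "ClipModel",
    "CollisionResult",
    "make_clip",
    "set_clip_state",
    "collision_query",
    "collision_query_batch",
    "resolve_collision",
    "resolve_collision_batch",
    "point_clip_distance",
    "clip_surface_closest",
]

logger = logging.getLogger(__name__)

#: fraction of the collision distance a colliding point travels
DEFAULT_COLLISION_SLACK = 0.9

_STRICT_INSIDE_TOL = -1e-12


def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    T = np.eye(4)
    T[:3, :3] = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return T


def _translate(v) -> np.ndarray:
    T = np.eye(4)
    T[:3, 3] = v
    return T


@dataclass(frozen=True)
class ClipModel:
    """Two rigid blades hinged about the clip-local y axis through the origin.

    In the local frame each blade is a rectangular box extending from the
    hinge along +x (``blade_length``), spanning ``blade_width`` along y and
    ``blade_thickness`` along z; blade A sits on the +z side, blade B on the
    -z side, and their inner faces meet at z = 0 when the clip is closed.
    ``opening_angle`` rotates the blades by +/- half the angle about the
    hinge; ``pose`` (4x4 rigid transform) places the clip in world space.
    """

    blade_length: float
    blade_width: float
    blade_thickness: float
    opening_angle: float  # degrees
    pose: np.ndarray = field(default_factory=lambda: np.eye(4))
    # optional custom blade solids in the clip-local, closed (angle 0) frame;
    # when None, parametric boxes from the dimensions above are used
    _local_blades: tuple[ConvexSolid, ConvexSolid] | None = None

    def __post_init__(self) -> None:
        pose = np.asarray(self.pose, dtype=np.float64)
        if pose.shape != (4, 4):
            raise ValueError("pose must be a 4x4 homogeneous transform")
        R = pose[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-9 or not np.allclose(
            R @ R.T, np.eye(3), atol=1e-9
        ):
            raise ValueError("pose rotation must be orthonormal with det +1")
        if self.opening_angle < 0:
            raise ValueError("opening_angle must be non-negative")
        object.__setattr__(self, "pose", pose)

    @property
    def hinge_axis(self) -> np.ndarray:
        """World-space hinge direction (clip-local y)."""
        return self.pose[:3, 1].copy()

    def _blade_transforms(self) -> tuple[np.ndarray, np.ndarray]:
        half = np.deg2rad(self.opening_angle) / 2.0
        # blade A (+z side) swings towards +z => rotate by -half about y
        return self.pose @ _rot_y(-half), self.pose @ _rot_y(+half)

    def blade_solids(self) -> tuple[ConvexSolid, ConvexSolid]:
        """World-space convex blade solids at the current pose and angle."""
        Ta, Tb = self._blade_transforms()
        if self._local_blades is not None:
            return self._local_blades[0].transformed(Ta), self._local_blades[1].transformed(Tb)
        L, w, th = self.blade_length, self.blade_width, self.blade_thickness
        half = np.array([L / 2, w / 2, th / 2])
        ca = _translate([L / 2, 0.0, th / 2])
        cb = _translate([L / 2, 0.0, -th / 2])
        return box_solid(Ta @ ca, half), box_solid(Tb @ cb, half)

    def blade_meshes(self) -> tuple[TriangleMesh, TriangleMesh]:
        """World-space triangle meshes of the two blades (closed boxes)."""
        a, b = self.blade_solids()
        return (
            TriangleMesh(a.vertices, a.faces).validate(),
            TriangleMesh(b.vertices, b.faces).validate(),
        )

    @classmethod
    def from_blade_meshes(
        cls, blade_a: TriangleMesh, blade_b: TriangleMesh, hinge_frame: np.ndarray | None = None
    ) -> "ClipModel":
        """Build a clip from two imported blade meshes.

        Non-convex blades are replaced by their convex hulls so that
        containment and first-crossing queries stay exact; a notice is
        logged when that happens.
        """
        solids = []
        for name, m in (("blade_a", blade_a), ("blade_b", blade_b)):
            hull = ConvexSolid.from_points(m.vertices)
            if len(hull.vertices) != m.n_vertices:
                logger.info("%s is non-convex; using its convex hull", name)
            solids.append(hull)
        ext = blade_a.vertices.max(axis=0) - blade_a.vertices.min(axis=0)
        pose = np.eye(4) if hinge_frame is None else np.asarray(hinge_frame, float)
        return cls(
            blade_length=float(ext[0]),
            blade_width=float(ext[1]),
            blade_thickness=float(ext[2]),
            opening_angle=0.0,
            pose=pose,
            _local_blades=(solids[0], solids[1]),
        )


def make_clip(
    blade_length: float,
    blade_width: float,
    blade_thickness: float,
    opening_angle: float,
) -> ClipModel:
    """Parametric two-blade clip with rectangular-box blades, identity pose."""
    if min(blade_length, blade_width, blade_thickness) <= 0:
        raise ValueError("blade dimensions must be positive")
    if not 0.0 <= opening_angle <= 90.0:
        raise ValueError("opening_angle must be in [0, 90] degrees")
    return ClipModel(blade_length, blade_width, blade_thickness, opening_angle)


def set_clip_state(clip: ClipModel, pose: np.ndarray, opening_angle: float) -> ClipModel:
    """Return the clip at an absolute pose and opening angle (stateless)."""
    if opening_angle < 0:
        raise ValueError("opening_angle must be non-negative")
    return replace(clip, pose=np.asarray(pose, dtype=np.float64), opening_angle=float(opening_angle))


@dataclass(frozen=True)
class CollisionResult:
    """Outcome of a motion-segment vs clip query.

    ``d_collision`` is measured from the current position along the motion
    to the first blade-surface crossing.  ``trapped`` flags a point whose
    current position is already strictly inside a blade (closing faster
    than the point can retreat); ``escape_point`` is then the nearest blade
    surface point it will be projected to.
    """

    colliding: bool
    d_collision: float
    hit_direction: np.ndarray
    trapped: bool = False
    escape_point: np.ndarray | None = None


def collision_query(x_t: np.ndarray, x_proposed: np.ndarray, clip: ClipModel) -> CollisionResult:
    """Does the motion x_t -> x_proposed contact a blade, and how far in?"""
    x_t = np.asarray(x_t, dtype=np.float64)
    x_p = np.asarray(x_proposed, dtype=np.float64)
    hit, d, trapped, esc = _query_arrays(x_t[None], x_p[None], clip)
    motion = x_p - x_t
    norm = np.linalg.norm(motion)
    direction = motion / norm if norm > 1e-15 else np.zeros(3)
    return CollisionResult(
        colliding=bool(hit[0]),
        d_collision=float(d[0]) if hit[0] else float("nan"),
        hit_direction=direction,
        trapped=bool(trapped[0]),
        escape_point=esc[0] if trapped[0] else None,
    )


def _query_arrays(x_t: np.ndarray, x_p: np.ndarray, clip: ClipModel):
    """Vectorised collision query. Returns (hit, d_collision, trapped, escape)."""
    blades = clip.blade_solids()
    n = len(x_t)
    seg_len = np.linalg.norm(x_p - x_t, axis=1)

    trapped = np.zeros(n, dtype=bool)
    escape = np.zeros_like(x_t)
    t_first = np.full(n, np.inf)
    hit_any = np.zeros(n, dtype=bool)
    for solid in blades:
        inside = solid.depth(x_t) > -_STRICT_INSIDE_TOL  # strictly inside
        if inside.any():
            pts, _ = solid.surface_closest(x_t[inside])
            # nudge outward so the escaped point is not re-captured
            away = pts - x_t[inside]
            nrm = np.linalg.norm(away, axis=1, keepdims=True)
            nudge = np.where(nrm > 1e-12, away / np.where(nrm == 0, 1, nrm), 0.0)
            escape[inside] = pts + 1e-9 * nudge
            trapped |= inside
        hit, t = solid.segment_entry(x_t, x_p)
        hit_any |= hit
        t_first = np.where(hit, np.minimum(t_first, np.where(np.isnan(t), np.inf, t)), t_first)

    hit_any |= trapped
    d = np.where(np.isfinite(t_first), t_first, 0.0) * seg_len
    d = np.where(trapped, 0.0, d)
    return hit_any, d, trapped, escape


def collision_query_batch(x_t: np.ndarray, x_p: np.ndarray, clip: ClipModel):
    """Array form of :func:`collision_query` for the simulation driver."""
    return _query_arrays(np.atleast_2d(x_t), np.atleast_2d(x_p), clip)


def resolve_collision(
    x_t: np.ndarray,
    x_proposed: np.ndarray,
    result: CollisionResult,
    slack: float = DEFAULT_COLLISION_SLACK,
) -> np.ndarray:
    """Adapted next position: stop ``slack * d_collision`` along the motion.

    Without a collision the integrated position passes through unchanged;
    a trapped point is projected to the nearest blade surface.
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    x_p = np.asarray(x_proposed, dtype=np.float64)
    if result.trapped:
        return result.escape_point if result.escape_point is not None else x_t
    if not result.colliding:
        return x_p.copy()
    return x_t + result.hit_direction * (slack * result.d_collision)


def resolve_collision_batch(
    x_t: np.ndarray,
    x_p: np.ndarray,
    clip: ClipModel,
    slack: float = DEFAULT_COLLISION_SLACK,
):
    """Vectorised query + resolve. Returns (adapted, hit, trapped)."""
    x_t = np.atleast_2d(x_t)
    x_p = np.atleast_2d(x_p)
    hit, d, trapped, escape = _query_arrays(x_t, x_p, clip)
    motion = x_p - x_t
    seg_len = np.linalg.norm(motion, axis=1, keepdims=True)
    direction = np.where(seg_len > 1e-15, motion / np.where(seg_len == 0, 1, seg_len), 0.0)
    adapted = x_p.copy()
    stop = hit & ~trapped
    adapted[stop] = x_t[stop] + direction[stop] * (slack * d[stop, None])
    adapted[trapped] = escape[trapped]
    return adapted, hit, trapped


def project_outside(points: np.ndarray, clip: ClipModel, eps: float = 1e-9) -> np.ndarray:
    """Move any point inside a blade to its nearest blade-surface point.

    The returned points sit ``eps`` outside the surface along the escape
    direction; points already outside are untouched.  This is the
    nearest-point projection used by the post-compensation collision
    re-check and for trapped particles.
    """
    pts = np.atleast_2d(points).copy()
    for solid in clip.blade_solids():
        inside = solid.depth(pts) > 0
        if inside.any():
            surf, _ = solid.surface_closest(pts[inside])
            out = surf - pts[inside]
            nrm = np.linalg.norm(out, axis=1, keepdims=True)
            pts[inside] = surf + eps * np.where(
                nrm > 1e-15, out / np.where(nrm == 0, 1.0, nrm), 0.0
            )
    return pts


def point_clip_distance(p: np.ndarray, clip: ClipModel) -> float | np.ndarray:
    """Minimum Euclidean distance from point(s) to the blade surfaces.

    Zero for a point on or inside a blade.  Accepts a single point or an
    (n, 3) array and returns a scalar or (n,) array accordingly.
    """
    pts = np.atleast_2d(np.asarray(p, dtype=np.float64))
    a, b = clip.blade_solids()
    d = np.minimum(a.distance(pts), b.distance(pts))
    return float(d[0]) if np.asarray(p).ndim == 1 else d


def clip_surface_closest(p: np.ndarray, clip: ClipModel) -> tuple[np.ndarray, np.ndarray]:
    """Closest blade-surface point(s) and surface distance(s) for point(s)."""
    pts = np.atleast_2d(np.asarray(p, dtype=np.float64))
    a, b = clip.blade_solids()
    ca, da = a.surface_closest(pts)
    cb, db = b.surface_closest(pts)
    use_b = db < da
    closest = np.where(use_b[:, None], cb, ca)
    dist = np.where(use_b, db, da)
    return closest, dist
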