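"""Distance and force visualisation data products.

On a flat screen, judging how close the clip is to the vessel wall — and how
hard the closed clip deforms it — is difficult.  These routines compute the
data behind the supporting visualisations as plain geometry and per-vertex
arrays, leaving rendering to an external viewer:

* distance products: a per-vertex clip-distance colour map, the single
  smallest-distance segment (drawn as a cylinder by the renderer), and
  semi-transparent rays for all distances under a threshold;
* force products: the per-vertex displacement field (initial to current
  position, the available proxy for the applied force), rays from initial to
  current positions, and oriented arrow/drop glyphs;
* the diverging colour scales those products share (green-to-red, plus a
  red-to-blue alternative for dyschromatopsia).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .clip import ClipModel, clip_surface_closest, point_clip_distance
from .driver import SimulationState
from .geometry import TriangleMesh

__all__ = [
    "ScalarField",
    "VectorField",
    "RaySet",
    "GlyphSet",
    "ColourScale",
    "distance_field",
    "min_distance_segment",
    "distance_rays",
    "displacement_field",
    "displacement_rays",
    "make_glyphs",
    "map_colour",
]

_DISPLACED_TOL = 1e-9
_GLYPH_ALPHA_FLOOR = 0.2  # faintest glyph; alpha rises linearly to 1


@dataclass(frozen=True)
class ScalarField:
    """One non-negative scalar per mesh vertex (distance or |displacement|)."""

    mesh: TriangleMesh
    values: np.ndarray
    kind: Literal["distance", "displacement_magnitude"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if len(v) != self.mesh.n_vertices:
            raise ValueError("one value per vertex required")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("values must be finite and non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class VectorField:
    """One 3-D vector per mesh vertex (the displacement field)."""

    mesh: TriangleMesh
    vectors: np.ndarray
    anchors: np.ndarray | None = None  # ray start points (initial positions)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.shape != (self.mesh.n_vertices, 3):
            raise ValueError("one 3-D vector per vertex required")
        if not np.isfinite(v).all():
            raise ValueError("vectors must be finite")
        object.__setattr__(self, "vectors", v)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass(frozen=True)
class RaySet:
    """Line segments with a scalar and an opacity, for semi-transparent rays."""

    starts: np.ndarray  # (n, 3)
    ends: np.ndarray  # (n, 3)
    values: np.ndarray  # (n,)
    alphas: np.ndarray  # (n,) in [0, 1]

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.ends) == len(self.values) == len(self.alphas) == n):
            raise ValueError("ray arrays must have equal length")
        if n and ((self.alphas < 0).any() or (self.alphas > 1).any()):
            raise ValueError("alpha must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class GlyphSet:
    """Oriented per-vertex glyphs (arrow or drop) as renderable records."""

    anchors: np.ndarray  # (n, 3)
    orientations: np.ndarray  # (n, 3) unit vectors
    colours: np.ndarray  # (n, 3) RGB in [0, 1]
    axial_scales: np.ndarray  # (n,)
    alphas: np.ndarray  # (n,) in [0, 1]
    glyph_kind: Literal["arrow", "drop"] = "arrow"

    def __post_init__(self) -> None:
        if len(self.orientations):
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.abs(norms - 1.0).max() > 1e-9:
                raise ValueError("orientations must be unit vectors")
        if len(self.alphas) and ((self.alphas < 0).any() or (self.alphas > 1).any()):
            raise ValueError("alpha must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class ColourScale:
    """Diverging scale banding values into low / mid / high.

    ``critical_end`` names the end of the domain rendered pure red: "low"
    for clip distances (small gap = danger), "high" for displacement
    magnitudes (large deformation = danger).  The safe end is green for the
    green_red scale and blue for the red_blue (dyschromatopsia-friendly)
    scale; the midpoint is the neutral hinge (yellow resp. white).
    """

    kind: Literal["green_red", "red_blue"]
    v_min: float
    v_max: float
    critical_end: Literal["low", "high"] = "low"

    def __post_init__(self) -> None:
        if not self.v_min < self.v_max:
            raise ValueError("v_min must be strictly less than v_max")

    @classmethod
    def for_field(cls, values: np.ndarray, kind: str = "green_red",
                  critical_end: str = "low", percentile: float = 95.0) -> "ColourScale":
        """Default domain [0, given percentile of the field] (outlier-robust)."""
        hi = float(np.percentile(values, percentile))
        if hi <= 0:
            hi = max(float(np.max(values)), 1e-9)
        return cls(kind, 0.0, hi, critical_end)  # type: ignore[arg-type]


_END_COLOURS = {
    "green_red": (np.array([1.0, 0.0, 0.0]), np.array([1.0, 1.0, 0.0]),
                  np.array([0.0, 1.0, 0.0])),
    "red_blue": (np.array([1.0, 0.0, 0.0]), np.array([1.0, 1.0, 1.0]),
                 np.array([0.0, 0.0, 1.0])),
}


def map_colour(value, scale: ColourScale) -> np.ndarray:
    """Piecewise-linear diverging colour for scalar value(s).

    Critical end -> red, domain midpoint -> neutral hinge, safe end -> green
    (or blue); values outside the domain clamp to the end colours.  Accepts
    a scalar (returns shape (3,)) or an array (returns (n, 3)).
    """
    critical, hinge, safe = _END_COLOURS[scale.kind]
    v = np.asarray(value, dtype=np.float64)
    scalar_in = v.ndim == 0
    t = (np.atleast_1d(v) - scale.v_min) / (scale.v_max - scale.v_min)
    if scale.critical_end == "high":
        t = 1.0 - t
    t = np.clip(t, 0.0, 1.0)  # t = 0 at the critical end
    lo = t[:, None] * 2.0  # within [critical, hinge]
    hi = (t[:, None] - 0.5) * 2.0  # within [hinge, safe]
    rgb = np.where(
        t[:, None] <= 0.5,
        critical + lo * (hinge - critical),
        hinge + hi * (safe - hinge),
    )
    return rgb[0] if scalar_in else rgb


# ---------------------------------------------------------------------------
# distance products
# ---------------------------------------------------------------------------


def distance_field(mesh: TriangleMesh, clip: ClipModel) -> ScalarField:
    """Per-vertex distance from the vessel surface to the clip blades."""
    d = point_clip_distance(mesh.vertices, clip)
    return ScalarField(mesh, d, "distance")


def min_distance_segment(mesh: TriangleMesh, clip: ClipModel):
    """The single smallest vertex-to-clip distance as a segment.

    Returns (vertex point, closest clip point, distance).  Ties resolve to
    the lowest vertex index.
    """
    fieldv = distance_field(mesh, clip).values
    v = int(np.argmin(fieldv))  # argmin takes the first == lowest index
    closest, _ = clip_surface_closest(mesh.vertices[v], clip)
    return mesh.vertices[v].copy(), closest[0], float(fieldv[v])


def distance_rays(mesh: TriangleMesh, clip: ClipModel, threshold: float) -> RaySet:
    """Semi-transparent rays for every vertex closer than ``threshold``.

    Rays run from the vertex to its closest blade-surface point; opacity
    falls linearly from 1 at contact to 0 at the threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    d = point_clip_distance(mesh.vertices, clip)
    sel = d < threshold
    starts = mesh.vertices[sel]
    closest, _ = clip_surface_closest(starts, clip) if sel.any() else (np.zeros((0, 3)),) * 2
    with np.errstate(invalid="ignore"):
        alphas = 1.0 - d[sel] / threshold if np.isfinite(threshold) else np.ones(sel.sum())
    return RaySet(starts, closest, d[sel], np.clip(alphas, 0.0, 1.0))


# ---------------------------------------------------------------------------
# force (displacement) products
# ---------------------------------------------------------------------------


def displacement_field(state: SimulationState) -> VectorField:
    """Vector from each vertex's initial position to its current position.

    This is the simulation's proxy for the force the clip applies to the
    wall: direction and magnitude of the accumulated displacement.
    """
    mesh = TriangleMesh(state.initial_positions.copy(), np.zeros((0, 3), dtype=np.int64))
    return VectorField(mesh, state.positions - state.initial_positions,
                       anchors=state.initial_positions.copy())


def displacement_rays(field: VectorField) -> RaySet:
    """One ray per displaced vertex, initial -> current position.

    Length encodes magnitude; opacity rises linearly with magnitude up to
    the field maximum.  Vertices displaced less than 1e-9 mm are omitted.
    """
    mags = field.magnitudes()
    sel = mags > _DISPLACED_TOL
    starts = field.anchors[sel] if field.anchors is not None else field.mesh.vertices[sel]
    ends = starts + field.vectors[sel]
    top = mags.max() if sel.any() else 1.0
    return RaySet(starts, ends, mags[sel], np.clip(mags[sel] / top, 0.0, 1.0))


def make_glyphs(
    field: VectorField,
    kind: Literal["arrow", "drop"],
    scale_clamp: tuple[float, float],
    colour_scale: ColourScale,
) -> GlyphSet:
    """Oriented glyphs encoding the displacement field per vertex.

    Orientation is the normalised displacement and colour its magnitude on
    the given scale.  Drop glyphs additionally stretch along their axis —
    the magnitude is mapped linearly from the colour-scale domain into the
    clamp range ``[s_min, s_max]`` and clamped, so extreme displacements
    cannot occlude everything else; arrows keep the fixed size ``s_min``.
    Opacity rises linearly with magnitude (floor 0.2), in [0, 1].  Vertices
    with zero displacement carry no orientation and are skipped.
    """
    s_min, s_max = scale_clamp
    if s_min > s_max:
        raise ValueError("scale clamp must satisfy s_min <= s_max")
    mags = field.magnitudes()
    sel = mags > _DISPLACED_TOL
    m = mags[sel]
    anchors = field.anchors[sel] if field.anchors is not None else field.mesh.vertices[sel]
    orient = field.vectors[sel] / m[:, None]
    colours = map_colour(m, colour_scale)

    t = np.clip((m - colour_scale.v_min) / (colour_scale.v_max - colour_scale.v_min), 0.0, 1.0)
    if kind == "drop":
        scales = s_min + t * (s_max - s_min)
    elif kind == "arrow":
        scales = np.full(len(m), float(s_min))
    else:
        raise ValueError(f"unknown glyph kind {kind!r}")
    alphas = _GLYPH_ALPHA_FLOOR + (1.0 - _GLYPH_ALPHA_FLOOR) * t
    return GlyphSet(anchors, orient, colours, scales, alphas, glyph_kind=kind)
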