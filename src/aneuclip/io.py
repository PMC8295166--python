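"""File formats, configuration and run manifests.

Meshes travel as OBJ / PLY (ascii or binary) / STL through trimesh; the
visualisation products are exported as legacy-ASCII VTK polydata so runs can
be inspected in any standard viewer and diffed in tests.  The simulation
configuration is a flat key-value text file; the clip motion is a plain-text
table; every run ends with a JSON manifest from which it can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np

from .driver import SimulationConfig
from .geometry import MeshValidationError, TriangleMesh

__all__ = [
    "MeshLoadError",
    "ConfigError",
    "read_mesh",
    "write_mesh",
    "load_config",
    "save_config",
    "read_clip_schedule",
    "write_clip_schedule",
    "save_snapshot",
    "load_snapshot",
    "write_manifest",
    "write_polydata_mesh",
    "write_polydata_lines",
    "write_polydata_glyphs",
]

logger = logging.getLogger(__name__)

_MESH_FORMATS = {".obj": "obj", ".ply": "ply", ".stl": "stl"}
_WELD_TOL = 1e-6  # mm; STL stores every triangle's corners separately


class MeshLoadError(RuntimeError):
    """A mesh file could not be parsed or failed validation."""


class ConfigError(ValueError):
    """A configuration file contained an unknown key or a bad value."""


def _format_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _MESH_FORMATS.values():
            raise MeshLoadError(f"unknown mesh format {fmt!r}")
        return fmt
    try:
        return _MESH_FORMATS[path.suffix.lower()]
    except KeyError:
        raise MeshLoadError(f"cannot infer mesh format from suffix {path.suffix!r}") from None


def read_mesh(path: str | os.PathLike, fmt: str | None = None) -> TriangleMesh:
    """Load and validate a triangle mesh (OBJ, PLY ascii/binary, or STL).

    STL duplicates vertices per triangle; coincident vertices are welded
    (tolerance 1e-6 mm) so the spring topology is connected.  The returned
    mesh has passed the structural validator; a failure names the first
    violated invariant.
    """
    import trimesh

    path = Path(path)
    fmt = _format_for(path, fmt)
    if not path.exists():
        raise MeshLoadError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - loader failures become one class
        raise MeshLoadError(
            f"cannot parse {path} as {fmt} (size {path.stat().st_size} bytes): {exc}"
        ) from exc
    if tm.vertices.size == 0 or tm.faces.size == 0:
        raise MeshLoadError(f"{path}: no triangles parsed (truncated or empty file?)")
    if fmt == "stl":
        tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    mesh = TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    try:
        mesh.validate()
    except MeshValidationError as exc:
        raise MeshLoadError(f"{path}: {exc}") from exc
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | os.PathLike,
               fmt: str | None = None, binary: bool = False) -> Path:
    """Write a mesh as OBJ, PLY (ascii unless ``binary``) or STL (ascii)."""
    path = Path(path)
    fmt = _format_for(path, fmt)
    tm = mesh.to_trimesh()
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="binary" if binary else "ascii")
    elif fmt == "stl":
        data = tm.export(file_type="stl" if binary else "stl_ascii")
    else:
        data = tm.export(file_type="obj")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


# ---------------------------------------------------------------------------
# flat key-value configuration
# ---------------------------------------------------------------------------


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Parse a flat ``key = value`` text file into a SimulationConfig.

    Unknown keys are rejected; missing keys take the documented defaults;
    the fully-resolved configuration is echoed to the log.
    """
    valid = set(SimulationConfig.model_fields)
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in stripped.split("=", 1))
        if key not in valid:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        raw[key] = value
    try:
        config = SimulationConfig(**raw)
    except Exception as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    logger.info("resolved configuration: %s", config.model_dump())
    return config


def save_config(config: SimulationConfig, path: str | os.PathLike) -> Path:
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in config.model_dump().items()]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# clip schedule: step, quaternion (w x y z), translation (x y z), angle
# ---------------------------------------------------------------------------


def read_clip_schedule(path: str | os.PathLike) -> list[tuple[np.ndarray, float]]:
    """Plain-text clip motion table -> list of (pose 4x4, opening angle).

    Each row: ``step qw qx qy qz tx ty tz angle`` (whitespace-separated,
    ``#`` comments).  Rows must be sorted by step and contiguous from 0.
    """
    from scipy.spatial.transform import Rotation

    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 9:
            raise ConfigError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
        step = int(parts[0])
        qw, qx, qy, qz, tx, ty, tz, angle = map(float, parts[1:])
        if step != len(entries):
            raise ConfigError(f"{path}:{lineno}: steps must be contiguous from 0")
        pose = np.eye(4)
        pose[:3, :3] = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
        pose[:3, 3] = (tx, ty, tz)
        entries.append((pose, angle))
    return entries


def write_clip_schedule(schedule, path: str | os.PathLike) -> Path:
    from scipy.spatial.transform import Rotation

    lines = ["# step qw qx qy qz tx ty tz opening_angle_deg"]
    for k, (pose, angle) in enumerate(schedule):
        qx, qy, qz, qw = Rotation.from_matrix(pose[:3, :3]).as_quat()
        t = pose[:3, 3]
        lines.append(
            f"{k} {qw:.17g} {qx:.17g} {qy:.17g} {qz:.17g} "
            f"{t[0]:.17g} {t[1]:.17g} {t[2]:.17g} {angle:.17g}"
        )
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# system state snapshots: mesh file + JSON sidecar
# ---------------------------------------------------------------------------


def save_snapshot(mesh: TriangleMesh, system, state, path_prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Persist a simulation state as <prefix>.obj + <prefix>.state.json.

    The mesh carries the current positions; the sidecar holds previous and
    initial positions, anchor flags and the spring parameters, so a run can
    resume exactly.
    """
    prefix = Path(path_prefix)
    mesh_path = prefix.with_suffix(".obj")
    write_mesh(TriangleMesh(state.positions, mesh.faces), mesh_path)
    sidecar = {
        "step_index": state.step_index,
        "prev_positions": state.prev_positions.tolist(),
        "initial_positions": state.initial_positions.tolist(),
        "anchored": system.anchored.astype(int).tolist(),
        "edges": system.edges.tolist(),
        "stiffness": system.stiffness.tolist(),
        "rest_lengths": system.rest_lengths.tolist(),
        "masses": system.masses.tolist(),
        "k_d": system.k_d,
        "dt": system.dt,
    }
    side_path = prefix.parent / (prefix.name + ".state.json")
    side_path.write_text(json.dumps(sidecar))
    return mesh_path, side_path


def load_snapshot(path_prefix: str | os.PathLike):
    """Inverse of :func:`save_snapshot`; returns (mesh, system, state)."""
    from .driver import SimulationState
    from .massspring import MassSpringSystem

    prefix = Path(path_prefix)
    mesh = read_mesh(prefix.with_suffix(".obj"))
    side = json.loads((prefix.parent / (prefix.name + ".state.json")).read_text())
    system = MassSpringSystem(
        positions=mesh.vertices.copy(),
        prev_positions=np.asarray(side["prev_positions"], float),
        masses=np.asarray(side["masses"], float),
        anchored=np.asarray(side["anchored"], int).astype(bool),
        edges=np.asarray(side["edges"], np.int64),
        stiffness=np.asarray(side["stiffness"], float),
        rest_lengths=np.asarray(side["rest_lengths"], float),
        k_d=float(side["k_d"]),
        dt=float(side["dt"]),
    )
    state = SimulationState(
        step_index=int(side["step_index"]),
        positions=mesh.vertices.copy(),
        prev_positions=np.asarray(side["prev_positions"], float),
        clip=None,
        initial_positions=np.asarray(side["initial_positions"], float),
    )
    return mesh, system, state


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | os.PathLike, config: SimulationConfig,
                   inputs: list[str | os.PathLike], stats: dict) -> Path:
    """Write the run manifest atomically (tmp file + rename)."""
    from . import __version__

    manifest = {
        "package": "aneuclip",
        "version": __version__,
        "config": config.model_dump(),
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in inputs
        ],
        "stats": stats,
    }
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, path)
    return path


# ---------------------------------------------------------------------------
# legacy-ASCII VTK polydata export
# ---------------------------------------------------------------------------


def _vtk_header(fh, title: str, n_points: int, points: np.ndarray) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET POLYDATA\n")
    fh.write(f"POINTS {n_points} float\n")
    for p in points:
        fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")


def _vtk_point_data(fh, n: int, scalars: dict[str, np.ndarray] | None,
                    vectors: dict[str, np.ndarray] | None,
                    colours: np.ndarray | None) -> None:
    if not (scalars or vectors or colours is not None):
        return
    fh.write(f"POINT_DATA {n}\n")
    for name, vals in (scalars or {}).items():
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.9g}" for v in vals) + "\n")
    for name, vecs in (vectors or {}).items():
        fh.write(f"VECTORS {name} float\n")
        for v in vecs:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    if colours is not None:
        fh.write("COLOR_SCALARS rgb 3\n")
        for c in colours:
            fh.write(f"{c[0]:.6g} {c[1]:.6g} {c[2]:.6g}\n")


def write_polydata_mesh(path, mesh: TriangleMesh, scalars=None, vectors=None,
                        colours=None, title: str = "vessel surface") -> Path:
    """Mesh + per-vertex arrays as legacy-ASCII VTK polydata."""
    path = Path(path)
    with open(path, "w") as fh:
        _vtk_header(fh, title, mesh.n_vertices, mesh.vertices)
        m = mesh.n_faces
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        _vtk_point_data(fh, mesh.n_vertices, scalars, vectors, colours)
    return path


def write_polydata_lines(path, rays, title: str = "rays") -> Path:
    """A RaySet as VTK line polydata with value and alpha point arrays."""
    path = Path(path)
    n = len(rays)
    points = np.empty((2 * n, 3))
    points[0::2] = rays.starts
    points[1::2] = rays.ends
    with open(path, "w") as fh:
        _vtk_header(fh, title, 2 * n, points)
        fh.write(f"LINES {n} {3 * n}\n")
        for k in range(n):
            fh.write(f"2 {2 * k} {2 * k + 1}\n")
        scal = {
            "value": np.repeat(rays.values, 2),
            "alpha": np.repeat(rays.alphas, 2),
        }
        _vtk_point_data(fh, 2 * n, scal, None, None)
    return path


def write_polydata_glyphs(path, glyphs, title: str = "glyphs") -> Path:
    """A GlyphSet as VTK point polydata with orientation/scale/colour/alpha."""
    path = Path(path)
    n = len(glyphs)
    with open(path, "w") as fh:
        _vtk_header(fh, f"{title} ({glyphs.glyph_kind})", n, glyphs.anchors)
        fh.write(f"VERTICES {n} {2 * n}\n")
        for k in range(n):
            fh.write(f"1 {k}\n")
        _vtk_point_data(
            fh, n,
            {"axial_scale": glyphs.axial_scales, "alpha": glyphs.alphas},
            {"orientation": glyphs.orientations},
            glyphs.colours,
        )
    return path
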