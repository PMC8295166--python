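"""Mass-spring deformation core.

Mesh vertices are point masses joined by Hookean springs along the mesh
edges; time integration is position-based Verlet with a damping factor on
the velocity term.  A stretch-compensation pass caps edge elongation to
counter the error a large time step introduces.

Forces follow Hooke's law along each spring,

    f_ij = k_s * (x_j - x_i)/|x_j - x_i| * (|x_j - x_i| - l0_ij),

applied equally and oppositely to both endpoints, and positions advance by

    x(t+dt) = x(t) + (x(t) - x(t-dt)) * (1 - k_d) + f(t)/m * dt^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np

from .geometry import TriangleMesh, mesh_edges

__all__ = [
    "Particle",
    "Spring",
    "MassSpringSystem",
    "build_system",
    "spring_force",
    "verlet_step",
    "accumulate_forces",
    "verlet_propose",
    "stretch_compensate",
]

logger = logging.getLogger(__name__)

_COINCIDENT_TOL = 1e-12


@dataclass(frozen=True)
class Particle:
    """A mesh vertex acting as a point mass."""

    index: int
    m: float
    x_t: np.ndarray
    x_prev: np.ndarray
    anchored: bool = False

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("particle mass must be positive")


@dataclass(frozen=True)
class Spring:
    """A Hookean spring between particles i and j with rest length l0."""

    i: int
    j: int
    k_s: float
    l0: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("spring endpoints must differ")
        if self.k_s <= 0 or self.l0 <= 0:
            raise ValueError("k_s and l0 must be positive")


@dataclass
class MassSpringSystem:
    """Particles + springs in array form (one row per particle / spring).

    ``positions``/``prev_positions`` are the current and previous vertex
    positions (mm); ``edges`` holds the spring endpoint indices; ``l0`` the
    rest lengths taken from the undeformed mesh.
    """

    positions: np.ndarray  # (n, 3)
    prev_positions: np.ndarray  # (n, 3)
    masses: np.ndarray  # (n,)
    anchored: np.ndarray  # (n,) bool
    edges: np.ndarray  # (e, 2) int
    stiffness: np.ndarray  # (e,)
    rest_lengths: np.ndarray  # (e,)
    k_d: float
    dt: float

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not 0.0 <= self.k_d <= 1.0:
            raise ValueError("k_d must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if (self.masses <= 0).any():
            raise ValueError("all masses must be positive")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("spring endpoint outside particle range")
        if (self.edges[:, 0] == self.edges[:, 1]).any():
            raise ValueError("spring endpoints must differ")
        if (self.rest_lengths <= 0).any():
            raise ValueError("rest lengths must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_springs(self) -> int:
        return len(self.edges)

    def particle(self, i: int) -> Particle:
        return Particle(i, float(self.masses[i]), self.positions[i].copy(),
                        self.prev_positions[i].copy(), bool(self.anchored[i]))

    def spring(self, e: int) -> Spring:
        i, j = self.edges[e]
        return Spring(int(i), int(j), float(self.stiffness[e]), float(self.rest_lengths[e]))

    def copy(self) -> "MassSpringSystem":
        return MassSpringSystem(
            self.positions.copy(), self.prev_positions.copy(), self.masses.copy(),
            self.anchored.copy(), self.edges.copy(), self.stiffness.copy(),
            self.rest_lengths.copy(), self.k_d, self.dt,
        )


def build_system(
    mesh: TriangleMesh,
    k_s: float = 50.0,
    k_d: float = 0.05,
    mass_per_vertex: float = 1.0,
    anchored: np.ndarray | set | None = None,
    dt: float = 0.02,
) -> MassSpringSystem:
    """Mass-spring system over a mesh: one spring per unique edge.

    Rest lengths are the initial edge lengths, so the undeformed mesh is an
    exact equilibrium; the system starts at rest (previous position equal to
    the current one).  ``anchored`` vertex ids are held fixed forever.
    """
    edges = mesh_edges(mesh)
    pos = mesh.vertices.copy()
    l0 = np.linalg.norm(pos[edges[:, 1]] - pos[edges[:, 0]], axis=1)
    if (l0 <= 0).any():
        raise ValueError("mesh contains a zero-length edge")
    anch = np.zeros(len(pos), dtype=bool)
    if anchored is not None:
        idx = np.asarray(sorted(anchored) if isinstance(anchored, set) else anchored, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(pos)):
            raise ValueError("anchored vertex id outside vertex range")
        anch[idx] = True
    return MassSpringSystem(
        positions=pos,
        prev_positions=pos.copy(),
        masses=np.full(len(pos), float(mass_per_vertex)),
        anchored=anch,
        edges=edges,
        stiffness=np.full(len(edges), float(k_s)),
        rest_lengths=l0,
        k_d=float(k_d),
        dt=float(dt),
    )


def spring_force(spring: Spring, x_i: np.ndarray, x_j: np.ndarray):
    """Hooke force pair (on i, on j) for one spring.

    Coincident endpoints leave the direction undefined; the force is then
    zero and a warning is logged.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    d = x_j - x_i
    length = np.linalg.norm(d)
    if length < _COINCIDENT_TOL:
        logger.warning("spring (%d, %d) endpoints coincide; force set to zero",
                       spring.i, spring.j)
        return np.zeros(3), np.zeros(3)
    f_i = spring.k_s * (d / length) * (length - spring.l0)
    return f_i, -f_i


def accumulate_forces(system: MassSpringSystem, positions: np.ndarray) -> np.ndarray:
    """Total spring force on every particle (vectorised over springs)."""
    i, j = system.edges[:, 0], system.edges[:, 1]
    d = positions[j] - positions[i]
    length = np.linalg.norm(d, axis=1)
    safe = length >= _COINCIDENT_TOL
    if not safe.all():
        logger.warning("%d spring(s) with coincident endpoints; forces zeroed",
                       int((~safe).sum()))
    scale = np.where(safe, system.stiffness * (length - system.rest_lengths)
                     / np.where(length == 0, 1.0, length), 0.0)
    f_edge = d * scale[:, None]
    forces = np.zeros_like(positions)
    np.add.at(forces, i, f_edge)
    np.add.at(forces, j, -f_edge)
    return forces


def verlet_step(p: Particle, f: np.ndarray, k_d: float, dt: float) -> np.ndarray:
    """Proposed next position of one free particle (pure function)."""
    f = np.asarray(f, dtype=np.float64)
    return p.x_t + (p.x_t - p.x_prev) * (1.0 - k_d) + (f / p.m) * dt * dt


def verlet_propose(system: MassSpringSystem, forces: np.ndarray) -> np.ndarray:
    """Verlet proposal for all particles; anchored rows stay put."""
    x, xp = system.positions, system.prev_positions
    prop = x + (x - xp) * (1.0 - system.k_d) + (forces / system.masses[:, None]) * system.dt ** 2
    prop[system.anchored] = x[system.anchored]
    return prop


def stretch_compensate(
    system: MassSpringSystem,
    positions: np.ndarray,
    tau: float = 0.1,
    max_iterations: int = 20,
) -> np.ndarray:
    """Cap every spring at (1 + tau) times its rest length.

    Iterative pairwise edge projection: each over-stretched spring pulls its
    free endpoints symmetrically along the spring axis back to the cap (the
    free endpoint takes the full correction when the other is anchored).
    Sweeps repeat until the cap holds everywhere or the iteration limit is
    reached, in which case the worst residual ratio is logged and the best
    effort returned.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    pos = positions.copy()
    i, j = system.edges[:, 0], system.edges[:, 1]
    cap = (1.0 + tau) * system.rest_lengths
    free_i = ~system.anchored[i]
    free_j = ~system.anchored[j]
    movable = free_i | free_j

    _projection_sweeps(pos, system.edges, cap, free_i, free_j, max_iterations)

    length = np.linalg.norm(pos[j] - pos[i], axis=1)
    resid = (length / cap)[movable]
    if resid.size and resid.max() > 1.0 + 1e-9:
        logger.warning("stretch compensation did not converge; worst ratio %.6f",
                       float(resid.max()))
    return pos


@numba.njit(cache=False)
def _projection_sweeps(pos, edges, cap, free_i, free_j, max_iterations):
    """Sequential edge-projection sweeps (alternating direction).

    Sequential (Gauss-Seidel) updates let a correction propagate along a
    chain of edges within one sweep; alternating the sweep direction makes
    that propagation symmetric.
    """
    m = len(edges)
    for it in range(max_iterations):
        worst = 0.0
        # The cap is an inequality, so over-relaxed projections (which land
        # strictly inside the feasible side) are admissible and speed up
        # propagation along edge chains considerably.  The first sweep is
        # unrelaxed so isolated violations resolve to the cap exactly.
        omega = 1.0 if it == 0 else 1.5
        forward = it % 2 == 0
        for idx in range(m):
            e = idx if forward else m - 1 - idx
            a, b = edges[e, 0], edges[e, 1]
            fa, fb = free_i[e], free_j[e]
            if not (fa or fb):
                continue
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            length = np.sqrt(dx * dx + dy * dy + dz * dz)
            over = length - cap[e]
            if over <= 1e-12 or length < _COINCIDENT_TOL:
                continue
            if over > worst:
                worst = over
            excess = omega * over / length
            if fa and fb:
                wa = wb = 0.5
            elif fa:
                wa, wb = 1.0, 0.0
            else:
                wa, wb = 0.0, 1.0
            pos[a, 0] += dx * excess * wa
            pos[a, 1] += dy * excess * wa
            pos[a, 2] += dz * excess * wa
            pos[b, 0] -= dx * excess * wb
            pos[b, 1] -= dy * excess * wb
            pos[b, 2] -= dz * excess * wb
        if worst <= 0.0:
            break
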