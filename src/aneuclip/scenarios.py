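"""Ready-made clipping scenarios.

The pinch scenario — a straight vessel segment squeezed shut by a closing
clip at its midpoint — is the canonical end-to-end exercise of the
deformation loop: it touches spring forces, integration, collision
adaptation, trapped-point handling and stretch compensation, and its
outcome (a pinched lumen) is easy to quantify via the cross-sectional area
at the clip plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clip import ClipModel, make_clip
from .driver import SimulationConfig, SimulationState
from .geometry import TriangleMesh, boundary_vertices, make_tube
from .massspring import MassSpringSystem, build_system

__all__ = ["PinchScenario", "pinch_tube_scenario", "clip_closing_schedule"]

# pose placing the clip beside a z-aligned tube: blade length along world x,
# blades separating along world y, hinge axis along world -z
_PINCH_POSE = np.array(
    [
        [1.0, 0.0, 0.0, -3.5],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, -1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class PinchScenario:
    mesh: TriangleMesh
    system: MassSpringSystem
    clip: ClipModel
    schedule: list
    config: SimulationConfig
    clip_plane_origin: np.ndarray
    clip_plane_normal: np.ndarray

    def initial_state(self) -> SimulationState:
        return SimulationState.initial(self.system, self.clip)


def clip_closing_schedule(
    pose: np.ndarray,
    angle_start: float,
    angle_end: float,
    n_steps: int,
) -> list[tuple[np.ndarray, float]]:
    """Fixed-pose schedule closing the clip linearly between two angles."""
    angles = np.linspace(angle_start, angle_end, n_steps)
    return [(pose.copy(), float(a)) for a in angles]


def pinch_tube_scenario(
    tube_radius: float = 1.0,
    tube_length: float = 10.0,
    n_radial: int = 16,
    n_axial: int = 24,
    angle_start: float = 45.0,
    angle_end: float = 2.0,
    n_close_steps: int = 120,
    config: SimulationConfig | None = None,
) -> PinchScenario:
    """Straight tube pinched at its midpoint by a closing two-blade clip.

    The tube runs along z with its midpoint at the origin; its open rims
    are anchored.  The clip hinge sits 4.5 tube-radii to the side so the
    blades reach across the whole cross-section, and the opening angle
    closes linearly from ``angle_start`` to ``angle_end`` over
    ``n_close_steps`` simulation steps, after which the vessel relaxes.
    """
    if config is None:
        config = SimulationConfig()
    half = tube_length / 2.0
    centerline = np.array([[0.0, 0.0, -half], [0.0, 0.0, half]])
    mesh = make_tube(centerline, tube_radius, n_radial, n_axial)
    system = build_system(
        mesh,
        k_s=config.k_s,
        k_d=config.k_d,
        mass_per_vertex=config.mass_per_vertex,
        anchored=boundary_vertices(mesh),
        dt=config.dt,
    )
    pose = _PINCH_POSE.copy()
    pose[0, 3] = -4.5 * tube_radius
    from .clip import set_clip_state

    clip = make_clip(
        blade_length=6.0 * tube_radius,
        blade_width=2.0 * tube_radius,
        blade_thickness=0.4 * tube_radius,
        opening_angle=angle_start,
    )
    clip = set_clip_state(clip, pose, angle_start)
    schedule = clip_closing_schedule(pose, angle_start, angle_end, n_close_steps)
    return PinchScenario(
        mesh=mesh,
        system=system,
        clip=clip,
        schedule=schedule,
        config=config,
        clip_plane_origin=np.zeros(3),
        clip_plane_normal=np.array([0.0, 0.0, 1.0]),
    )
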