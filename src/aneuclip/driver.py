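"""Simulation driver: one deformation iteration and full clipping runs.

Each iteration applies, in order: spring-force accumulation, Verlet
integration, collision adaptation against the clip, and the stretch-
compensation pass.  Stretch compensation can push a point back towards the
clip, so it alternates with a collision re-check for a few rounds until both
the stretch cap and non-penetration hold.  The clip itself moves
kinematically along a user-supplied schedule of (pose, opening angle); after
the schedule is exhausted the vessel relaxes until the per-step displacement
falls below the convergence tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .clip import ClipModel, project_outside, resolve_collision_batch, set_clip_state
from .massspring import (
    MassSpringSystem,
    accumulate_forces,
    stretch_compensate,
    verlet_propose,
)

__all__ = ["SimulationConfig", "SimulationState", "step", "run", "cross_section_area"]

logger = logging.getLogger(__name__)


class SimulationConfig(BaseModel):
    """Free parameters of the deformation model.

    Defaults are implementer-tuned for plausible vessel behaviour at
    millimetre scale; none are claimed as measured tissue properties.
    """

    model_config = {"extra": "forbid", "frozen": True}

    k_s: float = Field(50.0, gt=0, description="spring constant (force/mm)")
    k_d: float = Field(0.05, ge=0, le=1, description="Verlet damping factor")
    dt: float = Field(0.02, gt=0, description="time step")
    mass_per_vertex: float = Field(1.0, gt=0)
    tau: float = Field(0.1, gt=0, description="max spring stretch ratio above rest")
    collision_slack: float = Field(0.9, gt=0, le=1.0,
                                   description="fraction of d_collision travelled on contact")
    max_steps: int = Field(6000, gt=0)
    convergence_tol: float = Field(1e-5, gt=0, description="per-step displacement (mm)")
    convergence_window: int = Field(10, gt=0, description="consecutive quiet steps required")
    stretch_max_iterations: int = Field(50, gt=0)
    stretch_collision_rounds: int = Field(30, gt=0,
                                          description="stretch/collision alternation rounds")

    @model_validator(mode="after")
    def _check(self):
        return self


class SimulationDiverged(RuntimeError):
    pass


class NonFiniteState(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationState:
    """Positions at one step plus the immutable initial configuration."""

    step_index: int
    positions: np.ndarray
    prev_positions: np.ndarray
    clip: ClipModel | None
    initial_positions: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.initial_positions):
            raise ValueError("position array lengths do not match")
        ip = self.initial_positions
        ip.setflags(write=False)

    @classmethod
    def initial(cls, system: MassSpringSystem, clip: ClipModel | None = None) -> "SimulationState":
        return cls(0, system.positions.copy(), system.prev_positions.copy(),
                   clip, system.positions.copy())


def step(
    state: SimulationState,
    system: MassSpringSystem,
    clip: ClipModel | None,
    config: SimulationConfig,
) -> SimulationState:
    """One deformation iteration; returns a new state, inputs unmodified."""
    work = system.copy()
    work.positions = state.positions.copy()
    work.prev_positions = state.prev_positions.copy()

    forces = accumulate_forces(work, work.positions)
    proposed = verlet_propose(work, forces)

    free = ~work.anchored
    if clip is not None:
        adapted, _, trapped = resolve_collision_batch(
            work.positions, proposed, clip, slack=config.collision_slack
        )
        if trapped[free].any():
            logger.debug("%d trapped particle(s) projected out", int(trapped[free].sum()))
        proposed[free] = adapted[free]

    # stretch cap, alternated with a collision re-check: the stretch pass
    # may pull a point back across a blade surface, so project violators to
    # the nearest blade-surface point (which keeps the tangential part of
    # the correction) and repeat until both constraints hold
    new_pos = proposed
    edge_i, edge_j = work.edges[:, 0], work.edges[:, 1]
    cap = (1.0 + config.tau) * work.rest_lengths
    for _ in range(config.stretch_collision_rounds):
        capped = stretch_compensate(work, new_pos, tau=config.tau,
                                    max_iterations=config.stretch_max_iterations)
        capped[work.anchored] = state.positions[work.anchored]
        if clip is None:
            new_pos = capped
            break
        projected = project_outside(capped, clip)
        projected[work.anchored] = state.positions[work.anchored]
        new_pos = projected
        lengths = np.linalg.norm(new_pos[edge_j] - new_pos[edge_i], axis=1)
        if (lengths <= cap + 1e-9).all():
            break

    if not np.isfinite(new_pos).all():
        bad = int(np.argmax(~np.isfinite(new_pos).all(axis=1)))
        raise NonFiniteState(f"non-finite position for particle {bad} at step "
                             f"{state.step_index + 1}")

    return SimulationState(
        step_index=state.step_index + 1,
        positions=new_pos,
        prev_positions=state.positions.copy(),
        clip=clip,
        initial_positions=state.initial_positions,
    )


def run(
    state: SimulationState,
    system: MassSpringSystem,
    clip_schedule: Sequence[tuple[np.ndarray, float]],
    config: SimulationConfig,
    clip: ClipModel | None = None,
) -> list[SimulationState]:
    """Drive a full clipping scenario to convergence.

    ``clip_schedule`` is one (pose, opening_angle) entry per step; when it is
    exhausted the clip holds its last state and the vessel relaxes until the
    maximum per-particle displacement stays below ``convergence_tol`` for
    ``convergence_window`` consecutive steps, or ``max_steps`` is reached.
    Returns the append-only history, starting with the given state.
    """
    if len(clip_schedule) > config.max_steps:
        raise ValueError("clip schedule longer than max_steps")
    if clip is None:
        clip = state.clip
    if clip_schedule and clip is None:
        raise ValueError("a clip model is required when a schedule is given")

    history = [state]
    quiet = 0
    current_clip = clip
    for k in range(config.max_steps):
        if k < len(clip_schedule):
            pose, angle = clip_schedule[k]
            current_clip = set_clip_state(clip, pose, angle)
        new = step(history[-1], system, current_clip, config)
        if np.linalg.norm(new.positions, axis=1).max() > 1e6:
            raise SimulationDiverged(
                f"position norm exceeded 1e6 mm at step {new.step_index}; "
                f"config: {config.model_dump()}"
            )
        disp = np.linalg.norm(new.positions - history[-1].positions, axis=1).max()
        if not clip_schedule and k == 0 and disp == 0.0:
            return [state]  # already at equilibrium: immediate convergence
        history.append(new)
        if k + 1 >= len(clip_schedule):
            quiet = quiet + 1 if disp < config.convergence_tol else 0
            if quiet >= config.convergence_window:
                break
    return history


def cross_section_area(vertices: np.ndarray, faces: np.ndarray,
                       plane_origin: np.ndarray, plane_normal: np.ndarray) -> float:
    """Enclosed area of a mesh cross-section (e.g. a pinched tube lumen).

    Slices the surface with the plane and sums the areas of the resulting
    closed loops; used to quantify how far a clip has occluded a vessel.
    """
    import trimesh

    tm = trimesh.Trimesh(np.asarray(vertices), np.asarray(faces), process=False)
    section = tm.section(plane_origin=np.asarray(plane_origin, float),
                         plane_normal=np.asarray(plane_normal, float))
    if section is None:
        return 0.0
    planar, _ = section.to_2D()
    return float(planar.area)
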