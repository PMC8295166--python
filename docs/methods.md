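# Methods

This note records the deformation model, the collision handling, the
visualisation-field definitions, the default parameters and the numerical
choices behind them. Units are millimetres throughout; masses, stiffnesses
and the time step are in consistent arbitrary units (no claim is made that
the defaults are measured tissue properties).

## Mass–spring vessel model

A vessel is a triangle surface mesh. Each vertex is a point mass; each unique
mesh edge carries one Hookean spring whose rest length `l0` is the edge
length in the undeformed mesh, so the input mesh is an exact equilibrium.
The force a spring exerts on its endpoint `i` is

    f_ij = k_s · (x_j − x_i)/|x_j − x_i| · (|x_j − x_i| − l0),

with the opposite force on `j`. Coincident endpoints leave the direction
undefined; the force is then zero and a warning is logged.

Positions advance by damped position-based Verlet:

    x(t+Δt) = x(t) + (x(t) − x(t−Δt)) · (1 − k_d) + f(t)/m · Δt².

Anchored vertices (e.g. the open rims of a vessel segment, standing in for
the surrounding tissue) never move. With `k_d = 0` the scheme is standard
Verlet: it reproduces the analytic period of an anchored-spring oscillator
to better than 1 % at 200 steps per period and conserves the total momentum
of a free chain to ~1e−12 per 1000 steps (both are pinned by tests).

### Stretch compensation

Large time steps let springs overshoot. After integration, every spring is
capped at `(1 + τ)·l0` by iterative pairwise projection: an over-stretched
edge pulls its free endpoints together along the edge axis (symmetrically
when both are free, fully onto the free one otherwise). The sweeps are
sequential (Gauss–Seidel) over the edges, alternating direction each
iteration so corrections propagate symmetrically along chains of edges.
Because the cap is an inequality constraint, sweeps after the first are
over-relaxed (factor 1.5) — the projection lands strictly inside the feasible
region, which cuts chain-like violation patterns to feasibility in a handful
of sweeps; the first sweep is unrelaxed so an isolated violation resolves to
the cap exactly. The inner loop is JIT-compiled with numba.

## Clip interaction

The clip is two rigid convex blades on a common hinge, posed in world space
by a 4×4 rigid transform and separated by an opening angle (each blade
rotates by half the angle about the hinge axis). Parametric clips use
rectangular-box blades; imported blade meshes are replaced by their convex
hulls (logged when that changes the mesh) so containment and first-crossing
queries stay exact. The clip is kinematic: it follows a user-supplied
schedule of (pose, opening angle) per step and feels no reaction force.

Collision handling is per vertex and per step:

* The motion segment from the current position to the Verlet proposal is
  clipped against each blade (exact segment/convex-polytope entry test). If
  it crosses a blade surface at Euclidean distance `d_collision` from the
  current position, the vertex stops at `0.9 · d_collision` along its motion
  — just short of the surface, so it never lands exactly on it. The factor
  0.9 is the model's collision slack and is exposed as `collision_slack`.
* A vertex whose *current* position is already strictly inside a blade (the
  closing blades can overtake slow vertices) is projected to the nearest
  blade-surface point, nudged 1e−9 mm outward.

Stretch compensation can pull a vertex back across a blade surface, so the
step alternates: stretch pass → nearest-surface projection of any violators →
repeat (up to `stretch_collision_rounds` times) until both the stretch cap
and non-penetration hold. Nearest-surface projection (rather than undoing
the stretch correction) preserves the correction's tangential component, and
the alternation contracts quickly in practice. The canonical pinch run ends
every one of its ~5400 steps with zero penetration and a worst cap excess of
1e−9 mm.

## Visualisation fields

* **Distance products**: per-vertex minimum Euclidean distance to the blade
  surfaces (zero on or inside a blade); the single minimum-distance
  vertex–clip segment (ties resolve to the lowest vertex index); and rays
  from every vertex closer than a threshold to its nearest blade point, with
  opacity falling linearly from 1 at contact to 0 at the threshold.
* **Force products**: the displacement field (initial → current position, the
  model's proxy for applied force), per-vertex rays along it, and oriented
  glyphs. Arrow glyphs have fixed size; drop glyphs stretch linearly with
  magnitude across the colour-scale domain and clamp to a `[s_min, s_max]`
  range so outliers cannot occlude the scene. Glyph opacity rises linearly
  with magnitude from a floor of 0.2.
* **Colour scales**: piecewise-linear diverging maps with a neutral hinge at
  the domain midpoint. `green_red` runs red → yellow → green; `red_blue`
  (for dyschromatopsia) runs red → white → blue. `critical_end` selects
  which domain end is red: "low" for distances (small gap = danger), "high"
  for displacement magnitudes. Values outside the domain clamp to the end
  colours. The default domain is [0, 95th percentile] of the field, which is
  robust to outliers.

All products export as legacy-ASCII VTK polydata (points, polygons, lines or
vertices plus SCALARS/VECTORS/COLOR_SCALARS point data), readable by any
standard viewer and diffable in tests.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `k_s` | 50 | visible but stable deformation at mm scale with unit masses |
| `k_d` | 0.05 | light damping; removes oscillation without freezing the wall |
| `dt` | 0.02 | ~1/14 of the natural period at `k_s`=50, m=1; stable with the cap |
| `mass_per_vertex` | 1 | uniform wall; only the ratio `k_s/m` matters |
| `tau` | 0.1 | springs may stretch 10 % past rest before the cap engages |
| `collision_slack` | 0.9 | the model's collision constant (see above) |
| `convergence_tol` | 1e−5 mm | per-step displacement considered "at rest" |
| `convergence_window` | 10 | consecutive quiet steps required |
| `max_steps` | 6000 | covers the canonical pinch run (~5400 steps) with margin |
| `stretch_max_iterations` | 50 | projection sweeps per stretch pass |
| `stretch_collision_rounds` | 30 | stretch/collision alternations per step |

The configuration is a frozen, validated record; unknown keys and
out-of-range values are rejected, and a loaded configuration is echoed to the
log fully resolved.

## Fixtures

Synthetic geometry keeps the package self-contained:

* **Tubes**: parallel-transport frames along an arbitrary centerline,
  `n_radial × (n_axial + 1)` vertices, open ends; exact radius for straight
  centerlines.
* **Bifurcation aneurysms**: a signed-distance union of capsules (parent and
  two daughter vessels), a neck capsule and a spherical dome, surfaced by
  marching cubes and cut open at the three tube ends. Parameters (radii,
  bifurcation angle, dome and neck radius) are study conditions, not tuning
  knobs; five presets cover small/large dome, narrow/wide neck and the
  degenerate no-dome case.
* **Clips**: rectangular-box blades as above.

These are geometric stand-ins with realistic dimensions (parent radius
~1.4 mm, dome radius ~2.5 mm), not patient anatomy.

## Problem sizes and performance

Chosen as this package's own working scale: fixture meshes run from a few
hundred to a few thousand vertices (the canonical tube is 400 vertices /
1168 springs; aneurysm fixtures ~2–4 k vertices at the default voxel pitch of
0.22 × the smallest radius). The canonical pinch run (400 vertices, 120
schedule steps + relaxation to convergence, ~5400 steps total) takes ~10 s on
one CPU core; the full test suite runs in under a minute.

## Limitations

* The wall is a surface mass–spring system: no volumetric elasticity, no
  bending stiffness, no self-collision, and spring stiffness is not fitted to
  tissue data — deformation is plausible, not predictive.
* The clip is kinematic and convex-bladed; it feels no reaction force, and
  non-convex blade geometry is approximated by convex hulls.
* Collision handling is vertex-based; a blade thinner than the local edge
  length could pass between vertices without contact. Fixture resolutions
  and the default blade thickness avoid this regime.
* Convergence near a fully closed clip is slow (cap-limited springs drag
  material in small increments), hence the generous `max_steps`.
* The displacement field is a proxy for force; no stress tensor is computed.
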