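import numpy as np
import pytest

from aneuclip._convex import ConvexSolid, box_solid
from aneuclip.clip import (
    ClipModel,
    collision_query,
    collision_query_batch,
    make_clip,
    point_clip_distance,
    project_outside,
    resolve_collision,
    resolve_collision_batch,
    set_clip_state,
)
from aneuclip.geometry import TriangleMesh


def unit_cube_mesh(center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    solid = box_solid(np.eye(4), np.array([0.5, 0.5, 0.5]))
    verts = solid.vertices + np.asarray(center, float)
    return TriangleMesh(verts, solid.faces)


def random_pose(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    T = np.eye(4)
    T[:3, :3] = Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()
    T[:3, 3] = rng.normal(scale=3.0, size=3)
    return T


class TestKinematics:
    def test_set_clip_state_is_stateless(self):
        clip = make_clip(6.0, 2.0, 0.4, 45.0)
        pose = np.eye(4)
        pose[:3, 3] = [1.0, 2.0, 3.0]
        moved = set_clip_state(clip, pose, 10.0)
        # the original is untouched
        assert clip.opening_angle == 45.0
        assert np.array_equal(clip.pose, np.eye(4))
        assert moved.opening_angle == 10.0

    def test_set_clip_state_idempotent(self):
        clip = make_clip(6.0, 2.0, 0.4, 45.0)
        pose = np.eye(4)
        a = set_clip_state(clip, pose, 20.0)
        b = set_clip_state(a, pose, 20.0)
        sa, sb = a.blade_solids()[0], b.blade_solids()[0]
        assert np.array_equal(sa.vertices, sb.vertices)

    def test_blade_gap_monotone_in_angle(self):
        clip = make_clip(6.0, 2.0, 0.4, 0.0)
        tip = np.array([[6.0, 0.0, 0.0]])  # point at the blade tips when closed
        gaps = []
        for angle in np.linspace(2.0, 60.0, 15):
            c = set_clip_state(clip, np.eye(4), float(angle))
            a, b = c.blade_solids()
            # distance between the two inner faces, sampled at the tip point
            gaps.append(float(a.distance(tip)[0] + b.distance(tip)[0]))
        assert all(g2 > g1 for g1, g2 in zip(gaps, gaps[1:]))

    def test_invalid_pose_rejected(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError, match="orthonormal"):
            ClipModel(1.0, 1.0, 1.0, 10.0, pose=bad)

    def test_negative_angle_rejected(self):
        clip = make_clip(1.0, 1.0, 0.1, 10.0)
        with pytest.raises(ValueError, match="non-negative"):
            set_clip_state(clip, np.eye(4), -1.0)

    def test_hinge_axis_follows_pose(self):
        clip = make_clip(6.0, 2.0, 0.4, 30.0)
        pose = np.eye(4)
        pose[:3, :3] = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0.0]])
        assert set_clip_state(clip, pose, 30.0).hinge_axis == pytest.approx([0, 0, 1.0])


class TestFromBladeMeshes:
    def test_unit_cube_blades_round_trip(self):
        a = unit_cube_mesh(center=(0.0, 0.0, 1.0))
        b = unit_cube_mesh(center=(0.0, 0.0, -1.0))
        clip = ClipModel.from_blade_meshes(a, b)
        sa, sb = clip.blade_solids()
        assert sa.contains(np.array([[0.0, 0.0, 1.0]]))[0]
        assert sb.contains(np.array([[0.0, 0.0, -1.0]]))[0]
        assert not sa.contains(np.array([[0.0, 0.0, 0.0]]))[0]

    def test_nonconvex_blade_hulled_with_notice(self, caplog):
        import logging

        # a cube with an extra vertex dented inwards is not convex
        cube = unit_cube_mesh()
        verts = np.vstack([cube.vertices, [[0.0, 0.0, 0.45]]])
        dented = TriangleMesh(verts, cube.faces)
        with caplog.at_level(logging.INFO, logger="aneuclip.clip"):
            clip = ClipModel.from_blade_meshes(dented, cube)
        assert any("convex hull" in r.message for r in caplog.records)
        # hull equals the original cube: the dent vertex is absorbed
        sa, _ = clip.blade_solids()
        assert len(sa.vertices) == 8


class TestCollisionQuery:
    def setup_method(self):
        a = unit_cube_mesh(center=(0.0, 0.0, 1.0))
        b = unit_cube_mesh(center=(0.0, 0.0, -1.0))
        self.clip = ClipModel.from_blade_meshes(a, b)

    def test_miss_reports_no_collision(self):
        res = collision_query(np.array([5.0, 0, 0]), np.array([5.0, 0, 1.0]), self.clip)
        assert not res.colliding and not res.trapped

    def test_head_on_hit_distance(self):
        # motion from z=0 towards blade A whose near face is at z=0.5
        res = collision_query(np.zeros(3), np.array([0.0, 0.0, 2.0]), self.clip)
        assert res.colliding
        assert res.d_collision == pytest.approx(0.5, abs=1e-12)
        assert res.hit_direction == pytest.approx([0.0, 0.0, 1.0])

    def test_oblique_hit_distance(self):
        # 45-degree approach: euclidean distance to the face is sqrt(2)*0.5
        res = collision_query(np.zeros(3), np.array([1.0, 0.0, 1.0]), self.clip)
        assert res.colliding
        assert res.d_collision == pytest.approx(np.sqrt(2) * 0.5, abs=1e-12)

    def test_segment_stopping_short_is_a_miss(self):
        res = collision_query(np.zeros(3), np.array([0.0, 0.0, 0.4]), self.clip)
        assert not res.colliding

    def test_point_inside_is_trapped(self):
        res = collision_query(np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, 1.1]), self.clip)
        assert res.trapped
        assert res.escape_point is not None
        # escape lands (just) outside both blades
        assert point_clip_distance(res.escape_point, self.clip) >= 0.0
        sa, sb = self.clip.blade_solids()
        assert not sa.contains(res.escape_point[None], tol=0.0)[0]

    def test_batch_matches_scalar(self, rng):
        starts = rng.normal(scale=2.0, size=(64, 3))
        ends = starts + rng.normal(scale=2.0, size=(64, 3))
        hit, d, trapped, _ = collision_query_batch(starts, ends, self.clip)
        for k in range(64):
            res = collision_query(starts[k], ends[k], self.clip)
            assert res.colliding == hit[k]
            assert res.trapped == trapped[k]
            if hit[k] and not trapped[k]:
                assert res.d_collision == pytest.approx(d[k], abs=1e-12)


class TestResolveCollision:
    def setup_method(self):
        a = unit_cube_mesh(center=(0.0, 0.0, 1.0))
        b = unit_cube_mesh(center=(0.0, 0.0, -1.0))
        self.clip = ClipModel.from_blade_meshes(a, b)

    def test_no_collision_passes_through(self):
        x_t, x_p = np.array([5.0, 0, 0]), np.array([5.0, 0, 1.0])
        res = collision_query(x_t, x_p, self.clip)
        assert np.array_equal(resolve_collision(x_t, x_p, res), x_p)

    def test_stops_at_slack_fraction(self):
        x_t, x_p = np.zeros(3), np.array([0.0, 0.0, 2.0])
        res = collision_query(x_t, x_p, self.clip)
        out = resolve_collision(x_t, x_p, res, slack=0.9)
        # d_collision = 0.5 towards the face at z = 0.5
        assert out == pytest.approx([0.0, 0.0, 0.45], abs=1e-12)

    def test_resolved_point_outside_blades(self, rng):
        starts = rng.normal(scale=1.5, size=(200, 3))
        ends = starts + rng.normal(scale=1.5, size=(200, 3))
        adapted, _, _ = resolve_collision_batch(starts, ends, self.clip)
        sa, sb = self.clip.blade_solids()
        outside_start = ~(sa.contains(starts) | sb.contains(starts))
        depth = np.maximum(sa.depth(adapted), sb.depth(adapted))
        assert depth[outside_start].max() <= 1e-12

    def test_slack_monotonicity(self):
        x_t, x_p = np.zeros(3), np.array([0.0, 0.0, 2.0])
        res = collision_query(x_t, x_p, self.clip)
        travelled = [np.linalg.norm(resolve_collision(x_t, x_p, res, slack=s) - x_t)
                     for s in (0.3, 0.6, 0.9)]
        assert travelled[0] < travelled[1] < travelled[2]

    def test_trapped_point_escapes_to_surface(self):
        x_t = np.array([0.1, 0.0, 1.0])  # inside blade A
        x_p = x_t + 0.01
        res = collision_query(x_t, x_p, self.clip)
        out = resolve_collision(x_t, x_p, res)
        assert res.trapped
        # lands within a nudge of the blade surface, outside the solid
        sa, _ = self.clip.blade_solids()
        assert abs(sa.distance(out[None])[0]) < 1e-6
        assert sa.depth(out[None])[0] <= 0.0


class TestProjectOutside:
    def test_inside_points_land_on_surface(self, rng):
        clip = make_clip(6.0, 2.0, 0.4, 20.0)
        sa, sb = clip.blade_solids()
        pts = rng.uniform(low=[-1, -2, -2], high=[7, 2, 2], size=(500, 3))
        out = project_outside(pts, clip)
        depth = np.maximum(sa.depth(out), sb.depth(out))
        assert depth.max() <= 1e-12
        inside = (sa.depth(pts) > 0) | (sb.depth(pts) > 0)
        # outside points untouched
        assert np.array_equal(out[~inside], pts[~inside])
        # projection is the nearest surface point: moved at most the depth + eps
        moved = np.linalg.norm(out[inside] - pts[inside], axis=1)
        worst_depth = np.maximum(sa.depth(pts), sb.depth(pts))[inside]
        assert (moved <= worst_depth + 1e-8).all()


class TestDistances:
    def test_distance_matches_analytic_box_distance(self, rng):
        # at angle 0 with identity pose the blades are axis-aligned boxes:
        # A spans [0,6]x[-1,1]x[0,0.4], B spans [0,6]x[-1,1]x[-0.4,0],
        # so the exact distance is the clamped-coordinate norm
        clip = make_clip(6.0, 2.0, 0.4, 0.0)
        pts = rng.uniform(low=[-2, -3, -4], high=[8, 3, 4], size=(500, 3))

        def aabb_dist(p, lo, hi):
            gap = np.maximum(np.maximum(lo - p, p - hi), 0.0)
            return np.linalg.norm(gap, axis=1)

        ref = np.minimum(
            aabb_dist(pts, np.array([0, -1, 0.0]), np.array([6, 1, 0.4])),
            aabb_dist(pts, np.array([0, -1, -0.4]), np.array([6, 1, 0.0])),
        )
        ours = point_clip_distance(pts, clip)
        assert np.abs(ours - ref).max() < 1e-9

    def test_scalar_and_array_forms_agree(self):
        clip = make_clip(6.0, 2.0, 0.4, 25.0)
        p = np.array([0.0, 0.0, 3.0])
        assert point_clip_distance(p, clip) == point_clip_distance(p[None], clip)[0]

    def test_pose_invariance(self, rng):
        clip0 = make_clip(6.0, 2.0, 0.4, 30.0)
        pts = rng.normal(scale=4.0, size=(100, 3))
        d0 = point_clip_distance(pts, clip0)
        for _ in range(3):
            T = random_pose(rng)
            moved = set_clip_state(clip0, T, 30.0)
            pts_T = pts @ T[:3, :3].T + T[:3, 3]
            dT = point_clip_distance(pts_T, moved)
            assert np.abs(dT - d0).max() < 1e-9
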