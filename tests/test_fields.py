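import numpy as np
import pytest

from aneuclip.clip import make_clip, point_clip_distance, set_clip_state
from aneuclip.driver import SimulationState
from aneuclip.fields import (
    ColourScale,
    VectorField,
    displacement_field,
    displacement_rays,
    distance_field,
    distance_rays,
    make_glyphs,
    map_colour,
    min_distance_segment,
)
from aneuclip.geometry import TriangleMesh, make_tube

STRAIGHT = np.array([[0.0, 0.0, -5.0], [0.0, 0.0, 5.0]])


def posed_clip(offset=(0.0, 3.0, 0.0), angle=20.0):
    clip = make_clip(6.0, 2.0, 0.4, angle)
    pose = np.eye(4)
    pose[:3, 3] = offset
    return set_clip_state(clip, pose, angle)


def displaced_state(mesh, rng, scale=0.1):
    disp = rng.normal(scale=scale, size=mesh.vertices.shape)
    pos = mesh.vertices + disp
    return SimulationState(5, pos, pos.copy(), None, mesh.vertices.copy())


class TestColourScale:
    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError, match="v_min"):
            ColourScale("green_red", 1.0, 1.0)

    def test_green_red_endpoints(self):
        scale = ColourScale("green_red", 0.0, 2.0, critical_end="low")
        assert map_colour(0.0, scale) == pytest.approx([1.0, 0.0, 0.0])  # red
        assert map_colour(2.0, scale) == pytest.approx([0.0, 1.0, 0.0])  # green
        assert map_colour(1.0, scale) == pytest.approx([1.0, 1.0, 0.0])  # yellow

    def test_red_blue_endpoints(self):
        scale = ColourScale("red_blue", 0.0, 2.0, critical_end="low")
        assert map_colour(0.0, scale) == pytest.approx([1.0, 0.0, 0.0])  # red
        assert map_colour(2.0, scale) == pytest.approx([0.0, 0.0, 1.0])  # blue
        assert map_colour(1.0, scale) == pytest.approx([1.0, 1.0, 1.0])  # white

    def test_critical_high_flips_ends(self):
        scale = ColourScale("green_red", 0.0, 2.0, critical_end="high")
        assert map_colour(2.0, scale) == pytest.approx([1.0, 0.0, 0.0])
        assert map_colour(0.0, scale) == pytest.approx([0.0, 1.0, 0.0])

    def test_out_of_domain_clamps(self):
        scale = ColourScale("green_red", 0.0, 1.0)
        assert map_colour(-5.0, scale) == pytest.approx([1.0, 0.0, 0.0])
        assert map_colour(9.0, scale) == pytest.approx([0.0, 1.0, 0.0])

    def test_array_form_matches_scalars(self, rng):
        scale = ColourScale("green_red", 0.0, 3.0)
        vals = rng.uniform(-1, 4, size=50)
        arr = map_colour(vals, scale)
        for k, v in enumerate(vals):
            assert arr[k] == pytest.approx(map_colour(float(v), scale))

    def test_colours_stay_in_unit_cube(self, rng):
        for kind in ("green_red", "red_blue"):
            scale = ColourScale(kind, 0.0, 1.0)
            rgb = map_colour(rng.uniform(-2, 3, size=200), scale)
            assert rgb.min() >= 0.0 and rgb.max() <= 1.0

    def test_for_field_domain_is_percentile(self):
        values = np.linspace(0.0, 10.0, 101)  # 95th percentile = 9.5
        scale = ColourScale.for_field(values)
        assert scale.v_min == 0.0
        assert scale.v_max == pytest.approx(9.5)


class TestDistanceProducts:
    def test_field_matches_pointwise_oracle(self, straight_tube):
        clip = posed_clip()
        field = distance_field(straight_tube, clip)
        ref = np.array([point_clip_distance(v, clip) for v in straight_tube.vertices])
        assert np.abs(field.values - ref).max() < 1e-12

    def test_min_segment_is_the_global_minimum(self, straight_tube):
        clip = posed_clip()
        vtx, closest, d = min_distance_segment(straight_tube, clip)
        field = distance_field(straight_tube, clip)
        assert d == pytest.approx(field.values.min())
        assert np.linalg.norm(vtx - closest) == pytest.approx(d, abs=1e-9)

    def test_min_segment_tie_breaks_to_lowest_index(self):
        # two vertices at identical distance from the clip
        verts = np.array([[0.0, 1.0, 1.0], [0.0, 1.0, -1.0], [5.0, 8.0, 0.0]])
        mesh = TriangleMesh(verts, np.array([[0, 1, 2]]))
        vtx, _, _ = min_distance_segment(mesh, posed_clip(offset=(0, 3, 0), angle=0.0))
        assert np.array_equal(vtx, verts[0])

    def test_rays_select_below_threshold(self, straight_tube):
        clip = posed_clip()
        d = distance_field(straight_tube, clip).values
        for thr in (0.5, 1.5, 3.0):
            rays = distance_rays(straight_tube, clip, thr)
            assert len(rays) == int((d < thr).sum())
            if len(rays):
                assert rays.values.max() < thr
                # alpha falls linearly: 1 at contact, 0 at the threshold
                assert rays.alphas == pytest.approx(1.0 - rays.values / thr)

    def test_ray_endpoints_on_clip_surface(self, straight_tube):
        clip = posed_clip()
        rays = distance_rays(straight_tube, clip, 2.0)
        assert len(rays) > 0
        end_d = point_clip_distance(rays.ends, clip)
        assert np.abs(end_d).max() < 1e-9

    def test_negative_threshold_rejected(self, straight_tube):
        with pytest.raises(ValueError, match="threshold"):
            distance_rays(straight_tube, posed_clip(), -1.0)

    def test_isometry_invariance(self, straight_tube, rng):
        from scipy.spatial.transform import Rotation

        clip = posed_clip()
        d0 = distance_field(straight_tube, clip).values
        R = Rotation.random(random_state=np.random.RandomState(3)).as_matrix()
        t = rng.normal(scale=5.0, size=3)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        moved_mesh = TriangleMesh(straight_tube.vertices @ R.T + t, straight_tube.faces)
        moved_clip = set_clip_state(clip, T @ clip.pose, clip.opening_angle)
        d1 = distance_field(moved_mesh, moved_clip).values
        assert np.abs(d1 - d0).max() < 1e-9


class TestDisplacementProducts:
    def test_field_is_current_minus_initial(self, straight_tube, rng):
        state = displaced_state(straight_tube, rng)
        field = displacement_field(state)
        assert np.array_equal(field.vectors, state.positions - state.initial_positions)
        assert np.array_equal(field.anchors, state.initial_positions)

    def test_field_linearity(self, straight_tube, rng):
        disp = rng.normal(scale=0.1, size=straight_tube.vertices.shape)
        init = straight_tube.vertices
        s1 = SimulationState(1, init + disp, init.copy(), None, init.copy())
        s2 = SimulationState(1, init + 2 * disp, init.copy(), None, init.copy())
        f1, f2 = displacement_field(s1), displacement_field(s2)
        assert np.abs(f2.vectors - 2 * f1.vectors).max() < 1e-12

    def test_rays_skip_undisplaced(self, straight_tube, rng):
        init = straight_tube.vertices
        disp = np.zeros_like(init)
        disp[:10] = rng.normal(scale=0.2, size=(10, 3))
        state = SimulationState(1, init + disp, init.copy(), None, init.copy())
        rays = displacement_rays(displacement_field(state))
        assert len(rays) == 10
        assert np.array_equal(rays.starts, init[:10])
        assert np.abs(rays.ends - (init[:10] + disp[:10])).max() < 1e-12

    def test_ray_alpha_proportional_to_magnitude(self, straight_tube, rng):
        state = displaced_state(straight_tube, rng)
        rays = displacement_rays(displacement_field(state))
        assert rays.alphas.max() == pytest.approx(1.0)
        assert rays.alphas == pytest.approx(rays.values / rays.values.max())


class TestGlyphs:
    def make_field(self, rng, n=100):
        verts = rng.normal(size=(n, 3))
        mesh = TriangleMesh(verts, np.zeros((0, 3), dtype=np.int64))
        return VectorField(mesh, rng.normal(scale=0.5, size=(n, 3)), anchors=verts)

    def test_orientations_are_unit_displacement_directions(self, rng):
        field = self.make_field(rng)
        scale = ColourScale.for_field(field.magnitudes(), critical_end="high")
        glyphs = make_glyphs(field, "arrow", (0.1, 0.5), scale)
        mags = field.magnitudes()
        expected = field.vectors[mags > 1e-9] / mags[mags > 1e-9, None]
        assert np.abs(glyphs.orientations - expected).max() < 1e-12

    def test_arrow_scale_fixed_drop_scale_clamped(self, rng):
        field = self.make_field(rng)
        scale = ColourScale(kind="green_red", v_min=0.0, v_max=0.5, critical_end="high")
        arrows = make_glyphs(field, "arrow", (0.2, 0.8), scale)
        drops = make_glyphs(field, "drop", (0.2, 0.8), scale)
        assert (arrows.axial_scales == 0.2).all()
        assert drops.axial_scales.min() >= 0.2 - 1e-12
        assert drops.axial_scales.max() <= 0.8 + 1e-12
        # magnitudes above the colour domain clamp to s_max
        big = field.magnitudes()[field.magnitudes() > 1e-9] >= 0.5
        assert drops.axial_scales[big] == pytest.approx(0.8)

    def test_drop_scale_monotone_in_magnitude(self, rng):
        field = self.make_field(rng)
        scale = ColourScale.for_field(field.magnitudes(), critical_end="high")
        drops = make_glyphs(field, "drop", (0.1, 1.0), scale)
        m = field.magnitudes()[field.magnitudes() > 1e-9]
        order = np.argsort(m)
        diffs = np.diff(drops.axial_scales[order])
        assert (diffs >= -1e-12).all()

    def test_alpha_rises_with_magnitude_within_bounds(self, rng):
        field = self.make_field(rng)
        scale = ColourScale.for_field(field.magnitudes(), critical_end="high")
        glyphs = make_glyphs(field, "drop", (0.1, 1.0), scale)
        assert glyphs.alphas.min() >= 0.2 - 1e-12
        assert glyphs.alphas.max() <= 1.0 + 1e-12
        m = field.magnitudes()[field.magnitudes() > 1e-9]
        order = np.argsort(m)
        assert (np.diff(glyphs.alphas[order]) >= -1e-12).all()

    def test_unknown_kind_rejected(self, rng):
        field = self.make_field(rng)
        scale = ColourScale.for_field(field.magnitudes())
        with pytest.raises(ValueError, match="glyph kind"):
            make_glyphs(field, "sphere", (0.1, 1.0), scale)

    def test_inputs_unmodified(self, rng):
        field = self.make_field(rng)
        snap = field.vectors.copy()
        scale = ColourScale.for_field(field.magnitudes())
        make_glyphs(field, "drop", (0.1, 1.0), scale)
        assert np.array_equal(field.vectors, snap)
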