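import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rm3d.beam_model import RIGUR
from rm3d.mesh_geometry import (RigidTransform, StlFormatError, TriangleMesh,
                                analytic_heightfield, apply_transform,
                                heightfield_of, read_stl, tessellate,
                                wet_sample_table, write_stl)
from rm3d.mesh_geometry import _analytic_volume
from rm3d.rm_builder import uniform_modulator
from rm3d.sobp_design import contour_wet_distribution, step_to_stepless


@pytest.fixture(scope="module")
def small_modulator(four_level_pin):
    return uniform_modulator(four_level_pin, n_cells=3)


@pytest.fixture(scope="module")
def small_mesh(small_modulator):
    return tessellate(small_modulator, 0.1)


class TestTessellation:
    def test_watertight(self, small_mesh):
        assert small_mesh.is_watertight()

    def test_volume_matches_analytic(self, small_modulator, small_mesh):
        expected = _analytic_volume(small_modulator)
        assert small_mesh.volume() == pytest.approx(expected, rel=5e-3)

    def test_volume_matches_trimesh(self, small_mesh):
        trimesh = pytest.importorskip("trimesh")
        tm = trimesh.Trimesh(vertices=small_mesh.vertices,
                             faces=small_mesh.triangles, process=False)
        assert small_mesh.volume() == pytest.approx(tm.volume, rel=1e-9)

    def test_flat_slab_volume_exact(self, four_level_weights):
        # a one-level pin field is a box: footprint x (height + base)
        from rm3d.sobp_design import WeightVector, weights_to_step_contour

        w = WeightVector(np.array([3.0]), np.array([1.0]))
        pin = weights_to_step_contour(w, 3.0, RIGUR)
        mod = uniform_modulator(pin, n_cells=2, wall_thickness_mm=0.0)
        mesh = tessellate(mod)
        h = 3.0 / RIGUR.relative_stopping_power
        assert mesh.volume() == pytest.approx(36.0 * (8.0 + h), rel=1e-9)

    def test_stepless_volume(self, sobp_weights):
        pin = step_to_stepless(sobp_weights, base_period_mm=3.0,
                               material=RIGUR)
        mod = uniform_modulator(pin, n_cells=2)
        mesh = tessellate(mod, tolerance_mm=0.1)
        assert mesh.is_watertight()
        assert mesh.volume() == pytest.approx(_analytic_volume(mod),
                                              rel=5e-3)


class TestRigidTransform:
    def test_identity_bit_identical(self, small_mesh):
        out = apply_transform(small_mesh, RigidTransform())
        assert np.array_equal(out.vertices, small_mesh.vertices)

    def test_pure_translation(self, small_mesh):
        t = RigidTransform(translation=(1.5, 0.0, 0.0))
        out = apply_transform(small_mesh, t)
        assert np.allclose(out.vertices[:, 0],
                           small_mesh.vertices[:, 0] + 1.5)
        assert np.allclose(out.vertices[:, 1:], small_mesh.vertices[:, 1:])

    def test_rotation_about_pivot_oracle(self):
        # 1.5 deg about Y, pivot (-200, 0, -180); vertex at the origin.
        # Independent 2D rotation oracle in the xz plane:
        th = np.deg2rad(1.5)
        rel = np.array([200.0, 180.0])  # origin minus pivot, (x, z)
        exp_x = -200.0 + np.cos(th) * rel[0] + np.sin(th) * rel[1]
        exp_z = -180.0 - np.sin(th) * rel[0] + np.cos(th) * rel[1]
        t = RigidTransform(rotation_deg=1.5, axis="y",
                           pivot=(-200.0, 0.0, -180.0))
        out = t.apply(np.array([[0.0, 0.0, 0.0]]))[0]
        assert out[0] == pytest.approx(exp_x, abs=1e-9)
        assert out[1] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(exp_z, abs=1e-9)

    @given(st.floats(-180, 180), st.sampled_from(["x", "y", "z"]),
           st.lists(st.floats(-100, 100), min_size=3, max_size=3),
           st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_distance_preservation(self, angle, axis, pivot, shift):
        t = RigidTransform(angle, axis, tuple(pivot), tuple(shift))
        pts = np.array([[0.0, 0.0, 0.0], [10.0, 0, 0], [0, 10.0, 0],
                        [3.0, -4.0, 5.0]])
        out = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)

    def test_rotation_composition(self):
        p = np.array([[12.0, -3.0, 7.0]])
        pivot = (1.0, 2.0, 3.0)
        a = RigidTransform(10.0, "y", pivot)
        b = RigidTransform(25.0, "y", pivot)
        c = RigidTransform(35.0, "y", pivot)
        assert np.allclose(b.apply(a.apply(p)), c.apply(p), atol=1e-9)

    def test_inverse_round_trip(self):
        t = RigidTransform(33.0, "x", (5.0, -2.0, 1.0), (0.5, 1.5, -4.0))
        p = np.random.default_rng(0).normal(size=(20, 3)) * 30
        assert np.allclose(t.apply_inverse(t.apply(p)), p, atol=1e-9)


class TestStlIO:
    def test_binary_round_trip(self, small_mesh, tmp_path):
        path = tmp_path / "m.stl"
        write_stl(small_mesh, path, "binary")
        back = read_stl(path)
        assert back.n_triangles == small_mesh.n_triangles
        expected = small_mesh.triangle_corners().astype(np.float32)
        assert np.array_equal(back.vertices.reshape(-1, 3, 3),
                              expected.astype(np.float64))

    def test_ascii_binary_equivalence(self, small_mesh, tmp_path):
        pa = tmp_path / "a.stl"
        pb = tmp_path / "b.stl"
        write_stl(small_mesh, pa, "ascii")
        write_stl(small_mesh, pb, "binary")
        ma = read_stl(pa)
        mb = read_stl(pb)
        assert ma.n_triangles == mb.n_triangles
        assert np.allclose(ma.vertices, mb.vertices, rtol=1e-6, atol=1e-6)

    def test_truncated_binary_raises_with_offset(self, small_mesh, tmp_path):
        path = tmp_path / "t.stl"
        write_stl(small_mesh, path, "binary")
        data = path.read_bytes()[:-7]
        bad = tmp_path / "bad.stl"
        bad.write_bytes(data)
        with pytest.raises(StlFormatError) as err:
            read_stl(bad)
        assert err.value.byte_offset is not None

    def test_malformed_ascii_vertex(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_text("solid x\n facet\n vertex 1 2\n endfacet\nendsolid\n")
        with pytest.raises(StlFormatError):
            read_stl(bad)


class TestHeightfields:
    def test_flat_slab_constant(self):
        from rm3d.sobp_design import WeightVector, weights_to_step_contour

        w = WeightVector(np.array([3.0]), np.array([1.0]))
        pin = weights_to_step_contour(w, 3.0, RIGUR)
        mod = uniform_modulator(pin, n_cells=2, wall_thickness_mm=0.0)
        xs, ys, h = analytic_heightfield(mod, 0.5)
        assert np.allclose(h, 8.0 + 3.0 / RIGUR.relative_stopping_power)

    def test_mesh_raycast_matches_analytic(self, small_modulator,
                                           small_mesh):
        xs, ys, h_mesh = heightfield_of(small_mesh, 0.25)
        # same sample positions analytically
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        h_ana = small_modulator.column_height(gx.ravel(),
                                              gy.ravel()).reshape(gx.shape)
        # agree everywhere except within a sample of a step edge
        diff = np.abs(h_mesh - h_ana)
        frac_exact = np.mean(diff < 1e-6)
        assert frac_exact > 0.9
        assert np.median(diff) < 1e-6

    def test_ray_through_gap_sees_base_only(self, small_modulator):
        # valley floor of the four-level pin: outermost ring has height 0,
        # so a ray near a cell corner crosses the base layer only
        col = small_modulator.column_height(1.49, 1.49)
        assert col[0] == pytest.approx(8.0, abs=1e-9)


class TestWetSampleTable:
    def test_identity_reproduces_area_fractions(self, four_level_pin,
                                                four_level_weights):
        mod = uniform_modulator(four_level_pin, n_cells=5)
        st_ = wet_sample_table(mod, samples_per_cell=24,
                               region=(-7.5, 7.5, -7.5, 7.5))
        wet = st_.column_mm * RIGUR.relative_stopping_power
        base_wet = 8.0 * RIGUR.relative_stopping_power
        bins = np.round((wet - base_wet) / 3.0).astype(int)
        agg = np.bincount(np.clip(bins, 0, 5), weights=st_.area_mm2)
        agg /= agg.sum()
        assert np.allclose(agg[:4], four_level_weights.weights, atol=0.01)

    def test_translation_equals_shifted_identity(self, four_level_pin):
        mod = uniform_modulator(four_level_pin, n_cells=5)
        t = RigidTransform(translation=(3.0, 0.0, 0.0))  # one full period
        region = (-4.5, 4.5, -4.5, 4.5)  # period-aligned, inside footprint
        s0 = wet_sample_table(mod, samples_per_cell=12, region=region)
        s1 = wet_sample_table(mod, t, samples_per_cell=12, region=region)
        # same lattice, structure shifted by exactly one period: identical
        assert np.allclose(np.sort(s0.column_mm), np.sort(s1.column_mm),
                           atol=1e-9)

    def test_small_rotation_conserves_material(self, four_level_pin):
        mod = uniform_modulator(four_level_pin, n_cells=5)
        t = RigidTransform(rotation_deg=1.0, axis="y", pivot=(0, 0, 8.0))
        s0 = wet_sample_table(mod, samples_per_cell=16,
                              region=(-6.0, 6.0, -6.0, 6.0))
        s1 = wet_sample_table(mod, t, samples_per_cell=16,
                              region=(-6.0, 6.0, -6.0, 6.0))
        m0 = np.sum(s0.column_mm * s0.area_mm2)
        m1 = np.sum(s1.column_mm * s1.area_mm2)
        assert m1 == pytest.approx(m0, rel=5e-3)
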