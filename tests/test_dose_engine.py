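import numpy as np
import pytest

from rm3d.beam_model import RIGUR, ScanSpot, range_from_energy, wet_of_slab
from rm3d.dose_engine import (DoseGrid, PROFILES, Sampling, Scene,
                              compute_dose, fluence_cov,
                              integrated_depth_dose, score_fluence,
                              sobp_profile)
from rm3d.mesh_geometry import RigidTransform, heightfield_of, tessellate
from rm3d.rm_builder import RasterPlan, uniform_field_plan, uniform_modulator


@pytest.fixture(scope="module")
def baseline_scene():
    # 20 cm absorber, isocenter 9 cm inside the phantom
    return Scene(absorber_thickness_mm=200.0, phantom_surface_z=-90.0)


@pytest.fixture(scope="module")
def baseline_dose(baseline_scene, beamline, curve250):
    plan = uniform_field_plan()
    return compute_dose(plan, baseline_scene, beamline, curve=curve250,
                        sampling=Sampling(depth_max_mm=200.0))


@pytest.fixture(scope="module")
def pencil_plan():
    return RasterPlan([ScanSpot(0.0, 0.0, 1.0)])


@pytest.fixture(scope="module")
def rm2d_step(step_pin):
    return uniform_modulator(step_pin, n_cells=13)


class TestBaseline:
    def test_peak_depth_range_arithmetic(self, baseline_dose, curve250):
        # range-arithmetic oracle: peak near R80(250) - WET(200 mm PMMA)
        prof = sobp_profile(baseline_dose)
        peak = baseline_dose.depth_mm[int(np.argmax(prof))]
        expected = range_from_energy(250.0) - 232.0
        assert peak == pytest.approx(expected, abs=5.0)

    def test_lateral_uniformity_inside_field(self, baseline_dose):
        sl = baseline_dose.depth_slice(100.0)
        cen = sl[np.abs(baseline_dose.x_mm) < 30][:,
                 np.abs(baseline_dose.y_mm) < 30]
        assert cen.std() / cen.mean() < 0.05


class TestLinearity:
    def test_dose_linear_in_mu(self, baseline_scene, beamline, curve250):
        plan = uniform_field_plan((20.0, 20.0), 5.0, 1.0)
        s = Sampling(depth_max_mm=180.0, lateral_half_mm=30.0)
        d1 = compute_dose(plan, baseline_scene, beamline, curve=curve250,
                          sampling=s)
        d2 = compute_dose(plan.scaled(2.0), baseline_scene, beamline,
                          curve=curve250, sampling=s)
        assert np.allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_mu_permutation_invariance(self, baseline_scene, beamline,
                                       curve250):
        plan = uniform_field_plan((20.0, 20.0), 5.0, 1.0)
        rng = np.random.default_rng(7)
        spots = list(plan.spots)
        shuffled = RasterPlan([spots[i] for i in
                               rng.permutation(len(spots))],
                              plan.field_mm, plan.spacing_mm)
        s = Sampling(depth_max_mm=150.0, lateral_half_mm=30.0)
        d1 = compute_dose(plan, baseline_scene, beamline, curve=curve250,
                          sampling=s)
        d2 = compute_dose(shuffled, baseline_scene, beamline, curve=curve250,
                          sampling=s)
        assert np.allclose(d1.values, d2.values, rtol=1e-12)


class Test2DModulator:
    def test_single_pencil_plateau_flat(self, pencil_plan, reference_scene,
                                        beamline, curve250, rm2d_step,
                                        sobp_interval):
        prox, distal = sobp_interval
        z, d = integrated_depth_dose(pencil_plan, reference_scene, beamline,
                                     modulator=rm2d_step, curve=curve250,
                                     sampling=PROFILES["pencil"])
        sel = (z >= prox + 3.0) & (z <= distal - 3.0)
        flat = np.max(np.abs(d[sel] - d[sel].mean())) / d[sel].mean()
        assert flat <= 0.015

    def test_period_equivariance(self, pencil_plan, reference_scene,
                                 beamline, curve250, rm2d_step,
                                 sobp_interval):
        # translating the 2D RM by exactly one pin period leaves the
        # central SOBP unchanged up to discretization
        prox, distal = sobp_interval
        s = PROFILES["pencil"]
        z, d0 = integrated_depth_dose(pencil_plan, reference_scene, beamline,
                                      modulator=rm2d_step, curve=curve250,
                                      sampling=s)
        t = RigidTransform(translation=(3.0, 0.0, 0.0))
        z, d1 = integrated_depth_dose(pencil_plan, reference_scene, beamline,
                                      modulator=rm2d_step, transform=t,
                                      curve=curve250, sampling=s)
        sel = (z >= prox + 3.0) & (z <= distal - 3.0)
        dev = np.abs(d1[sel] / d1[sel].mean() - d0[sel] / d0[sel].mean())
        assert dev.max() < 0.002

    def test_mesh_path_matches_analytic(self, pencil_plan, reference_scene,
                                        beamline, curve250):
        # identity-transformed mesh route vs the analytic solid route
        from rm3d.sobp_design import WeightVector, weights_to_step_contour

        w = WeightVector(np.array([0.0, 3.0]), np.array([0.6, 0.4]))
        pin = weights_to_step_contour(w, 3.0, RIGUR)
        mod = uniform_modulator(pin, n_cells=7)
        mesh = tessellate(mod)
        xs, ys, h_mesh = heightfield_of(mesh, 0.02)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        h_ana = mod.column_height(gx.ravel(), gy.ravel()).reshape(gx.shape)
        s = Sampling(samples_per_cell=24, wet_bin_mm=0.5,
                     fluence_res_mm=0.5, lateral_half_mm=30.0)
        d_mesh = compute_dose(pencil_plan, reference_scene, beamline,
                              modulator=mod, heightfield=(xs, ys, h_mesh),
                              curve=curve250, sampling=s)
        d_ana = compute_dose(pencil_plan, reference_scene, beamline,
                             modulator=mod, heightfield=(xs, ys, h_ana),
                             curve=curve250, sampling=s)
        level = 0.2 * d_ana.values.max()
        sel = d_ana.values >= level
        rel = np.abs(d_mesh.values[sel] - d_ana.values[sel]) \
            / d_ana.values.max()
        assert rel.max() < 0.005


class TestFluence:
    def test_cov_drops_behind_absorber(self, reference_scene, beamline,
                                       rm2d_step):
        plan = uniform_field_plan((30.0, 30.0), 5.0, 1.0)
        s = Sampling(samples_per_cell=24, fluence_res_mm=0.5,
                     lateral_half_mm=40.0)
        at_rm = score_fluence(plan, reference_scene, beamline,
                              plane="absorber_entrance", modulator=rm2d_step,
                              sampling=s)
        at_wp = score_fluence(plan, reference_scene, beamline,
                              plane="phantom_surface", modulator=rm2d_step,
                              sampling=s)
        cov_rm = fluence_cov(at_rm, 10.0)
        cov_wp = fluence_cov(at_wp, 10.0)
        assert cov_rm > 0.1
        assert cov_rm >= 5.0 * cov_wp

    def test_no_modulator_smooth_everywhere(self, reference_scene, beamline):
        plan = uniform_field_plan((30.0, 30.0), 5.0, 1.0)
        s = Sampling(fluence_res_mm=0.5, lateral_half_mm=40.0)
        for plane in ("absorber_entrance", "phantom_surface"):
            fm = score_fluence(plan, reference_scene, beamline, plane=plane,
                               sampling=s)
            assert fluence_cov(fm, 10.0) < 0.1

    def test_plane_outside_geometry_rejected(self, reference_scene,
                                             beamline):
        plan = uniform_field_plan((10.0, 10.0), 5.0, 1.0)
        with pytest.raises(ValueError):
            score_fluence(plan, reference_scene, beamline, plane=50.0)


class TestProfilesAndIO:
    def test_sobp_profile_identity_on_separable_dose(self):
        x = np.arange(-10, 11, 2.5)
        z = np.arange(0.5, 50.0, 1.0)
        depth_curve = np.exp(-((z - 30) / 10.0) ** 2)
        vals = np.ones((x.size, x.size, 1)) * depth_curve[None, None, :]
        d = DoseGrid(x, x.copy(), z, vals)
        assert np.allclose(sobp_profile(d), depth_curve)

    def test_window_average(self):
        x = np.arange(-5, 6, 2.5)
        z = np.arange(0.5, 10.0, 1.0)
        rng = np.random.default_rng(3)
        vals = rng.random((x.size, x.size, z.size))
        d = DoseGrid(x, x.copy(), z, vals)
        ix = np.argmin(np.abs(x))
        expected = vals[ix - 1:ix + 2, ix - 1:ix + 2, :].mean(axis=(0, 1))
        assert np.allclose(sobp_profile(d, window_voxels=3), expected)

    def test_hdf5_round_trip(self, baseline_dose, tmp_path):
        path = tmp_path / "dose.h5"
        baseline_dose.to_hdf5(path)
        back = DoseGrid.from_hdf5(path)
        assert np.array_equal(back.values, baseline_dose.values)
        assert np.array_equal(back.depth_mm, baseline_dose.depth_mm)

    def test_csv_slice_export(self, baseline_dose, tmp_path):
        import pandas as pd

        path = tmp_path / "slice.csv"
        baseline_dose.slice_to_csv(100.0, path)
        df = pd.read_csv(path, index_col=0)
        assert df.shape == baseline_dose.depth_slice(100.0).shape

    def test_depth_slice_out_of_range(self, baseline_dose):
        with pytest.raises(ValueError):
            baseline_dose.depth_slice(1000.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseGrid(np.array([0.0]), np.array([0.0]), np.array([0.5]),
                     -np.ones((1, 1, 1)))
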