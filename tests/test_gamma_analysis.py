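import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from rm3d.dose_engine import DoseGrid
from rm3d.gamma_analysis import (GammaCriteria, gamma_index, gamma_nd,
                                 gamma_slices, report_table, sobp_metrics)


def brute_force_gamma(ref, ev, spacing, crit):
    """Independent dense-search oracle: per-voxel full scan, no shortcuts."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    spacing = np.broadcast_to(np.asarray(spacing, float), (ref.ndim,))
    axes = [np.arange(n) * s for n, s in zip(ref.shape, spacing)]
    interp = RegularGridInterpolator(axes, ev, bounds_error=False,
                                     fill_value=None)
    step = crit.search_step_fraction * crit.dta_mm
    radius = crit.search_radius_factor * crit.dta_mm
    off_1d = np.arange(-radius, radius + step / 2, step)
    mesh = np.meshgrid(*([off_1d] * ref.ndim), indexing="ij")
    offsets = np.stack([m.ravel() for m in mesh], axis=1)
    offsets = offsets[(offsets**2).sum(1) <= radius**2 + 1e-9]

    thr = crit.low_dose_threshold * ref.max()
    gammas = []
    for vox in np.argwhere(ref >= thr):
        pos = vox * spacing
        pts = np.clip(pos + offsets, 0, [a[-1] for a in axes])
        dose_term = (interp(pts) - ref[tuple(vox)]) \
            / (crit.dose_criterion * ref[tuple(vox)])
        # spatial term uses the clipped (actually sampled) displacement
        disp = pts - pos
        g2 = (disp**2).sum(1) / crit.dta_mm**2 + dose_term**2
        gammas.append(np.sqrt(g2.min()))
    return np.array(gammas)


@pytest.fixture
def smooth_pair():
    """A smooth field whose above-threshold region is interior."""
    x = np.arange(41.0)
    ref = np.exp(-((x[:, None] - 20) ** 2 + (x[None, :] - 20) ** 2)
                 / (2 * 7.0**2))
    return ref


class TestGammaBasics:
    def test_identity_passes_everywhere(self, smooth_pair):
        res = gamma_nd(smooth_pair, smooth_pair, 1.0)
        assert res.passing_rate == 100.0
        assert np.nanmax(res.gamma_map) < 1e-6

    def test_shift_below_dta_passes(self, smooth_pair):
        x = np.arange(41.0)
        ev = np.exp(-((x[:, None] - 21) ** 2 + (x[None, :] - 20) ** 2)
                    / (2 * 7.0**2))
        res = gamma_nd(smooth_pair, ev, 1.0)
        assert res.passing_rate == 100.0

    def test_uniform_scaling_fails_locally(self):
        # no spatial rescue on a uniform field: gamma = 5% / 2% = 2.5
        ref = np.ones((15, 15))
        res = gamma_nd(ref, 1.05 * ref, 1.0)
        assert res.passing_rate == 0.0
        assert np.allclose(res.gamma_map, 2.5, atol=1e-9)

    def test_scale_invariance_of_local_gamma(self, smooth_pair):
        ev = np.roll(smooth_pair, 1, axis=0)
        r1 = gamma_nd(smooth_pair, ev, 1.0)
        r2 = gamma_nd(7.3 * smooth_pair, 7.3 * ev, 1.0)
        assert np.allclose(r1.gamma_map, r2.gamma_map, atol=1e-9,
                           equal_nan=True)

    def test_passing_rate_monotone_in_criteria(self, smooth_pair):
        ev = 1.015 * np.roll(smooth_pair, 2, axis=0)
        rates = []
        for dd, dta in [(0.03, 3.0), (0.02, 2.0), (0.01, 1.0)]:
            crit = GammaCriteria(dose_criterion=dd, dta_mm=dta)
            rates.append(gamma_nd(smooth_pair, ev, 1.0, crit).passing_rate)
        assert rates[0] >= rates[1] >= rates[2]

    def test_all_below_threshold_rejected(self):
        ref = np.ones((5, 5))
        with pytest.raises(ValueError):
            gamma_nd(0 * ref, ref, 1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.random((12, 12))
        from scipy.ndimage import gaussian_filter

        ref = gaussian_filter(base, 2.0) + 0.3
        ev = ref * (1 + 0.03 * gaussian_filter(rng.standard_normal((12, 12)),
                                               1.5))
        crit = GammaCriteria(search_step_fraction=0.25)
        fast = gamma_nd(ref, ev, 1.0, crit)
        slow = brute_force_gamma(ref, ev, 1.0, crit)
        assert np.allclose(fast.gamma_map[~np.isnan(fast.gamma_map)], slow,
                           atol=0.01)

    def test_matches_brute_force_3d(self):
        rng = np.random.default_rng(42)
        from scipy.ndimage import gaussian_filter

        ref = gaussian_filter(rng.random((8, 8, 8)), 1.5) + 0.4
        ev = np.roll(ref, 1, axis=2) * 1.01
        crit = GammaCriteria(search_step_fraction=0.5,
                             search_radius_factor=2.0)
        fast = gamma_nd(ref, ev, 1.0, crit)
        slow = brute_force_gamma(ref, ev, 1.0, crit)
        assert np.allclose(fast.gamma_map[~np.isnan(fast.gamma_map)], slow,
                           atol=0.01)


class TestSlices:
    def _grid(self, values):
        nx, ny, nz = values.shape
        return DoseGrid((np.arange(nx) - nx / 2) * 2.5,
                        (np.arange(ny) - ny / 2) * 2.5,
                        np.arange(nz) + 0.5, values)

    def test_identical_slices_pass(self):
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter

        v = gaussian_filter(rng.random((21, 21, 30)), 2.0) + 0.2
        d = self._grid(v)
        out = gamma_slices(d, self._grid(v.copy()), (10.0, 20.0))
        assert out[10.0].passing_rate == 100.0
        assert out[20.0].passing_rate == 100.0

    def test_slice_matches_2d_gamma(self):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter

        v = gaussian_filter(rng.random((21, 21, 30)), 2.0) + 0.2
        w = v * (1 + 0.02 * gaussian_filter(rng.standard_normal(v.shape),
                                            2.0))
        a, b = self._grid(v), self._grid(w)
        out = gamma_slices(a, b, (15.0,))
        direct = gamma_nd(a.depth_slice(15.0), b.depth_slice(15.0),
                          (2.5, 2.5))
        assert out[15.0].passing_rate == direct.passing_rate

    def test_depth_outside_grid_rejected(self):
        v = np.ones((5, 5, 10))
        d = self._grid(v)
        with pytest.raises(ValueError):
            gamma_slices(d, d, (500.0,))

    def test_mismatched_frames_rejected(self):
        v = np.ones((5, 5, 10))
        a = self._grid(v)
        b = DoseGrid(a.x_mm + 1.0, a.y_mm, a.depth_mm, v)
        with pytest.raises(ValueError):
            gamma_slices(a, b, (5.0,))


class TestSobpMetrics:
    def test_profile_vs_itself(self):
        z = np.arange(0.0, 100.0)
        p = np.ones(100)
        m = sobp_metrics(p, z, (10.0, 90.0), p)
        assert m["flatness_pct"] == 0.0
        assert m["max_deviation_pct"] == 0.0

    def test_constant_offset(self):
        z = np.arange(0.0, 50.0)
        m = sobp_metrics(np.full(50, 1.002), z, (5.0, 45.0),
                         np.full(50, 1.000))
        # both normalized to their plateau means: identical shapes
        assert m["max_deviation_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_flatness_against_manual_oracle(self):
        rng = np.random.default_rng(5)
        z = np.arange(0.0, 80.0)
        p = 1.0 + 0.01 * rng.standard_normal(80)
        sel = (z >= 10) & (z <= 70)
        expected = 100 * np.max(np.abs(p[sel] - p[sel].mean())) \
            / p[sel].mean()
        m = sobp_metrics(p, z, (10.0, 70.0))
        assert m["flatness_pct"] == pytest.approx(expected)

    def test_plateau_outside_profile_rejected(self):
        with pytest.raises(ValueError):
            sobp_metrics(np.ones(10), np.arange(10.0), (50.0, 60.0))


class TestReportTable:
    def test_rounded_table(self, tmp_path):
        from rm3d.gamma_analysis import GammaResult

        rows = [{"name": "a",
                 "proximal": GammaResult(np.array([0.5]), 99.4, 1),
                 "distal": GammaResult(np.array([0.5]), 72.6, 1)}]
        df = report_table(rows, tmp_path / "t.csv")
        assert df.loc[0, "proximal_gi_pct"] == 99
        assert df.loc[0, "distal_gi_pct"] == 73
        assert (tmp_path / "t.csv").exists()
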