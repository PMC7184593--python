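import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from pmbrt import synthetic as syn
from pmbrt.fractionation import find_peaks_prominence, pvdr_at_depth
from pmbrt.grids import Profile

from conftest import gaussian_profile_array


class TestPristineBragg:
    @pytest.mark.parametrize("range_mm", [50.0, 90.0, 150.0])
    def test_peak_position_and_shape(self, range_mm):
        z = np.arange(0.0, range_mm + 30.0, 0.05)
        curve = syn.pristine_bragg(range_mm, z)
        peak = z[np.argmax(curve.dose)]
        assert abs(peak - range_mm) <= 0.5
        ratio = curve.dose[0] / curve.dose.max()
        assert 0.2 <= ratio <= 0.5
        distal = curve.dose[np.searchsorted(z, range_mm + 10.0)]
        assert distal < 0.01 * curve.dose.max()

    def test_integral_matches_quadrature(self):
        # trapezoid on the sampled curve vs adaptive quadrature of the form
        z = np.arange(0.0, 120.0, 0.02)
        curve = syn.pristine_bragg(90.0, z)
        sampled = np.trapezoid(curve.dose, z)
        exact, _ = quad(lambda t: syn.pristine_bragg_form(t, 90.0),
                        0.0, 120.0, limit=200)
        assert sampled == pytest.approx(exact, rel=1e-3)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.pristine_bragg(-5.0, np.arange(0.0, 10.0))


class TestSOBP:
    def test_single_layer_is_pristine(self):
        z = np.arange(0.0, 120.0, 0.1)
        one = syn.build_sobp([(90.0, 1.0)], z)
        np.testing.assert_array_equal(one.dose,
                                      syn.pristine_bragg(90.0, z).dose)

    def test_linearity_in_weights(self):
        z = np.arange(0.0, 120.0, 0.1)
        split = syn.build_sobp([(90.0, 0.3), (90.0, 0.7)], z)
        whole = syn.build_sobp([(90.0, 1.0)], z)
        np.testing.assert_allclose(split.dose, whole.dose, rtol=1e-12)

    def test_empty_layers_and_negative_weight_rejected(self):
        z = np.arange(0.0, 50.0)
        with pytest.raises(syn.ConfigError):
            syn.build_sobp([], z)
        with pytest.raises(syn.ConfigError):
            syn.build_sobp([(40.0, -1.0)], z)

    def test_single_range_weight_one(self):
        w, _ = syn.optimize_sobp_weights([90.0], (89.0, 91.0))
        assert w.tolist() == [1.0]

    def test_permuting_ranges_permutes_weights(self):
        ranges = [80.0, 84.0, 88.0, 92.0, 96.0]
        w, _ = syn.optimize_sobp_weights(ranges, (82.0, 94.0))
        w2, _ = syn.optimize_sobp_weights(ranges[::-1], (82.0, 94.0))
        np.testing.assert_allclose(w, w2[::-1], atol=1e-12)

    def test_optimized_flatter_than_equal_weights(self):
        ranges = np.arange(70.0, 100.1, 2.0)
        band = (72.0, 97.0)
        weights, ripple = syn.optimize_sobp_weights(ranges, band)
        assert ripple <= 0.03
        z = np.linspace(band[0], band[1], 256)
        equal = syn.build_sobp(np.column_stack(
            [ranges, np.full(ranges.size, 1.0 / ranges.size)]), z)
        assert ripple < syn.sobp_ripple(equal, band)

    def test_band_outside_ranges_rejected(self):
        with pytest.raises(syn.ConfigError):
            syn.optimize_sobp_weights([50.0, 55.0], (70.0, 90.0))


class TestLateralProfile:
    def test_single_slit_fwhm(self):
        cfg = syn.MinibeamPlanConfig(
            ctc=4.0, n_slits=1, halo_fraction_model=0.0,
            fwhm_model=[[0.0, 2.0], [200.0, 2.0]])
        x = np.arange(-10.0, 10.001, 0.05)
        y = syn.lateral_minibeam_profile(x, 50.0, cfg)
        ps = find_peaks_prominence(Profile(x, y))
        assert ps.n_peaks == 1
        assert ps.fwhm == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("ctc,expected_valley", [
        (4.0, 2.0 * 2.0**-4),       # half-spacing Gaussian tails
        (6.0, 2.0 * 2.0**-9),
    ])
    def test_closed_form_valley(self, ctc, expected_valley):
        x, y = gaussian_profile_array(ctc=ctc, n_slits=9, fwhm=2.0)
        mid = np.argmin(np.abs(x - ctc / 2.0))   # central inter-peak valley
        centre = np.argmin(np.abs(x))
        assert y[mid] / y[centre] == pytest.approx(expected_valley, rel=1e-3)

    def test_interior_periodicity(self):
        x, y = gaussian_profile_array(ctc=4.0, n_slits=9, fwhm=2.0)
        shift = int(round(4.0 / 0.05))
        inner = slice(2 * shift, y.size - 3 * shift)
        np.testing.assert_allclose(y[inner], y[inner.start + shift:
                                               inner.stop + shift], atol=1e-6)

    def test_depth_outside_model_domain(self):
        cfg = syn.MinibeamPlanConfig(fwhm_model=[[0.0, 1.0], [100.0, 2.0]])
        with pytest.raises(syn.ConfigError):
            syn.lateral_minibeam_profile(np.arange(-5.0, 5.0), 150.0, cfg)

    @given(fwhm=st.floats(0.5, 3.0), ctc_lo=st.floats(2.0, 7.0),
           delta=st.floats(0.1, 3.0))
    def test_peak_valley_ratio_monotone_in_ctc(self, fwhm, ctc_lo, delta):
        """Wider slit spacing never decreases the analytic peak/valley ratio."""
        def ratio(ctc):
            cfg = syn.MinibeamPlanConfig(
                ctc=ctc, n_slits=9, halo_fraction_model=0.0,
                fwhm_model=[[0.0, fwhm], [200.0, fwhm]])
            peak = syn.lateral_minibeam_profile(np.array([0.0]), 50.0, cfg)[0]
            valley = syn.lateral_minibeam_profile(
                np.array([ctc / 2.0]), 50.0, cfg)[0]
            return peak / valley

        assert ratio(ctc_lo + delta) >= ratio(ctc_lo) * (1 - 1e-9)


class TestGeneratedFields:
    def test_same_seed_reproducible(self, small_grid):
        cfg = syn.MinibeamPlanConfig(noise_rel=0.03, seed=42,
                                     target_band=(75.0, 95.0))
        d1, l1 = syn.generate_pmbrt_dose(cfg, small_grid)
        d2, l2 = syn.generate_pmbrt_dose(cfg, small_grid)
        np.testing.assert_array_equal(d1.values, d2.values)
        np.testing.assert_array_equal(l1.values, l2.values)
        d3, _ = syn.generate_pmbrt_dose(
            dataclasses.replace(cfg, seed=43), small_grid)
        assert not np.array_equal(d1.values, d3.values)

    def test_single_slit_separability(self, small_grid):
        # without halo or noise the central line is proportional to the SOBP
        cfg = syn.MinibeamPlanConfig(n_slits=1, halo_fraction_model=0.0,
                                     target_band=(75.0, 95.0))
        dose, _ = syn.generate_pmbrt_dose(cfg, small_grid)
        ix = int(np.argmin(np.abs(small_grid.positions(0))))
        line = dose.values[ix, 2, :]
        sobp = syn.build_sobp(syn.default_sobp_layers((75.0, 95.0)),
                              small_grid.positions(2)).dose
        np.testing.assert_allclose(line / line.max(), sobp / sobp.max(),
                                   rtol=1e-9)

    def test_peak_line_normalisation(self, glioma_field, glioma_cfg):
        dose, _ = glioma_field
        x = dose.positions(0)
        ix = int(np.argmin(np.abs(x)))
        z = dose.positions(2)
        band = (z >= glioma_cfg.target_band[0]) & (z <= glioma_cfg.target_band[1])
        mean_peak = dose.values[ix, dose.values.shape[1] // 2, band].mean()
        assert mean_peak == pytest.approx(100.0, abs=0.1)

    def test_measured_fwhm_nondecreasing_with_depth(self):
        cfg = syn.MinibeamPlanConfig(
            ctc=4.0, n_slits=9, halo_fraction_model=0.0,
            fwhm_model=[[0.0, 0.7], [20.0, 0.9], [40.0, 1.2], [60.0, 1.7],
                        [200.0, 2.2]])
        x = np.arange(-18.0, 18.001, 0.02)
        widths = []
        for depth in (1.0, 20.0, 40.0, 60.0, 120.0):
            y = syn.lateral_minibeam_profile(x, depth, cfg)
            widths.append(find_peaks_prominence(Profile(x, y)).fwhm)
        assert np.all(np.diff(widths) >= -1e-6)

    def test_fwhm_consistent_with_depth_model(self, glioma_field):
        # beam size at 40 mm depth ~1.2 mm, within one lattice step
        dose, _ = glioma_field
        ps = pvdr_at_depth(dose, 40.0, slab_voxels=3, interior_only=True)
        assert ps.fwhm == pytest.approx(1.2, abs=0.5)

    def test_let_contrast_valley_vs_peak(self, glioma_field):
        # valleys see only scattered particles: LET 1-3 keV/um above peaks
        dose, let = glioma_field
        from pmbrt.grids import depth_to_index
        kz = depth_to_index(dose, 30.0)
        x = dose.positions(0)
        peak = let.values[np.argmin(np.abs(x)), 4, kz]
        valley = let.values[np.argmin(np.abs(x - 2.0)), 4, kz]
        assert 1.0 <= valley - peak <= 3.0


class TestSeamless:
    def test_central_region_flat(self, small_grid):
        cfg = syn.MinibeamPlanConfig(target_band=(75.0, 95.0))
        dose = syn.generate_seamless_dose(cfg, small_grid)
        x = small_grid.positions(0)
        central = np.abs(x) <= 8.0
        lateral = dose.values[central, 2, 100]
        assert lateral.std() / lateral.mean() < 0.005

    def test_both_arms_share_normalisation(self, small_grid):
        cfg = syn.MinibeamPlanConfig(target_band=(75.0, 95.0),
                                     halo_fraction_model=0.0)
        mb, _ = syn.generate_pmbrt_dose(cfg, small_grid)
        bb = syn.generate_seamless_dose(cfg, small_grid)
        z = small_grid.positions(2)
        band = (z >= 75.0) & (z <= 95.0)
        ix = int(np.argmin(np.abs(small_grid.positions(0))))
        assert mb.values[ix, 2, band].mean() == pytest.approx(100.0, abs=0.1)
        assert bb.values[ix, 2, band].mean() == pytest.approx(100.0, abs=0.1)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"ctc": 0.0},
        {"n_slits": 0},
        {"fwhm_model": [[0.0, 2.0], [100.0, 1.0]]},   # decreasing
        {"fwhm_model": [[0.0, -1.0], [100.0, 1.0]]},
        {"halo_fraction_model": 1.0},
        {"noise_rel": -0.1},
        {"sobp_layers": [[90.0, -2.0]]},
        {"target_band": (50.0, 40.0)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(syn.ConfigError):
            syn.MinibeamPlanConfig(**kwargs)

    def test_bundled_configs_load(self):
        for name in ("glioma_field2_ctc4", "glioma_field2_ctc6",
                     "meningioma_field1_ctc4", "meningioma_field1_ctc6"):
            cfg = syn.MinibeamPlanConfig.bundled(name)
            assert cfg.name == name
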