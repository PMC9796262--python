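"""SXRF calibration, attenuation physics and map quantification."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from enamelkit.sxrf import (ElementMap, FoilStandard, MatrixModel,
                            PHASE_BACKGROUND, PHASE_ENAMEL,
                            SensitivityCurve, attenuation_factor,
                            calibrate_sensitivity, denoise_map,
                            phase_summary, quantify_map)
from enamelkit.synthetic import (SectionConfig, forward_xrf_counts,
                                 generate_section)
from enamelkit.xraydata import KALPHA_KEV, matrix_mass_attenuation


def quadrature_attenuation(line_energy, matrix, phase):
    """Independent oracle: numeric average of exp(-chi rho z) over depth."""
    mu_in = matrix_mass_attenuation(matrix.incident_energy_kev)
    mu_out = matrix_mass_attenuation(line_energy)
    chi = mu_in / math.sin(math.radians(matrix.psi_in_deg)) \
        + mu_out / math.sin(math.radians(matrix.psi_out_deg))
    rho = matrix.density(phase)
    t = matrix.thickness_um * 1e-4
    val, _ = quad(lambda z: math.exp(-chi * rho * z), 0.0, t)
    return val / t


class TestSensitivity:
    def test_counts_over_areal_density(self):
        curve = calibrate_sensitivity(
            [FoilStandard("Ti", 59.0, 118.0)])
        assert curve("Ti") == (pytest.approx(2.0), False)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            calibrate_sensitivity([FoilStandard("Ti", 59.0, 0.0)])

    def test_log_linear_interpolation_between_anchors(self):
        # anchors exactly log-linear in energy -> interior query exact
        a, b = 0.4, 0.12
        foils = [FoilStandard(el, 50.0,
                              50.0 * math.exp(a + b * KALPHA_KEV[el]))
                 for el in ("Ti", "Cu")]
        curve = calibrate_sensitivity(foils)
        got, extrapolated = curve("Fe")
        assert got == pytest.approx(math.exp(a + b * KALPHA_KEV["Fe"]))
        assert not extrapolated

    def test_extrapolation_is_flagged(self):
        curve = calibrate_sensitivity(
            [FoilStandard("Ti", 59.0, 118.0), FoilStandard("Cu", 47.9, 95.8)])
        for el in ("Ca", "Sr"):  # below Ti, above Cu line energies
            _, extrapolated = curve(el)
            assert extrapolated

    def test_unknown_element_rejected(self):
        curve = calibrate_sensitivity([FoilStandard("Ti", 59.0, 118.0)])
        with pytest.raises(ValueError):
            curve("Xx")


class TestAttenuationFactor:
    matrix = MatrixModel(thickness_um=160.0)

    def test_thin_sample_limit(self):
        thin = MatrixModel(thickness_um=1e-6)
        assert attenuation_factor(8.0478, thin, "enamel") == \
            pytest.approx(1.0, abs=1e-6)

    def test_unit_optical_depth_closed_form(self):
        # choose thickness so that chi*rho*t = 1 exactly
        mu_in = matrix_mass_attenuation(16.6)
        mu_out = matrix_mass_attenuation(8.0478)
        chi = mu_in / 1.0 + mu_out / math.sin(math.radians(45.0))
        t_cm = 1.0 / (chi * 2.85)
        m = MatrixModel(thickness_um=t_cm * 1e4)
        assert attenuation_factor(8.0478, m, "enamel") == \
            pytest.approx(1.0 - math.exp(-1.0), rel=1e-9)

    @pytest.mark.parametrize("energy", [3.6917, 6.4039, 8.6389, 14.165])
    @pytest.mark.parametrize("phase", ["enamel", "dentin"])
    def test_matches_quadrature_oracle(self, energy, phase):
        a = attenuation_factor(energy, self.matrix, phase)
        assert a == pytest.approx(
            quadrature_attenuation(energy, self.matrix, phase), abs=1e-10)
        assert 0.0 < a <= 1.0

    def test_monotone_decreasing_in_thickness(self):
        factors = [attenuation_factor(8.6389, MatrixModel(thickness_um=t),
                                      "enamel") for t in (10, 60, 160, 400)]
        assert all(b < a for a, b in zip(factors, factors[1:]))

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            attenuation_factor(8.0478, self.matrix, "bone")


class TestQuantifyMap:
    matrix = MatrixModel(thickness_um=160.0)

    def _curve(self, element, sens):
        return SensitivityCurve(anchors=((element, KALPHA_KEV[element], sens),))

    def test_uniform_ca_round_trip(self, noiseless_section):
        """Forward model then quantification recovers 4.0e5 ppm Ca."""
        truth = noiseless_section.element_maps["Ca"]
        counts = forward_xrf_counts(truth, 2.0, self.matrix)
        ppm, _, _ = quantify_map(counts, self._curve("Ca", 2.0), self.matrix)
        enamel = ppm.grid[truth.phase_mask == PHASE_ENAMEL]
        assert np.allclose(enamel, 4.0e5, rtol=1e-3)
        summary = phase_summary(ppm)
        assert summary["enamel"]["mean"] == pytest.approx(4.0e5, rel=1e-3)

    def test_zn_surface_peak_recovered(self, noiseless_section):
        cfg = noiseless_section.config
        truth = noiseless_section.element_maps["Zn"]
        counts = forward_xrf_counts(truth, 1.7, self.matrix)
        ppm, _, _ = quantify_map(counts, self._curve("Zn", 1.7), self.matrix)
        peak = ppm.grid[truth.phase_mask == PHASE_ENAMEL].max()
        assert peak == pytest.approx(cfg.zn_surface_peak_ppm, rel=0.02)

    def test_background_pixels_are_zero(self, noiseless_section):
        truth = noiseless_section.element_maps["Sr"]
        counts = forward_xrf_counts(truth, 2.0, self.matrix)
        ppm, _, _ = quantify_map(counts, self._curve("Sr", 2.0), self.matrix)
        assert np.all(ppm.grid[truth.phase_mask == PHASE_BACKGROUND] == 0.0)

    def test_linearity_in_concentration(self, noiseless_section):
        truth = noiseless_section.element_maps["Sr"]
        counts1 = forward_xrf_counts(truth, 2.0, self.matrix)
        doubled = ElementMap(element="Sr", grid=truth.grid * 2,
                             pixel_size_um=truth.pixel_size_um,
                             units_state="ppm", phase_mask=truth.phase_mask)
        counts2 = forward_xrf_counts(doubled, 2.0, self.matrix)
        curve = self._curve("Sr", 2.0)
        ppm1, _, _ = quantify_map(counts1, curve, self.matrix)
        ppm2, _, _ = quantify_map(counts2, curve, self.matrix)
        sel = truth.phase_mask > 0
        assert np.allclose(ppm2.grid[sel], 2 * ppm1.grid[sel], rtol=1e-9)

    def test_zero_flux_pixels_masked_not_nan(self):
        grid = np.full((4, 4), 100.0)
        mask = np.full((4, 4), PHASE_ENAMEL)
        raw = ElementMap("Zn", grid, 2.0, "counts", mask)
        flux = np.ones((4, 4))
        flux[1, 1] = 0.0
        ppm, _, info = quantify_map(raw, self._curve("Zn", 2.0), self.matrix,
                                    flux_map=flux)
        assert info["masked_pixels"] == 1
        assert ppm.grid[1, 1] == 0.0
        assert np.isfinite(ppm.grid).all()

    def test_negative_after_background_clipped(self):
        grid = np.full((3, 3), 5.0)
        mask = np.full((3, 3), PHASE_ENAMEL)
        raw = ElementMap("Zn", grid, 2.0, "counts", mask)
        ppm, _, info = quantify_map(raw, self._curve("Zn", 2.0), self.matrix,
                                    background=10.0)
        assert info["clipped_pixels"] == 9
        assert np.all(ppm.grid == 0.0)


class TestDenoise:
    def test_constant_map_unchanged(self):
        emap = ElementMap("Sr", np.full((20, 20), 7.0), 2.0, "ppm")
        out = denoise_map(emap)
        assert np.allclose(out.grid, 7.0, atol=1e-12)

    def test_impulse_mass_preserved(self):
        grid = np.zeros((41, 41))
        grid[20, 20] = 1.0
        out = denoise_map(ElementMap("Sr", grid, 2.0, "ppm"),
                          kernel_sigma=0.8)
        assert out.grid.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.grid.mean() == pytest.approx(grid.mean(), abs=1e-9)
        assert out.grid[20, 20] == out.grid.max()

    def test_band_positions_stable_under_smoothing(self, default_section):
        emap = default_section.element_maps["Sr"]
        row = emap.grid[60]
        smoothed = denoise_map(emap, kernel_sigma=0.8).grid[60]
        assert abs(int(np.argmax(row)) - int(np.argmax(smoothed))) <= 1

    def test_nonpositive_sigma_rejected(self):
        emap = ElementMap("Sr", np.zeros((4, 4)), 2.0, "ppm")
        with pytest.raises(ValueError):
            denoise_map(emap, kernel_sigma=0.0)
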