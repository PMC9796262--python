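"""Synthetic section generator: geometry, banding, foils, determinism."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from enamelkit.sxrf import PHASE_DENTIN, calibrate_sensitivity
from enamelkit.synthetic import (SectionConfig, SrEventSpec, day_to_distance,
                                 distance_to_day, generate_foil_standards,
                                 generate_section, _increment_positions)


def oracle_day_to_distance(cfg: SectionConfig, t_query):
    """Independent day->distance map: cumulative trapezoid of the DSR.

    Integrates t(s) = int ds/r(s) on a fine distance grid and inverts by
    interpolation; knows nothing of the closed form used by the package.
    """
    a, m = cfg._gradient
    s = np.linspace(0.0, cfg.cuspal_thickness_um, 400_001)
    t = cumulative_trapezoid(1.0 / (a + m * s), s, initial=0.0)
    return np.interp(t_query, t, s)


class TestDayDistanceMaps:
    def test_uniform_rate_gives_uniform_increments(self):
        cfg = SectionConfig(dsr_inner=2.0, dsr_outer=2.0, noise_sd=0.0)
        pos = _increment_positions(cfg)
        assert np.allclose(np.diff(pos), 2.0)
        # striae (every 8th increment) fall every 16 um
        assert np.allclose(pos[::8][:5], [0, 16, 32, 48, 64])

    def test_maps_match_trapezoid_oracle(self):
        cfg = SectionConfig(noise_sd=0.0)
        days = np.linspace(0.0, cfg.total_cuspal_days, 50)
        assert np.allclose(day_to_distance(cfg, days),
                           oracle_day_to_distance(cfg, days), atol=5e-3)

    def test_maps_mutually_inverse(self):
        cfg = SectionConfig(noise_sd=0.0)
        s = np.linspace(0.0, cfg.cuspal_thickness_um, 37)
        back = day_to_distance(cfg, distance_to_day(cfg, s))
        assert np.allclose(back, s, atol=1e-9)


class TestGroundTruthChronology:
    def test_hand_computed_sums(self, noiseless_section):
        chron = noiseless_section.ground_truth.chronology
        assert chron.deciles12_days == 52
        assert sum(chron.per_decile_days[2:]) == 712
        assert chron.lateral_days == 764
        assert chron.total_days == chron.cuspal_days + 764

    def test_zone_rates_span_configured_gradient(self, noiseless_section):
        rates = noiseless_section.ground_truth.zone_mean_rates
        cfg = noiseless_section.config
        assert rates[0] == pytest.approx(cfg.dsr_inner, rel=0.02)
        assert rates[-1] == pytest.approx(cfg.dsr_outer, rel=0.02)
        assert all(b > a for a, b in zip(rates, rates[1:]))


class TestSrBands:
    def test_band_count_and_positions_vs_oracle(self, noiseless_section):
        """Each configured event paints one band whose edges match the
        independent trapezoid integration of the DSR."""
        sec = noiseless_section
        cfg = sec.config
        profile = sec.midline_transect("Sr")
        base = cfg.sr_baseline_ppm
        on = np.abs(profile.values_ppm - base) > 1.0
        # count maximal runs
        edges = np.flatnonzero(np.diff(on.astype(int)))
        n_bands = (len(edges) + (1 if on[0] else 0) + (1 if on[-1] else 0)) // 2
        assert n_bands == len(cfg.sr_event_spec) == 8
        px = cfg.pixel_size_um
        starts = profile.positions_um[np.flatnonzero(np.diff(on.astype(int)) == 1) + 1]
        for (lbl, onset, dur), s_det in zip(sec.ground_truth.event_days, starts):
            s_true = oracle_day_to_distance(cfg, onset)
            assert abs(s_det - s_true) <= px + 1e-6

    def test_banding_imprinted_in_dentin(self, noiseless_section):
        sr = noiseless_section.ground_truth.element_fields["Sr"]
        mask = noiseless_section.element_maps["Sr"].phase_mask
        dentin_vals = sr[mask == PHASE_DENTIN]
        base = noiseless_section.config.sr_baseline_ppm
        assert (dentin_vals > base + 1).any() and (dentin_vals < base - 1).any()

    def test_event_onsets_strictly_increasing(self, noiseless_section):
        onsets = [o for _, o, _ in noiseless_section.ground_truth.event_days]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))


class TestDeterminismAndValidation:
    def test_reproducible_under_fixed_seed(self):
        a = generate_section(SectionConfig(seed=3))
        b = generate_section(SectionConfig(seed=3))
        for el in a.element_maps:
            assert np.array_equal(a.element_maps[el].grid,
                                  b.element_maps[el].grid)
        assert a.tables["spacing"].equals(b.tables["spacing"])

    def test_seed_changes_noise(self):
        a = generate_section(SectionConfig(seed=3))
        b = generate_section(SectionConfig(seed=4))
        assert not np.array_equal(a.element_maps["Sr"].grid,
                                  b.element_maps["Sr"].grid)

    @pytest.mark.parametrize("kwargs", [
        {"dsr_inner": 5.0, "dsr_outer": 2.0},
        {"periodicity_days": 0},
        {"pixel_size_um": 0.0},
        {"decile_stria_counts": (1, 0, 3, 5, 7, 9, 12, 14, 19, 20)},
        {"decile_stria_counts": (0, 0, 3)},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SectionConfig(**kwargs)

    def test_overlapping_events_rejected(self):
        evs = (SrEventSpec(10, 50, 100, "enrich"),
               SrEventSpec(40, 30, 100, "deplete"))
        with pytest.raises(ValueError, match="non-overlapping"):
            SectionConfig(sr_event_spec=evs)

    def test_event_beyond_cuspal_window_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            SectionConfig(sr_event_spec=(SrEventSpec(430, 50, 100, "enrich"),))

    def test_curved_path_lengthens_deciles12(self):
        straight = SectionConfig(noise_sd=0.0)
        curved = SectionConfig(noise_sd=0.0, deciles12_path="curved")
        assert curved.deciles12_length_um > straight.deciles12_length_um


class TestFoilStandards:
    def test_counts_proportional_to_areal_density(self):
        foils = generate_foil_standards(elements=("Ti",),
                                        areal_densities=(59.0,),
                                        sensitivity_truth={"Ti": 1.0})
        assert foils[0].counts == pytest.approx(59.0)

    def test_noiseless_sensitivities_recovered_exactly(self):
        truth = {"Ti": 2.0, "Fe": 2.5, "Cu": 3.0}
        curve = calibrate_sensitivity(generate_foil_standards(
            sensitivity_truth=truth))
        for el, s in truth.items():
            got, extrapolated = curve(el)
            assert got == pytest.approx(s, abs=1e-12)
            assert not extrapolated

    def test_poisson_replicates_recover_sensitivity(self):
        """Monte-Carlo: mean recovered sensitivity within 3 SE of truth."""
        truth = {"Ti": 2.0}
        n = 100
        recovered = []
        for i in range(n):
            foil = generate_foil_standards(
                elements=("Ti",), areal_densities=(59.0,),
                sensitivity_truth=truth, flux=100.0,
                poisson_noise=True, seed=i)[0]
            recovered.append((foil.counts / foil.flux)
                             / foil.areal_density_ug_cm2)
        recovered = np.array(recovered)
        se = recovered.std(ddof=1) / np.sqrt(n)
        assert abs(recovered.mean() - 2.0) < 3 * se

    def test_nonpositive_flux_rejected(self):
        with pytest.raises(ValueError):
            generate_foil_standards(flux=0.0)
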