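"""Forward simulator: elution model, band shapes, detector physics, scenarios."""

import numpy as np
import pytest

import sectd as sd
from sectd.simulate import (
    EffectiveSpecies,
    SIM_GAINS,
    band_profile,
    default_grid,
    detector_signals,
)


class TestElutionModel:
    def test_anchor_masses(self, column):
        assert column.elution_volume(930.0) == pytest.approx(12.0, abs=1e-6)
        assert column.elution_volume(480.0) == pytest.approx(13.5, abs=0.05)

    def test_strictly_decreasing_in_mass(self, column):
        masses = np.linspace(90, 1400, 40)
        ves = [column.elution_volume(m) for m in masses]
        assert all(a > b for a, b in zip(ves[:-1], ves[1:]))

    def test_out_of_range_clipped_with_warning(self, column):
        with pytest.warns(UserWarning):
            ve = column.elution_volume(1e9)
        assert ve == column.volume_range[0]

    def test_free_antibody_elutes_late(self, column):
        assert column.elution_volume(147.0) == pytest.approx(16.25, abs=0.05)


class TestBandProfile:
    def test_area_equals_injected_mass(self):
        grid = default_grid()
        trace = band_profile(0.15, 14.0, 0.35, grid)
        assert np.trapezoid(trace, grid) == pytest.approx(0.15, rel=1e-6)

    def test_linearity_in_mass(self):
        grid = default_grid()
        a = band_profile(0.1, 14.0, 0.35, grid)
        b = band_profile(0.2, 14.0, 0.35, grid)
        assert np.allclose(2 * a, b)

    def test_narrow_band_preserves_area(self):
        grid = default_grid()
        trace = band_profile(0.1, 14.0, 0.05, grid)
        assert np.trapezoid(trace, grid) == pytest.approx(0.1, rel=1e-6)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            band_profile(0.1, 14.0, 0.0, default_grid())


class TestDetectorSignals:
    def _species(self, name="x", mw=147.0, dadc=1.38, visc=6.5):
        return EffectiveSpecies(name, mw, 0.185, dadc, visc)

    def test_linearity_over_mixture(self):
        grid = default_grid()
        sp1, sp2 = self._species("a", 147.0), self._species("b", 86.3, 0.9, 6.5)
        t1 = band_profile(0.1, 16.2, 0.35, grid)
        t2 = band_profile(0.05, 17.5, 0.35, grid)
        mix = detector_signals(grid, [(sp1, t1), (sp2, t2)])
        solo = [detector_signals(grid, [(sp1, t1)]),
                detector_signals(grid, [(sp2, t2)])]
        for ch in sd.CHANNELS:
            assert np.allclose(mix[ch], solo[0][ch] + solo[1][ch])

    def test_single_species_ls_ri_ratio_constant(self):
        grid = default_grid()
        sp = self._species()
        chrom = detector_signals(grid, [(sp, band_profile(0.1, 16.2, 0.35, grid))])
        mask = chrom["RI"] > 0.05 * chrom["RI"].max()
        ratio = chrom["RALS"][mask] / chrom["RI"][mask]
        assert np.allclose(ratio, ratio[0])

    def test_coeluting_ratio_is_weighted_mean(self):
        """LS/RI slice ratio for co-eluting species equals the closed-form
        concentration-weighted mean of Mw * dn/dc over the dn/dc mean."""
        grid = default_grid()
        sp1 = self._species("a", 100.0)
        sp2 = self._species("b", 300.0)
        t1 = band_profile(0.1, 14.0, 0.35, grid)
        t2 = band_profile(0.1, 14.0, 0.35, grid)
        chrom = detector_signals(grid, [(sp1, t1), (sp2, t2)])
        i = np.argmax(chrom["RI"])
        got = chrom["RALS"][i] / chrom["RI"][i]
        c1, c2 = t1[i], t2[i]
        expect = (SIM_GAINS["RALS"] * (c1 * 100 + c2 * 300) * 0.185 ** 2) / (
            SIM_GAINS["RI"] * (c1 + c2) * 0.185)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_zero_concentration_all_zero(self):
        grid = default_grid()
        chrom = detector_signals(grid, [(self._species(), np.zeros_like(grid))])
        for ch in sd.CHANNELS:
            assert np.all(chrom[ch] == 0)

    def test_missing_parameter_names_species(self):
        with pytest.raises(ValueError, match="bad"):
            EffectiveSpecies("bad", 147.0, 0.185, float("nan"), 6.5)

    def test_mass_conservation_through_ri(self, registry):
        """Integral of RI/(k dn/dc) over the run equals injected mass."""
        scen = sd.scenario_case(3)
        chrom, _ = sd.simulate_scenario(scen, registry)
        recovered = np.trapezoid(chrom["RI"], chrom.volume) / (
            SIM_GAINS["RI"] * 0.185)
        assert recovered == pytest.approx(scen.injected_mass_mg, rel=1e-6)


class TestNoise:
    def test_infinite_snr_returns_unchanged(self):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"))
        noisy = sd.add_noise(chrom, sd.NoiseSpec())
        for ch in sd.CHANNELS:
            assert np.array_equal(noisy[ch], chrom[ch])

    def test_same_seed_identical(self):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"))
        a = sd.add_noise(chrom, sd.NoiseSpec(snr=50, seed=3))
        b = sd.add_noise(chrom, sd.NoiseSpec(snr=50, seed=3))
        for ch in sd.CHANNELS:
            assert np.array_equal(a[ch], b[ch])

    def test_sample_sd_matches_request(self):
        grid = np.linspace(8.0, 20.0, 2401)
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"), grid=grid)
        spec = sd.NoiseSpec(snr=100, seed=1)
        noisy = sd.add_noise(chrom, spec)
        for ch in sd.CHANNELS:
            requested = np.max(np.abs(chrom[ch])) / 100
            sample = np.std(noisy[ch] - chrom[ch])
            assert sample == pytest.approx(requested, rel=0.10)

    def test_drift_added(self):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"))
        noisy = sd.add_noise(chrom, sd.NoiseSpec(drift=2.0))
        span = chrom.volume[-1] - chrom.volume[0]
        assert noisy["RI"][-1] - chrom["RI"][-1] == pytest.approx(2.0 * span)


class TestScenarios:
    @pytest.mark.parametrize("case", ["1", "2", "3"])
    def test_fractions_sum_to_one(self, registry, case):
        scen = sd.scenario_case(case, registry)
        assert sum(c.mass_fraction for c in scen.components) == pytest.approx(1.0)

    def test_case3_high_order_budget(self, registry):
        scen = sd.scenario_case(3, registry)
        assert scen.her2_budget["HO(2)"] == pytest.approx(0.30)

    @pytest.mark.parametrize("case", ["1", "2"])
    def test_sequential_cases_high_order_band(self, registry, case):
        ho = sd.scenario_case(case, registry).her2_budget["HO(2)"]
        assert 0.01 <= ho <= 0.03

    def test_antigen_is_quarter_of_mass(self, registry):
        scen = sd.scenario_case(1, registry)
        assert scen.antigen_mass_mg(registry) == pytest.approx(
            0.25 * scen.injected_mass_mg, rel=1e-9)

    def test_unknown_case_rejected(self, registry):
        with pytest.raises(ValueError):
            sd.scenario_case("4", registry)

    def test_ground_truth_sidecar_lists_components(self, registry, column):
        scen = sd.scenario_case(2, registry)
        truth = scen.ground_truth(registry, column)
        labels = {c["label"] for c in truth["components"]}
        assert {"C3", "C2", "HO(2)", "free"} <= labels
        assert truth["mab_her2_mass_ratio"] == 3.0


class TestBsaStandard:
    def test_reference_record(self):
        _, ref = sd.make_bsa_standard()
        assert ref.conc_mg_ml == 2.0
        assert ref.dn_dc == 0.185
        assert ref.da_dc == 0.67

    def test_single_peak_at_calibrated_volume(self, column):
        chrom, ref = sd.make_bsa_standard(column=column)
        apex = chrom.volume[np.argmax(chrom["RI"])]
        assert apex == pytest.approx(column.elution_volume(ref.mw_kda), abs=0.01)


class TestInterdetectorDelaySimulation:
    def test_simulated_delay_recovered_by_apex_matching(self):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"),
                                        delays={"UV280": 0.02})
        est = sd.estimate_delay(chrom, "UV280")
        assert est == pytest.approx(0.02, abs=0.011)  # within one grid step
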