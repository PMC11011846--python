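"""Inversion pipeline: baseline, peaks, deconvolution, parameter recovery."""

import math

import numpy as np
import pytest

import sectd as sd
from sectd.analysis import component_mw, slice_mw
from sectd.simulate import EffectiveSpecies, band_profile, default_grid, detector_signals

from conftest import analyze_case


class TestBaseline:
    def test_zero_baseline_unchanged(self):
        grid = default_grid()
        trace = band_profile(0.1, 14.0, 0.35, grid)
        assert np.allclose(sd.baseline_correct(grid, trace), trace,
                           atol=1e-5 * trace.max())

    def test_constant_offset_removed(self):
        grid = default_grid()
        trace = band_profile(0.1, 14.0, 0.35, grid) + 5.0
        corrected = sd.baseline_correct(grid, trace)
        assert abs(corrected[0]) < 1e-6 and abs(corrected[-1]) < 1e-6

    def test_drift_slope_recovered(self):
        grid = default_grid()
        clean = band_profile(0.1, 14.0, 0.35, grid)
        drift = 0.5 * (grid - grid[0])
        corrected = sd.baseline_correct(grid, clean + drift)
        # recovered baseline = injected drift within 1%
        removed = (clean + drift) - corrected
        slope = np.polyfit(grid, removed, 1)[0]
        assert slope == pytest.approx(0.5, rel=0.01)

    def test_no_free_region_warns_and_passes_through(self):
        grid = default_grid()
        trace = band_profile(1.0, 14.0, 3.0, grid)  # band fills the window
        with pytest.warns(UserWarning):
            out = sd.baseline_correct(grid, trace)
        assert np.array_equal(out, trace)


class TestDetectPeaks:
    def test_single_gaussian_single_region(self):
        grid = default_grid()
        trace = band_profile(0.1, 14.0, 0.35, grid)
        regions = sd.detect_peaks(grid, trace)
        assert len(regions) == 1
        assert regions[0].apex_volume == pytest.approx(14.0, abs=0.011)

    def test_two_gaussians_three_sd_apart(self):
        grid = default_grid()
        trace = (band_profile(0.1, 13.0, 0.35, grid)
                 + band_profile(0.1, 14.05, 0.35, grid))
        assert len(sd.detect_peaks(grid, trace)) == 2

    def test_flat_trace_no_peaks(self):
        grid = default_grid()
        assert sd.detect_peaks(grid, np.zeros_like(grid)) == []

    def test_case3_regions_near_12_and_13p5(self, registry):
        chrom, _ = sd.simulate_scenario(sd.scenario_case(3, registry))
        regions = sd.detect_peaks(chrom.volume, chrom["RI"])
        apexes = [r.apex_volume for r in regions]
        assert any(abs(a - 12.0) < 0.15 for a in apexes)
        assert any(abs(a - 13.5) < 0.15 for a in apexes)


class TestDeconvolve:
    def test_single_component_near_perfect(self):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("trastuzumab"))
        comps = sd.deconvolve(chrom)
        assert len(comps) == 1
        assert comps[0].diagnostics["relative_residual"] < 1e-8

    def test_noiseless_two_component_areas(self, registry, column):
        """C3 + HO(2) mixture: recovered RI areas within 0.5% of generated."""
        scen = sd.scenario_case(3, registry)
        chrom, truth = sd.simulate_scenario(scen, registry)
        centers = [c["center_mL"] for c in truth["components"]]
        comps = sd.deconvolve(chrom, init_centers=centers, share_width=True)
        # free antibodies co-elute; merge generated masses of bands whose
        # centers coincide within the deconvolution merge tolerance
        merged: list[list[float]] = []  # [center, mass]
        for c in sorted(truth["components"], key=lambda c: c["center_mL"]):
            if merged and c["center_mL"] - merged[-1][0] < 0.05:
                merged[-1][1] += c["injected_mass_mg"]
            else:
                merged.append([c["center_mL"], c["injected_mass_mg"]])
        assert len(comps) == len(merged)
        k_ri = sd.simulate.SIM_GAINS["RI"] * 0.185
        for comp, (center, want) in zip(comps, merged):
            assert abs(comp.center_ml - center) < 0.05
            assert comp.areas["RI"] / k_ri == pytest.approx(want, rel=0.005)

    def test_noisy_case3_ho2_area_within_ten_percent(self, registry, column):
        scen = sd.scenario_case(3, registry)
        chrom, truth = sd.simulate_scenario(
            scen, registry, noise=sd.NoiseSpec(snr=100, seed=5))
        chrom.channels["RI"] = sd.baseline_correct(chrom.volume, chrom["RI"])
        centers = [c["center_mL"] for c in truth["components"]]
        comps = sd.deconvolve(chrom, init_centers=centers, share_width=True)
        ho2 = [c for c in truth["components"] if c["label"] == "HO(2)"][0]
        got = [c for c in comps
               if abs(c.center_ml - ho2["center_mL"]) < 0.1][0]
        k_ri = sd.simulate.SIM_GAINS["RI"] * 0.185
        assert got.areas["RI"] / k_ri == pytest.approx(
            ho2["injected_mass_mg"], rel=0.10)


class TestSliceMw:
    def test_single_species_exact(self, detector_calibration):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("trastuzumab"))
        _, mw = slice_mw(chrom, detector_calibration)
        assert mw == pytest.approx(147.0, rel=1e-3)

    def test_antigen_exact(self, detector_calibration):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"))
        _, mw = slice_mw(chrom, detector_calibration)
        assert mw == pytest.approx(86.3, rel=1e-3)

    def test_coeluting_weight_average(self, detector_calibration):
        """Equal-mass co-eluting 100 + 300 kDa species average to 200 kDa."""
        grid = default_grid()
        t = band_profile(0.05, 14.0, 0.35, grid)
        chrom = detector_signals(grid, [
            (EffectiveSpecies("a", 100.0, 0.185, 1.0, 5.0), t),
            (EffectiveSpecies("b", 300.0, 0.185, 1.0, 5.0), t)])
        mw_trace, mw = slice_mw(chrom, detector_calibration)
        mid = np.argmax(chrom["RI"])
        assert mw_trace[mid] == pytest.approx(200.0, rel=1e-3)
        assert mw == pytest.approx(200.0, rel=0.005)

    def test_blend_ratio_closed_form(self, detector_calibration):
        grid = default_grid()
        chrom = detector_signals(grid, [
            (EffectiveSpecies("a", 100.0, 0.185, 1.0, 5.0),
             band_profile(0.03, 14.0, 0.35, grid)),
            (EffectiveSpecies("b", 300.0, 0.185, 1.0, 5.0),
             band_profile(0.09, 14.0, 0.35, grid))])
        _, mw = slice_mw(chrom, detector_calibration)
        expect = (0.03 * 100 + 0.09 * 300) / 0.12
        assert mw == pytest.approx(expect, rel=0.005)


class TestComponentRatios:
    def test_viscosity_concentration_invariant(self, detector_calibration, trio):
        res = []
        for conc in (1.0, 0.5):
            chrom, _ = sd.simulate_scenario(
                sd.scenario_single("trastuzumab", total_conc_mg_ml=conc))
            s = sd.SECTDModel(chrom, detector_calibration, trio).fit().species[0]
            res.append(s.intrinsic_viscosity)
        assert res[0] == pytest.approx(res[1], rel=1e-9)
        assert res[0] == pytest.approx(6.5, rel=1e-3)

    def test_zero_uv_gives_zero_dadc(self, detector_calibration):
        assert sd.peak_dadc(0.0, 10.0, detector_calibration) == 0.0

    def test_nonpositive_ri_area_rejected(self, detector_calibration):
        with pytest.raises(ValueError):
            sd.peak_intrinsic_viscosity(1.0, 0.0, detector_calibration)


class TestEinsteinRadius:
    def test_her2_value(self):
        assert sd.einstein_rh(86.3, 6.5) == pytest.approx(4.46, abs=0.01)

    def test_cube_root_mass_scaling(self):
        assert sd.einstein_rh(8 * 147.0, 6.5) == pytest.approx(
            2 * sd.einstein_rh(147.0, 6.5), rel=1e-12)

    def test_c2_value(self):
        assert sd.einstein_rh(310.8, 7.9) == pytest.approx(7.30, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sd.einstein_rh(0.0, 6.5)


class TestStokesEinstein:
    def test_round_trip_5p5_nm(self):
        d = 1.380649e-23 * 309 / (6 * math.pi * 7.05e-4 * 5.5e-9)
        assert sd.stokes_einstein_rh(d, 309.0, 7.05e-4) == pytest.approx(5.5, rel=1e-9)

    def test_forward_diffusion_value(self):
        d = 1.380649e-23 * 309 / (6 * math.pi * 7.05e-4 * 5.5e-9)
        assert d == pytest.approx(5.84e-11, rel=0.005)

    def test_monotone_in_temperature(self):
        r1 = sd.stokes_einstein_rh(5e-11, 300.0, 7e-4)
        r2 = sd.stokes_einstein_rh(5e-11, 320.0, 7e-4)
        assert r2 > r1


class TestNoiseRecovery:
    def test_mw_bias_and_spread_at_snr100(self, detector_calibration):
        """Lone 147 kDa species over 20 seeds: bias < 0.5%, sd < 2%."""
        mws = []
        for seed in range(20):
            chrom, _ = sd.simulate_scenario(
                sd.scenario_single("trastuzumab"),
                noise=sd.NoiseSpec(snr=100, seed=seed))
            chrom.channels["RI"] = sd.baseline_correct(chrom.volume, chrom["RI"])
            comps = sd.deconvolve(chrom, n_components=1)
            mws.append(component_mw(comps[0].areas, detector_calibration))
        mws = np.array(mws)
        assert abs(mws.mean() - 147.0) / 147.0 < 0.005
        assert mws.std() / 147.0 < 0.02


class TestQuantification:
    def test_single_species_mass_fraction_one(self, detector_calibration, trio):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("trastuzumab"))
        res = sd.SECTDModel(chrom, detector_calibration, trio).fit()
        assert res.species[0].mass_fraction == pytest.approx(1.0)

    def test_noiseless_case3_ho2_fraction(self, registry, trio,
                                          detector_calibration):
        res = analyze_case("3", None, registry, trio, detector_calibration,
                           snr=None)
        assert res.production("HO(2)") == pytest.approx(0.30, abs=0.005)

    def test_mass_fractions_sum_to_one(self, registry, trio,
                                       detector_calibration):
        res = analyze_case("2", 4, registry, trio, detector_calibration)
        assert sum(s.mass_fraction for s in res.species) == pytest.approx(1.0, abs=0.02)

    def test_detected_only_normalisation_flagged(self, detector_calibration, trio):
        chrom, _ = sd.simulate_scenario(sd.scenario_single("her2"))
        res = sd.SECTDModel(chrom, detector_calibration, trio).fit()
        assert res.totals["antigen_reference_is_detected_only"]
        assert res.species[0].her2_mass_fraction == pytest.approx(1.0)

    def test_summary_mentions_productions(self, registry, trio,
                                          detector_calibration):
        res = analyze_case("2", 4, registry, trio, detector_calibration)
        text = res.summary()
        assert "C3 production" in text and "C3" in res.to_frame()["label"].values


class TestCompareCases:
    def test_identical_inputs_zero_difference(self, registry, trio,
                                              detector_calibration):
        res = analyze_case("2", 4, registry, trio, detector_calibration)
        report = sd.compare_cases({"a": res, "b": res})
        assert all(d == 0.0 for d in report.c3_differences.values())

    def test_case3_vs_case1_order_of_magnitude(self, registry, trio,
                                               detector_calibration):
        r1 = analyze_case("1", 4, registry, trio, detector_calibration)
        r3 = analyze_case("3", 4, registry, trio, detector_calibration)
        report = sd.compare_cases({"case1": r1, "case3": r3})
        assert ("case3", "case1") in report.order_of_magnitude_pairs

    def test_single_case_rejected(self, registry, trio, detector_calibration):
        res = analyze_case("2", 4, registry, trio, detector_calibration)
        with pytest.raises(ValueError):
            sd.compare_cases({"a": res})
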