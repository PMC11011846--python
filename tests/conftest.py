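import pytest

import sectd as sd


@pytest.fixture(scope="session")
def registry():
    return sd.default_registry()


@pytest.fixture(scope="session")
def trio(registry):
    return registry.subset(sd.DEFAULT_ANALYSIS_SPECIES)


@pytest.fixture(scope="session")
def column():
    return sd.default_column_calibration()


@pytest.fixture(scope="session")
def detector_calibration(column):
    """Detector constants from a noiseless BSA standard run."""
    std, ref = sd.make_bsa_standard(column=column)
    return sd.calibrate_detectors(std, ref, column=column)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def analyze_case(case, seed, registry, trio, detector_calibration, snr=100):
    """Simulate one order-of-addition case and run the full inversion."""
    scen = sd.scenario_case(case)
    noise = sd.NoiseSpec(snr=snr, seed=seed) if snr is not None else None
    chrom, truth = sd.simulate_scenario(scen, registry, noise=noise)
    model = sd.SECTDModel(chrom, detector_calibration, trio,
                          expected_compositions=[c.composition
                                                 for c in scen.components])
    return model.fit(total_antigen_mass_mg=scen.antigen_mass_mg(registry))
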