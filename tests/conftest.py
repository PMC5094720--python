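import dataclasses

import numpy as np
import pytest

import nanoxrf as nx


@pytest.fixture(scope="session")
def instrument():
    return nx.InstrumentModel()


@pytest.fixture(scope="session")
def fit_model(instrument):
    return nx.default_fit_model(
        gain=instrument.gain_ev,
        n_channels=instrument.n_channels,
        excitation_kev=instrument.excitation_kev,
        compton_kev=instrument.compton_kev,
    )


@pytest.fixture(scope="session")
def standard():
    return nx.ReferenceStandard.default()


@pytest.fixture(scope="session")
def small_phantom_scan(instrument):
    """One noisy 40x40 uniform-cell phantom scan, shared across tests."""
    spec = nx.control_cell_phantom(grid_shape=(40, 40), seed=7)
    scan, label_map, element_maps, areal = nx.simulate_phantom_scan(spec, instrument)
    return {
        "spec": spec,
        "scan": scan,
        "label_map": label_map,
        "element_maps": element_maps,
        "areal": areal,
    }


@pytest.fixture(scope="session")
def srm_scan_noiseless(instrument, standard):
    """Noiseless reference-standard scan with the 12.5% absorber."""
    srm_instr = dataclasses.replace(
        instrument, absorber_transmission=0.125, diode_drift_rsd=0.0
    )
    return nx.simulate_reference_scan(standard, srm_instr, seed=3, poisson=False)


@pytest.fixture(scope="session")
def calibrated_yields(instrument, standard, fit_model, srm_scan_noiseless):
    """Yield table calibrated from the noiseless standard scan."""
    from nanoxrf.segmentation import ClusterMask, cluster_sum
    from nanoxrf.spectral import fit_spectrum

    mask = ClusterMask("srm", np.ones(srm_scan_noiseless.shape, dtype=bool))
    css = cluster_sum(srm_scan_noiseless, mask, fit_model=fit_model)
    fit = fit_spectrum(css.spectrum, fit_model)
    norm = nx.normalize_sum_spectrum(fit, css, instrument.diode_nominal)
    return nx.calibrate_yields(
        norm,
        standard,
        instrument.geometry(),
        beam_fwhm_nm=instrument.beam_fwhm_nm,
        lod_live_time=instrument.dwell_s,
    )
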