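"""Fundamental-parameter quantification: normalization, absorption, yields,
LODs, concentration conversions and uncertainty propagation."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import nanoxrf as nx
from nanoxrf.fpquant import (
    GeometryConfig,
    NormalizedIntensities,
    absorption_correction,
    beam_area_cm2,
    compton_normalize,
    counting_sigma,
    format_weight_fraction,
    propagate_uncertainty,
    quantify_cluster,
    relative_lod,
)
from nanoxrf.spectral import Spectrum
from nanoxrf.segmentation import ClusterMask, cluster_sum
from nanoxrf.spectral import fit_spectrum


class TestAbsorptionCorrection:
    GEO = GeometryConfig()

    def test_thin_sample_limit_is_unity(self):
        a = absorption_correction(1e-9, 1e-9, self.GEO, 1e-3)
        assert a == pytest.approx(1.0, abs=1e-9)

    def test_unit_optical_depth_closed_form(self):
        # chi*phi_d = 1  ->  A = 1 - e^-1
        geo = GeometryConfig(incidence_deg=90.0, takeoff_deg=90.0)
        a = absorption_correction(0.5, 0.5, geo, 1.0)
        assert a == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)

    def test_matches_depth_integration_oracle(self):
        """A_corr equals the numerical average of exp(-chi t) over depth."""
        mu0, mu1, phid = 1.0, 10.0, 0.0131
        chi = mu0 / math.sin(math.radians(90)) + mu1 / math.sin(math.radians(15))
        oracle = quad(lambda t: math.exp(-chi * t), 0.0, phid)[0] / phid
        assert absorption_correction(mu0, mu1, self.GEO, phid) == pytest.approx(
            oracle, rel=1e-9
        )

    def test_monotone_decreasing_in_optical_depth(self):
        vals = [
            absorption_correction(1.0, mu1, self.GEO, 0.0131) for mu1 in (1, 5, 20, 80)
        ]
        assert all(0 < v <= 1 for v in vals)
        assert np.all(np.diff(vals) < 0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            absorption_correction(0.0, 1.0, self.GEO, 0.0131)
        with pytest.raises(ValueError):
            absorption_correction(1.0, 1.0, self.GEO, -1.0)


class TestNormalization:
    def _fit_stub(self, net=100.0):
        from nanoxrf.spectral import FitResult, LineResult

        return FitResult(
            lines={"Fe": LineResult(net, 1.0, 10.0)},
            compton_area=50.0,
            compton_sigma=1.0,
            rayleigh_area=5.0,
            rayleigh_sigma=1.0,
            reduced_chi2=1.0,
        )

    def _spectrum(self, dt=0.0, diode=1.0):
        return Spectrum(
            counts=np.zeros(8), gain=20.0, live_time=1.0 - dt, real_time=1.0,
            deadtime_fraction=dt, diode_mean=diode,
        )

    def test_identity_when_no_deadtime_and_matched_diode(self):
        norm = nx.normalize_sum_spectrum(self._fit_stub(), self._spectrum(), 1.0)
        assert norm.net["Fe"] == pytest.approx(100.0)
        assert norm.compton == pytest.approx(50.0)

    def test_deadtime_multiplier_at_11_27_percent(self):
        """DT = 11.27% gives the 1/(1-DT) = 1.12702... correction."""
        norm = nx.normalize_sum_spectrum(
            self._fit_stub(), self._spectrum(dt=0.1127), 1.0
        )
        assert norm.net["Fe"] / 100.0 == pytest.approx(1.0 / (1.0 - 0.1127), rel=1e-9)
        assert norm.net["Fe"] / 100.0 == pytest.approx(1.12702, rel=1e-5)

    def test_diode_ratio_multiplier_from_printed_telemetry(self):
        """Reference diode 1.511e8 over standard diode 1.583e7 -> x9.545."""
        norm = nx.normalize_sum_spectrum(
            self._fit_stub(), self._spectrum(diode=1.583e7), 1.511e8
        )
        assert norm.net["Fe"] / 100.0 == pytest.approx(1.511e8 / 1.583e7, rel=1e-9)
        assert norm.net["Fe"] / 100.0 == pytest.approx(9.545, abs=2e-3)

    def test_missing_diode_telemetry_is_an_error(self):
        with pytest.raises(ValueError, match="diode"):
            nx.normalize_sum_spectrum(self._fit_stub(), self._spectrum(diode=0.0), 1.0)


class TestComptonNormalize:
    def test_identity_and_halving(self):
        assert compton_normalize(10.0, 5.0, 5.0) == 10.0
        assert compton_normalize(10.0, 10.0, 5.0) == 5.0

    def test_nonpositive_compton_rejected(self):
        with pytest.raises(ValueError):
            compton_normalize(1.0, 0.0, 1.0)


class TestRelativeLod:
    def test_direct_arithmetic_example(self):
        # net 1e6, background 1e4, A=1, conc 100 ppm -> 0.03 ppm
        lod = relative_lod(1e6, 1e4, 1.0, 100e-6, 1.0, 1.0)
        assert lod == pytest.approx(0.03e-6, rel=1e-12)

    def test_hundredfold_gain_from_ten_thousandfold_live_time(self):
        """0.3 s scanning vs 3000 s cluster: LOD improves by exactly 100x."""
        base = relative_lod(1e6, 1e4, 1.0, 100e-6, 0.3, 0.3)
        cluster = relative_lod(1e6, 1e4, 1.0, 100e-6, 0.3, 3000.0)
        assert base / cluster == pytest.approx(100.0, rel=1e-12)

    def test_zero_background_is_counting_limited_ideal(self):
        assert relative_lod(1e6, 0.0, 1.0, 1e-6, 1.0, 1.0) == 0.0

    def test_zero_net_undefined(self):
        with pytest.raises(ValueError):
            relative_lod(0.0, 10.0, 1.0, 1e-6, 1.0, 1.0)


class TestUncertainty:
    def test_zero_components_give_zero(self):
        assert propagate_uncertainty(0.0, 0.0, 0.0) == 0.0

    def test_three_four_five_quadrature(self):
        assert propagate_uncertainty(0.03, 0.04) == pytest.approx(0.05, rel=1e-12)

    def test_nonfinite_component_rejected(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(0.03, float("nan"))

    def test_counting_sigma_fallback(self):
        assert counting_sigma(100.0, 50.0, None) == pytest.approx(math.sqrt(200.0))
        assert counting_sigma(100.0, 50.0, 7.0) == 7.0


class TestCalibrateYields:
    def test_roundtrip_recovers_true_yields_to_half_percent(
        self, calibrated_yields, instrument
    ):
        """Simulator and quantifier share the absorption model: noiseless
        calibration returns the generator's ground-truth sensitivities."""
        for sym, rec in calibrated_yields.records.items():
            assert rec.yield_cps_per_ag == pytest.approx(
                instrument.true_yields[sym], rel=5e-3
            )

    def test_yield_inverse_in_certified_concentration(
        self, instrument, standard, fit_model, srm_scan_noiseless
    ):
        mask = ClusterMask("srm", np.ones(srm_scan_noiseless.shape, bool))
        css = cluster_sum(srm_scan_noiseless, mask, fit_model=fit_model)
        fit = fit_spectrum(css.spectrum, fit_model)
        norm = nx.normalize_sum_spectrum(fit, css, instrument.diode_nominal)
        doubled = dataclasses.replace(
            standard,
            certified={
                k: ((2 * v[0], v[1]) if k == "Fe" else v)
                for k, v in standard.certified.items()
            },
        )
        y1 = nx.calibrate_yields(norm, standard, instrument.geometry(),
                                 beam_fwhm_nm=instrument.beam_fwhm_nm)
        y2 = nx.calibrate_yields(norm, doubled, instrument.geometry(),
                                 beam_fwhm_nm=instrument.beam_fwhm_nm)
        assert y2["Fe"].yield_cps_per_ag == pytest.approx(
            y1["Fe"].yield_cps_per_ag / 2.0, rel=1e-9
        )

    def test_uncertified_element_skipped_with_warning(
        self, instrument, standard, fit_model, srm_scan_noiseless
    ):
        mask = ClusterMask("srm", np.ones(srm_scan_noiseless.shape, bool))
        css = cluster_sum(srm_scan_noiseless, mask, fit_model=fit_model)
        fit = fit_spectrum(css.spectrum, fit_model)
        norm = nx.normalize_sum_spectrum(fit, css, instrument.diode_nominal)
        trimmed = dataclasses.replace(
            standard,
            certified={k: v for k, v in standard.certified.items() if k != "Ca"},
        )
        with pytest.warns(UserWarning, match="Ca"):
            yt = nx.calibrate_yields(norm, trimmed, instrument.geometry(),
                                     beam_fwhm_nm=instrument.beam_fwhm_nm)
        assert "Ca" not in yt


def _norm_stub(net, n_pixels=1000, real_time=300.0, live_time=295.0):
    return NormalizedIntensities(
        net=dict(net),
        net_sigma={k: max(math.sqrt(max(v, 1.0)), 1e-6) for k, v in net.items()},
        background={k: 0.0 for k in net},
        compton=1e6,
        rayleigh=1e4,
        n_pixels=n_pixels,
        real_time=real_time,
        live_time=live_time,
        label="stub",
    )


class TestQuantifyCluster:
    def test_density_substitution_scales_weight_fractions_by_1p13(
        self, calibrated_yields, instrument
    ):
        """Replacing the resin density 1.13 by water 1.00 g/cm^3 raises
        every weight fraction by exactly 13%."""
        norm = _norm_stub({"Fe": 5e4, "Zn": 2e4})
        q_resin = quantify_cluster(norm, calibrated_yields,
                                   beam_fwhm_nm=instrument.beam_fwhm_nm,
                                   density_g_cm3=1.13)
        q_water = quantify_cluster(norm, calibrated_yields,
                                   beam_fwhm_nm=instrument.beam_fwhm_nm,
                                   density_g_cm3=1.00)
        for el in ("Fe", "Zn"):
            ratio = q_water[el].weight_fraction / q_resin[el].weight_fraction
            assert ratio == pytest.approx(1.13, rel=1e-12)

    def test_zero_intensity_gives_zero_masses(self, calibrated_yields, instrument):
        q = quantify_cluster(_norm_stub({"Fe": 0.0}), calibrated_yields,
                             beam_fwhm_nm=instrument.beam_fwhm_nm)
        assert q["Fe"].weight_fraction == 0.0
        assert q["Fe"].absolute_mass_g == 0.0
        assert q["Fe"].below_lod

    def test_conversions_mutually_consistent(self, calibrated_yields, instrument):
        """molar = wf*rho/M (mol/L) and areal = wf*rho*T exactly."""
        q = quantify_cluster(_norm_stub({"Fe": 5e4, "P": 3e6}), calibrated_yields,
                             beam_fwhm_nm=instrument.beam_fwhm_nm)
        rho, t_cm = 1.13, 2.0e-4
        for el in ("Fe", "P"):
            eq = q[el]
            molar = eq.weight_fraction * rho / nx.atomic_mass(el) * 1e3
            areal = eq.weight_fraction * rho * t_cm
            assert eq.molar_mol_per_l == pytest.approx(molar, rel=1e-9)
            assert eq.areal_g_per_cm2 == pytest.approx(areal, rel=1e-9)

    def test_compton_mode_requires_reference(self, calibrated_yields, instrument):
        with pytest.raises(ValueError, match="reference"):
            quantify_cluster(_norm_stub({"Fe": 1.0}), calibrated_yields,
                             beam_fwhm_nm=instrument.beam_fwhm_nm,
                             normalization="compton")

    def test_unknown_normalization_rejected(self, calibrated_yields):
        with pytest.raises(ValueError):
            quantify_cluster(_norm_stub({"Fe": 1.0}), calibrated_yields,
                             normalization="banana")


class TestFormatting:
    @pytest.mark.parametrize(
        "wf,value,unit",
        [
            (1.4e-2, 1.4, "w%"),
            (1.0e-3, 0.1, "w%"),
            (125e-6, 125.0, "ppm"),
            (183e-9, 183.0, "ppb"),
        ],
    )
    def test_units_chosen_by_magnitude(self, wf, value, unit):
        v, u = format_weight_fraction(wf)
        assert u == unit
        assert v == pytest.approx(value)


@settings(deadline=None, max_examples=100)
@given(
    mu0=st.floats(0.1, 10.0),
    mu1=st.floats(0.1, 500.0),
    phid=st.floats(1e-5, 0.05),
)
def test_absorption_correction_bounded_property(mu0, mu1, phid):
    a = absorption_correction(mu0, mu1, GeometryConfig(), phid)
    assert 0.0 < a <= 1.0
    thinner = absorption_correction(mu0, mu1, GeometryConfig(), phid / 2.0)
    assert thinner >= a


def test_beam_area_is_fwhm_product():
    assert beam_area_cm2((64.0, 54.0)) == pytest.approx(64 * 54 * 1e-14)
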