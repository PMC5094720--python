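"""Fundamental-parameter quantification of cluster sum spectra.

The chain implemented here turns fitted, raw cluster intensities into element
weight fractions, molar and areal concentrations and absolute masses:

1. conventional normalization — dead-time correction ``1/(1-DT)`` and scaling
   to the diode (incident-flux) reading of a chosen reference cluster;
2. self-absorption correction of the thick reference standard,
   ``A_corr = (1 - exp(-chi*phi_d)) / (chi*phi_d)`` with
   ``chi = mu0/sin(alpha) + mu1/sin(beta)``;
3. absolute element yields (counts per second per attogram) calibrated from a
   certified standard scan;
4. relative detection limits from counting statistics,
   ``LOD = 3 sqrt(I_back)/I_net * conc / A_corr``, rescaled with the square
   root of the live-time ratio;
5. optional Compton renormalization — net intensities scaled by the ratio of
   per-area Compton intensities of reference and target cluster, removing
   section-to-section thickness/density variation;
6. conversion to weight fraction, molarity, areal concentration and absolute
   mass for a cluster of ``N_pix`` pixels of known beam footprint, assuming a
   uniform embedding-resin matrix (density 1.13 g/cm^3, 2 um sections);
7. uncertainty propagation: relative variances of independent multiplicative
   factors add in quadrature.

Thin-section self-absorption of the 2 um sample sections is neglected by
default (an optional correction is available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .elements import ParametricCrossSections, atomic_mass, line_energy

__all__ = [
    "ReferenceStandard",
    "GeometryConfig",
    "NormalizedIntensities",
    "YieldRecord",
    "YieldTable",
    "ElementQuant",
    "QuantResult",
    "matrix_attenuation",
    "absorption_correction",
    "normalize_sum_spectrum",
    "compton_normalize",
    "calibrate_yields",
    "relative_lod",
    "quantify_cluster",
    "propagate_uncertainty",
    "counting_sigma",
    "beam_area_cm2",
    "format_weight_fraction",
]

_AG_PER_G = 1e18


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeometryConfig:
    """Beam/sample/detector geometry: incidence and take-off angles, E0."""

    incidence_deg: float = 90.0
    takeoff_deg: float = 15.0
    excitation_kev: float = 17.0

    def __post_init__(self) -> None:
        for name in ("incidence_deg", "takeoff_deg"):
            v = getattr(self, name)
            if not (0.0 < v <= 90.0):
                raise ValueError(f"{name} must be in (0, 90] degrees, got {v}")


@dataclass
class ReferenceStandard:
    """A certified reference material (bovine-liver-like pressed pellet).

    ``certified`` maps element symbol to (weight fraction, relative 1-sigma
    uncertainty); ``areal_mass`` is the pellet mass per unit area in g/cm^2;
    ``matrix_composition`` maps symbols to mass fractions summing to 1
    (certified traces plus an assumed organic residual).
    """

    name: str
    certified: dict[str, tuple[float, float]]
    areal_mass: float  # g/cm^2
    matrix_composition: dict[str, float]

    def __post_init__(self) -> None:
        if self.areal_mass <= 0:
            raise ValueError("areal_mass must be positive")
        total = sum(self.matrix_composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"matrix composition sums to {total}, expected 1")

    @classmethod
    def from_yaml(cls, path) -> "ReferenceStandard":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "ReferenceStandard":
        certified = {}
        for sym, rec in raw["certified_mg_per_kg"].items():
            wf = rec["value"] * 1e-6
            rel = rec["uncertainty"] / rec["value"]
            certified[sym] = (wf, rel)
        residual = dict(raw["organic_residual"])
        trace_total = sum(wf for wf, _ in certified.values())
        scale = (1.0 - trace_total) / sum(residual.values())
        matrix = {sym: f * scale for sym, f in residual.items()}
        for sym, (wf, _) in certified.items():
            matrix[sym] = matrix.get(sym, 0.0) + wf
        return cls(
            name=raw["name"],
            certified=certified,
            areal_mass=float(raw["areal_mass_g_per_cm2"]),
            matrix_composition=matrix,
        )

    @classmethod
    def default(cls) -> "ReferenceStandard":
        """The bundled bovine-liver standard (areal mass 13.1 mg/cm^2)."""
        ref = resources.files("nanoxrf.data").joinpath("srm1577c.yaml")
        with resources.as_file(ref) as path:
            return cls.from_yaml(path)


@dataclass
class NormalizedIntensities:
    """Dead-time- and diode-normalized intensities of one sum spectrum."""

    net: dict[str, float]
    net_sigma: dict[str, float]
    background: dict[str, float]
    compton: float
    rayleigh: float
    n_pixels: int
    real_time: float  # summed over member pixels, s
    live_time: float  # summed over member pixels, s
    label: str = ""


@dataclass
class YieldRecord:
    element: str
    yield_cps_per_ag: float
    rel_sigma: float
    lod_scanning: float  # weight fraction at ``lod_live_time``
    background_rate: float  # counts/s under the peak, normalized
    a_corr: float
    #: calibration line significant on the standard (net area >= 3 sigma);
    #: an insignificant line cannot anchor a trustworthy absolute yield
    significant: bool = True


@dataclass
class YieldTable:
    """Calibrated absolute element yields plus LOD bookkeeping."""

    records: dict[str, YieldRecord]
    lod_live_time: float  # s, live time the LODs refer to
    srm_live_time: float  # s, total live time of the calibration scan

    def __contains__(self, element: str) -> bool:
        return element in self.records

    def __getitem__(self, element: str) -> YieldRecord:
        return self.records[element]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element": r.element,
                "yield_counts_per_s_ag": r.yield_cps_per_ag,
                "rel_sigma": r.rel_sigma,
                "lod_scanning": r.lod_scanning,
                "lod_live_time_s": self.lod_live_time,
                "srm_live_time_s": self.srm_live_time,
                "background_rate_cps": r.background_rate,
                "a_corr": r.a_corr,
                "significant": r.significant,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows).set_index("element")

    @classmethod
    def from_csv(cls, path) -> "YieldTable":
        df = pd.read_csv(path).set_index("element")
        records = {
            sym: YieldRecord(
                element=sym,
                yield_cps_per_ag=row["yield_counts_per_s_ag"],
                rel_sigma=row["rel_sigma"],
                lod_scanning=row["lod_scanning"],
                background_rate=row["background_rate_cps"],
                a_corr=row["a_corr"],
                significant=bool(row.get("significant", True)),
            )
            for sym, row in df.iterrows()
        }
        return cls(
            records=records,
            lod_live_time=float(df["lod_live_time_s"].iloc[0]),
            srm_live_time=float(df["srm_live_time_s"].iloc[0]),
        )


@dataclass
class ElementQuant:
    element: str
    weight_fraction: float
    rel_sigma: float
    molar_mol_per_l: float
    areal_g_per_cm2: float
    absolute_mass_g: float
    below_lod: bool
    lod: float
    calibration_limited: bool = False


@dataclass
class QuantResult:
    """Per-element quantification of one cluster."""

    cluster_label: str
    normalization: str  # "conventional" | "compton"
    elements: dict[str, ElementQuant]
    n_pixels: int

    def __getitem__(self, element: str) -> ElementQuant:
        return self.elements[element]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for q in self.elements.values():
            value, unit = format_weight_fraction(q.weight_fraction)
            sigma_scaled = q.weight_fraction * q.rel_sigma
            rows.append(
                {
                    "element": q.element,
                    "cluster": self.cluster_label,
                    "weight_fraction": q.weight_fraction,
                    "weight_fraction_sigma": sigma_scaled,
                    "display_value": value,
                    "display_unit": unit,
                    "molar_mol_per_L": q.molar_mol_per_l,
                    "areal_g_per_cm2": q.areal_g_per_cm2,
                    "absolute_mass_g": q.absolute_mass_g,
                    "below_lod": q.below_lod,
                    "calibration_limited": q.calibration_limited,
                    "lod_weight_fraction": q.lod,
                    "normalization": self.normalization,
                }
            )
        return pd.DataFrame(rows).set_index("element")


def format_weight_fraction(wf: float) -> tuple[float, str]:
    """Display value + unit, by magnitude: >=0.1% -> %, >=1 ppm -> ppm, else ppb."""
    if wf >= 1e-3:
        return wf * 100.0, "w%"
    if wf >= 1e-6:
        return wf * 1e6, "ppm"
    return wf * 1e9, "ppb"


def beam_area_cm2(beam_fwhm_nm: tuple[float, float]) -> float:
    """Beam footprint area as the FWHM product, cm^2."""
    h, v = beam_fwhm_nm
    return h * v * 1e-14


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def matrix_attenuation(
    composition: Mapping[str, float],
    energy_kev: float,
    provider: ParametricCrossSections | None = None,
) -> float:
    """Total mass attenuation coefficient of a mixture, cm^2/g."""
    if provider is None:
        provider = ParametricCrossSections()
    return provider(composition, energy_kev)


def absorption_correction(
    mu0: float, mu1: float, geometry: GeometryConfig, areal_mass: float
) -> float:
    """Self-absorption factor of a uniform slab, in (0, 1].

    ``chi = mu0/sin(alpha) + mu1/sin(beta)``; the correction is
    ``(1 - exp(-chi*phi_d)) / (chi*phi_d)``, monotone decreasing in
    ``chi*phi_d`` and approaching 1 in the thin-sample limit.
    """
    if mu0 <= 0 or mu1 <= 0 or areal_mass <= 0:
        raise ValueError("mu0, mu1 and areal mass must be positive")
    chi = mu0 / math.sin(math.radians(geometry.incidence_deg)) + mu1 / math.sin(
        math.radians(geometry.takeoff_deg)
    )
    x = chi * areal_mass
    if x < 1e-8:
        return 1.0 - x / 2.0
    return float(-math.expm1(-x) / x)


def normalize_sum_spectrum(fit, telemetry, reference_diode: float) -> NormalizedIntensities:
    """Dead-time correct and diode-normalize a fitted sum spectrum.

    ``fit`` is a spectral ``FitResult``; ``telemetry`` is the summed
    ``Spectrum`` (or a ``ClusterSumSpectrum``, whose embedded spectrum is
    used).  Every intensity — net, background, Compton and Rayleigh — is
    multiplied by ``1/(1-DT) * k_ref/k_self``.
    """
    spectrum = getattr(telemetry, "spectrum", telemetry)
    label = getattr(telemetry, "label", "")
    dt = float(spectrum.deadtime_fraction)
    diode = float(spectrum.diode_mean)
    if not np.isfinite(diode) or diode <= 0:
        raise ValueError("missing or non-positive diode telemetry")
    if not np.isfinite(reference_diode) or reference_diode <= 0:
        raise ValueError("missing or non-positive reference diode value")
    if dt >= 1.0:
        raise ValueError("dead-time fraction must be < 1")
    factor = 1.0 / (1.0 - dt) * reference_diode / diode
    return NormalizedIntensities(
        net={e: lr.net_area * factor for e, lr in fit.lines.items()},
        net_sigma={e: lr.net_area_sigma * factor for e, lr in fit.lines.items()},
        background={e: lr.background_under_peak * factor for e, lr in fit.lines.items()},
        compton=fit.compton_area * factor,
        rayleigh=fit.rayleigh_area * factor,
        n_pixels=int(spectrum.n_pixels_summed),
        real_time=float(spectrum.real_time),
        live_time=float(spectrum.live_time),
        label=label,
    )


def compton_normalize(intensity: float, compton_self: float, compton_ref: float) -> float:
    """Scale an intensity by the reference/self Compton ratio."""
    if compton_self <= 0 or compton_ref <= 0:
        raise ValueError("Compton intensities must be positive")
    return intensity * compton_ref / compton_self


def propagate_uncertainty(*relative_sigmas: float) -> float:
    """Total relative 1-sigma of a product of independent factors."""
    for s in relative_sigmas:
        if not np.isfinite(s):
            raise ValueError("all component sigmas must be finite")
    return math.sqrt(sum(s * s for s in relative_sigmas))


def counting_sigma(net: float, background: float, fit_sigma: float | None = None) -> float:
    """Absolute counting 1-sigma of a net area.

    Uses the reported fit sigma when available, otherwise the Poisson
    fallback ``sqrt(net + 2*background)``.
    """
    if fit_sigma is not None and np.isfinite(fit_sigma) and fit_sigma > 0:
        return float(fit_sigma)
    return math.sqrt(max(net, 0.0) + 2.0 * max(background, 0.0))


def calibrate_yields(
    srm_norm: NormalizedIntensities,
    standard: ReferenceStandard,
    geometry: GeometryConfig,
    provider: ParametricCrossSections | None = None,
    beam_fwhm_nm: tuple[float, float] = (64.0, 54.0),
    lod_live_time: float = 0.3,
    lod_factor: float = 3.0,
) -> YieldTable:
    """Absolute element yields and scanning LODs from a standard scan.

    The normalized standard intensities must already be on the no-absorber
    sample condition (the diode normalization of the conventional step takes
    the absorber out).  Per element:
    ``Yield = I_norm / (A_corr * m_ag * t_real)`` with ``m_ag`` the element
    mass in one beam footprint (ag) and ``t_real`` the per-pixel real time
    times the pixel count; elements without certified values are skipped with
    a warning.
    """
    if provider is None:
        provider = ParametricCrossSections()
    mu0 = matrix_attenuation(standard.matrix_composition, geometry.excitation_kev, provider)
    area = beam_area_cm2(beam_fwhm_nm)
    records: dict[str, YieldRecord] = {}
    for element, net in srm_norm.net.items():
        cert = standard.certified.get(element)
        if cert is None:
            warnings.warn(f"no certified concentration for {element}; skipped")
            continue
        conc, cert_rel = cert
        if net <= 0:
            warnings.warn(f"non-positive net intensity for {element}; skipped")
            continue
        mu1 = matrix_attenuation(standard.matrix_composition, line_energy(element), provider)
        a_corr = absorption_correction(mu0, mu1, geometry, standard.areal_mass)
        mass_ag = conc * standard.areal_mass * area * _AG_PER_G
        y = net / (a_corr * mass_ag * srm_norm.real_time)
        count_sigma = counting_sigma(
            net, srm_norm.background.get(element, 0.0), srm_norm.net_sigma.get(element)
        )
        count_rel = count_sigma / net
        significant = net >= 3.0 * count_sigma
        if not significant:
            warnings.warn(
                f"standard line of {element} insignificant (net {net:.0f} < 3 sigma); "
                "yield flagged unreliable"
            )
        rel = propagate_uncertainty(count_rel, cert_rel)
        lod = relative_lod(
            net,
            srm_norm.background.get(element, 0.0),
            a_corr,
            conc,
            live_time_ref=srm_norm.live_time,
            live_time_target=lod_live_time,
            factor=lod_factor,
        )
        records[element] = YieldRecord(
            element=element,
            yield_cps_per_ag=y,
            rel_sigma=rel,
            lod_scanning=lod,
            background_rate=srm_norm.background.get(element, 0.0) / srm_norm.real_time,
            a_corr=a_corr,
            significant=significant,
        )
    return YieldTable(records=records, lod_live_time=lod_live_time,
                      srm_live_time=srm_norm.live_time)


def relative_lod(
    net: float,
    background: float,
    a_corr: float,
    conc_srm: float,
    live_time_ref: float,
    live_time_target: float,
    factor: float = 3.0,
) -> float:
    """Counting-statistics detection limit as a weight fraction.

    ``LOD = factor * sqrt(I_back)/I_net * conc / A_corr`` at the reference
    live time, improved by ``sqrt(live_ref/live_target)`` for longer counting.
    A zero background yields LOD 0 (counting-limited ideal).
    """
    if net <= 0:
        raise ValueError("net intensity must be positive for an LOD")
    if background < 0:
        raise ValueError("background must be non-negative")
    base = factor * math.sqrt(background) / net * conc_srm / a_corr
    return base * math.sqrt(live_time_ref / live_time_target)


def quantify_cluster(
    norm: NormalizedIntensities,
    yields: YieldTable,
    beam_fwhm_nm: tuple[float, float] = (64.0, 54.0),
    thickness_um: float = 2.0,
    density_g_cm3: float = 1.13,
    normalization: str = "conventional",
    compton_ref: float | None = None,
    compton_ref_pixels: int | None = None,
    compton_rel_sigma: float = 0.0,
) -> QuantResult:
    """Element weight fractions and derived concentrations for one cluster.

    With ``normalization="compton"`` the conventionally normalized net
    intensities are additionally scaled by the per-area Compton ratio of the
    reference cluster to this cluster, cancelling thickness/density
    variation.  Conversions (spec notation: N_pix pixels, beam area A_b,
    section thickness T, matrix density rho):

    * absolute mass  ``m = I_norm / (Yield * t_px)`` with ``t_px`` the mean
      per-pixel real time;
    * weight fraction ``w = m / (rho * N_pix * A_b * T)``;
    * molarity ``c = m / (M * N_pix * A_b * T)`` (converted to mol/L);
    * areal concentration ``m / (N_pix * A_b)``.
    """
    if normalization not in ("conventional", "compton"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    if norm.n_pixels <= 0:
        raise ValueError("cluster has no pixels")
    area = beam_area_cm2(beam_fwhm_nm)
    t_cm = thickness_um * 1e-4
    n_pix = norm.n_pixels
    t_px = norm.real_time / n_pix
    matrix_mass = density_g_cm3 * n_pix * area * t_cm  # g
    volume_l = n_pix * area * t_cm * 1e-3  # cm^3 -> L

    compton_factor = 1.0
    if normalization == "compton":
        if compton_ref is None or compton_ref_pixels is None:
            raise ValueError("compton normalization requires a reference Compton record")
        self_per_area = norm.compton / n_pix
        ref_per_area = compton_ref / compton_ref_pixels
        compton_factor = compton_normalize(1.0, self_per_area, ref_per_area)

    out: dict[str, ElementQuant] = {}
    for element, net_raw in norm.net.items():
        if element not in yields:
            continue
        rec = yields[element]
        if rec.yield_cps_per_ag <= 0:
            warnings.warn(f"zero yield for {element}; skipped")
            continue
        net = max(net_raw, 0.0) * compton_factor
        mass_ag = net / (rec.yield_cps_per_ag * t_px)
        mass_g = mass_ag / _AG_PER_G
        wf = mass_g / matrix_mass
        molar = mass_g / (atomic_mass(element) * volume_l)
        areal = mass_g / (n_pix * area)
        count_rel = (
            counting_sigma(net_raw, norm.background.get(element, 0.0),
                           norm.net_sigma.get(element)) / net_raw
            if net_raw > 0
            else float("inf")
        )
        extra = (compton_rel_sigma,) if normalization == "compton" else ()
        rel = (
            propagate_uncertainty(count_rel, rec.rel_sigma, *extra)
            if math.isfinite(count_rel)
            else float("inf")
        )
        lod = rec.lod_scanning * math.sqrt(yields.lod_live_time / norm.live_time)
        out[element] = ElementQuant(
            element=element,
            weight_fraction=wf,
            rel_sigma=rel,
            molar_mol_per_l=molar,
            areal_g_per_cm2=areal,
            absolute_mass_g=mass_g,
            below_lod=bool(wf < lod) or not rec.significant,
            lod=lod,
            calibration_limited=not rec.significant,
        )
    return QuantResult(
        cluster_label=norm.label,
        normalization=normalization,
        elements=out,
        n_pixels=n_pix,
    )
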