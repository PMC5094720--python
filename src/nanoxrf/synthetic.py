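"""Phantom cells and simulated nano-XRF scans with known ground truth.

The generator emulates the measurement conditions of embedded single-cell
scans: 2 um resin sections (density 1.13 g/cm^3) raster-scanned with a
64 x 54 nm beam at 17 keV excitation, 300 ms dwell per pixel, an
energy-dispersive detector with Gaussian response, Poisson counting noise, a
Compton scatter peak proportional to the illuminated areal mass, per-pixel
diode (flux) drift, and a non-paralyzable dead-time model.  A reference
standard scan (10 x 10 um^2, 200 nm step, 500 ms dwell, beam absorber with
12.5% transmission) is simulated with thick-target self-absorption applied to
its expected line intensities.

Section-to-section thickness variation (~15% RSD between microtome sections)
enters through a per-dataset ``thickness_scale``; per-pixel variation is
available as an option.

All expectations are exact closed forms, so every downstream stage can be
validated against known truth; identical spec + seed reproduce a dataset
bit for bit (array draws in a fixed order from one counter-based Philox
generator).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .dataset import ScanDataset
from .elements import DETECTABLE_ELEMENTS, REGISTRY, ParametricCrossSections, line_energy
from .fpquant import (
    GeometryConfig,
    ReferenceStandard,
    absorption_correction,
    beam_area_cm2,
    matrix_attenuation,
)

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "InstrumentModel",
    "DEFAULT_TRUE_YIELDS",
    "CONTROL_CELL",
    "CONTROL_NUCLEUS",
    "CONTROL_CYTOPLASM",
    "build_phantom",
    "simulate_scan",
    "simulate_reference_scan",
    "control_cell_phantom",
    "compartment_phantom",
    "condition_phantom",
    "simulate_phantom_scan",
    "STUDY_CONDITIONS",
    "STUDY_REPLICATES",
    "sample_thickness_scale",
]

_AG_PER_G = 1e18
_VALID_LABELS = ("background", "cytoplasm", "nucleus")


# ---------------------------------------------------------------------------
# phantom geometry and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (row/col centres)."""

    center_row: float
    center_col: float
    semi_row: float
    semi_col: float

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.center_row) / self.semi_row) ** 2
            + ((cols - self.center_col) / self.semi_col) ** 2
        ) <= 1.0

    def boundary(self, n: int = 720) -> tuple[np.ndarray, np.ndarray]:
        t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
        return (
            self.center_row + self.semi_row * np.cos(t),
            self.center_col + self.semi_col * np.sin(t),
        )


@dataclass
class PhantomSpec:
    """Geometry and ground-truth composition of one phantom section."""

    grid_shape: tuple[int, int]
    regions: Sequence[tuple[str, Ellipse]]
    region_concentrations: Mapping[str, Mapping[str, float]]
    pixel_step_nm: float = 50.0
    section_thickness_um: float = 2.0
    matrix_density_g_cm3: float = 1.13
    thickness_scale: float = 1.0
    thickness_rsd_per_pixel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_scale <= 0:
            raise ValueError("thickness_scale must be positive")
        for label, _ in self.regions:
            if label not in _VALID_LABELS:
                raise ValueError(f"unknown region label {label!r}")
        for label, conc in self.region_concentrations.items():
            if label not in _VALID_LABELS:
                raise ValueError(f"unknown region label {label!r}")
            total = 0.0
            for sym, wf in conc.items():
                if sym not in REGISTRY:
                    raise ValueError(f"unknown element {sym!r}")
                if wf < 0:
                    raise ValueError(f"negative weight fraction for {sym}")
                total += wf
            if total >= 1.0:
                raise ValueError(f"weight fractions in {label!r} sum to {total} >= 1")


def build_phantom(spec: PhantomSpec):
    """Rasterize a phantom: label map, element maps and areal-mass grid.

    Regions are painted in order onto a background-initialised grid, so each
    pixel receives exactly one label.  A nucleus ellipse must be fully
    contained in the preceding cell (cytoplasm) ellipse.  The areal-mass grid
    (g/cm^2) is ``density * thickness * thickness_scale``, optionally with
    per-pixel lognormal variation.
    """
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    label_map = np.full((rows, cols), "background", dtype="U10")

    cell_ellipse = None
    for label, ell in spec.regions:
        if label == "cytoplasm":
            cell_ellipse = ell
        if label == "nucleus" and cell_ellipse is not None:
            br, bc = ell.boundary()
            inside = (
                ((br - cell_ellipse.center_row) / cell_ellipse.semi_row) ** 2
                + ((bc - cell_ellipse.center_col) / cell_ellipse.semi_col) ** 2
            ) <= 1.0 + 1e-9
            if not np.all(inside):
                raise ValueError("nucleus geometry not contained in cell geometry")
        label_map[ell.contains(rr, cc)] = label

    areal = np.full(
        (rows, cols),
        spec.matrix_density_g_cm3
        * spec.section_thickness_um
        * 1e-4
        * spec.thickness_scale,
    )
    if spec.thickness_rsd_per_pixel > 0:
        rng = np.random.Generator(np.random.Philox(spec.seed))
        sigma = math.sqrt(math.log(1.0 + spec.thickness_rsd_per_pixel**2))
        areal = areal * rng.lognormal(-0.5 * sigma**2, sigma, size=(rows, cols))

    elements: set[str] = set()
    for conc in spec.region_concentrations.values():
        elements.update(conc)
    element_maps: dict[str, np.ndarray] = {}
    for sym in sorted(elements):
        grid = np.zeros((rows, cols))
        for label in _VALID_LABELS:
            wf = spec.region_concentrations.get(label, {}).get(sym, 0.0)
            if wf:
                grid[label_map == label] = wf
        element_maps[sym] = grid
    return label_map, element_maps, areal


# ---------------------------------------------------------------------------
# instrument
# ---------------------------------------------------------------------------

#: Ground-truth absolute sensitivities, counts/(s*ag), roughly increasing
#: with Z as detection efficiency and fluorescence yield rise toward the
#: excitation energy.
DEFAULT_TRUE_YIELDS: dict[str, float] = {
    "P": 2.0, "S": 3.0, "Cl": 4.0, "K": 8.0, "Ca": 10.0,
    "Mn": 30.0, "Fe": 35.0, "Co": 40.0, "Ni": 45.0, "Cu": 50.0,
    "Zn": 55.0, "Se": 80.0, "Br": 85.0, "Rb": 95.0, "Sr": 100.0,
    "Pb": 30.0,
}


@dataclass
class InstrumentModel:
    """Beamline, detector and acquisition parameters for the simulator."""

    excitation_kev: float = 17.0
    beam_fwhm_nm: tuple[float, float] = (64.0, 54.0)
    incidence_deg: float = 90.0
    takeoff_deg: float = 15.0
    dwell_s: float = 0.300
    n_channels: int = 1024
    gain_ev: float = 20.0
    offset_ev: float = 0.0
    true_yields: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_YIELDS)
    )
    #: quadratic continuum in E: b0 * (1 + b1*(E/E0) + b2*(E/E0)^2),
    #: counts/(s * keV) per g/cm^2 of illuminated areal mass
    background_shape: tuple[float, float, float] = (2.0e4, -0.5, -0.3)
    compton_kev: float = 16.3
    rayleigh_kev: float = 17.0
    #: counts/s per g/cm^2 of illuminated areal mass
    compton_per_mass: float = 2.53e7
    rayleigh_fraction: float = 0.03
    diode_nominal: float = 1.511e8
    diode_drift_rsd: float = 0.01
    deadtime_tau_s: float = 3.0e-6  # non-paralyzable dead time per count
    absorber_transmission: float = 1.0
    noise_ev: float = 100.0
    fano: float = 0.114
    pair_creation_ev: float = 3.85

    def __post_init__(self) -> None:
        if not (0.0 < self.absorber_transmission <= 1.0):
            raise ValueError("absorber_transmission must be in (0, 1]")
        if self.gain_ev <= 0:
            raise ValueError("gain must be positive")
        if any(y < 0 for y in self.true_yields.values()):
            raise ValueError("yields must be non-negative")
        if self.deadtime_tau_s < 0:
            raise ValueError("dead-time coefficient must be non-negative")

    @property
    def beam_area_cm2(self) -> float:
        return beam_area_cm2(self.beam_fwhm_nm)

    def geometry(self) -> GeometryConfig:
        return GeometryConfig(self.incidence_deg, self.takeoff_deg, self.excitation_kev)

    def sigma_kev(self, energy_kev: float) -> float:
        fwhm_const = 2.0 * math.sqrt(2.0 * math.log(2.0))
        fwhm2 = self.noise_ev**2 + fwhm_const**2 * self.fano * self.pair_creation_ev * (
            energy_kev * 1000.0
        )
        return math.sqrt(fwhm2) / fwhm_const / 1000.0


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _unit_gaussian(e: np.ndarray, center: float, sigma: float, gain_kev: float) -> np.ndarray:
    return gain_kev / (math.sqrt(2.0 * math.pi) * sigma) * np.exp(
        -0.5 * ((e - center) / sigma) ** 2
    )


def simulate_scan(
    element_maps: Mapping[str, np.ndarray],
    areal_mass: np.ndarray,
    instrument: InstrumentModel,
    seed: int,
    dwell_s: float | None = None,
    poisson: bool = True,
    line_attenuation: Mapping[str, float] | None = None,
) -> ScanDataset:
    """Simulate one raster scan from ground-truth maps.

    Expected net counts of element ``e`` in a pixel are
    ``yield(e) * mass_in_footprint_ag * dwell * transmission * drift``
    (times an optional per-element attenuation factor, used for thick
    standards), reduced by the dead-time fraction; the Compton expectation is
    proportional to the illuminated areal mass.  ``poisson=False`` returns
    the (float) expectations instead of Poisson draws.
    """
    areal_mass = np.asarray(areal_mass, dtype=float)
    rows, cols = areal_mass.shape
    npix = rows * cols
    dwell = instrument.dwell_s if dwell_s is None else dwell_s
    rng = np.random.Generator(np.random.Philox(seed))

    # draw order fixed: (1) diode drift, (2) Poisson counts
    if instrument.diode_drift_rsd > 0:
        s = math.sqrt(math.log(1.0 + instrument.diode_drift_rsd**2))
        drift = rng.lognormal(-0.5 * s**2, s, size=npix)
    else:
        drift = np.ones(npix)
    flux = instrument.absorber_transmission * drift

    symbols = [s for s in instrument.true_yields if s in element_maps]
    for s in element_maps:
        if s not in instrument.true_yields:
            warnings.warn(f"no yield for element {s!r}; omitted from simulation")
    area = instrument.beam_area_cm2
    amass = areal_mass.ravel()

    # expected counts per pixel per component, before dead time
    n_comp = len(symbols) + 2
    amp = np.zeros((npix, n_comp))
    for j, sym in enumerate(symbols):
        mass_ag = element_maps[sym].ravel() * amass * area * _AG_PER_G
        att = 1.0 if line_attenuation is None else line_attenuation.get(sym, 1.0)
        amp[:, j] = instrument.true_yields[sym] * mass_ag * dwell * flux * att
    compton = instrument.compton_per_mass * amass * dwell * flux
    amp[:, -2] = compton
    amp[:, -1] = instrument.rayleigh_fraction * compton

    e = (instrument.offset_ev + instrument.gain_ev * np.arange(instrument.n_channels)) / 1000.0
    gain_kev = instrument.gain_ev / 1000.0
    profiles = np.zeros((n_comp, instrument.n_channels))
    for j, sym in enumerate(symbols):
        le = line_energy(sym)
        profiles[j] = _unit_gaussian(e, le, instrument.sigma_kev(le), gain_kev)
    profiles[-2] = _unit_gaussian(
        e, instrument.compton_kev, 3.0 * instrument.sigma_kev(instrument.compton_kev), gain_kev
    )
    profiles[-1] = _unit_gaussian(
        e, instrument.rayleigh_kev, instrument.sigma_kev(instrument.rayleigh_kev), gain_kev
    )

    b0, b1, b2 = instrument.background_shape
    x = e / instrument.excitation_kev
    cont_kev = np.clip(b0 * (1.0 + b1 * x + b2 * x**2), 0.0, None) * gain_kev
    cont = np.outer(amass * dwell * flux, cont_kev)

    total = amp.sum(axis=1) + cont.sum(axis=1)
    rate = total / dwell
    deadtime = rate * instrument.deadtime_tau_s / (1.0 + rate * instrument.deadtime_tau_s)
    live_frac = 1.0 - deadtime

    lam = (amp @ profiles + cont) * live_frac[:, None]
    if poisson:
        counts = rng.poisson(lam).astype(np.uint32)
    else:
        counts = lam

    return ScanDataset(
        counts=counts.reshape(rows, cols, instrument.n_channels),
        live_time=(dwell * live_frac).reshape(rows, cols),
        real_time=np.full((rows, cols), dwell),
        deadtime=deadtime.reshape(rows, cols),
        diode=(instrument.diode_nominal * flux).reshape(rows, cols),
        gain=instrument.gain_ev,
        offset=instrument.offset_ev,
        meta={
            "dwell_s": dwell,
            "excitation_kev": instrument.excitation_kev,
            "absorber_transmission": instrument.absorber_transmission,
            "seed": seed,
        },
    )


def simulate_phantom_scan(
    spec: PhantomSpec,
    instrument: InstrumentModel,
    seed: int | None = None,
    poisson: bool = True,
):
    """Convenience: rasterize ``spec`` and simulate its scan.

    Returns ``(scan, label_map, element_maps, areal_mass)``.
    """
    label_map, element_maps, areal = build_phantom(spec)
    scan = simulate_scan(
        element_maps,
        areal,
        instrument,
        seed=spec.seed if seed is None else seed,
        poisson=poisson,
    )
    return scan, label_map, element_maps, areal


def simulate_reference_scan(
    standard: ReferenceStandard,
    instrument: InstrumentModel,
    seed: int,
    shape: tuple[int, int] = (50, 50),
    dwell_s: float = 0.5,
    poisson: bool = True,
    provider: ParametricCrossSections | None = None,
) -> ScanDataset:
    """Simulate a scan of the certified reference standard.

    A 10 x 10 um^2 area at 200 nm step and 500 ms dwell corresponds to the
    default 50 x 50 grid.  Thick-target self-absorption is applied to the
    expected line intensities using the same correction model the quantifier
    uses; elements without certified values are omitted with a warning.
    """
    if provider is None:
        provider = ParametricCrossSections()
    geometry = instrument.geometry()
    mu0 = matrix_attenuation(standard.matrix_composition, geometry.excitation_kev, provider)
    maps: dict[str, np.ndarray] = {}
    attenuation: dict[str, float] = {}
    for sym in instrument.true_yields:
        cert = standard.certified.get(sym)
        if cert is None:
            warnings.warn(f"no certified value for {sym!r}; omitted from standard scan")
            continue
        wf = cert[0]
        maps[sym] = np.full(shape, wf)
        mu1 = matrix_attenuation(standard.matrix_composition, line_energy(sym), provider)
        attenuation[sym] = absorption_correction(mu0, mu1, geometry, standard.areal_mass)
    areal = np.full(shape, standard.areal_mass)
    return simulate_scan(
        maps,
        areal,
        instrument,
        seed=seed,
        dwell_s=dwell_s,
        poisson=poisson,
        line_attenuation=attenuation,
    )


def sample_thickness_scale(rng: np.random.Generator, rsd: float = 0.15) -> float:
    """One per-section thickness factor (lognormal, mean 1, ~15% RSD)."""
    sigma = math.sqrt(math.log(1.0 + rsd**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


# ---------------------------------------------------------------------------
# default phantoms (study-condition ground truth)
# ---------------------------------------------------------------------------

#: Mean element weight fractions of unstimulated (control) cells — entire
#: cell, nucleus and cytoplasm.
CONTROL_CELL: dict[str, float] = {
    "P": 1.40e-2, "S": 0.938e-2, "Cl": 3.26e-2, "K": 13.0e-6, "Ca": 125e-6,
    "Mn": 8.66e-6, "Fe": 10.6e-6, "Co": 241e-9, "Ni": 187e-9, "Cu": 17.8e-6,
    "Zn": 10.8e-6, "Se": 30e-9, "Br": 2.21e-6, "Sr": 183e-9, "Pb": 739e-9,
}
CONTROL_NUCLEUS: dict[str, float] = {
    "P": 9.29e-2, "S": 1.36e-2, "Cl": 4.87e-2, "K": 40.1e-6, "Ca": 470e-6,
    "Mn": 34.2e-6, "Fe": 28.0e-6, "Co": 1.18e-6, "Ni": 878e-9, "Cu": 30.6e-6,
    "Zn": 40.0e-6, "Se": 0.0, "Br": 2.62e-6, "Sr": 350e-9, "Pb": 3.13e-6,
}
CONTROL_CYTOPLASM: dict[str, float] = {
    "P": 0.196e-2, "S": 2.29e-2, "Cl": 7.64e-2, "K": 34.5e-6, "Ca": 91.4e-6,
    "Mn": 6.88e-6, "Fe": 17.5e-6, "Co": 59e-9, "Ni": 254e-9, "Cu": 39.2e-6,
    "Zn": 10.4e-6, "Se": 42e-9, "Br": 5.59e-6, "Sr": 362e-9, "Pb": 517e-9,
}


def _default_geometry(grid_shape: tuple[int, int]):
    rows, cols = grid_shape
    cell = Ellipse(rows / 2.0, cols / 2.0, rows * 0.30, cols * 0.20)
    nucleus = Ellipse(rows / 2.0, cols / 2.0, rows * 0.15, cols * 0.10)
    return cell, nucleus


def control_cell_phantom(
    grid_shape: tuple[int, int] = (100, 100),
    thickness_scale: float = 1.0,
    seed: int = 0,
) -> PhantomSpec:
    """A cell with uniform control-condition composition (resin background)."""
    cell, nucleus = _default_geometry(grid_shape)
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=[("cytoplasm", cell), ("nucleus", nucleus)],
        region_concentrations={
            "cytoplasm": dict(CONTROL_CELL),
            "nucleus": dict(CONTROL_CELL),
            "background": {},
        },
        thickness_scale=thickness_scale,
        seed=seed,
    )


def compartment_phantom(
    grid_shape: tuple[int, int] = (100, 100),
    thickness_scale: float = 1.0,
    seed: int = 0,
) -> PhantomSpec:
    """A cell with distinct control-condition nucleus and cytoplasm."""
    cell, nucleus = _default_geometry(grid_shape)
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=[("cytoplasm", cell), ("nucleus", nucleus)],
        region_concentrations={
            "cytoplasm": dict(CONTROL_CYTOPLASM),
            "nucleus": dict(CONTROL_NUCLEUS),
            "background": {},
        },
        thickness_scale=thickness_scale,
        seed=seed,
    )


#: Mean nucleus/cytoplasm weight fractions per stimulation time (h); the
#: study conditions emulated by the time-course phantoms (replicate counts
#: 3/3/2 cells at 0/1/2 h).
STUDY_CONDITIONS: dict[float, dict[str, dict[str, float]]] = {
    0.0: {"nucleus": CONTROL_NUCLEUS, "cytoplasm": CONTROL_CYTOPLASM},
    1.0: {
        "nucleus": {
            "P": 12.9e-2, "S": 1.13e-2, "Cl": 3.45e-2, "K": 34.5e-6,
            "Ca": 1830e-6, "Mn": 37.5e-6, "Fe": 20.4e-6, "Co": 25.4e-9,
            "Ni": 509e-9, "Cu": 103e-6, "Zn": 48.0e-6, "Se": 111e-9,
            "Br": 1.55e-6, "Sr": 587e-9, "Pb": 714e-9,
        },
        "cytoplasm": {
            "P": 0.772e-2, "S": 1.44e-2, "Cl": 4.20e-2, "K": 22.1e-6,
            "Ca": 112e-6, "Mn": 10.1e-6, "Fe": 13.8e-6, "Co": 10.2e-9,
            "Ni": 270e-9, "Cu": 107e-6, "Zn": 14.5e-6, "Se": 23e-9,
            "Br": 2.70e-6, "Sr": 158e-9, "Pb": 422e-9,
        },
    },
    2.0: {
        "nucleus": {
            "P": 15.9e-2, "S": 0.415e-2, "Cl": 1.38e-2, "K": 26.1e-6,
            "Ca": 2640e-6, "Mn": 90.9e-6, "Fe": 14.1e-6, "Co": 30e-9,
            "Ni": 592e-9, "Cu": 57.3e-6, "Zn": 54.9e-6, "Se": 144e-9,
            "Br": 103e-9, "Sr": 2.75e-6, "Pb": 388e-9,
        },
        "cytoplasm": {
            "P": 6.43e-2, "S": 2.08e-2, "Cl": 0.572e-2, "K": 547e-6,
            "Ca": 163e-6, "Mn": 169e-6, "Fe": 7.86e-6, "Co": 29e-9,
            "Ni": 10.2e-6, "Cu": 32.7e-6, "Zn": 6.68e-6, "Se": 212e-9,
            "Br": 1.70e-6, "Sr": 613e-9, "Pb": 152e-9,
        },
    },
}

#: Replicate cells measured per stimulation time.
STUDY_REPLICATES: dict[float, int] = {0.0: 3, 1.0: 3, 2.0: 2}


def condition_phantom(
    time_h: float,
    grid_shape: tuple[int, int] = (100, 100),
    thickness_scale: float = 1.0,
    cell_rsd: float = 0.10,
    seed: int = 0,
) -> PhantomSpec:
    """Phantom for one cell at one stimulation time.

    Ground-truth nucleus/cytoplasm compositions are the condition means
    perturbed by an independent lognormal cell-to-cell factor per element
    (~10% RSD), emulating biological replicate variability.
    """
    if time_h not in STUDY_CONDITIONS:
        raise ValueError(f"no study condition at {time_h} h")
    cell, nucleus = _default_geometry(grid_shape)
    rng = np.random.Generator(np.random.Philox(seed))
    sigma = math.sqrt(math.log(1.0 + cell_rsd**2)) if cell_rsd > 0 else 0.0
    conc: dict[str, dict[str, float]] = {"background": {}}
    for region in ("nucleus", "cytoplasm"):
        base = STUDY_CONDITIONS[time_h][region]
        factors = (
            rng.lognormal(-0.5 * sigma**2, sigma, size=len(base))
            if sigma > 0
            else np.ones(len(base))
        )
        conc[region] = {
            sym: wf * float(f) for (sym, wf), f in zip(sorted(base.items()), factors)
        }
    return PhantomSpec(
        grid_shape=grid_shape,
        regions=[("cytoplasm", cell), ("nucleus", nucleus)],
        region_concentrations=conc,
        thickness_scale=thickness_scale,
        seed=seed,
    )
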