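"""Energy-dispersive XRF spectrum model and fitting.

A recorded spectrum is modelled over a region of interest (ROI) as a sum of

* one effective Gaussian per element line group, centred at the K-alpha
  (or L-alpha) energy with the detector's energy-dependent width
  ``sigma(E) = sqrt(noise^2 + fano * eps * E)``,
* a low-order polynomial continuum in energy,
* Gaussian Compton and Rayleigh scatter peaks (the Compton peak broadened
  by a configurable width scale).

Because centres and widths are fixed by the calibration, the model is linear
in its amplitudes: fitting is a weighted bounded linear least-squares problem
(areas constrained non-negative, continuum coefficients free), with per-channel
weights 1/max(counts, 1) and 1-sigma area uncertainties from the covariance of
the weighted normal equations.  This mirrors the classical iterative
least-squares treatment of XRF spectra in a deterministic, reproducible form;
escape and pile-up sum peaks are not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .elements import DETECTABLE_ELEMENTS, line_energy

__all__ = [
    "Spectrum",
    "SpectralLine",
    "FitModel",
    "FitResult",
    "LineResult",
    "default_fit_model",
    "fit_spectrum",
    "batch_fit",
    "sum_spectra",
]

_SQRT2PI = math.sqrt(2.0 * math.pi)
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """One energy-dispersive spectrum plus its acquisition telemetry.

    ``counts`` is one value per channel; channel ``i`` spans energies around
    ``offset + gain * i`` (both in eV).  ``n_pixels_summed`` is 1 for a point
    spectrum and the number of members for a cluster sum spectrum.
    """

    counts: np.ndarray
    gain: float  # eV / channel
    offset: float = 0.0  # eV
    live_time: float = 1.0  # s
    real_time: float = 1.0  # s
    deadtime_fraction: float = 0.0
    diode_mean: float = 1.0  # arbitrary units
    n_pixels_summed: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.live_time > self.real_time * (1 + 1e-9):
            raise ValueError("live_time cannot exceed real_time")
        if not (0.0 <= self.deadtime_fraction < 1.0):
            raise ValueError("deadtime_fraction must be in [0, 1)")

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    def energies_kev(self) -> np.ndarray:
        """Channel-centre energies in keV."""
        return (self.offset + self.gain * np.arange(self.n_channels)) / 1000.0


@dataclass(frozen=True)
class SpectralLine:
    """One element line group fitted as a single effective Gaussian."""

    element: str
    group: str  # "K" or "L"
    energy_kev: float


@dataclass
class FitModel:
    """Fit configuration shared by point spectra and cluster sum spectra."""

    roi: tuple[int, int]  # [start, stop) channel range
    lines: Sequence[SpectralLine]
    background_order: int = 4
    compton_kev: float = 16.3
    rayleigh_kev: float = 17.0
    compton_width_scale: float = 3.0
    noise_ev: float = 100.0  # electronic noise FWHM, eV
    fano: float = 0.114
    pair_creation_ev: float = 3.85  # eV per electron-hole pair in Si

    def __post_init__(self) -> None:
        if self.background_order < 0:
            raise ValueError("background order must be >= 0")
        if self.roi[1] <= self.roi[0]:
            raise ValueError("empty ROI")

    def sigma_kev(self, energy_kev: np.ndarray | float) -> np.ndarray | float:
        """Detector Gaussian sigma at ``energy_kev``, in keV."""
        fwhm2_ev2 = self.noise_ev**2 + _FWHM**2 * self.fano * self.pair_creation_ev * (
            np.asarray(energy_kev) * 1000.0
        )
        return np.sqrt(fwhm2_ev2) / _FWHM / 1000.0

    def validate_against(self, spectrum: Spectrum) -> None:
        lo, hi = self.roi
        if lo < 0 or hi > spectrum.n_channels:
            raise ValueError(
                f"ROI {self.roi} outside spectrum with {spectrum.n_channels} channels"
            )
        e = spectrum.energies_kev()
        e_lo, e_hi = e[lo], e[hi - 1]
        for line in self.lines:
            if not (e_lo <= line.energy_kev <= e_hi):
                raise ValueError(
                    f"line {line.element} at {line.energy_kev} keV outside ROI "
                    f"[{e_lo:.3f}, {e_hi:.3f}] keV"
                )


@dataclass
class LineResult:
    net_area: float
    net_area_sigma: float
    background_under_peak: float


@dataclass
class FitResult:
    """Net areas per line group plus continuum and scatter peak areas."""

    lines: dict[str, LineResult]
    compton_area: float
    compton_sigma: float
    rayleigh_area: float
    rayleigh_sigma: float
    reduced_chi2: float
    converged: bool = True

    def net(self, element: str) -> float:
        return self.lines[element].net_area

    def net_sigma(self, element: str) -> float:
        return self.lines[element].net_area_sigma

    def background(self, element: str) -> float:
        return self.lines[element].background_under_peak


def default_fit_model(
    gain: float = 20.0,
    n_channels: int = 1024,
    offset: float = 0.0,
    elements: Iterable[str] = DETECTABLE_ELEMENTS + ("Rb",),
    excitation_kev: float = 17.0,
    compton_kev: float = 16.3,
    background_order: int = 4,
) -> FitModel:
    """Fit model covering the standard element list.

    The ROI runs from just below the P K-alpha line to just above the
    Rayleigh peak at the excitation energy.
    """
    lines = []
    for sym in elements:
        e = line_energy(sym)
        group = "L" if sym == "Pb" else "K"
        lines.append(SpectralLine(sym, group, e))
    lo = max(0, int((1.7 * 1000.0 - offset) / gain))
    hi = min(n_channels, int(((excitation_kev + 1.0) * 1000.0 - offset) / gain))
    return FitModel(
        roi=(lo, hi),
        lines=tuple(lines),
        background_order=background_order,
        compton_kev=compton_kev,
        rayleigh_kev=excitation_kev,
    )


# ---------------------------------------------------------------------------
# design matrix and solver
# ---------------------------------------------------------------------------


def _gaussian_profile(e: np.ndarray, center: float, sigma: float, gain_kev: float) -> np.ndarray:
    """Unit-area Gaussian sampled at channel centres (area in counts)."""
    return gain_kev / (_SQRT2PI * sigma) * np.exp(-0.5 * ((e - center) / sigma) ** 2)


def _design_matrix(model: FitModel, gain: float, offset: float, n_channels: int):
    """Columns: one unit-area profile per line, Compton, Rayleigh, continuum."""
    lo, hi = model.roi
    e = (offset + gain * np.arange(n_channels))[lo:hi] / 1000.0
    gain_kev = gain / 1000.0
    cols = []
    names = []
    for line in model.lines:
        sigma = float(model.sigma_kev(line.energy_kev))
        cols.append(_gaussian_profile(e, line.energy_kev, sigma, gain_kev))
        names.append(line.element)
    cols.append(
        _gaussian_profile(
            e,
            model.compton_kev,
            model.compton_width_scale * float(model.sigma_kev(model.compton_kev)),
            gain_kev,
        )
    )
    names.append("__compton__")
    cols.append(
        _gaussian_profile(
            e, model.rayleigh_kev, float(model.sigma_kev(model.rayleigh_kev)), gain_kev
        )
    )
    names.append("__rayleigh__")
    # continuum: Legendre-like scaled polynomial basis on [-1, 1] for conditioning
    x = 2.0 * (e - e[0]) / (e[-1] - e[0]) - 1.0
    for k in range(model.background_order + 1):
        cols.append(np.polynomial.legendre.Legendre.basis(k)(x))
        names.append(f"__bg{k}__")
    a = np.column_stack(cols)
    n_amp = len(model.lines) + 2  # non-negative columns
    return a, names, e, n_amp


def _solve_wls_nonneg(a: np.ndarray, y: np.ndarray, w: np.ndarray, n_amp: int):
    """Weighted least squares with the first ``n_amp`` coefficients >= 0.

    Solves the unconstrained weighted problem first; falls back to bounded
    BVLS only when an amplitude goes negative.  Returns (coef, cov, converged).
    """
    sw = np.sqrt(w)
    aw = a * sw[:, None]
    yw = y * sw
    coef, *_ = np.linalg.lstsq(aw, yw, rcond=None)
    if np.any(coef[:n_amp] < 0):
        n = a.shape[1]
        lb = np.full(n, -np.inf)
        ub = np.full(n, np.inf)
        lb[:n_amp] = 0.0
        res = lsq_linear(aw, yw, bounds=(lb, ub), method="bvls", tol=1e-12)
        coef = res.x
        converged = bool(res.status > 0 or res.status == 0)
    else:
        converged = True
    ata = aw.T @ aw
    try:
        cov = np.linalg.inv(ata)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(ata)
    return coef, cov, converged


def fit_spectrum(spectrum: Spectrum, model: FitModel) -> FitResult:
    """Fit one spectrum, returning net areas with 1-sigma uncertainties.

    Per-channel weights are ``1/max(counts, 1)`` (Poisson-motivated); the fit
    is deterministic for fixed inputs.  A failed bounded solve is flagged
    through ``converged=False`` with NaN areas, never silently.
    """
    model.validate_against(spectrum)
    a, names, e, n_amp = _design_matrix(
        model, spectrum.gain, spectrum.offset, spectrum.n_channels
    )
    lo, hi = model.roi
    y = spectrum.counts[lo:hi].astype(float)
    w = 1.0 / np.maximum(y, 1.0)
    try:
        coef, cov, converged = _solve_wls_nonneg(a, y, w, n_amp)
    except Exception:
        coef = np.full(a.shape[1], np.nan)
        cov = np.full((a.shape[1], a.shape[1]), np.nan)
        converged = False
    sig = np.sqrt(np.maximum(np.diag(cov), 0.0))
    resid = y - a @ coef if converged else np.full_like(y, np.nan)
    dof = max(len(y) - a.shape[1], 1)
    red_chi2 = float(np.sum(resid**2 * w) / dof) if converged else float("nan")

    bg_cols = [i for i, n in enumerate(names) if n.startswith("__bg")]
    bg_profile = a[:, bg_cols] @ coef[bg_cols] if converged else np.zeros_like(y)

    lines: dict[str, LineResult] = {}
    for i, line in enumerate(model.lines):
        sigma_kev = float(model.sigma_kev(line.energy_kev))
        if converged:
            win = np.abs(e - line.energy_kev) <= 1.5 * sigma_kev
            bg_under = float(np.clip(np.sum(bg_profile[win]), 0.0, None))
        else:
            bg_under = float("nan")
        lines[line.element] = LineResult(
            net_area=float(coef[i]),
            net_area_sigma=float(max(sig[i], 1e-12)),
            background_under_peak=bg_under,
        )
    i_c = names.index("__compton__")
    i_r = names.index("__rayleigh__")
    return FitResult(
        lines=lines,
        compton_area=float(coef[i_c]),
        compton_sigma=float(max(sig[i_c], 1e-12)),
        rayleigh_area=float(coef[i_r]),
        rayleigh_sigma=float(max(sig[i_r], 1e-12)),
        reduced_chi2=red_chi2,
        converged=converged,
    )


def batch_fit(scan, model: FitModel) -> dict[str, np.ndarray]:
    """Fit every pixel of a scan with the same model.

    Returns a dict of maps: one per element (net counts), plus
    ``"__compton__"``, ``"__rayleigh__"``, ``"__background__"`` (total
    continuum counts in the ROI) and a boolean ``"__ok__"`` quality mask.
    A failing pixel is flagged in the mask, never aborts the batch.
    """
    rows, cols = scan.shape
    if rows * cols == 0:
        raise ValueError("empty scan")
    a, names, e, n_amp = _design_matrix(model, scan.gain, scan.offset, scan.n_channels)
    lo, hi = model.roi
    bg_cols = [i for i, n in enumerate(names) if n.startswith("__bg")]
    elems = [ln.element for ln in model.lines]
    maps = {sym: np.zeros((rows, cols)) for sym in elems}
    maps["__compton__"] = np.zeros((rows, cols))
    maps["__rayleigh__"] = np.zeros((rows, cols))
    maps["__background__"] = np.zeros((rows, cols))
    ok = np.ones((rows, cols), dtype=bool)
    i_c = names.index("__compton__")
    i_r = names.index("__rayleigh__")
    for r in range(rows):
        for c in range(cols):
            y = scan.counts[r, c, lo:hi].astype(float)
            w = 1.0 / np.maximum(y, 1.0)
            try:
                coef, _, converged = _solve_wls_nonneg(a, y, w, n_amp)
            except Exception:
                converged = False
            if not converged:
                ok[r, c] = False
                for sym in elems:
                    maps[sym][r, c] = np.nan
                maps["__compton__"][r, c] = np.nan
                maps["__rayleigh__"][r, c] = np.nan
                maps["__background__"][r, c] = np.nan
                continue
            for i, sym in enumerate(elems):
                maps[sym][r, c] = coef[i]
            maps["__compton__"][r, c] = coef[i_c]
            maps["__rayleigh__"][r, c] = coef[i_r]
            maps["__background__"][r, c] = float(np.sum(a[:, bg_cols] @ coef[bg_cols]))
    maps["__ok__"] = ok
    return maps


# ---------------------------------------------------------------------------
# spectrum summation
# ---------------------------------------------------------------------------


def sum_spectra(spectra: Iterable[Spectrum]) -> Spectrum:
    """Channelwise sum of point spectra sharing one calibration.

    Counts add exactly (integer conservation); live and real times add; the
    aggregated dead-time fraction is ``1 - sum(live)/sum(real)``; the diode
    reading is averaged; ``n_pixels_summed`` accumulates.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to sum")
    first = spectra[0]
    total = np.zeros_like(np.asarray(first.counts))
    live = real = 0.0
    diode = 0.0
    n = 0
    for s in spectra:
        if s.n_channels != first.n_channels or s.gain != first.gain or s.offset != first.offset:
            raise ValueError("calibration mismatch between spectra")
        total = total + s.counts
        live += s.live_time
        real += s.real_time
        diode += s.diode_mean * s.n_pixels_summed
        n += s.n_pixels_summed
    dt = 1.0 - live / real if real > 0 else 0.0
    return Spectrum(
        counts=total,
        gain=first.gain,
        offset=first.offset,
        live_time=live,
        real_time=real,
        deadtime_fraction=max(dt, 0.0),
        diode_mean=diode / n,
        n_pixels_summed=n,
    )
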