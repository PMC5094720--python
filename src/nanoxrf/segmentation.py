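"""Cluster masks and cluster sum spectra.

A cluster is a labelled pixel set of one scan — entire cell, nucleus,
cytoplasm or background.  Cell and nucleus outlines come from the Zn K-alpha
intensity map (clear drop at the cell/resin border, clear rise at the
cytoplasm/nucleus transition); cytoplasm and background follow by set
algebra: cytoplasm = cell minus nucleus, background = scan minus cell.
Summing the member point spectra raises counting statistics by the member
count, which is what makes trace elements quantifiable at all.

Pixel convention: row-major, 0-based grids matching the scan shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label

from .dataset import ScanDataset
from .spectral import FitModel, Spectrum, fit_spectrum, sum_spectra

__all__ = [
    "ClusterMask",
    "ClusterSumSpectrum",
    "threshold_mask",
    "mask_algebra",
    "cluster_sum",
    "segment_cell_nucleus",
]


@dataclass
class ClusterMask:
    """A labelled boolean pixel set."""

    label: str
    pixels: np.ndarray  # boolean grid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D grid")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ClusterSumSpectrum:
    """Sum spectrum of a cluster plus its aggregated telemetry."""

    spectrum: Spectrum
    label: str
    n_pixels: int
    mean_deadtime: float
    mean_diode: float
    compton_intensity: float  # dead-time corrected counts
    rayleigh_intensity: float

    def __post_init__(self) -> None:
        if self.n_pixels != self.spectrum.n_pixels_summed:
            raise ValueError("n_pixels inconsistent with summed spectrum")

    def metadata_row(self) -> dict:
        """CSV-ready record mirroring the cluster bookkeeping of a run."""
        return {
            "label": self.label,
            "n_pixels": self.n_pixels,
            "mean_deadtime": self.mean_deadtime,
            "mean_diode": self.mean_diode,
            "compton_intensity": self.compton_intensity,
            "rayleigh_intensity": self.rayleigh_intensity,
        }


def _cleanup(mask: np.ndarray) -> np.ndarray:
    """Keep the largest connected component and fill its holes."""
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def _smooth(intensity: np.ndarray, sigma: float) -> np.ndarray:
    if sigma > 0:
        return ndimage.gaussian_filter(np.asarray(intensity, dtype=float), sigma)
    return np.asarray(intensity, dtype=float)


def threshold_mask(
    intensity: np.ndarray,
    method: str = "otsu",
    label: str = "cluster",
    quantile: float | None = None,
    smooth_sigma: float = 0.0,
    log_scale: bool = False,
) -> ClusterMask:
    """Foreground mask from an element intensity map.

    ``method`` is ``"otsu"`` or ``"quantile"`` (threshold at the given
    quantile of the map).  Unless importing a manual mask elsewhere, the
    result is cleaned up: largest connected component kept, holes filled.
    A constant map (no separable foreground) or an empty cleaned mask is an
    error naming the threshold.
    """
    arr = np.asarray(intensity, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensity map contains non-finite values")
    work = _smooth(arr, smooth_sigma)
    if log_scale:
        work = np.log1p(np.clip(work, 0.0, None))
    if np.ptp(work) == 0:
        raise ValueError("constant intensity map: no separable foreground")
    if method == "otsu":
        thr = threshold_otsu(work)
    elif method == "quantile":
        if quantile is None:
            raise ValueError("quantile method requires a quantile")
        thr = np.quantile(work, quantile)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = work > thr
    mask = _cleanup(mask)
    if not mask.any():
        raise ValueError(f"empty mask after cleanup at threshold {thr}")
    return ClusterMask(label=label, pixels=mask)


def segment_cell_nucleus(
    zn_map: np.ndarray,
    smooth_sigma: float = 2.0,
    nucleus_contrast: float = 2.0,
) -> tuple[ClusterMask, ClusterMask]:
    """Cell and nucleus masks from a Zn intensity map.

    Hierarchical two-level Otsu on the smoothed map: the upper multi-Otsu
    threshold isolates the Zn-enriched nucleus candidate; the cell/resin
    boundary is then an Otsu split of the remaining (non-nucleus) pixels, so
    a dim cytoplasm is not swallowed by the bright nucleus mode.  The
    nucleus is only accepted when its mean intensity exceeds the rest of the
    cell by ``nucleus_contrast``; otherwise (a uniform cell) the nucleus
    mask comes back empty and set algebra makes cytoplasm = cell.
    """
    work = _smooth(np.clip(zn_map, 0.0, None), smooth_sigma)
    if np.ptp(work) == 0:
        raise ValueError("constant intensity map: no separable foreground")
    _, thr_hi = threshold_multiotsu(work, classes=3)
    # resin level from the border frame (the cell sits inside the field of
    # view); cytoplasm plateau from the eroded non-nucleus foreground (the
    # erosion removes the smoothing ramp at the cell edge); cell boundary at
    # the half-height midpoint between the two levels.
    frame = np.ones(work.shape, dtype=bool)
    frame[2:-2, 2:-2] = False
    bg_level = float(np.median(work[frame]))
    bg_std = float(work[frame].std())
    peak = float(np.percentile(work, 99.0))
    cand = work > bg_level + max(3.0 * bg_std, 0.05 * (peak - bg_level))
    if not cand.any():
        raise ValueError("no separable foreground above the resin background")
    eroded = ndimage.binary_erosion(cand, iterations=max(int(2 * smooth_sigma), 1))
    # histogram mode of the eroded candidate estimates the cytoplasm
    # plateau: robust to the bright nucleus (and its blur halo) and to
    # residual edge-ramp pixels
    vals = work[eroded if eroded.any() else cand]
    hist, edges = np.histogram(vals, bins=48)
    i = int(np.argmax(hist))
    plateau = 0.5 * float(edges[i] + edges[i + 1])
    thr_cell = 0.5 * (bg_level + plateau)
    cell = _cleanup(work > thr_cell)
    if not cell.any():
        raise ValueError("empty cell mask after cleanup")
    candidate = (work > thr_hi) & cell
    body = cell & ~candidate
    nucleus = np.zeros_like(cell)
    if candidate.any() and body.any():
        if work[candidate].mean() >= nucleus_contrast * work[body].mean():
            nucleus = _cleanup(candidate) & cell
    return ClusterMask("cell", cell), ClusterMask("nucleus", nucleus)


def mask_algebra(
    total: ClusterMask, cell: ClusterMask, nucleus: ClusterMask
) -> tuple[ClusterMask, ClusterMask]:
    """Cytoplasm and background by set subtraction.

    ``cytoplasm = cell AND NOT nucleus``; ``background = total AND NOT
    cell``.  Requires nucleus within cell within total; a containment
    violation reports the number of offending pixels.
    """
    if not (total.shape == cell.shape == nucleus.shape):
        raise ValueError("mask shapes differ")
    out_nuc = int(np.sum(nucleus.pixels & ~cell.pixels))
    if out_nuc:
        raise ValueError(f"{out_nuc} nucleus pixels outside the cell mask")
    out_cell = int(np.sum(cell.pixels & ~total.pixels))
    if out_cell:
        raise ValueError(f"{out_cell} cell pixels outside the total mask")
    cytoplasm = ClusterMask("cytoplasm", cell.pixels & ~nucleus.pixels)
    background = ClusterMask("background", total.pixels & ~cell.pixels)
    return cytoplasm, background


def cluster_sum(
    scan: ScanDataset,
    mask: ClusterMask,
    fit_model: FitModel | None = None,
) -> ClusterSumSpectrum:
    """Sum the member point spectra of a cluster.

    The summed spectrum carries summed live/real times; the cluster record
    carries the arithmetic means of dead time and diode reading over members.
    When a fit model is given, the Compton and Rayleigh intensities of the
    summed spectrum are extracted by fitting and dead-time corrected.
    """
    if mask.shape != scan.shape:
        raise ValueError("mask shape does not match scan shape")
    idx = np.nonzero(mask.pixels)
    if idx[0].size == 0:
        raise ValueError("empty cluster mask")
    counts = scan.counts[idx].sum(axis=0)
    live = float(scan.live_time[idx].sum())
    real = float(scan.real_time[idx].sum())
    mean_dt = float(scan.deadtime[idx].mean())
    mean_diode = float(scan.diode[idx].mean())
    n = int(idx[0].size)
    spectrum = Spectrum(
        counts=counts,
        gain=scan.gain,
        offset=scan.offset,
        live_time=live,
        real_time=real,
        deadtime_fraction=max(1.0 - live / real, 0.0),
        diode_mean=mean_diode,
        n_pixels_summed=n,
    )
    compton = rayleigh = float("nan")
    if fit_model is not None:
        fit = fit_spectrum(spectrum, fit_model)
        dt_corr = 1.0 / (1.0 - mean_dt)
        compton = fit.compton_area * dt_corr
        rayleigh = fit.rayleigh_area * dt_corr
    return ClusterSumSpectrum(
        spectrum=spectrum,
        label=mask.label,
        n_pixels=n,
        mean_deadtime=mean_dt,
        mean_diode=mean_diode,
        compton_intensity=compton,
        rayleigh_intensity=rayleigh,
    )
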