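"""Raster-scan dataset container.

A ``ScanDataset`` bundles the per-pixel energy-dispersive spectra of one
raster scan with the acquisition telemetry needed downstream: per-pixel live
and real time, dead-time fraction and diode (incident-flux monitor) reading,
plus the energy calibration and free-form metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .spectral import Spectrum

__all__ = ["ScanDataset"]


@dataclass
class ScanDataset:
    """One raster XRF scan: spectra plus telemetry.

    ``counts`` has shape (rows, cols, n_channels); the telemetry arrays have
    shape (rows, cols).
    """

    counts: np.ndarray
    live_time: np.ndarray  # s
    real_time: np.ndarray  # s
    deadtime: np.ndarray  # fraction in [0, 1)
    diode: np.ndarray  # arbitrary units
    gain: float  # eV / channel
    offset: float = 0.0  # eV
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (rows, cols, n_channels)")
        shape = self.counts.shape[:2]
        for name in ("live_time", "real_time", "deadtime", "diode"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != scan shape {shape}")
            setattr(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_channels(self) -> int:
        return int(self.counts.shape[2])

    def spectrum(self, row: int, col: int) -> Spectrum:
        """The point spectrum of one pixel."""
        return Spectrum(
            counts=self.counts[row, col],
            gain=self.gain,
            offset=self.offset,
            live_time=float(self.live_time[row, col]),
            real_time=float(self.real_time[row, col]),
            deadtime_fraction=float(self.deadtime[row, col]),
            diode_mean=float(self.diode[row, col]),
            n_pixels_summed=1,
        )

    def iter_spectra(self):
        rows, cols = self.shape
        for r in range(rows):
            for c in range(cols):
                yield (r, c), self.spectrum(r, c)
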