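"""Container and sidecar-file I/O.

The scan container is HDF5 with groups ``/scan`` (spectra + telemetry),
``/maps`` (fitted intensity maps), ``/masks`` and ``/meta``.  Masks travel as
single-channel TIFF or PNG (0 = out, 255 = in); tables as CSV; ground truth
as CSV plus a TIFF label map.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .dataset import ScanDataset
from .segmentation import ClusterMask

__all__ = [
    "save_scan",
    "load_scan",
    "save_mask",
    "load_mask",
    "save_label_map",
    "save_truth_csv",
]

_LABEL_CODES = {"background": 0, "cytoplasm": 1, "nucleus": 2, "cell": 3}


def save_scan(
    path,
    scan: ScanDataset,
    maps: Mapping[str, np.ndarray] | None = None,
    masks: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write a scan (and optional derived maps/masks) to an HDF5 container."""
    with h5py.File(path, "w") as h5:
        g = h5.create_group("scan")
        g.create_dataset("spectra", data=scan.counts, compression="gzip")
        g.create_dataset("live_time", data=scan.live_time)
        g.create_dataset("real_time", data=scan.real_time)
        g.create_dataset("deadtime", data=scan.deadtime)
        g.create_dataset("diode", data=scan.diode)
        meta = h5.create_group("meta")
        meta.attrs["gain_ev"] = scan.gain
        meta.attrs["offset_ev"] = scan.offset
        meta.attrs["extra"] = json.dumps(scan.meta, sort_keys=True, default=float)
        if maps:
            gm = h5.create_group("maps")
            for name, arr in maps.items():
                gm.create_dataset(name.strip("_"), data=np.asarray(arr))
        if masks:
            gk = h5.create_group("masks")
            for name, arr in masks.items():
                gk.create_dataset(name, data=np.asarray(arr, dtype=np.uint8))


def load_scan(path) -> ScanDataset:
    with h5py.File(path, "r") as h5:
        g = h5["scan"]
        meta = h5["meta"]
        return ScanDataset(
            counts=g["spectra"][...],
            live_time=g["live_time"][...],
            real_time=g["real_time"][...],
            deadtime=g["deadtime"][...],
            diode=g["diode"][...],
            gain=float(meta.attrs["gain_ev"]),
            offset=float(meta.attrs["offset_ev"]),
            meta=json.loads(meta.attrs.get("extra", "{}")),
        )


def save_mask(path, mask: ClusterMask) -> None:
    """Write a mask as 0/255 single-channel TIFF or PNG."""
    path = Path(path)
    img = np.where(mask.pixels, 255, 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def load_mask(path, label: str | None = None) -> ClusterMask:
    """Read a manual mask (any nonzero pixel is a member)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return ClusterMask(label=label or path.stem, pixels=img > 0)


def save_label_map(path, label_map: np.ndarray) -> None:
    codes = np.zeros(label_map.shape, dtype=np.uint8)
    for name, code in _LABEL_CODES.items():
        codes[label_map == name] = code
    tifffile.imwrite(path, codes)


def save_truth_csv(path, region_concentrations: Mapping[str, Mapping[str, float]]) -> None:
    rows = [
        {"region": region, "element": sym, "weight_fraction": wf}
        for region, conc in sorted(region_concentrations.items())
        for sym, wf in sorted(conc.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
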