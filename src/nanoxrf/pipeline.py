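"""End-to-end pipeline: simulate -> fit -> segment -> quantify -> stats -> render.

Orchestrates the full quantification chain on a synthetic study (replicate
phantom cells at 0/1/2 h stimulation plus a reference-standard scan) and
writes the run outputs: per-cluster quantification CSVs, a group-summary
table (mean +/- RSD per element, compartment and time), a trend table
(regression/ANOVA/KW), cluster metadata, RGB composites of the Ca/Zn/Fe maps,
and a JSON run log with the config hash and seed.  The run is a pure
function of (config, seed): reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import imageio.v3 as iio

from . import io as nio
from .dataset import ScanDataset
from .elements import DETECTABLE_ELEMENTS
from .fpquant import (
    NormalizedIntensities,
    QuantResult,
    ReferenceStandard,
    calibrate_yields,
    normalize_sum_spectrum,
    quantify_cluster,
)
from .segmentation import ClusterMask, cluster_sum, mask_algebra, segment_cell_nucleus
from .spectral import batch_fit, default_fit_model, fit_spectrum
from .synthetic import (
    STUDY_REPLICATES,
    InstrumentModel,
    condition_phantom,
    sample_thickness_scale,
    simulate_phantom_scan,
    simulate_reference_scan,
)
from .stats import TimeCourse, build_trend_table, group_summary

__all__ = [
    "PipelineConfig",
    "RGBComposite",
    "render_rgb",
    "run_pipeline",
    "PipelineStageError",
    "run_closure_experiment",
    "run_thickness_pair_experiment",
]


class PipelineStageError(RuntimeError):
    """Failure of one named pipeline stage; earlier outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one run; every field has a printable default."""

    output_dir: str = "nanoxrf_run"
    seed: int = 0
    grid_shape: tuple[int, int] = (64, 64)
    replicates: dict = field(default_factory=lambda: dict(STUDY_REPLICATES))
    cell_rsd: float = 0.10
    thickness_rsd: float = 0.15
    normalization: str = "compton"  # or "conventional"
    density_g_cm3: float = 1.13
    thickness_um: float = 2.0
    srm_shape: tuple[int, int] = (50, 50)
    srm_dwell_s: float = 0.5
    srm_transmission: float = 0.125
    significance: float = 0.05
    ci_level: float = 0.95
    plotting_positions: str = "blom"
    save_containers: bool = False
    render_elements: tuple[str, str, str] = ("Ca", "Zn", "Fe")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["srm_shape"] = list(self.srm_shape)
        d["render_elements"] = list(self.render_elements)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RGBComposite:
    """8-bit composite of three normalized intensity maps."""

    channels: tuple[str, str, str]
    thresholds: tuple[float, float, float]
    image: np.ndarray  # (rows, cols, 3) uint8


def render_rgb(
    maps: tuple[np.ndarray, np.ndarray, np.ndarray],
    thresholds: tuple[float, float, float],
    channels: tuple[str, str, str] = ("Ca", "Zn", "Fe"),
) -> RGBComposite:
    """Clip-and-scale three maps into one RGB image.

    Channel value is ``round(255 * min(intensity/threshold, 1))``
    (round half up); sharing thresholds across a series keeps brightness
    comparable between images.
    """
    shapes = {np.asarray(m).shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share one shape")
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    img = np.zeros(maps[0].shape + (3,), dtype=np.uint8)
    for k, (m, thr) in enumerate(zip(maps, thresholds)):
        scaled = np.minimum(np.asarray(m, dtype=float) / thr, 1.0)
        img[..., k] = np.floor(255.0 * np.clip(scaled, 0.0, None) + 0.5).astype(np.uint8)
    return RGBComposite(channels=channels, thresholds=tuple(thresholds), image=img)


def _normalized_maps(scan: ScanDataset, maps: dict, ref_diode: float) -> dict:
    """Per-pixel maps normalized to diode, dead time and dwell."""
    factor = ref_diode / (scan.diode * (1.0 - scan.deadtime) * scan.real_time)
    return {
        sym: np.nan_to_num(maps[sym]) * factor
        for sym in maps
        if not sym.startswith("__")
    }


def _quantify_cell(
    scan: ScanDataset,
    fit_model,
    instrument: InstrumentModel,
    label: str,
):
    """Fit, segment and sum one cell scan; returns cluster records + maps."""
    maps = batch_fit(scan, fit_model)
    cell_mask, nucleus_mask = segment_cell_nucleus(np.nan_to_num(maps["Zn"]))
    total = ClusterMask("total", np.ones(scan.shape, dtype=bool))
    cytoplasm_mask, background_mask = mask_algebra(total, cell_mask, nucleus_mask)
    clusters = {}
    for mask, name in (
        (cell_mask, "entire_cell"),
        (nucleus_mask, "nucleus"),
        (cytoplasm_mask, "cytoplasm"),
        (background_mask, "background"),
    ):
        if mask.n_pixels == 0:
            continue
        css = cluster_sum(scan, mask, fit_model=fit_model)
        css.label = f"{label}_{name}"
        clusters[name] = css
    return clusters, maps


def run_closure_experiment(
    seed: int,
    grid_shape: tuple[int, int] = (100, 100),
    srm_poisson: bool = True,
) -> dict:
    """Parameter-recovery experiment on one control-condition cell.

    Simulates a uniform control cell and a reference-standard scan, runs the
    full chain (batch fit, Zn segmentation, cluster sum, normalization, yield
    calibration, quantification) and compares recovered weight fractions to
    the phantom ground truth.  Returns the quantification, the truth and the
    per-element z-scores ``(recovered - truth) / (recovered * rel_sigma)``
    for elements above their detection limit.
    """
    from .synthetic import CONTROL_CELL, control_cell_phantom

    instrument = InstrumentModel()
    fit_model = default_fit_model(
        gain=instrument.gain_ev,
        n_channels=instrument.n_channels,
        excitation_kev=instrument.excitation_kev,
        compton_kev=instrument.compton_kev,
    )
    standard = ReferenceStandard.default()
    rng = np.random.Generator(np.random.Philox(seed))
    cell_seed = int(rng.integers(0, 2**31 - 1))
    srm_seed = int(rng.integers(0, 2**31 - 1))

    spec = control_cell_phantom(grid_shape=grid_shape, seed=cell_seed)
    scan, label_map, _, _ = simulate_phantom_scan(spec, instrument)
    maps = batch_fit(scan, fit_model)
    cell_mask, _ = segment_cell_nucleus(np.nan_to_num(maps["Zn"]))
    css = cluster_sum(scan, cell_mask, fit_model=fit_model)
    fit = fit_spectrum(css.spectrum, fit_model)
    ref_diode = css.mean_diode
    norm = normalize_sum_spectrum(fit, css, ref_diode)

    srm_instr = dataclasses.replace(instrument, absorber_transmission=0.125)
    srm = simulate_reference_scan(
        standard, srm_instr, seed=srm_seed, poisson=srm_poisson
    )
    srm_mask = ClusterMask("srm", np.ones(srm.shape, dtype=bool))
    srm_css = cluster_sum(srm, srm_mask, fit_model=fit_model)
    srm_norm = normalize_sum_spectrum(
        fit_spectrum(srm_css.spectrum, fit_model), srm_css, ref_diode
    )
    yields = calibrate_yields(
        srm_norm, standard, instrument.geometry(),
        beam_fwhm_nm=instrument.beam_fwhm_nm,
        lod_live_time=instrument.dwell_s,
    )
    quant = quantify_cluster(norm, yields, beam_fwhm_nm=instrument.beam_fwhm_nm)

    z_scores: dict[str, float] = {}
    flagged: list[str] = []
    for element, truth in CONTROL_CELL.items():
        if element not in quant.elements:
            flagged.append(element)  # uncalibratable on this standard scan
            continue
        eq = quant[element]
        if eq.below_lod:
            flagged.append(element)
            continue
        z_scores[element] = (eq.weight_fraction - truth) / (
            eq.weight_fraction * eq.rel_sigma
        )
    truth_mask = label_map != "background"
    dice = (
        2.0 * np.sum(cell_mask.pixels & truth_mask)
        / (cell_mask.n_pixels + truth_mask.sum())
    )
    return {
        "quant": quant,
        "yields": yields,
        "truth": dict(CONTROL_CELL),
        "z_scores": z_scores,
        "below_lod": flagged,
        "cell_dice": float(dice),
        "n_pixels": int(cell_mask.n_pixels),
    }


def run_thickness_pair_experiment(
    seed: int, grid_shape: tuple[int, int] = (100, 100),
    thickness_factor: float = 1.3,
    elements: tuple[str, ...] = ("P", "S", "Cl", "Ca", "Fe", "Zn"),
) -> dict:
    """Compton-normalization property experiment.

    Two replicate cells identical except for a thickness factor, simulated at
    the expectation level (no counting noise) so the comparison isolates the
    normalization itself.  Returns the per-element ratios of quantified
    weight fractions (thick/thin) under conventional and Compton
    normalization.
    """
    from .synthetic import control_cell_phantom

    instrument = dataclasses.replace(InstrumentModel(), diode_drift_rsd=0.0)
    fit_model = default_fit_model(
        gain=instrument.gain_ev,
        n_channels=instrument.n_channels,
        excitation_kev=instrument.excitation_kev,
        compton_kev=instrument.compton_kev,
    )
    standard = ReferenceStandard.default()
    rng = np.random.Generator(np.random.Philox(seed))
    cell_seed = int(rng.integers(0, 2**31 - 1))
    srm_seed = int(rng.integers(0, 2**31 - 1))

    clusters = {}
    for ts in (1.0, thickness_factor):
        spec = control_cell_phantom(
            grid_shape=grid_shape, thickness_scale=ts, seed=cell_seed
        )
        scan, label_map, _, _ = simulate_phantom_scan(spec, instrument, poisson=False)
        mask = ClusterMask("cell", label_map != "background")
        css = cluster_sum(scan, mask, fit_model=fit_model)
        clusters[ts] = (css, fit_spectrum(css.spectrum, fit_model))

    ref_css, ref_fit = clusters[1.0]
    ref_diode = ref_css.mean_diode
    ref_norm = normalize_sum_spectrum(ref_fit, ref_css, ref_diode)

    srm_instr = dataclasses.replace(instrument, absorber_transmission=0.125)
    srm = simulate_reference_scan(standard, srm_instr, seed=srm_seed, poisson=False)
    srm_css = cluster_sum(
        srm, ClusterMask("srm", np.ones(srm.shape, dtype=bool)), fit_model=fit_model
    )
    srm_norm = normalize_sum_spectrum(
        fit_spectrum(srm_css.spectrum, fit_model), srm_css, ref_diode
    )
    yields = calibrate_yields(
        srm_norm, standard, instrument.geometry(),
        beam_fwhm_nm=instrument.beam_fwhm_nm,
        lod_live_time=instrument.dwell_s,
    )

    out = {"conventional": {}, "compton": {}}
    for mode in out:
        results = {}
        for ts, (css, fit) in clusters.items():
            norm = normalize_sum_spectrum(fit, css, ref_diode)
            kwargs = (
                {"compton_ref": ref_norm.compton, "compton_ref_pixels": ref_css.n_pixels}
                if mode == "compton"
                else {}
            )
            results[ts] = quantify_cluster(
                norm, yields, beam_fwhm_nm=instrument.beam_fwhm_nm,
                normalization=mode, **kwargs,
            )
        for el in elements:
            out[mode][el] = (
                results[thickness_factor][el].weight_fraction
                / results[1.0][el].weight_fraction
            )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic study and write the output bundle.

    Returns a dict with the key in-memory products (yield table, quant
    results, tables, paths).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t_s": round(time.time() - t0, 3)})

    instrument = InstrumentModel()
    fit_model = default_fit_model(
        gain=instrument.gain_ev,
        n_channels=instrument.n_channels,
        excitation_kev=instrument.excitation_kev,
        compton_kev=instrument.compton_kev,
    )
    standard = ReferenceStandard.default()
    master = np.random.Generator(np.random.Philox(config.seed))

    # --- simulate + quantify the study cells -----------------------------
    try:
        stage("simulate")
        cells = []
        for time_h, n_rep in sorted(config.replicates.items()):
            for rep in range(n_rep):
                cell_seed = int(master.integers(0, 2**31 - 1))
                thick = sample_thickness_scale(master, config.thickness_rsd)
                spec = condition_phantom(
                    float(time_h),
                    grid_shape=config.grid_shape,
                    thickness_scale=thick,
                    cell_rsd=config.cell_rsd,
                    seed=cell_seed,
                )
                label = f"{time_h:g}h_cell{rep + 1}"
                scan, label_map, element_maps, areal = simulate_phantom_scan(
                    spec, instrument
                )
                cells.append(
                    {
                        "label": label,
                        "time_h": float(time_h),
                        "scan": scan,
                        "spec": spec,
                        "label_map": label_map,
                    }
                )
    except Exception as e:  # pragma: no cover - smoke guard
        raise PipelineStageError("simulate", e) from e

    try:
        stage("fit_segment")
        for cell in cells:
            clusters, maps = _quantify_cell(
                cell["scan"], fit_model, instrument, cell["label"]
            )
            cell["clusters"] = clusters
            cell["maps"] = maps
    except Exception as e:
        raise PipelineStageError("fit_segment", e) from e

    # reference cluster: entire cell of the first control cell
    ref_cell = cells[0]
    ref_cluster = ref_cell["clusters"]["entire_cell"]
    ref_diode = ref_cluster.mean_diode
    ref_fit = fit_spectrum(ref_cluster.spectrum, fit_model)
    ref_norm = normalize_sum_spectrum(ref_fit, ref_cluster, ref_diode)

    # --- reference standard & yields -------------------------------------
    try:
        stage("calibrate")
        srm_instr = dataclasses.replace(
            instrument, absorber_transmission=config.srm_transmission
        )
        srm_seed = int(master.integers(0, 2**31 - 1))
        srm_scan = simulate_reference_scan(
            standard, srm_instr, seed=srm_seed,
            shape=config.srm_shape, dwell_s=config.srm_dwell_s,
        )
        srm_mask = ClusterMask("srm", np.ones(srm_scan.shape, dtype=bool))
        srm_cluster = cluster_sum(srm_scan, srm_mask, fit_model=fit_model)
        srm_fit = fit_spectrum(srm_cluster.spectrum, fit_model)
        srm_norm = normalize_sum_spectrum(srm_fit, srm_cluster, ref_diode)
        yields = calibrate_yields(
            srm_norm, standard, instrument.geometry(),
            beam_fwhm_nm=instrument.beam_fwhm_nm,
            lod_live_time=instrument.dwell_s,
        )
        yields.to_frame().to_csv(out / "yields.csv", float_format="%.10g")
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("calibrate", e) from e

    # --- quantify every cluster ------------------------------------------
    try:
        stage("quantify")
        quant_rows = []
        meta_rows = []
        results: list[tuple[dict, str, QuantResult]] = []
        for cell in cells:
            for name, css in cell["clusters"].items():
                fit = fit_spectrum(css.spectrum, fit_model)
                norm = normalize_sum_spectrum(fit, css, ref_diode)
                kwargs = {}
                if config.normalization == "compton":
                    kwargs = {
                        "compton_ref": ref_norm.compton,
                        "compton_ref_pixels": ref_cluster.n_pixels,
                    }
                q = quantify_cluster(
                    norm,
                    yields,
                    beam_fwhm_nm=instrument.beam_fwhm_nm,
                    thickness_um=config.thickness_um,
                    density_g_cm3=config.density_g_cm3,
                    normalization=config.normalization,
                    **kwargs,
                )
                results.append((cell, name, q))
                meta_rows.append(css.metadata_row())
                frame = q.to_frame().reset_index()
                frame.insert(0, "time_h", cell["time_h"])
                frame.insert(0, "compartment", name)
                quant_rows.append(frame)
        quant_table = pd.concat(quant_rows, ignore_index=True)
        quant_table.to_csv(out / "quant_results.csv", index=False, float_format="%.10g")
        pd.DataFrame(meta_rows).to_csv(
            out / "cluster_metadata.csv", index=False, float_format="%.10g"
        )
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("quantify", e) from e

    # --- statistics -------------------------------------------------------
    try:
        stage("stats")
        compartments = ("entire_cell", "nucleus", "cytoplasm")
        summary_rows = []
        timecourses = []
        for element in DETECTABLE_ELEMENTS:
            for comp in compartments:
                times, values, labels = [], [], []
                for cell, name, q in results:
                    if name != comp or element not in q.elements:
                        continue
                    times.append(cell["time_h"])
                    values.append(q[element].weight_fraction)
                    labels.append(cell["label"])
                if not values:
                    continue
                tc = TimeCourse(element, comp, np.array(times), np.array(values), labels)
                timecourses.append(tc)
                for t, g in tc.groups().items():
                    mean, sd, n, flag = group_summary(g)
                    summary_rows.append(
                        {
                            "element": element,
                            "compartment": comp,
                            "time_h": t,
                            "mean_weight_fraction": mean,
                            "rsd_weight_fraction": sd,
                            "n": n,
                            "high_variance_italic": flag,
                        }
                    )
        pd.DataFrame(summary_rows).to_csv(
            out / "group_summary.csv", index=False, float_format="%.10g"
        )
        trend = build_trend_table(timecourses, significance=config.significance)
        trend.to_csv(out / "trend_table.csv", index=False, float_format="%.10g")
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("stats", e) from e

    # --- rendering --------------------------------------------------------
    try:
        stage("render")
        r_el, g_el, b_el = config.render_elements
        norm_maps = {
            c["label"]: _normalized_maps(c["scan"], c["maps"], ref_diode)
            for c in cells
        }
        control_labels = [c["label"] for c in cells if c["time_h"] == 0.0] or [
            cells[0]["label"]
        ]
        thresholds = tuple(
            max(float(np.max(norm_maps[lbl][el])) for lbl in control_labels) or 1.0
            for el in (r_el, g_el, b_el)
        )
        for cell in cells:
            nm = norm_maps[cell["label"]]
            comp = render_rgb((nm[r_el], nm[g_el], nm[b_el]), thresholds)
            iio.imwrite(out / f"rgb_{cell['label']}.png", comp.image)
        if config.save_containers:
            for cell in cells:
                nio.save_scan(
                    out / f"scan_{cell['label']}.h5", cell["scan"], maps=cell["maps"]
                )
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("render", e) from e

    stage("done")
    run_log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": log,
        "n_cells": len(cells),
        "below_lod": sorted(
            {
                f"{cell['label']}:{name}:{el}"
                for cell, name, q in results
                for el, eq in q.elements.items()
                if eq.below_lod
            }
        ),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return {
        "yields": yields,
        "results": results,
        "quant_table": quant_table,
        "trend_table": trend,
        "timecourses": timecourses,
        "output_dir": out,
    }
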