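"""End-to-end pipeline stages behind the CLI.

Each stage reads its upstream artifacts from the output directory and writes
its own, so stages can be re-run independently:

design -> layout.csv
calibrate -> calibration.csv (needs the design)
simulate-assay -> dataset manifest + per-measurement CSVs
quantify -> dose-response CSVs + report.json (needs calibration + dataset)
compare -> comparison.json (needs both channels' dose responses)

Determinism: the global seed is expanded into per-measurement child seeds by
the dataset generator, and every artifact records the seed it used.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .assay_sim import ColorimetricAssay, generate_dataset
from .calibration import build_calibration_curve
from .config import RunConfig
from .errors import DependencyError
from .filter_model import build_layout
from .instrument import build_transmission_matrix
from .quantify import (build_dose_response, compare_instruments,
                       estimate_lod, extract_measurement, fit_dose_response,
                       intensity_at_wavelength)

_LAYOUT = "layout.csv"
_CALIBRATION = "calibration.csv"
_MANIFEST = "dataset/manifest.json"
_REPORT = "report.json"
_COMPARISON = "comparison.json"


def _outdir(config: RunConfig, out=None) -> Path:
    path = Path(out) if out is not None else Path(config.output_dir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _build_system(config: RunConfig):
    design = config.device.design.build()
    materials = config.device.materials.build()
    layout = build_layout(design, materials, band=config.device.design.band,
                          model=config.device.design.neff_model)
    ccd = config.instrument.ccd.build(layout)
    lineshape = config.instrument.lineshape.build()
    cal = config.calibration
    grid = np.arange(cal.scan_start, cal.scan_stop, 1.0)
    tmatrix = build_transmission_matrix(layout, ccd, lineshape, grid)
    return layout, ccd, lineshape, tmatrix


def run_design(config: RunConfig, out=None) -> Path:
    """Emit the gradient layout CSV."""
    outdir = _outdir(config, out)
    design = config.device.design.build()
    materials = config.device.materials.build()
    layout = build_layout(design, materials, band=config.device.design.band,
                          model=config.device.design.neff_model)
    gio.write_layout_csv(layout, outdir / _LAYOUT)
    return outdir / _LAYOUT


def run_calibrate(config: RunConfig, out=None, no_noise: bool = True) -> Path:
    """Simulate the monochromatic scan and emit the calibration CSV."""
    outdir = _outdir(config, out)
    layout, ccd, lineshape, tmatrix = _build_system(config)
    cal = config.calibration
    noise = None if no_noise else config.instrument.detector_noise.build(config.seed)
    curve = build_calibration_curve(
        layout, ccd, lineshape, scan_start=cal.scan_start,
        scan_stop=cal.scan_stop, scan_step=cal.scan_step,
        linewidth=cal.linewidth, noise=noise, tmatrix=tmatrix,
        smoothing_window=cal.smoothing_window,
        min_dip_depth=cal.min_dip_depth)
    gio.write_calibration_csv(curve, outdir / _CALIBRATION)
    return outdir / _CALIBRATION


def run_simulate(config: RunConfig, out=None, no_noise: bool = False) -> Path:
    """Generate the replicated assay dataset and write its manifest."""
    outdir = _outdir(config, out)
    _, _, _, tmatrix = _build_system(config)
    assay, plan = config.assay.build(config.seed)
    det = None if no_noise else config.instrument.detector_noise.build(config.seed)
    spec = None if no_noise else config.instrument.spectrometer_noise.build(config.seed)
    dataset = generate_dataset(plan, assay, tmatrix, det, spec)
    ds_dir = outdir / "dataset"
    ds_dir.mkdir(exist_ok=True)
    entries = []
    for k, rec in enumerate(dataset.records):
        trace_file = f"trace_{k:04d}.csv"
        spec_file = f"spectrum_{k:04d}.csv"
        gio.write_trace_csv(rec.trace, ds_dir / trace_file)
        gio.write_spectrum_csv(rec.spectrum, ds_dir / spec_file)
        entries.append({
            "run": rec.run, "concentration": rec.concentration,
            "replicate": rec.replicate, "timepoint": rec.timepoint,
            "trace": trace_file, "spectrum": spec_file,
            "seeds": rec.seeds, "truth": rec.truth,
        })
    manifest = {
        "preset": config.assay.preset,
        "unit": plan.unit,
        "seed": plan.seed,
        "kinetic": isinstance(assay, ColorimetricAssay) and assay.kinetics is not None,
        "no_noise": no_noise,
        "readout_wavelength": (assay.chromogen.led_center
                               if isinstance(assay, ColorimetricAssay) else None),
        "measurements": entries,
    }
    gio.write_manifest(manifest, outdir / _MANIFEST)
    return outdir / _MANIFEST


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"{stage} requires missing artifact: {path}")
    return path


def run_quantify(config: RunConfig, out=None) -> Path:
    """Extract measurements, build both channels' dose responses, fit + LOD."""
    outdir = _outdir(config, out)
    curve = gio.read_calibration_csv(_require(outdir / _CALIBRATION, "quantify"))
    manifest = gio.read_manifest(_require(outdir / _MANIFEST, "quantify"))
    ds_dir = outdir / "dataset"
    kinetic = bool(manifest["kinetic"])
    readout_wl = manifest.get("readout_wavelength")
    rows = []
    for entry in manifest["measurements"]:
        trace = gio.read_trace_csv(ds_dir / entry["trace"])
        spectrum = gio.read_spectrum_csv(ds_dir / entry["spectrum"])
        row = {"run": entry["run"], "concentration": entry["concentration"],
               "replicate": entry["replicate"], "timepoint": entry["timepoint"]}
        if kinetic:
            pixel = int(round(curve.wavelength_to_pixel(readout_wl)))
            row["ggp_intensity"] = trace.intensity_at(pixel)
            row["spec_intensity"] = intensity_at_wavelength(spectrum, readout_wl)
        else:
            m_t = extract_measurement(trace, curve,
                                      config.calibration.smoothing_window,
                                      config.calibration.min_dip_depth)
            m_s = extract_measurement(spectrum)
            row["ggp_intensity"] = m_t.intensity
            row["spec_intensity"] = m_s.intensity
            row["micp_pixel"] = m_t.micp_pixel
            row["estimated_wavelength"] = m_t.estimated_wavelength
            row["peak_wavelength"] = m_s.peak_wavelength
        rows.append(row)
    df = pd.DataFrame(rows)
    unit = manifest["unit"]
    conc_scale = 10.0 if unit in ("mg/L",) else 1.0
    report = {"unit": unit, "conc_scale": conc_scale, "channels": {}}
    for channel, col in (("ggp-gmr", "ggp_intensity"),
                         ("spectrometer", "spec_intensity")):
        if kinetic:
            wide = df.pivot_table(
                index=["run", "concentration", "replicate"], columns="timepoint",
                values=col).reset_index()
            tps = sorted(c for c in wide.columns if isinstance(c, float))
            meas = wide.rename(columns={tps[0]: "intensity_t0",
                                        tps[-1]: "intensity_t1"})
        else:
            meas = df.rename(columns={col: "intensity"})
        table = build_dose_response(meas, unit=unit, channel=channel,
                                    kinetic=kinetic)
        gio.write_dose_response_csv(table, outdir / f"dose_response_{channel}.csv")
        fit = fit_dose_response(table, conc_scale=conc_scale)
        entry = {"slope": fit.slope, "intercept": fit.intercept,
                 "r_squared": fit.r_squared,
                 "sensitivity_convention": f"normalized intensity per "
                                           f"{conc_scale:g} {unit}"}
        try:
            lod = estimate_lod(table, fit, conc_scale=conc_scale)
            entry.update({"noise": lod.noise, "lod": lod.lod,
                          "noise_definition": lod.noise_definition})
        except Exception as exc:  # single-replicate tables have no pooled SD
            entry["lod_error"] = str(exc)
        report["channels"][channel] = entry
    gio.write_manifest(report, outdir / _REPORT)
    return outdir / _REPORT


def run_compare(config: RunConfig, out=None) -> Path:
    """Regress the compact system's dose response on the spectrometer's."""
    outdir = _outdir(config, out)
    table_a = gio.read_dose_response_csv(
        _require(outdir / "dose_response_ggp-gmr.csv", "compare"))
    table_b = gio.read_dose_response_csv(
        _require(outdir / "dose_response_spectrometer.csv", "compare"))
    comp = compare_instruments(table_a, table_b)
    gio.write_manifest({"slope": comp.slope, "intercept": comp.intercept,
                        "r_squared": comp.r_squared, "n_pairs": comp.n_pairs},
                       outdir / _COMPARISON)
    return outdir / _COMPARISON


def run_all(config: RunConfig, out=None, no_noise: bool = False) -> Path:
    """design -> calibrate -> simulate -> quantify -> compare."""
    run_design(config, out)
    run_calibrate(config, out)
    run_simulate(config, out, no_noise=no_noise)
    run_quantify(config, out)
    return run_compare(config, out)
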