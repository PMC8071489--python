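"""Strict CSV and manifest I/O.

All files are comma-separated UTF-8 with a mandatory header, ``.`` decimal
separator and LF line endings; numbers are written with 17 significant
digits so a write-then-read round trip is value-exact.  Headers are matched
exactly — a renamed column is a :class:`FormatError`, not a guess.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .errors import FormatError
from .filter_model import DeviceLayout
from .instrument import TransmissionMatrix
from .quantify import DoseResponseTable
from .signals import CCDTrace, SpectrumSample

_FLOAT_FMT = "%.17g"

SPECTRUM_COLUMNS = ["wavelength_nm", "intensity"]
TRACE_COLUMNS = ["pixel", "intensity"]
CALIBRATION_COLUMNS = ["wavelength_nm", "micp_pixel"]
LAYOUT_COLUMNS = ["segment_index", "period_nm", "start_nm", "length_nm",
                  "resonant_wavelength_nm"]
DOSE_RESPONSE_COLUMNS = ["run", "concentration", "unit", "channel",
                         "raw_intensity", "normalized_intensity"]


def _write_frame(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _read_frame(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if list(df.columns) != columns:
        raise FormatError(f"{path}: expected header {','.join(columns)}, "
                          f"got {','.join(map(str, df.columns))}")
    return df


def _numeric(df: pd.DataFrame, column: str, path) -> np.ndarray:
    # builtin float() is correctly rounded, so 17-digit text round-trips
    # bit-exactly (pandas' fast CSV float parser is not)
    out = np.empty(len(df), dtype=float)
    for i, text in enumerate(df[column]):
        try:
            out[i] = float(text)
        except ValueError:
            # +2: one for the header row, one for 1-based numbering
            raise FormatError(f"{path}: non-numeric value in column "
                              f"'{column}' at row {i + 2}") from None
        if not np.isfinite(out[i]):
            raise FormatError(f"{path}: non-finite value in column "
                              f"'{column}' at row {i + 2}")
    return out


def write_spectrum_csv(spectrum: SpectrumSample, path) -> None:
    _write_frame(pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                               "intensity": spectrum.intensity}), path)


def read_spectrum_csv(path) -> SpectrumSample:
    df = _read_frame(path, SPECTRUM_COLUMNS)
    wl = _numeric(df, "wavelength_nm", path)
    inten = _numeric(df, "intensity", path)
    if np.any(np.diff(wl) <= 0):
        row = int(np.nonzero(np.diff(wl) <= 0)[0][0]) + 3
        raise FormatError(f"{path}: wavelength grid not increasing at row {row}")
    neg = np.nonzero(inten < 0)[0]
    if neg.size:
        raise FormatError(f"{path}: negative intensity at row {neg[0] + 2}")
    return SpectrumSample(wl, inten)


def write_trace_csv(trace: CCDTrace, path) -> None:
    _write_frame(pd.DataFrame({"pixel": trace.pixel,
                               "intensity": trace.intensity}), path)


def read_trace_csv(path) -> CCDTrace:
    df = _read_frame(path, TRACE_COLUMNS)
    px = _numeric(df, "pixel", path)
    inten = _numeric(df, "intensity", path)
    neg = np.nonzero(inten < 0)[0]
    if neg.size:
        raise FormatError(f"{path}: negative intensity at row {neg[0] + 2}")
    return CCDTrace(px.astype(int), inten)


def write_calibration_csv(curve: CalibrationCurve, path) -> None:
    _write_frame(curve.to_frame(), path)


def read_calibration_csv(path) -> CalibrationCurve:
    df = _read_frame(path, CALIBRATION_COLUMNS)
    return CalibrationCurve(_numeric(df, "wavelength_nm", path),
                            _numeric(df, "micp_pixel", path))


def write_layout_csv(layout: DeviceLayout, path) -> None:
    _write_frame(layout.to_frame(), path)


def write_matrix_csv(tmatrix: TransmissionMatrix, path) -> None:
    _write_frame(tmatrix.to_frame(), path)


def write_dose_response_csv(table: DoseResponseTable, path) -> None:
    df = table.data.copy()
    df["unit"] = table.unit
    df["channel"] = table.channel
    _write_frame(df[["run", "concentration", "unit", "channel",
                     "raw_intensity", "normalized_intensity",
                     "replicate"]], path)


def read_dose_response_csv(path) -> DoseResponseTable:
    df = _read_frame(path, DOSE_RESPONSE_COLUMNS + ["replicate"])
    out = pd.DataFrame({
        "run": _numeric(df, "run", path).astype(int),
        "concentration": _numeric(df, "concentration", path),
        "replicate": _numeric(df, "replicate", path).astype(int),
        "raw_intensity": _numeric(df, "raw_intensity", path),
        "normalized_intensity": _numeric(df, "normalized_intensity", path),
    })
    units = df["unit"].unique()
    channels = df["channel"].unique()
    if len(units) != 1 or len(channels) != 1:
        raise FormatError(f"{path}: mixed units or channels in one table")
    return DoseResponseTable(out, unit=str(units[0]), channel=str(channels[0]))


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_manifest(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    try:
        return json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid manifest JSON ({exc})") from exc
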