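"""Quantification pipeline: MICP extraction, dose response, LOD statistics.

The analysis chain mirrors how the physical platform is used: locate the
transmission dip (MICP) on each CCD trace and map it to a wavelength through
the calibration curve; normalize intensities per run to the highest
concentration; fit the dose response by ordinary least squares; and compute

    noise = 3 x (pooled within-concentration SD of normalized intensity)
    LOD   = noise / sensitivity

with sensitivity expressed per ``conc_scale`` concentration units (default
10 mg/L — the convention under which the reported noise/sensitivity/LOD
triplets are arithmetically consistent, e.g. 10 x 0.1517 / 0.037 = 41.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .calibration import CalibrationCurve, find_micp
from .errors import (DegenerateRegressionError, ExtrapolationError,
                     InsufficientDataError, NormalizationError, PairingError,
                     ValidationError)
from .signals import CCDTrace, SpectrumSample

#: Concentration units per sensitivity unit: slope is "per conc_scale units".
DEFAULT_CONC_SCALE = 10.0


@dataclass
class Measurement:
    """Peak location + intensity from one channel.

    CCD channel: ``micp_pixel``/``micp_subpixel`` with the calibrated
    ``estimated_wavelength``; spectrometer channel: ``peak_wavelength``.
    ``intensity`` is the readout intensity at the located peak/dip in both
    cases.  ``out_of_range`` flags an MICP outside the calibrated span.
    """

    channel: str
    intensity: float
    micp_pixel: int | None = None
    micp_subpixel: float | None = None
    estimated_wavelength: float | None = None
    peak_wavelength: float | None = None
    out_of_range: bool = False


def _refined_argmax(x: np.ndarray, y: np.ndarray, window: int = 5):
    """Smoothed argmax with parabolic sub-bin refinement; returns (pos, val)."""
    s = uniform_filter1d(y, size=window, mode="nearest")
    i = int(np.argmax(s))
    if 0 < i < s.size - 1:
        a, b, c = s[i - 1], s[i], s[i + 1]
        denom = a - 2.0 * b + c
        frac = 0.5 * (a - c) / denom if denom < 0 else 0.0
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    step = x[min(i + 1, x.size - 1)] - x[max(i - 1, 0)]
    pos = float(x[i] + frac * step / (2.0 if 0 < i < x.size - 1 else 1.0))
    return pos, float(y[i])


def extract_measurement(obj, curve: CalibrationCurve | None = None,
                        smoothing_window: int = 5,
                        min_dip_depth: float = 0.005) -> Measurement:
    """Measure one trace (CCD channel) or spectrum (spectrometer channel).

    The default dip threshold is far below the calibration-scan default:
    a broadband assay emission (tens of nm) driven through a few-nm
    resonance produces a dip only a few percent deep, unlike the near-total
    dips of narrowband scan sources.
    """
    if isinstance(obj, CCDTrace):
        if curve is None:
            raise ValidationError("a calibration curve is required for traces")
        micp = find_micp(obj, smoothing_window, min_dip_depth)
        out_of_range = False
        try:
            lam = curve.pixel_to_wavelength(micp.subpixel_position)
        except ExtrapolationError:
            lam, out_of_range = None, True
        return Measurement(channel="ggp-gmr",
                           intensity=obj.intensity_at(micp.micp_pixel),
                           micp_pixel=micp.micp_pixel,
                           micp_subpixel=micp.subpixel_position,
                           estimated_wavelength=lam, out_of_range=out_of_range)
    if isinstance(obj, SpectrumSample):
        pos, val = _refined_argmax(obj.wavelength_nm, obj.intensity,
                                   smoothing_window)
        return Measurement(channel="spectrometer", intensity=val,
                           peak_wavelength=pos)
    raise ValidationError(f"cannot measure object of type {type(obj).__name__}")


def intensity_at_wavelength(spectrum: SpectrumSample, wavelength: float) -> float:
    """Spectrometer intensity at a fixed wavelength (linear interpolation)."""
    grid = spectrum.wavelength_nm
    if not grid[0] <= wavelength <= grid[-1]:
        raise ValidationError(f"wavelength {wavelength} nm outside spectrum grid")
    return float(np.interp(wavelength, grid, spectrum.intensity))


@dataclass
class DoseResponseTable:
    """Replicated normalized intensities versus concentration.

    ``data`` columns: run, concentration, replicate, raw_intensity,
    normalized_intensity.  Normalization is per run, to the mean raw
    intensity at the highest concentration of that run; kinetic tables hold
    the fixed-pixel 0-vs-5-min intensity difference in ``raw_intensity``.
    """

    data: pd.DataFrame
    unit: str = "mg/L"
    channel: str = "ggp-gmr"
    kinetic: bool = False
    normalization: str = "max-concentration"

    def __post_init__(self):
        required = {"run", "concentration", "replicate",
                    "raw_intensity", "normalized_intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"dose-response table missing columns {sorted(missing)}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration"].unique())


def build_dose_response(measurements: pd.DataFrame, unit: str = "mg/L",
                        channel: str = "ggp-gmr",
                        normalization: str = "max-concentration",
                        kinetic: bool = False) -> DoseResponseTable:
    """Assemble and normalize a dose-response table.

    ``measurements`` needs columns run, concentration, replicate and either
    ``intensity`` (static assays) or ``intensity_t0``/``intensity_t1``
    (kinetic assays, already read at the fixed pixel/wavelength); kinetic raw
    signal is intensity(t0) - intensity(t1), positive as color develops.
    """
    df = measurements.copy()
    if kinetic:
        if not {"intensity_t0", "intensity_t1"} <= set(df.columns):
            raise ValidationError("kinetic tables need intensity_t0/intensity_t1")
        df["raw_intensity"] = df["intensity_t0"] - df["intensity_t1"]
    else:
        if "intensity" not in df.columns:
            raise ValidationError("static tables need an 'intensity' column")
        df["raw_intensity"] = df["intensity"]
    if normalization == "max-concentration":
        c_ref = df["concentration"].max()
        parts = []
        for run, grp in df.groupby("run", sort=True):
            ref_rows = grp.loc[grp["concentration"] == c_ref, "raw_intensity"]
            if ref_rows.empty:
                raise NormalizationError(
                    f"run {run} lacks the reference concentration {c_ref}")
            ref = float(ref_rows.mean())
            if ref == 0:
                raise NormalizationError(f"run {run}: zero reference intensity")
            grp = grp.assign(normalized_intensity=grp["raw_intensity"] / ref)
            parts.append(grp)
        df = pd.concat(parts, ignore_index=True)
    elif normalization == "none":
        df["normalized_intensity"] = df["raw_intensity"]
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    cols = ["run", "concentration", "replicate", "raw_intensity",
            "normalized_intensity"]
    return DoseResponseTable(df[cols].reset_index(drop=True), unit=unit,
                             channel=channel, kinetic=kinetic,
                             normalization=normalization)


@dataclass
class RegressionResult:
    """OLS slope (the sensitivity), intercept, and R^2."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    degenerate: bool = False


def ols(x, y) -> RegressionResult:
    """Two-pass closed-form simple linear regression.

    Returns slope = Sxy/Sxx, intercept = ybar - slope*xbar, R^2 =
    Sxy^2/(Sxx*Syy).  Zero predictor variance raises; zero response variance
    yields slope 0, R^2 0 flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("regression needs >= 2 paired points")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    syy = float(((y - ybar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    if sxx == 0.0:
        raise DegenerateRegressionError("predictor has zero variance")
    if syy == 0.0:
        return RegressionResult(slope=0.0, intercept=ybar, r_squared=0.0,
                                n=x.size, degenerate=True)
    slope = sxy / sxx
    return RegressionResult(slope=slope, intercept=ybar - slope * xbar,
                            r_squared=sxy * sxy / (sxx * syy), n=x.size)


def fit_dose_response(table: DoseResponseTable,
                      conc_scale: float = DEFAULT_CONC_SCALE,
                      include_blank: bool = True,
                      restrict_lowest: int | None = None) -> RegressionResult:
    """OLS of normalized intensity against concentration / ``conc_scale``.

    ``restrict_lowest=k`` fits only the k lowest non-blank concentrations
    (the local-linear convention for assays with saturating response).
    """
    df = table.data
    if not include_blank:
        df = df[df["concentration"] > 0]
    if restrict_lowest is not None:
        keep = np.sort(df.loc[df["concentration"] > 0, "concentration"].unique())[:restrict_lowest]
        df = df[df["concentration"].isin(keep) | (df["concentration"] == 0)]
    if df["concentration"].nunique() < 3:
        raise InsufficientDataError("need >= 3 distinct concentrations to fit")
    return ols(df["concentration"].to_numpy() / conc_scale,
               df["normalized_intensity"].to_numpy())


@dataclass
class LODResult:
    """Noise (3 SD), sensitivity (per conc_scale units), and their ratio."""

    noise: float
    sensitivity: float
    lod: float
    unit: str
    noise_definition: str = "pooled"
    conc_scale: float = DEFAULT_CONC_SCALE


def lod_from_noise_sensitivity(noise: float, sensitivity: float,
                               conc_scale: float = DEFAULT_CONC_SCALE,
                               unit: str = "mg/L") -> LODResult:
    """LOD = noise / sensitivity, converted to concentration units.

    With sensitivity per ``conc_scale`` units, the ratio is in units of
    ``conc_scale`` and is rescaled: LOD = conc_scale * noise / sensitivity.
    """
    if noise < 0:
        raise ValidationError("noise must be >= 0")
    if sensitivity <= 0:
        raise ValidationError("sensitivity must be positive for an LOD")
    return LODResult(noise=noise, sensitivity=sensitivity,
                     lod=conc_scale * noise / sensitivity, unit=unit,
                     conc_scale=conc_scale)


def measurement_noise(table: DoseResponseTable,
                      noise_definition: str = "pooled") -> float:
    """Three standard deviations of the normalized intensities.

    ``pooled``: SD pooled within concentrations (every level needs >= 2
    measurements); ``global``: one SD over all measurements ignoring the
    concentration structure; ``blank``: SD of the blank only.
    """
    y = table.data["normalized_intensity"]
    if noise_definition == "pooled":
        groups = table.data.groupby("concentration")["normalized_intensity"]
        sizes = groups.size()
        if (sizes < 2).any():
            raise InsufficientDataError(
                "pooled noise needs >= 2 measurements at every concentration")
        ss = float((groups.var(ddof=1) * (sizes - 1)).sum())
        sd = np.sqrt(ss / float((sizes - 1).sum()))
    elif noise_definition == "global":
        if y.size < 2:
            raise InsufficientDataError("global noise needs >= 2 measurements")
        sd = float(y.std(ddof=1))
    elif noise_definition == "blank":
        blank = table.data.loc[table.data["concentration"] == 0,
                               "normalized_intensity"]
        if blank.size < 2:
            raise InsufficientDataError("blank noise needs >= 2 blank replicates")
        sd = float(blank.std(ddof=1))
    else:
        raise ValidationError(f"unknown noise definition {noise_definition!r}")
    return 3.0 * float(sd)


def estimate_lod(table: DoseResponseTable, fit: RegressionResult,
                 noise_definition: str = "pooled",
                 conc_scale: float = DEFAULT_CONC_SCALE) -> LODResult:
    """LOD from a dose-response table and its fitted sensitivity."""
    noise = measurement_noise(table, noise_definition)
    result = lod_from_noise_sensitivity(noise, fit.slope, conc_scale, table.unit)
    result.noise_definition = noise_definition
    return result


@dataclass
class InstrumentComparison:
    """Regression of one channel's normalized intensities on the other's."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int


def compare_instruments(table_a: DoseResponseTable,
                        table_b: DoseResponseTable) -> InstrumentComparison:
    """Pair by (run, concentration, replicate) and regress A on B.

    Slope and R^2 near 1 certify that the compact system reproduces the
    reference spectrometer's dose response.
    """
    keys = ["run", "concentration", "replicate"]
    merged = table_a.data.merge(table_b.data, on=keys, suffixes=("_a", "_b"))
    if len(merged) != len(table_a.data) or len(merged) != len(table_b.data):
        raise PairingError("tables do not share identical (run, concentration, "
                           "replicate) keys")
    if len(merged) < 3:
        raise InsufficientDataError("need >= 3 pairs to compare instruments")
    fit = ols(merged["normalized_intensity_b"].to_numpy(),
              merged["normalized_intensity_a"].to_numpy())
    return InstrumentComparison(slope=fit.slope, intercept=fit.intercept,
                                r_squared=fit.r_squared, n_pairs=fit.n)


def correlate_micp_wavelength(measurements: pd.DataFrame) -> RegressionResult:
    """OLS of MICP pixel against spectrometer peak wavelength.

    ``measurements`` needs columns ``micp_pixel`` and ``peak_wavelength``;
    the slope (pixels per nm) should match the local calibration-curve slope
    and R^2 near 1 confirms the spectral-to-spatial encoding.
    """
    required = {"micp_pixel", "peak_wavelength"}
    if not required <= set(measurements.columns):
        raise ValidationError(f"need columns {sorted(required)}")
    if measurements["peak_wavelength"].nunique() < 2:
        raise DegenerateRegressionError("peak wavelengths do not vary")
    if len(measurements) < 3:
        raise InsufficientDataError("need >= 3 points")
    return ols(measurements["peak_wavelength"].to_numpy(),
               measurements["micp_pixel"].to_numpy())
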