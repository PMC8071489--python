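"""Wavelength <-> pixel calibration by monochromatic scanning.

A narrowband source (~2.5 nm FWHM) is stepped across the operating band in
1-nm increments; each readout shows a transmission dip whose minimum-intensity
corresponding pixel (MICP) is located with sub-pixel precision.  The resulting
(wavelength, MICP) knots form a monotone calibration curve used in both
directions: wavelength -> pixel when predicting, pixel -> wavelength when
quantifying unknown spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import isotonic_regression

from .errors import (CalibrationQualityError, ExtrapolationError, NoDipError,
                     ValidationError)
from .filter_model import DeviceLayout
from .instrument import (CCDGeometry, NoiseParams, ResonanceLineshape,
                         TransmissionMatrix, build_transmission_matrix,
                         forward_readout)
from .signals import CCDTrace, SpectrumSample, gaussian_profile

_RANGE_EPS = 1e-9


def monochromatic_spectrum(center: float, linewidth: float, amplitude: float,
                           grid) -> SpectrumSample:
    """Gaussian narrowband source with the stated FWHM on ``grid`` (nm)."""
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= center <= grid[-1]:
        raise ValidationError(f"center {center} nm outside the grid span")
    if linewidth <= 0:
        raise ValidationError("linewidth must be positive")
    return SpectrumSample(grid, gaussian_profile(grid, center, linewidth, amplitude))


@dataclass
class MicpResult:
    """Located transmission dip on a CCD trace."""

    micp_pixel: int
    subpixel_position: float
    dip_depth: float
    tie: bool = False


def find_micp(trace: CCDTrace, smoothing_window: int = 5,
              min_dip_depth: float = 0.05) -> MicpResult:
    """Locate the minimum-intensity corresponding pixel of a trace.

    Moving-average smoothing, discrete argmin, then parabolic refinement on
    the three smoothed points around the minimum.  The dip depth is measured
    against the median of the smoothed trace; traces whose dip is shallower
    than ``min_dip_depth`` (e.g. dark frames) raise :class:`NoDipError`.
    """
    y = trace.intensity
    if y.size < max(smoothing_window, 3):
        raise ValidationError("trace shorter than the smoothing window")
    s = uniform_filter1d(y, size=smoothing_window, mode="nearest")
    baseline = float(np.median(s))
    smin = float(s.min())
    depth = (baseline - smin) / baseline if baseline > 0 else 0.0
    if depth < min_dip_depth:
        raise NoDipError(f"dip depth {depth:.4f} below threshold {min_dip_depth}")
    minima = np.nonzero(s == smin)[0]
    tie = minima.size > 1
    i = int(minima[0])
    if 0 < i < s.size - 1:
        a, b, c = s[i - 1], s[i], s[i + 1]
        denom = a - 2.0 * b + c
        frac = 0.5 * (a - c) / denom if denom > 0 else 0.0
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    sub = float(trace.pixel[i]) + frac
    return MicpResult(micp_pixel=int(round(sub)), subpixel_position=sub,
                      dip_depth=depth, tie=tie)


@dataclass
class CalibrationScan:
    """Raw monochromatic scan: one trace per scan wavelength."""

    scan_wavelengths: np.ndarray
    linewidth: float
    traces: list

    def __post_init__(self):
        self.scan_wavelengths = np.asarray(self.scan_wavelengths, dtype=float)
        if np.any(np.diff(self.scan_wavelengths) <= 0):
            raise ValidationError("scan wavelengths must be strictly increasing")
        if len(self.traces) != self.scan_wavelengths.size:
            raise ValidationError("one trace is required per scan wavelength")


@dataclass
class CalibrationCurve:
    """Monotone wavelength <-> MICP lookup with linear interpolation.

    Knots are stored post-isotonic-projection, so the forward lookup is
    non-decreasing by construction; the inverse collapses flat runs to their
    mean wavelength so it is well defined everywhere on the pixel range.
    """

    wavelengths: np.ndarray
    micp_pixels: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.micp_pixels = np.asarray(self.micp_pixels, dtype=float)
        if self.wavelengths.size != self.micp_pixels.size:
            raise ValidationError("knot arrays differ in length")
        if self.wavelengths.size < 2:
            raise ValidationError("calibration needs >= 2 knots")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError("knot wavelengths must be strictly increasing")
        if np.any(np.diff(self.micp_pixels) < 0):
            raise ValidationError("knot pixels must be non-decreasing")
        # inverse support: unique pixel knots, mean wavelength over flat runs
        px, inv = np.unique(self.micp_pixels, return_inverse=True)
        wl = np.zeros_like(px)
        counts = np.zeros_like(px)
        np.add.at(wl, inv, self.wavelengths)
        np.add.at(counts, inv, 1.0)
        self._inv_px = px
        self._inv_wl = wl / counts

    @property
    def valid_range(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    @property
    def pixel_range(self) -> tuple[float, float]:
        return float(self.micp_pixels[0]), float(self.micp_pixels[-1])

    def wavelength_to_pixel(self, wavelength):
        lam = np.asarray(wavelength, dtype=float)
        lo, hi = self.valid_range
        if np.any(lam < lo - _RANGE_EPS) or np.any(lam > hi + _RANGE_EPS):
            raise ExtrapolationError(
                f"wavelength outside calibrated range [{lo:.2f}, {hi:.2f}] nm")
        out = np.interp(lam, self.wavelengths, self.micp_pixels)
        return out if out.ndim else float(out)

    def pixel_to_wavelength(self, micp):
        p = np.asarray(micp, dtype=float)
        lo, hi = self.pixel_range
        if np.any(p < lo - _RANGE_EPS) or np.any(p > hi + _RANGE_EPS):
            raise ExtrapolationError(
                f"pixel outside calibrated range [{lo:.2f}, {hi:.2f}]")
        out = np.interp(p, self._inv_px, self._inv_wl)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.wavelengths,
                             "micp_pixel": self.micp_pixels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CalibrationCurve":
        return cls(df["wavelength_nm"].to_numpy(), df["micp_pixel"].to_numpy())


def simulate_calibration_scan(tmatrix: TransmissionMatrix,
                              scan_wavelengths, linewidth: float = 2.5,
                              amplitude: float = 1.0,
                              noise: NoiseParams | None = None) -> CalibrationScan:
    """Readout of one monochromatic source per scan wavelength.

    The scan amplitude is arbitrary: MICP location is invariant to uniform
    intensity scaling, so calibration does not depend on source brightness.
    """
    scan_wavelengths = np.asarray(scan_wavelengths, dtype=float)
    traces = []
    for k, lam in enumerate(scan_wavelengths):
        spec = monochromatic_spectrum(lam, linewidth, amplitude,
                                      tmatrix.column_wavelengths)
        step_noise = None
        if noise is not None and noise.enabled:
            step_noise = NoiseParams(
                read_noise_sd=noise.read_noise_sd,
                shot_noise_scale=noise.shot_noise_scale,
                dark_offset=noise.dark_offset,
                seed=int(np.random.SeedSequence([noise.seed, k]).generate_state(1)[0] % (2**31)),
            )
        traces.append(forward_readout(tmatrix, spec, step_noise))
    return CalibrationScan(scan_wavelengths, linewidth, traces)


def calibration_curve_from_scan(scan: CalibrationScan,
                                smoothing_window: int = 5,
                                min_dip_depth: float = 0.05,
                                max_inversion_pixels: float = 2.0) -> CalibrationCurve:
    """Extract MICPs from a scan and build the monotone curve.

    Small noise-induced inversions are repaired by isotonic projection
    (pool-adjacent-violators); inversions exceeding ``max_inversion_pixels``
    indicate a broken scan and raise :class:`CalibrationQualityError`.
    """
    raw = np.array([find_micp(t, smoothing_window, min_dip_depth).subpixel_position
                    for t in scan.traces])
    running_max = np.maximum.accumulate(raw)
    worst = float(np.max(running_max - raw))
    if worst > max_inversion_pixels:
        raise CalibrationQualityError(
            f"scan inverts by {worst:.2f} pixels (> {max_inversion_pixels})")
    iso = isotonic_regression(raw, increasing=True).x
    return CalibrationCurve(scan.scan_wavelengths, iso)


def build_calibration_curve(layout: DeviceLayout, ccd: CCDGeometry,
                            lineshape: ResonanceLineshape,
                            scan_start: float = 500.0, scan_stop: float = 700.0,
                            scan_step: float = 1.0, linewidth: float = 2.5,
                            wavelength_grid=None,
                            noise: NoiseParams | None = None,
                            tmatrix: TransmissionMatrix | None = None,
                            **micp_options) -> CalibrationCurve:
    """End-to-end calibration: simulate the scan on the system, fit the curve.

    ``wavelength_grid`` defaults to 1-nm bins covering [scan_start,
    scan_stop); a prebuilt ``tmatrix`` may be passed to skip reassembly.
    """
    if tmatrix is None:
        if wavelength_grid is None:
            wavelength_grid = np.arange(scan_start, scan_stop, 1.0)
        tmatrix = build_transmission_matrix(layout, ccd, lineshape, wavelength_grid)
    grid = tmatrix.column_wavelengths
    scan_wl = np.arange(scan_start, scan_stop, scan_step)
    scan_wl = scan_wl[(scan_wl >= grid[0]) & (scan_wl <= grid[-1])]
    if scan_wl.size < 2:
        raise ValidationError("scan range does not overlap the wavelength grid")
    scan = simulate_calibration_scan(tmatrix, scan_wl, linewidth, 1.0, noise)
    return calibration_curve_from_scan(scan, **micp_options)


def micp_to_wavelength(curve: CalibrationCurve, micp: float) -> float:
    """Map a sub-pixel MICP position to wavelength (nm); no extrapolation."""
    return curve.pixel_to_wavelength(micp)
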