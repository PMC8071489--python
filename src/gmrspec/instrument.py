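"""CCD geometry, resonance lineshape, transmission matrix, and readout.

The contact-mounted filter converts wavelength to position: each CCD pixel
sits under a grating segment whose resonance it rejects.  Collecting the
filter transmission at every (pixel, wavelength) pair gives the transmission
efficiency matrix T, and the CCD readout of an incident spectrum I is the
linear model C = T I.  The pixel where C is minimal (the MICP) encodes the
incident peak wavelength; its intensity scales with the incident intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, ValidationError
from .filter_model import DeviceLayout
from .signals import CCDTrace, SpectrumSample


@dataclass(frozen=True)
class CCDGeometry:
    """Linear-CCD sampling of the device coordinate.

    Pixel i covers device positions [offset + i*pitch, offset + (i+1)*pitch);
    its center is offset + (i + 0.5) * pitch.  ``position_offset`` is the
    device coordinate of pixel 0's left edge (negative when the device starts
    far into the pixel array, as with the reported 2073-pixel anchor).
    """

    pixel_pitch: float = 8000.0
    n_pixels: int = 3000
    position_offset: float = 0.0

    def __post_init__(self):
        if self.pixel_pitch <= 0:
            raise ValidationError("pixel_pitch must be positive")
        if self.n_pixels < 1:
            raise ValidationError("n_pixels must be >= 1")

    def pixel_centers(self, pixels) -> np.ndarray:
        return self.position_offset + (np.asarray(pixels) + 0.5) * self.pixel_pitch

    def fractional_pixel(self, position) -> np.ndarray:
        """Continuous pixel coordinate of a device position (center = integer)."""
        return (np.asarray(position, dtype=float) - self.position_offset) / self.pixel_pitch - 0.5

    @classmethod
    def from_anchors(cls, layout: DeviceLayout,
                     anchor_a: tuple[int, float] = (2073, 500.0),
                     anchor_b: tuple[int, float] = (2361, 700.0),
                     n_pixels: int = 3000) -> "CCDGeometry":
        """Geometry that reproduces the reported pixel numbering.

        Chooses pitch and offset so the device positions resonating at the
        two anchor wavelengths land on the two anchor pixel centers.
        """
        (pa, la), (pb, lb) = anchor_a, anchor_b
        xa = float(layout.position_of_wavelength(la))
        xb = float(layout.position_of_wavelength(lb))
        if pb == pa or xb == xa:
            raise ValidationError("anchors must be distinct")
        pitch = (xb - xa) / (pb - pa)
        if pitch <= 0:
            raise ValidationError("anchor ordering inconsistent with the layout")
        offset = xa - (pa + 0.5) * pitch
        return cls(pixel_pitch=pitch, n_pixels=n_pixels, position_offset=offset)


@dataclass(frozen=True)
class ResonanceLineshape:
    """Phenomenological bandstop dip: T(delta) = 1 - d * L(delta).

    ``depth`` d is the fractional transmission loss at resonance; ``fwhm`` is
    the full width of the dip.  A symmetric Lorentzian is the default; the
    true device lineshape (Fano-like) is not reported.
    """

    depth: float = 0.9
    fwhm: float = 3.0
    shape: str = "lorentzian"

    def __post_init__(self):
        if not 0.0 < self.depth <= 1.0:
            raise ValidationError("depth must lie in (0, 1]")
        if self.fwhm <= 0:
            raise ValidationError("fwhm must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValidationError("shape must be 'lorentzian' or 'gaussian'")


def transmission_profile(lineshape: ResonanceLineshape, wavelength,
                         resonant_wavelength):
    """Filter transmission at ``wavelength`` for a segment resonant at
    ``resonant_wavelength``; returns values in [1 - depth, 1]."""
    delta = np.asarray(wavelength, dtype=float) - resonant_wavelength
    if lineshape.shape == "lorentzian":
        unit = 1.0 / (1.0 + (2.0 * delta / lineshape.fwhm) ** 2)
    else:
        unit = np.exp(-4.0 * np.log(2.0) * (delta / lineshape.fwhm) ** 2)
    t = 1.0 - lineshape.depth * unit
    return t if t.ndim else float(t)


@dataclass
class TransmissionMatrix:
    """T with entries T[i, j]: transmission at pixel row i for wavelength j."""

    values: np.ndarray
    row_pixels: np.ndarray
    column_wavelengths: np.ndarray
    row_resonances: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.row_pixels = np.asarray(self.row_pixels, dtype=int)
        self.column_wavelengths = np.asarray(self.column_wavelengths, dtype=float)
        self.row_resonances = np.asarray(self.row_resonances, dtype=float)
        if self.values.shape != (self.row_pixels.size, self.column_wavelengths.size):
            raise DimensionError("matrix shape does not match row/column labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValidationError("transmission entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"{w:.6g}" for w in self.column_wavelengths])
        df.insert(0, "micp_pixel", self.row_pixels)
        return df


@dataclass(frozen=True)
class NoiseParams:
    """Detector noise model: dark offset + Gaussian read noise + shot noise.

    Shot noise is modeled as Gaussian with standard deviation
    ``shot_noise_scale * sqrt(signal)``; 0 disables it.  ``gain_jitter_sd``
    is a run-level multiplicative gain perturbation used for the reference
    spectrometer channel.
    """

    read_noise_sd: float = 0.0
    shot_noise_scale: float = 0.0
    dark_offset: float = 0.0
    gain_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("read_noise_sd", "shot_noise_scale", "dark_offset",
                     "gain_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def enabled(self) -> bool:
        return any((self.read_noise_sd, self.shot_noise_scale,
                    self.dark_offset, self.gain_jitter_sd))


def _pixel_resonances(layout: DeviceLayout, ccd: CCDGeometry):
    """Per-pixel resonant wavelength by segment overlap.

    Returns (pixel indices, lambda_R per pixel).  A pixel's resonance is the
    length-weighted mean lambda_R of the segments its footprint overlaps;
    pixels with no overlap with the device are excluded.
    """
    total = layout.total_length
    pixels = np.arange(ccd.n_pixels)
    left = ccd.position_offset + pixels * ccd.pixel_pitch
    right = left + ccd.pixel_pitch
    inside = (right > 0) & (left < total)
    pixels, left, right = pixels[inside], left[inside], right[inside]
    bounds = layout.boundaries
    lam = layout.resonant_wavelength_nm
    lam_pix = np.empty(pixels.size)
    warned = False
    for k in range(pixels.size):
        lo, hi = max(left[k], 0.0), min(right[k], total)
        i0 = int(np.searchsorted(bounds, lo, side="right") - 1)
        i1 = int(np.searchsorted(bounds, hi, side="left") - 1)
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), layout.n_segments - 1)
        if i1 - i0 >= 2 and not warned:
            warnings.warn("pixel pitch spans more than two grating segments; "
                          "per-pixel resonance is a multi-segment average",
                          stacklevel=2)
            warned = True
        seg = np.arange(i0, i1 + 1)
        w = np.minimum(bounds[seg + 1], hi) - np.maximum(bounds[seg], lo)
        lam_pix[k] = float(np.average(lam[seg], weights=np.maximum(w, 1e-12)))
    return pixels, lam_pix


def build_transmission_matrix(layout: DeviceLayout, ccd: CCDGeometry,
                              lineshape: ResonanceLineshape,
                              wavelength_grid, *,
                              square_mode: bool = False) -> TransmissionMatrix:
    """Assemble T over the CCD pixels covering the layout.

    ``square_mode=True`` returns a square matrix with one row per grid
    wavelength: for each wavelength the pixel whose footprint contains the
    resonant position is selected (strictly increasing row pixels), matching
    the square indexing convention of the reported 200 x 200 matrix.
    """
    grid = np.asarray(wavelength_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("wavelength grid must be 1-D strictly increasing")
    pixels, lam_pix = _pixel_resonances(layout, ccd)
    if pixels.size == 0:
        raise ValidationError("CCD does not overlap the device layout")
    if square_mode:
        pos = np.asarray(layout.position_of_wavelength(grid), dtype=float)
        frac = ccd.fractional_pixel(pos)
        rows = np.rint(frac).astype(int)
        for k in range(1, rows.size):  # enforce strictly increasing pixels
            if rows[k] <= rows[k - 1]:
                rows[k] = rows[k - 1] + 1
        sel = np.searchsorted(pixels, rows)
        if np.any(sel >= pixels.size) or np.any(pixels[sel] != rows):
            raise ValidationError("square-mode rows fall outside the device span")
        pixels, lam_pix = rows, lam_pix[sel]
    t = transmission_profile(lineshape, grid[None, :], lam_pix[:, None])
    return TransmissionMatrix(values=t, row_pixels=pixels,
                              column_wavelengths=grid, row_resonances=lam_pix)


def forward_readout(tmatrix: TransmissionMatrix, spectrum: SpectrumSample,
                    noise: NoiseParams | None = None,
                    quantize_bits: int | None = None) -> CCDTrace:
    """Simulate the CCD readout C = T I, optionally with seeded noise.

    The noiseless core is the exact matrix-vector product.  Noise adds, in
    order: dark offset, shot noise (Gaussian, SD = scale * sqrt(signal)),
    and read noise; the result is clipped at zero.  ``quantize_bits`` rounds
    to integer counts saturating at 2**bits - 1.
    """
    if spectrum.wavelength_nm.size != tmatrix.column_wavelengths.size or \
            not np.allclose(spectrum.wavelength_nm, tmatrix.column_wavelengths,
                            rtol=0, atol=1e-9):
        raise DimensionError("spectrum grid does not match the matrix columns")
    c = tmatrix.values @ spectrum.intensity
    meta = {}
    if noise is not None and noise.enabled:
        rng = np.random.default_rng(noise.seed)
        c = c + noise.dark_offset
        if noise.shot_noise_scale > 0:
            c = c + rng.normal(0.0, 1.0, c.size) * noise.shot_noise_scale * np.sqrt(np.maximum(c, 0.0))
        if noise.read_noise_sd > 0:
            c = c + rng.normal(0.0, noise.read_noise_sd, c.size)
        meta["seed"] = noise.seed
    c = np.maximum(c, 0.0)
    if quantize_bits is not None:
        c = np.clip(np.rint(c), 0, 2**quantize_bits - 1)
    return CCDTrace(pixel=tmatrix.row_pixels.copy(), intensity=c, metadata=meta)
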