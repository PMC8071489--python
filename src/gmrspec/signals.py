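"""In-memory containers for the two signal domains.

A :class:`SpectrumSample` is intensity versus wavelength (the instrument's
input domain); a :class:`CCDTrace` is intensity versus linear-CCD pixel (the
output domain).  The transmission matrix maps between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class SpectrumSample:
    """Intensity versus wavelength on a strictly increasing grid."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValidationError("wavelength grid and intensities differ in length")
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValidationError("spectrum needs a 1-D grid of >= 2 points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValidationError("spectral intensities must be non-negative")

    def scaled(self, factor: float) -> "SpectrumSample":
        return SpectrumSample(self.wavelength_nm.copy(), self.intensity * factor)


@dataclass
class CCDTrace:
    """Intensity versus pixel index on a linear CCD."""

    pixel: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixel = np.asarray(self.pixel, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pixel.shape != self.intensity.shape:
            raise ValidationError("pixel indices and intensities differ in length")
        if np.any(self.intensity < 0):
            raise ValidationError("trace intensities must be non-negative")

    def scaled(self, factor: float) -> "CCDTrace":
        return CCDTrace(self.pixel.copy(), self.intensity * factor,
                        dict(self.metadata))

    def intensity_at(self, pixel: int) -> float:
        """Raw intensity at one absolute pixel index."""
        idx = np.nonzero(self.pixel == pixel)[0]
        if idx.size == 0:
            raise ValidationError(f"pixel {pixel} not present in trace")
        return float(self.intensity[idx[0]])


def gaussian_profile(x, center: float, fwhm: float, amplitude: float = 1.0):
    """Unit-height Gaussian with the given FWHM, scaled by ``amplitude``."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return amplitude * np.exp(-0.5 * ((np.asarray(x, dtype=float) - center) / sigma) ** 2)
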