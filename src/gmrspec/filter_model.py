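"""Gradient grating-period filter model.

A guided-mode-resonance (GMR) filter rejects (reflects) the wavelength that
phase-matches the fundamental guided mode of its waveguide, which at normal
incidence is the second-order Bragg condition

    lambda_R = n_eff(lambda_R) * Lambda,

with Lambda the grating period.  A gradient device concatenates segments of
linearly increasing period, so the rejected wavelength increases linearly
along the device and spectral content is encoded in position.

Two effective-index models are provided:

* ``"weighted-average"`` — thickness- and duty-weighted mean of the guiding
  layer indices; the simple mental model of n_eff as an average over the
  structure.
* ``"slab-mode"`` (default) — the grating layer is homogenized with
  zeroth-order effective-medium theory (TE: n^2 = f n_ridge^2 + (1-f)
  n_groove^2) and the fundamental TE mode of the resulting asymmetric slab
  (substrate / homogenized grating / coating / superstrate) is solved
  numerically.  This captures modal dispersion and the evanescent tails the
  plain average ignores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, EmptyLayoutError, ValidationError
from .materials import MaterialSet, material_index
from .waveguide import te_mode_neff

NEFF_MODELS = ("weighted-average", "slab-mode")

#: Window (nm) inside which a Bragg fixed point is accepted.
RESONANCE_WINDOW = (400.0, 1100.0)


@dataclass(frozen=True)
class GratingDesign:
    """Geometric parameters of the gradient grating.

    Defaults are the fabricated design: periods 250-550 nm in 2-nm steps,
    100 cycles per period, 85-nm grating depth, duty ~0.5, ~130-nm TiO2.
    """

    period_start: float = 250.0
    period_end: float = 550.0
    period_step: float = 2.0
    cycles_per_period: int = 100
    duty_cycle: float = 0.5
    grating_depth: float = 85.0
    coating_thickness: float = 130.0

    def __post_init__(self):
        if self.period_start > self.period_end:
            raise ValidationError("period_start must not exceed period_end")
        if self.period_step <= 0:
            raise ValidationError("period_step must be positive")
        if not 0.0 < self.duty_cycle < 1.0:
            raise ValidationError("duty_cycle must lie strictly in (0, 1)")
        if self.cycles_per_period < 1:
            raise ValidationError("cycles_per_period must be >= 1")
        for name in ("period_start", "grating_depth", "coating_thickness"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def periods(self) -> np.ndarray:
        """All grating periods of the design, smallest first."""
        n = int(round((self.period_end - self.period_start) / self.period_step)) + 1
        return self.period_start + self.period_step * np.arange(n)


@dataclass(frozen=True)
class DeviceLayout:
    """Ordered gradient-grating segments with physical positions.

    Segment k spans [start_nm[k], start_nm[k] + length_nm[k]) in device
    coordinates, with position 0 at the smallest kept period; position,
    period and resonant wavelength all increase together.
    """

    period_nm: np.ndarray
    start_nm: np.ndarray
    length_nm: np.ndarray
    resonant_wavelength_nm: np.ndarray
    cycles_per_period: int

    def __post_init__(self):
        if len(self.period_nm) == 0:
            raise EmptyLayoutError("layout has no segments")
        if np.any(np.diff(self.resonant_wavelength_nm) <= 0):
            raise ValidationError("resonant wavelengths must increase with period")
        ends = self.start_nm + self.length_nm
        if not np.allclose(ends[:-1], self.start_nm[1:]):
            raise ValidationError("segments must tile the device without gaps")

    @property
    def n_segments(self) -> int:
        return len(self.period_nm)

    @property
    def total_length(self) -> float:
        return float(self.length_nm.sum())

    @property
    def boundaries(self) -> np.ndarray:
        """Segment boundary positions, length n_segments + 1."""
        return np.concatenate([self.start_nm, [self.total_length]])

    def segment_centers(self) -> np.ndarray:
        return self.start_nm + 0.5 * self.length_nm

    def position_of_wavelength(self, wavelength_nm) -> np.ndarray:
        """Device position whose local resonance equals ``wavelength_nm``.

        Linear interpolation on (lambda_R at segment center, center position),
        with linear end-slope extrapolation for wavelengths slightly outside
        the discrete set of segment resonances.
        """
        x = self.resonant_wavelength_nm
        y = self.segment_centers()
        lam = np.asarray(wavelength_nm, dtype=float)
        pos = np.interp(lam, x, y)
        if x.size > 1:
            lo_slope = (y[1] - y[0]) / (x[1] - x[0])
            hi_slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            pos = np.where(lam < x[0], y[0] + (lam - x[0]) * lo_slope, pos)
            pos = np.where(lam > x[-1], y[-1] + (lam - x[-1]) * hi_slope, pos)
        return pos if pos.ndim else float(pos)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "segment_index": np.arange(self.n_segments),
            "period_nm": self.period_nm,
            "start_nm": self.start_nm,
            "length_nm": self.length_nm,
            "resonant_wavelength_nm": self.resonant_wavelength_nm,
        })


def grating_layer_index(design: GratingDesign, materials: MaterialSet,
                        wavelength) -> float:
    """Zeroth-order TE effective-medium index of the grating layer.

    Ridges are the adhesive; grooves are filled by the sputtered coating, so
    n^2 = f n_adhesive^2 + (1 - f) n_coating^2 with f the duty cycle.
    """
    f = design.duty_cycle
    n_r = np.asarray(material_index(materials.adhesive, wavelength), dtype=float)
    n_g = np.asarray(material_index(materials.coating, wavelength), dtype=float)
    n = np.sqrt(f * n_r**2 + (1.0 - f) * n_g**2)
    return n if n.ndim else float(n)


def effective_index(design: GratingDesign, materials: MaterialSet,
                    period: float, wavelength: float,
                    model: str = "slab-mode") -> float:
    """Effective index of the guided mode at ``wavelength`` (nm).

    ``period`` participates only through validation (the homogenized layer is
    period-independent at zeroth order); it is kept in the signature because
    the resonance solver is naturally parameterized per segment.
    """
    if model not in NEFF_MODELS:
        raise ValidationError(f"unknown effective-index model {model!r}")
    if not (design.period_start <= period <= design.period_end):
        raise ValidationError(
            f"period {period} nm outside design range "
            f"[{design.period_start}, {design.period_end}] nm")
    n_emt = grating_layer_index(design, materials, wavelength)
    n_coat = material_index(materials.coating, wavelength)
    if model == "weighted-average":
        t_g, t_c = design.grating_depth, design.coating_thickness
        return (t_g * n_emt + t_c * n_coat) / (t_g + t_c)
    n_sub = material_index(materials.adhesive, wavelength)
    n_sup = material_index(materials.superstrate, wavelength)
    return te_mode_neff(
        wavelength,
        layer_indices=(n_emt, n_coat),
        layer_thicknesses=(design.grating_depth, design.coating_thickness),
        n_substrate=n_sub, n_cover=n_sup)


def resonant_wavelength(design: GratingDesign, materials: MaterialSet,
                        period: float, model: str = "slab-mode",
                        tol: float = 1e-6, max_iter: int = 100) -> float:
    """Solve the Bragg fixed point lambda = n_eff(lambda) * Lambda.

    Damped iteration starting from the weighted-average estimate; converged
    when the residual |lambda - n_eff(lambda) Lambda| <= ``tol`` nm.
    """
    lo, hi = RESONANCE_WINDOW
    lam = period * effective_index(design, materials, period,
                                   min(max(2.0 * period, lo), hi),
                                   model="weighted-average")
    lam = min(max(lam, lo), hi)
    damping = 0.7
    for _ in range(max_iter):
        target = period * effective_index(design, materials, period, lam, model)
        if abs(target - lam) <= tol:
            return target
        lam = min(max(lam + damping * (target - lam), lo), hi)
    raise ConvergenceError(
        f"Bragg fixed point did not converge for period {period} nm "
        f"(last residual {abs(target - lam):.3g} nm)")


def build_layout(design: GratingDesign, materials: MaterialSet,
                 band: tuple[float, float] | None = None,
                 model: str = "slab-mode") -> DeviceLayout:
    """Enumerate segments and assign resonances; optionally band-restrict.

    With ``band=(lmin, lmax)`` only segments whose resonance lies inside the
    band are kept (the reference device keeps 500-700 nm).  Positions are
    cumulative over the kept segments, smallest period at position 0.
    """
    if band is not None and not band[0] < band[1]:
        raise ValidationError("band must satisfy lmin < lmax")
    periods = design.periods()
    lam_r = np.empty_like(periods)
    for k, p in enumerate(periods):
        lam_r[k] = resonant_wavelength(design, materials, p, model=model)
    if band is not None:
        keep = (lam_r >= band[0]) & (lam_r <= band[1])
        if not keep.any():
            raise EmptyLayoutError(
                f"no grating period resonates inside [{band[0]}, {band[1]}] nm")
        periods, lam_r = periods[keep], lam_r[keep]
    lengths = design.cycles_per_period * periods
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]])
    return DeviceLayout(period_nm=periods, start_nm=starts, length_nm=lengths,
                        resonant_wavelength_nm=lam_r,
                        cycles_per_period=design.cycles_per_period)
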