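"""Refractive-index models for the filter stack.

The resonance condition lambda_R = n_eff * Lambda couples every layer of the
device through its refractive index, so materials are represented as callable
dispersion models mapping wavelength (nm) to a dimensionless index.  Two
models are provided: a constant index (adequate for the polymer layers over
the visible) and a Cauchy series for the dispersive TiO2 coating.

The default stack mirrors the fabricated device: a PET substrate, a UV-cured
optical-adhesive (NOA 68) grating, a sputtered TiO2 waveguiding layer, and an
air superstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DispersionRangeError, ValidationError

#: Default validity window of the shipped dispersion models, nm.  Wide enough
#: to cover every resonance the reference design's 250-550 nm period span can produce.
DEFAULT_VALID_RANGE: tuple[float, float] = (380.0, 1150.0)


def _check_range(wavelength, valid_range, label: str):
    lam = np.asarray(wavelength, dtype=float)
    lo, hi = valid_range
    if np.any(lam < lo) or np.any(lam > hi):
        raise DispersionRangeError(
            f"wavelength outside the {label} dispersion range [{lo}, {hi}] nm"
        )
    return lam


@dataclass(frozen=True)
class ConstantIndex:
    """Dispersionless refractive index n(lambda) = n."""

    n: float
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE
    label: str = "constant"

    def __post_init__(self):
        if self.n < 1.0:
            raise ValidationError("refractive index must be >= 1")

    def __call__(self, wavelength):
        lam = _check_range(wavelength, self.valid_range, self.label)
        return np.broadcast_to(np.float64(self.n), lam.shape).copy() if lam.ndim else float(self.n)


@dataclass(frozen=True)
class CauchyIndex:
    """Cauchy dispersion n(lambda) = a + b/lambda^2 + c/lambda^4, lambda in nm."""

    a: float
    b: float = 0.0
    c: float = 0.0
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE
    label: str = "cauchy"

    def __call__(self, wavelength):
        lam = _check_range(wavelength, self.valid_range, self.label)
        n = self.a + self.b / lam**2 + self.c / lam**4
        if np.any(np.asarray(n) < 1.0):
            raise ValidationError("Cauchy model evaluates below 1; bad coefficients")
        return n if lam.ndim else float(n)


IndexModel = ConstantIndex | CauchyIndex


@dataclass(frozen=True)
class MaterialSet:
    """The four materials entering the effective-index model.

    ``coating`` is the high-index waveguiding film (TiO2); ``adhesive`` is the
    grating ridge material (NOA 68); ``substrate`` sits below the grating
    (PET); ``superstrate`` is the medium above the coating (air by default).
    The guiding condition requires coating > adhesive > 1 across the band.
    """

    substrate: IndexModel
    adhesive: IndexModel
    coating: IndexModel
    superstrate: IndexModel

    def validate(self, band=(450.0, 750.0)) -> None:
        lam = np.linspace(band[0], band[1], 31)
        n_sub = np.asarray(self.substrate(lam))
        n_adh = np.asarray(self.adhesive(lam))
        n_coat = np.asarray(self.coating(lam))
        n_sup = np.asarray(self.superstrate(lam))
        for name, n in (("substrate", n_sub), ("adhesive", n_adh),
                        ("coating", n_coat), ("superstrate", n_sup)):
            if np.any(n < 1.0):
                raise ValidationError(f"{name} index drops below 1 on {band}")
        if not np.all(n_coat > n_adh):
            raise ValidationError("guiding condition violated: coating index "
                                  "must exceed adhesive index across the band")


def material_index(material: IndexModel, wavelength) -> float:
    """Evaluate a dispersion model at ``wavelength`` (nm).

    Raises :class:`DispersionRangeError` outside the model's validity window.
    """
    return material(wavelength)


def default_materials() -> MaterialSet:
    """Material set for the as-fabricated stack.

    PET 1.57 and NOA 68 1.54 are the manufacturers' nominal visible-band
    values; TiO2 uses a Cauchy fit typical of sputtered films (n ~ 2.21 at
    550 nm), chosen so the modeled resonance band of the reference geometry
    brackets the 500-700 nm operating window.
    """
    return MaterialSet(
        substrate=ConstantIndex(1.57, label="PET"),
        adhesive=ConstantIndex(1.54, label="NOA68"),
        coating=CauchyIndex(2.13, 2.5e4, label="TiO2"),
        superstrate=ConstantIndex(1.0, label="air"),
    )
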