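"""TE guided-mode solver for planar multilayer stacks.

The grating layer is homogenized (zeroth-order effective-medium theory), so
the mode problem reduces to the classic asymmetric multilayer slab: a
semi-infinite substrate, a small number of finite films, and a semi-infinite
cover.  The solver finds effective indices n_eff where the TE characteristic
function changes sign, refining each bracket with Brent's method.

Field convention: in the substrate the field decays as exp(+gamma_s x) going
down; a 2x2 real transfer matrix propagates (E, dE/dx) upward through the
films; the cover imposes dE/dx = -gamma_c E.  Guided modes satisfy

    F(n_eff) = gamma_c (m11 + m12 gamma_s) + (m21 + m22 gamma_s) = 0

with gamma = k0 sqrt(n_eff^2 - n^2) in the claddings.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .errors import NoGuidedModeError

_TWO_PI = 2.0 * np.pi


def _layer_entries(q, t):
    """Transfer-matrix entries for one film.

    ``q = k0^2 (n^2 - n_eff^2)`` may be positive (oscillatory) or negative
    (evanescent); both branches are expressed with real functions so F stays
    real and sign changes are meaningful.
    """
    q = np.asarray(q, dtype=float)
    c = np.empty_like(q)
    s = np.empty_like(q)
    pos = q > 0
    neg = q < 0
    zer = ~(pos | neg)
    kp = np.sqrt(q[pos])
    c[pos] = np.cos(kp * t)
    s[pos] = np.sin(kp * t) / kp
    km = np.sqrt(-q[neg])
    c[neg] = np.cosh(km * t)
    s[neg] = np.sinh(km * t) / km
    c[zer] = 1.0
    s[zer] = t
    # d(E')/dx row uses -q * s
    return c, s, -q * s


def te_characteristic(neff, wavelength_nm, layer_indices, layer_thicknesses,
                      n_substrate, n_cover):
    """Vectorized TE characteristic function F(n_eff); zeros are guided modes."""
    neff = np.asarray(neff, dtype=float)
    k0 = _TWO_PI / wavelength_nm
    ne2 = neff**2
    gam_s = k0 * np.sqrt(np.maximum(ne2 - n_substrate**2, 0.0))
    gam_c = k0 * np.sqrt(np.maximum(ne2 - n_cover**2, 0.0))
    # start vector (E, E') at the substrate interface
    e = np.ones_like(neff)
    ep = gam_s.copy() if neff.ndim else np.asarray(gam_s)
    for n_k, t_k in zip(layer_indices, layer_thicknesses):
        q = k0**2 * (n_k**2 - ne2)
        c, s, ms = _layer_entries(q, t_k)
        e, ep = c * e + s * ep, ms * e + c * ep
    return gam_c * e + ep


def te_mode_neff(wavelength_nm: float, layer_indices, layer_thicknesses,
                 n_substrate: float, n_cover: float, *,
                 mode: int = 0, n_grid: int = 1500) -> float:
    """Effective index of the TE_m guided mode at one wavelength.

    Layers are listed bottom (adjacent to the substrate) to top.  ``mode=0``
    returns the fundamental (largest n_eff) solution.  Raises
    :class:`NoGuidedModeError` when the requested mode does not exist.
    """
    lo = max(n_substrate, n_cover) + 1e-9
    hi = max(layer_indices) - 1e-9
    if hi <= lo:
        raise NoGuidedModeError("no index contrast: core does not exceed claddings")
    grid = np.linspace(lo, hi, n_grid)
    f = te_characteristic(grid, wavelength_nm, layer_indices,
                          layer_thicknesses, n_substrate, n_cover)
    sign = np.sign(f)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size <= mode:
        raise NoGuidedModeError(
            f"TE_{mode} mode not found at {wavelength_nm:.1f} nm "
            f"(stack too thin or contrast too low)")
    # roots ordered by decreasing n_eff: fundamental mode has the largest
    idx = flips[::-1][mode]
    a, b = grid[idx], grid[idx + 1]

    def scalar_f(x):
        return float(te_characteristic(np.asarray([x]), wavelength_nm,
                                       layer_indices, layer_thicknesses,
                                       n_substrate, n_cover)[0])

    return float(brentq(scalar_f, a, b, xtol=1e-12, rtol=1e-14))
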