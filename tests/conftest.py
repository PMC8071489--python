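"""Shared fixtures: the default device, instrument, and calibration.

Everything heavy (layout solve, transmission matrix, calibration scan) is
session-scoped; individual tests treat these as the reference system.
"""

import numpy as np
import pytest

from gmrspec.calibration import build_calibration_curve
from gmrspec.filter_model import GratingDesign, build_layout
from gmrspec.instrument import (CCDGeometry, ResonanceLineshape,
                                build_transmission_matrix)
from gmrspec.materials import default_materials


@pytest.fixture(scope="session")
def design():
    return GratingDesign()


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def band_layout(design, materials):
    """Gradient layout restricted to resonances in 500-700 nm."""
    return build_layout(design, materials, band=(500.0, 700.0))


@pytest.fixture(scope="session")
def ccd(band_layout):
    """CCD anchored to the reported pixel numbering (2073 <-> 500 nm)."""
    return CCDGeometry.from_anchors(band_layout)


@pytest.fixture(scope="session")
def lineshape():
    return ResonanceLineshape()


@pytest.fixture(scope="session")
def wavelength_grid():
    """200 one-nm bins covering the 500-700 nm operating band."""
    return np.arange(500.0, 700.0, 1.0)


@pytest.fixture(scope="session")
def tmatrix(band_layout, ccd, lineshape, wavelength_grid):
    return build_transmission_matrix(band_layout, ccd, lineshape,
                                     wavelength_grid)


@pytest.fixture(scope="session")
def square_tmatrix(band_layout, ccd, lineshape, wavelength_grid):
    return build_transmission_matrix(band_layout, ccd, lineshape,
                                     wavelength_grid, square_mode=True)


@pytest.fixture(scope="session")
def curve(band_layout, ccd, lineshape, tmatrix):
    """Noiseless calibration over the full scan (500-699 nm, 1-nm steps)."""
    return build_calibration_curve(band_layout, ccd, lineshape,
                                   tmatrix=tmatrix)
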