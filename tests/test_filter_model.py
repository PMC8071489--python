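"""Filter model: effective index, Bragg resonance, gradient layout."""

import numpy as np
import pytest
from scipy.optimize import brentq

from gmrspec.errors import (ConvergenceError, EmptyLayoutError,
                            NoGuidedModeError, ValidationError)
from gmrspec.filter_model import (GratingDesign, build_layout,
                                  effective_index, grating_layer_index,
                                  resonant_wavelength)
from gmrspec.materials import ConstantIndex, MaterialSet
from gmrspec.waveguide import te_mode_neff


def uniform_stack(n=1.8):
    model = ConstantIndex(n)
    return MaterialSet(substrate=model, adhesive=model, coating=model,
                       superstrate=model)


def analytic_slab_neff(n_core, n_sub, n_cover, thickness, lam):
    """Independent single-slab TE0 oracle.

    Solves the textbook transcendental tan(kappa t) = kappa (gamma_s +
    gamma_c) / (kappa^2 - gamma_s gamma_c) by dense bracketing + Brent, a
    different formulation from the transfer-matrix solver under test.
    """
    k0 = 2 * np.pi / lam

    def f(neff):
        kap = k0 * np.sqrt(n_core**2 - neff**2)
        gs = k0 * np.sqrt(neff**2 - n_sub**2)
        gc = k0 * np.sqrt(neff**2 - n_cover**2)
        return np.tan(kap * thickness) - kap * (gs + gc) / (kap**2 - gs * gc)

    grid = np.linspace(max(n_sub, n_cover) + 1e-6, n_core - 1e-6, 40001)
    vals = np.array([f(x) for x in grid])
    # reject tan-branch discontinuities: keep brackets with small magnitude
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] < 0 and abs(vals[i]) < 10 and abs(vals[i + 1]) < 10:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
    return max(roots)


def test_slab_solver_against_analytic_single_slab_dispersion():
    n_core, n_sub, n_cover, t, lam = 2.3, 1.54, 1.0, 200.0, 600.0
    got = te_mode_neff(lam, (n_core,), (t,), n_sub, n_cover)
    want = analytic_slab_neff(n_core, n_sub, n_cover, t, lam)
    assert got == pytest.approx(want, abs=1e-9)


def test_no_guided_mode_when_core_is_too_thin():
    with pytest.raises(NoGuidedModeError):
        te_mode_neff(600.0, (1.6,), (10.0,), 1.54, 1.0)


def test_degenerate_uniform_stack_weighted_average_is_that_index(design=GratingDesign()):
    assert effective_index(design, uniform_stack(1.8), 300.0, 600.0,
                           model="weighted-average") == pytest.approx(1.8)


def test_slab_mode_neff_respects_guided_bounds(design, materials):
    for lam in np.linspace(500.0, 700.0, 9):
        neff = effective_index(design, materials, 300.0, lam, model="slab-mode")
        n_clad = max(materials.adhesive(lam), materials.superstrate(lam))
        assert n_clad < neff < materials.coating(lam)


def test_weighted_average_and_slab_mode_agree_within_15_percent(design, materials):
    for lam in (500.0, 600.0, 700.0):
        wa = effective_index(design, materials, 300.0, lam, "weighted-average")
        sl = effective_index(design, materials, 300.0, lam, "slab-mode")
        assert abs(wa - sl) / sl < 0.15


def test_period_outside_design_range_is_rejected(design, materials):
    with pytest.raises(ValidationError):
        effective_index(design, materials, 100.0, 600.0)


@pytest.mark.parametrize("period, expected", [(300.0, 600.0), (250.0, 500.0)])
def test_dispersionless_resonance_is_exactly_neff_times_period(period, expected):
    design = GratingDesign()
    lam = resonant_wavelength(design, uniform_stack(2.0), period,
                              model="weighted-average")
    assert lam == pytest.approx(expected, abs=1e-9)


def test_dispersive_resonance_matches_dense_scan_oracle(design, materials):
    """Two-stage dense scan for the sign change of lambda - neff(lambda)*P."""
    period = 300.0

    def resid(lam):
        return lam - period * effective_index(design, materials, period, lam)

    coarse = np.arange(450.0, 1050.0, 1.0)
    vals = np.array([resid(x) for x in coarse])
    i = int(np.nonzero(vals[:-1] * vals[1:] < 0)[0][0])
    fine = np.arange(coarse[i], coarse[i + 1] + 1e-9, 0.001)
    fvals = np.array([resid(x) for x in fine])
    j = int(np.nonzero(fvals[:-1] * fvals[1:] < 0)[0][0])
    oracle = 0.5 * (fine[j] + fine[j + 1])

    assert resonant_wavelength(design, materials, period) == pytest.approx(
        oracle, abs=0.001)


def test_bragg_residual_below_tolerance_for_every_segment(design, materials,
                                                          band_layout):
    for period, lam in zip(band_layout.period_nm,
                           band_layout.resonant_wavelength_nm):
        neff = effective_index(design, materials, period, lam)
        assert abs(lam - neff * period) <= 1e-6


def test_full_design_enumerates_151_segments(design, materials):
    layout = build_layout(design, materials)
    assert layout.n_segments == 151


def test_total_length_matches_arithmetic_series(design, materials):
    """100 cycles x sum of periods 250..550 step 2 = 6.04 mm."""
    layout = build_layout(design, materials)
    periods = np.arange(250.0, 550.0 + 1.0, 2.0)
    expected = design.cycles_per_period * periods.sum()
    assert expected == 6.04e6
    assert layout.total_length == pytest.approx(expected, rel=1e-12)


def test_single_period_design_has_one_segment():
    design = GratingDesign(period_start=400.0, period_end=400.0)
    layout = build_layout(design, uniform_stack(1.5), model="weighted-average")
    assert layout.n_segments == 1
    assert layout.total_length == pytest.approx(40000.0)


def test_resonance_strictly_increases_with_period(design, materials):
    layout = build_layout(design, materials)
    assert np.all(np.diff(layout.resonant_wavelength_nm) > 0)


def test_band_restricted_layout_is_under_2_5_mm(band_layout):
    assert 500.0 <= band_layout.resonant_wavelength_nm[0]
    assert band_layout.resonant_wavelength_nm[-1] <= 700.0
    assert band_layout.total_length < 2.5e6


def test_period_span_supports_over_400_nm_bandwidth(design, materials):
    bw = (resonant_wavelength(design, materials, 550.0)
          - resonant_wavelength(design, materials, 250.0))
    assert bw > 400.0


def test_empty_band_selection_raises(design, materials):
    with pytest.raises(EmptyLayoutError):
        build_layout(design, materials, band=(430.0, 440.0))


def test_design_invariants_are_enforced():
    with pytest.raises(ValidationError):
        GratingDesign(duty_cycle=1.5)
    with pytest.raises(ValidationError):
        GratingDesign(period_start=500.0, period_end=400.0)
    with pytest.raises(ValidationError):
        GratingDesign(period_step=-1.0)


def test_grating_layer_index_interpolates_between_constituents(design, materials):
    n = grating_layer_index(design, materials, 600.0)
    assert materials.adhesive(600.0) < n < materials.coating(600.0)
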