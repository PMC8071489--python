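"""Transmission matrix and CCD readout: bandstop structure, C = TI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmrspec.calibration import find_micp, monochromatic_spectrum
from gmrspec.errors import DimensionError, ValidationError
from gmrspec.instrument import (NoiseParams, ResonanceLineshape,
                                forward_readout, transmission_profile)
from gmrspec.signals import SpectrumSample


class TestTransmissionProfile:
    def test_dip_bottom_is_one_minus_depth(self):
        ls = ResonanceLineshape(depth=0.9, fwhm=3.0)
        assert transmission_profile(ls, 600.0, 600.0) == pytest.approx(0.1)

    def test_far_detuned_transmission_approaches_unity(self):
        ls = ResonanceLineshape(depth=0.9, fwhm=3.0)
        t = transmission_profile(ls, 600.0 + 50 * ls.fwhm, 600.0)
        assert 1.0 - t < 1e-3

    def test_lorentzian_half_width_identity(self):
        # L(fwhm/2) = 1/2, so T = 1 - depth/2 exactly
        ls = ResonanceLineshape(depth=0.9, fwhm=3.0)
        assert transmission_profile(ls, 600.0 + ls.fwhm / 2, 600.0) == \
            pytest.approx(1.0 - 0.45, abs=1e-12)

    @given(delta=st.floats(-500, 500), depth=st.floats(0.01, 1.0),
           fwhm=st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=50)
    def test_profile_always_within_unit_band(self, delta, depth, fwhm):
        ls = ResonanceLineshape(depth=depth, fwhm=fwhm)
        t = transmission_profile(ls, 600.0 + delta, 600.0)
        assert 1.0 - depth <= t <= 1.0


class TestMatrixStructure:
    def test_square_mode_matrix_is_200_by_200(self, square_tmatrix):
        assert square_tmatrix.shape == (200, 200)

    def test_entries_bounded_and_row_minimum_at_own_resonance(self, tmatrix):
        v = tmatrix.values
        assert np.all(v >= 0) and np.all(v <= 1)
        argmin = tmatrix.column_wavelengths[np.argmin(v, axis=1)]
        nearest = tmatrix.column_wavelengths[np.argmin(
            np.abs(tmatrix.column_wavelengths[None, :]
                   - tmatrix.row_resonances[:, None]), axis=1)]
        assert np.array_equal(argmin, nearest)

    def test_row_resonances_nondecreasing_along_the_device(self, tmatrix):
        # piecewise constant within a segment (several pixels per segment),
        # stepping up at every segment boundary
        assert np.all(np.diff(tmatrix.row_resonances) >= 0)
        assert tmatrix.row_resonances[-1] > tmatrix.row_resonances[0]

    def test_anchored_system_maps_700_nm_to_pixel_2361(self, tmatrix):
        spec = monochromatic_spectrum(699.0, 2.5, 1.0,
                                      tmatrix.column_wavelengths)
        micp = find_micp(forward_readout(tmatrix, spec)).subpixel_position
        # 699 nm is the last grid bin; the reported anchor 2361 <-> 700 nm
        assert micp == pytest.approx(2361, abs=2.0)

    def test_monochromatic_micp_increases_with_wavelength(self, tmatrix):
        micps = []
        for lam in (520.0, 600.0, 680.0):
            spec = monochromatic_spectrum(lam, 2.5, 1.0,
                                          tmatrix.column_wavelengths)
            micps.append(find_micp(forward_readout(tmatrix, spec)).micp_pixel)
        assert micps[0] < micps[1] < micps[2]


class TestForwardReadout:
    def test_zero_spectrum_gives_zero_trace(self, tmatrix):
        spec = SpectrumSample(tmatrix.column_wavelengths,
                              np.zeros_like(tmatrix.column_wavelengths))
        assert np.all(forward_readout(tmatrix, spec).intensity == 0)

    def test_readout_is_homogeneous_in_intensity(self, tmatrix):
        rng = np.random.default_rng(0)
        spec = SpectrumSample(tmatrix.column_wavelengths,
                              rng.uniform(0, 5, tmatrix.shape[1]))
        a = forward_readout(tmatrix, spec).intensity
        b = forward_readout(tmatrix, spec.scaled(3.5)).intensity
        np.testing.assert_allclose(b, 3.5 * a, rtol=1e-12)

    def test_readout_is_additive_over_spectra(self, tmatrix):
        rng = np.random.default_rng(1)
        grid = tmatrix.column_wavelengths
        s1 = SpectrumSample(grid, rng.uniform(0, 2, grid.size))
        s2 = SpectrumSample(grid, rng.uniform(0, 2, grid.size))
        s12 = SpectrumSample(grid, s1.intensity + s2.intensity)
        np.testing.assert_allclose(
            forward_readout(tmatrix, s12).intensity,
            forward_readout(tmatrix, s1).intensity
            + forward_readout(tmatrix, s2).intensity, rtol=1e-12)

    def test_matches_explicit_double_loop_product(self, tmatrix):
        rng = np.random.default_rng(2)
        grid = tmatrix.column_wavelengths
        spec = SpectrumSample(grid, rng.uniform(0, 10, grid.size))
        got = forward_readout(tmatrix, spec).intensity
        want = np.empty(tmatrix.shape[0])
        for i in range(tmatrix.shape[0]):
            acc = 0.0
            for j in range(tmatrix.shape[1]):
                acc += tmatrix.values[i, j] * spec.intensity[j]
            want[i] = acc
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_grid_mismatch_is_a_dimension_error(self, tmatrix):
        grid = tmatrix.column_wavelengths[:-1]
        spec = SpectrumSample(grid, np.ones_like(grid))
        with pytest.raises(DimensionError):
            forward_readout(tmatrix, spec)

    def test_seeded_noise_is_reproducible(self, tmatrix):
        spec = monochromatic_spectrum(600.0, 2.5, 100.0,
                                      tmatrix.column_wavelengths)
        noise = NoiseParams(read_noise_sd=1.0, shot_noise_scale=0.5,
                            dark_offset=5.0, seed=42)
        a = forward_readout(tmatrix, spec, noise).intensity
        b = forward_readout(tmatrix, spec, noise).intensity
        assert np.array_equal(a, b)
        c = forward_readout(tmatrix, spec,
                            NoiseParams(read_noise_sd=1.0, seed=43)).intensity
        assert not np.array_equal(a, c)

    def test_noise_parameters_must_be_nonnegative(self):
        with pytest.raises(ValidationError):
            NoiseParams(read_noise_sd=-1.0)
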