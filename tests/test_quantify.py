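"""Quantification: extraction, dose response, OLS, LOD, comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gmrspec.assay_sim import generate_dataset, preset_assay
from gmrspec.errors import (DegenerateRegressionError, InsufficientDataError,
                            NormalizationError, PairingError)
from gmrspec.quantify import (build_dose_response, compare_instruments,
                              correlate_micp_wavelength, estimate_lod,
                              extract_measurement, fit_dose_response,
                              lod_from_noise_sensitivity, measurement_noise,
                              ols)

HSA_CONCS = (200.0, 150.0, 100.0, 50.0, 25.0, 12.5, 6.25)


def _table(rows):
    return pd.DataFrame(rows, columns=["run", "concentration", "replicate",
                                       "intensity"])


class TestExtraction:
    def test_bright_dye_trace_reads_600_nm(self, tmatrix, curve):
        assay, plan = preset_assay("tamra")
        rec = generate_dataset(plan, assay, tmatrix).select(
            run=0, concentration=1e-3)[0]
        m = extract_measurement(rec.trace, curve)
        assert m.estimated_wavelength == pytest.approx(600.0, abs=1.0)

    def test_spectrometer_channel_reads_the_gaussian_peak_exactly(self, tmatrix):
        assay, plan = preset_assay("tamra")
        rec = generate_dataset(plan, assay, tmatrix).select(
            run=0, concentration=1e-3)[0]
        m = extract_measurement(rec.spectrum)
        assert m.peak_wavelength == pytest.approx(600.0, abs=1e-6)

    def test_intensity_scales_but_micp_does_not(self, tmatrix, curve):
        assay, plan = preset_assay("tamra")
        rec = generate_dataset(plan, assay, tmatrix).select(
            run=0, concentration=1e-3)[0]
        m1 = extract_measurement(rec.trace, curve)
        m2 = extract_measurement(rec.trace.scaled(4.0), curve)
        assert m2.micp_pixel == m1.micp_pixel
        assert m2.estimated_wavelength == pytest.approx(m1.estimated_wavelength)
        assert m2.intensity == pytest.approx(4.0 * m1.intensity, rel=1e-12)


class TestDoseResponse:
    def test_normalization_divides_by_the_top_concentration(self):
        t = build_dose_response(_table([(0, 1.0, 0, 2.0), (0, 5.0, 0, 4.0),
                                        (0, 10.0, 0, 8.0)]))
        np.testing.assert_allclose(
            t.data.sort_values("concentration")["normalized_intensity"],
            [0.25, 0.5, 1.0])

    def test_three_runs_each_normalize_to_their_own_reference(self, tmatrix,
                                                              curve):
        assay, plan = preset_assay("hsa-fluorescent")
        ds = generate_dataset(plan, assay, tmatrix)
        rows = [dict(run=r.run, concentration=r.concentration,
                     replicate=r.replicate,
                     intensity=extract_measurement(r.trace, curve).intensity)
                for r in ds.records]
        t = build_dose_response(pd.DataFrame(rows))
        assert len(t.data) == 24
        top = t.data[t.data["concentration"] == 200.0]
        np.testing.assert_allclose(top["normalized_intensity"], 1.0)

    def test_missing_reference_concentration_raises(self):
        with pytest.raises(NormalizationError):
            build_dose_response(_table([(0, 1.0, 0, 2.0), (0, 10.0, 0, 8.0),
                                        (1, 1.0, 0, 2.0)]))

    def test_zero_rate_kinetic_table_is_identically_zero(self):
        df = pd.DataFrame({"run": [0, 0, 0], "concentration": [1.0, 5.0, 10.0],
                           "replicate": 0, "intensity_t0": [3.0, 3.0, 3.0],
                           "intensity_t1": [3.0, 3.0, 3.0]})
        t = build_dose_response(df, kinetic=True, normalization="none")
        assert np.all(t.data["raw_intensity"] == 0.0)


class TestRegression:
    def test_noiseless_line_is_recovered_exactly(self):
        rows = [(0, c, 0, 0.037 * (c / 10.0) + 0.26) for c in HSA_CONCS]
        t = build_dose_response(_table(rows), normalization="none")
        fit = fit_dose_response(t)
        assert fit.slope == pytest.approx(0.037, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_is_degenerate_with_zero_slope(self):
        rows = [(0, c, 0, 0.5) for c in (1.0, 2.0, 3.0)]
        fit = fit_dose_response(build_dose_response(_table(rows),
                                                    normalization="none"))
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.degenerate

    def test_three_point_cloud_matches_hand_computed_least_squares(self):
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 2.5, 3.0])
        fit = ols(x, y)
        # closed-form oracle computed independently
        n = 3
        sx, sy, sxy, sxx = x.sum(), y.sum(), (x * y).sum(), (x * x).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx**2)
        intercept = (sy - slope * sx) / n
        ss_res = ((y - slope * x - intercept) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-14)
        assert fit.intercept == pytest.approx(intercept, abs=1e-14)
        assert fit.r_squared == pytest.approx(1 - ss_res / ss_tot, abs=1e-14)

    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=25))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_ols_agrees_with_statsmodels_to_1e10(self, pts):
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        import statsmodels.api as sm
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        fit = ols(x, y)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10, rel=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10,
                                              rel=1e-10)
        assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)

    def test_too_few_concentrations_raise(self):
        rows = [(0, 1.0, 0, 0.1), (0, 2.0, 0, 0.2)]
        with pytest.raises(InsufficientDataError):
            fit_dose_response(build_dose_response(_table(rows),
                                                  normalization="none"))


class TestLod:
    def test_reported_noise_and_sensitivity_reproduce_reported_lods(self):
        assert lod_from_noise_sensitivity(0.1517, 0.037).lod == pytest.approx(
            40.99, rel=1e-3)
        assert lod_from_noise_sensitivity(0.0730, 0.042).lod == pytest.approx(
            17.39, rel=1e-3)

    def test_zero_noise_gives_zero_lod(self):
        assert lod_from_noise_sensitivity(0.0, 0.037).lod == 0.0

    def test_pooled_noise_is_three_pooled_standard_deviations(self):
        rows = [(r, c, 0, c / 10.0 + off) for c in (10.0, 20.0, 30.0)
                for r, off in ((0, -0.1), (1, 0.0), (2, 0.1))]
        t = build_dose_response(_table(rows), normalization="none")
        assert measurement_noise(t) == pytest.approx(3 * 0.1)

    def test_single_replicate_noise_is_undefined(self):
        rows = [(0, c, 0, c) for c in (1.0, 2.0, 3.0)]
        t = build_dose_response(_table(rows), normalization="none")
        with pytest.raises(InsufficientDataError):
            measurement_noise(t)

    def test_estimate_lod_combines_table_noise_and_fit_slope(self):
        rows = [(r, c, 0, 0.037 * c / 10.0 + off) for c in HSA_CONCS
                for r, off in ((0, -0.01), (1, 0.0), (2, 0.01))]
        t = build_dose_response(_table(rows), normalization="none")
        fit = fit_dose_response(t)
        lod = estimate_lod(t, fit)
        assert lod.noise == pytest.approx(3 * 0.01)
        assert lod.lod == pytest.approx(10 * 3 * 0.01 / 0.037, rel=1e-9)


class TestComparisons:
    def _pair(self, scale):
        rows_a, rows_b = [], []
        for r in range(2):
            for c in (1.0, 5.0, 10.0):
                y = c / 10.0 + 0.05 * r
                rows_a.append((r, c, 0, scale * y))
                rows_b.append((r, c, 0, y))
        return (build_dose_response(_table(rows_a), normalization="none"),
                build_dose_response(_table(rows_b), normalization="none"))

    def test_identical_tables_compare_with_unit_slope(self):
        a, b = self._pair(1.0)
        comp = compare_instruments(a, b)
        assert comp.slope == pytest.approx(1.0)
        assert comp.r_squared == pytest.approx(1.0)

    def test_doubled_channel_detects_slope_two(self):
        a, b = self._pair(2.0)
        assert compare_instruments(a, b).slope == pytest.approx(2.0)

    def test_mismatched_keys_raise_pairing_error(self):
        a, _ = self._pair(1.0)
        rows = [(5, c, 0, c) for c in (1.0, 5.0, 10.0)]
        b = build_dose_response(_table(rows), normalization="none")
        with pytest.raises(PairingError):
            compare_instruments(a, b)

    def test_noiseless_dual_channel_dose_responses_agree(self, tmatrix, curve):
        """End-to-end linear forward model: slope ~1, R^2 ~1 across channels."""
        assay, plan = preset_assay("hsa-fluorescent")
        ds = generate_dataset(plan, assay, tmatrix)
        rows = [dict(run=r.run, concentration=r.concentration,
                     replicate=r.replicate,
                     ggp=extract_measurement(r.trace, curve).intensity,
                     spec=extract_measurement(r.spectrum).intensity)
                for r in ds.records]
        df = pd.DataFrame(rows)
        ta = build_dose_response(df.rename(columns={"ggp": "intensity"}))
        tb = build_dose_response(df.rename(columns={"spec": "intensity"}))
        comp = compare_instruments(ta, tb)
        assert 0.97 <= comp.slope <= 1.03
        assert comp.r_squared >= 0.99


class TestMicpWavelengthCorrelation:
    def test_dye_series_correlates_micp_with_peak_wavelength(self, tmatrix,
                                                             curve):
        assay, plan = preset_assay("tamra")
        ds = generate_dataset(plan, assay, tmatrix)
        rows = [dict(micp_pixel=extract_measurement(r.trace, curve).micp_pixel,
                     peak_wavelength=extract_measurement(r.spectrum).peak_wavelength)
                for r in ds.select(run=0)]
        df = pd.DataFrame(rows)
        fit = correlate_micp_wavelength(df)
        assert fit.r_squared >= 0.99
        # slope (pixels/nm) tracks the local calibration slope within 10%
        local = (curve.wavelength_to_pixel(610.0)
                 - curve.wavelength_to_pixel(560.0)) / 50.0
        assert fit.slope == pytest.approx(local, rel=0.10)

    def test_constant_wavelengths_are_degenerate(self):
        df = pd.DataFrame({"micp_pixel": [2100, 2101, 2102],
                           "peak_wavelength": [600.0, 600.0, 600.0]})
        with pytest.raises(DegenerateRegressionError):
            correlate_micp_wavelength(df)
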