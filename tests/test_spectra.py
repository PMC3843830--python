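"""Spectrum container, I/O and transmittance-metric unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aviomt import (
    DEFAULT_GRID,
    Spectrum,
    average_spectra,
    cutoff_slopes,
    lambda_t50,
    normalize_to_range_max,
    process_omt,
    read_spectra_table,
    resample_linear,
    retinal_uv_fraction,
    smooth_running_average,
    wavelength_at_level,
)

from conftest import logistic_spectrum


class TestSpectrumInvariants:
    def test_rejects_decreasing_wavelengths(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(np.array([400.0, 300.0]), np.array([0.1, 0.2]))

    def test_rejects_negative_and_nonfinite_values(self):
        wl = np.array([300.0, 400.0])
        with pytest.raises(ValueError):
            Spectrum(wl, np.array([-0.1, 0.2]))
        with pytest.raises(ValueError):
            Spectrum(wl, np.array([np.nan, 0.2]))

    def test_rejects_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            Spectrum(np.array([300.0, 400.0]), np.array([0.1, 0.2]), kind="absorbance")


class TestReadSpectraTable:
    def test_two_column_wide(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,T\n300,0.1\n301,0.2\n302,0.3\n")
        (s,) = read_spectra_table(p, layout="wide")
        assert len(s) == 3
        assert s.name == "T"
        np.testing.assert_allclose(s.values, [0.1, 0.2, 0.3])

    def test_wide_three_value_columns(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,a,b,c\n300,1,2,3\n310,4,5,6\n")
        out = read_spectra_table(p)
        assert [s.name for s in out] == ["a", "b", "c"]

    def test_descending_input_reordered_consistently(self, tmp_path):
        rng = np.random.default_rng(7)
        wl = np.arange(300.0, 340.0)
        vals = rng.uniform(0.1, 1.0, wl.size)
        asc, desc = tmp_path / "asc.csv", tmp_path / "desc.csv"
        asc.write_text("wavelength_nm,T\n" + "\n".join(
            f"{w},{v}" for w, v in zip(wl, vals)))
        desc.write_text("wavelength_nm,T\n" + "\n".join(
            f"{w},{v}" for w, v in zip(wl[::-1], vals[::-1])))
        (s1,), (s2,) = read_spectra_table(asc), read_spectra_table(desc)
        np.testing.assert_array_equal(s1.wavelengths, s2.wavelengths)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_duplicate_wavelengths_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,T\n300,0.1\n300,0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra_table(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,T\n300,0.1\n301,oops\n")
        with pytest.raises(ValueError, match="row 1"):
            read_spectra_table(p)

    def test_long_layout(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("series,wavelength_nm,value\nx,300,0.1\nx,301,0.2\ny,300,0.5\n")
        out = read_spectra_table(p, layout="long")
        assert [s.name for s in out] == ["x", "y"]
        assert len(out[0]) == 2 and len(out[1]) == 1

    def test_percent_input_scaled(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("wavelength_nm,T\n300,50\n301,100\n")
        (s,) = read_spectra_table(p, percent=True)
        np.testing.assert_allclose(s.values, [0.5, 1.0])


class TestResampleLinear:
    def test_identity_on_same_grid(self):
        s = logistic_spectrum()
        out = resample_linear(s, s.wavelengths)
        np.testing.assert_array_equal(out.values, s.values)

    def test_midpoint(self):
        s = Spectrum(np.array([300.0, 400.0]), np.array([0.0, 1.0]))
        out = resample_linear(s, np.array([350.0]))
        assert out.values[0] == pytest.approx(0.5)

    def test_matches_two_point_interpolation_oracle(self):
        rng = np.random.default_rng(3)
        wl = np.sort(rng.uniform(300, 700, 40))
        wl[0], wl[-1] = 300.0, 700.0
        vals = rng.uniform(0, 1, 40)
        s = Spectrum(wl, vals)
        grid = np.sort(rng.uniform(300, 700, 200))
        out = resample_linear(s, grid)
        # brute-force two-point interpolation, one grid point at a time
        for g, v in zip(grid, out.values):
            j = np.searchsorted(wl, g)
            if wl[min(j, len(wl) - 1)] == g:
                expected = vals[j]
            else:
                w0, w1, v0, v1 = wl[j - 1], wl[j], vals[j - 1], vals[j]
                expected = v0 + (v1 - v0) * (g - w0) / (w1 - w0)
            assert v == pytest.approx(expected, abs=1e-12)

    def test_no_extrapolation(self):
        s = Spectrum(np.array([310.0, 400.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="extrapolation"):
            resample_linear(s, np.array([300.0, 350.0]))


class TestSmoothRunningAverage:
    def test_constant_unchanged(self):
        s = Spectrum(DEFAULT_GRID, np.full(DEFAULT_GRID.size, 0.4))
        out = smooth_running_average(s, 11)
        np.testing.assert_allclose(out.values, 0.4)

    def test_unit_impulse_spreads_to_window(self):
        vals = np.zeros(101)
        vals[50] = 1.0
        s = Spectrum(np.arange(300.0, 401.0), vals)
        out = smooth_running_average(s, 11)
        inner = out.values[45:56]
        np.testing.assert_allclose(inner, 1.0 / 11.0)
        assert out.values[:40].sum() == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 1, 60)
        s = Spectrum(np.arange(300.0, 360.0), vals)
        out = smooth_running_average(s, 7)
        for i in range(60):
            r = min(3, i, 59 - i)
            assert out.values[i] == pytest.approx(vals[i - r:i + r + 1].mean())

    def test_even_window_rejected(self):
        s = logistic_spectrum()
        with pytest.raises(ValueError, match="odd"):
            smooth_running_average(s, 10)


class TestNormalize:
    def test_in_range_max_becomes_one(self):
        wl = np.arange(300.0, 701.0)
        vals = 0.8 * np.exp(-0.5 * ((wl - 650.0) / 60.0) ** 2)
        out = normalize_to_range_max(Spectrum(wl, vals))
        assert out.values[wl == 650.0][0] == pytest.approx(1.0)

    def test_idempotent(self):
        s = normalize_to_range_max(logistic_spectrum())
        out = normalize_to_range_max(s)
        np.testing.assert_allclose(out.values, s.values)

    def test_global_max_outside_range(self):
        # in-range max at 700 is 0.5, global max 1.0 sits at 750 nm
        wl = np.arange(300.0, 801.0)
        vals = (wl - 300.0) / 900.0
        vals[wl > 700] = np.linspace(0.5, 1.0, (wl > 700).sum())
        out = normalize_to_range_max(Spectrum(wl, vals))
        in_range = (wl >= 300) & (wl <= 700)
        expected = vals / vals[in_range].max()
        np.testing.assert_allclose(out.values, expected)
        assert out.values[in_range].max() == pytest.approx(1.0)
        assert out.values.max() > 1.0

    def test_zero_max_rejected(self):
        s = Spectrum(np.arange(300.0, 310.0), np.zeros(10))
        with pytest.raises(ValueError):
            normalize_to_range_max(s)


class TestAverageSpectra:
    def test_single_spectrum(self):
        s = logistic_spectrum()
        mean, sd = average_spectra([s])
        np.testing.assert_array_equal(mean.values, s.values)
        np.testing.assert_array_equal(sd.values, 0.0)

    def test_two_constant_spectra(self, grid):
        a = Spectrum(grid, np.full(grid.size, 0.2))
        b = Spectrum(grid, np.full(grid.size, 0.4))
        mean, sd = average_spectra([a, b])
        np.testing.assert_allclose(mean.values, 0.3)
        np.testing.assert_allclose(sd.values, np.sqrt(0.02) / np.sqrt(2) * np.sqrt(2))
        np.testing.assert_allclose(sd.values, 0.1414, atol=1e-3)

    def test_matches_loop_oracle(self, grid):
        rng = np.random.default_rng(5)
        stack = rng.uniform(0, 1, (5, grid.size))
        spectra = [Spectrum(grid, row) for row in stack]
        mean, sd = average_spectra(spectra)
        for j in range(0, grid.size, 37):
            col = stack[:, j]
            assert mean.values[j] == pytest.approx(col.mean())
            assert sd.values[j] == pytest.approx(col.std(ddof=1))

    def test_mismatched_grids_rejected(self):
        a = Spectrum(np.arange(300.0, 400.0), np.ones(100))
        b = Spectrum(np.arange(301.0, 401.0), np.ones(100))
        with pytest.raises(ValueError, match="grid"):
            average_spectra([a, b])


class TestWavelengthAtLevel:
    def test_linear_ramp(self):
        wl = np.arange(300.0, 401.0)
        s = Spectrum(wl, (wl - 300.0) / 100.0)
        assert wavelength_at_level(s, 0.5) == pytest.approx(350.0)

    def test_logistic_midpoint(self):
        s = logistic_spectrum(lambda50=350.0, scale=5.0)
        assert wavelength_at_level(s, 0.5) == pytest.approx(350.0, abs=0.01)

    def test_noisy_sigmoid_pipeline_vs_dense_oracle(self):
        # full pipeline (smooth + normalize) vs a 0.001 nm brute-force
        # crossing search on the same smoothed curve
        rng = np.random.default_rng(42)
        wl = DEFAULT_GRID
        vals = 1.0 / (1.0 + np.exp(-(wl - 340.0) / 6.0)) + rng.normal(0, 0.004, wl.size)
        s = normalize_to_range_max(
            smooth_running_average(Spectrum(wl, np.clip(vals, 0, None)), 11))
        measured = wavelength_at_level(s, 0.5)
        dense = np.arange(300.0, 700.0, 0.001)
        dvals = np.interp(dense, s.wavelengths, s.values)
        imax = np.argmax(dvals)
        below = np.flatnonzero(dvals[:imax] < 0.5)
        oracle = dense[below[-1]] if below.size else dense[0]
        assert measured == pytest.approx(oracle, abs=0.1)

    def test_level_not_attained(self):
        s = Spectrum(np.arange(300.0, 400.0), np.full(100, 0.8))
        with pytest.raises(ValueError, match="not attained"):
            wavelength_at_level(s, 0.5)

    @given(st.lists(st.integers(5, 95), min_size=2, max_size=6, unique=True))
    @settings(deadline=None, max_examples=25)
    def test_monotone_in_level_for_monotone_spectrum(self, percent_levels):
        s = logistic_spectrum(lambda50=360.0, scale=8.0)
        crossings = [wavelength_at_level(s, k / 100.0)
                     for k in sorted(percent_levels)]
        assert all(a < b for a, b in zip(crossings, crossings[1:]))

    def test_scale_invariance_of_pipeline(self):
        rng = np.random.default_rng(9)
        wl = DEFAULT_GRID
        raw = 0.73 / (1.0 + np.exp(-(wl - 345.0) / 7.0)) + rng.normal(0, 0.003, wl.size)
        raw = np.clip(raw, 0, None)
        def pipeline(v):
            s = Spectrum(wl, v)
            return lambda_t50(normalize_to_range_max(smooth_running_average(s, 11)))
        assert pipeline(raw) == pytest.approx(pipeline(raw * 17.3), abs=1e-9)


class TestCutoffSlopes:
    def test_linear_ramp_constant_slope(self):
        wl = np.arange(300.0, 401.0)
        s = Spectrum(wl, (wl - 300.0) / 100.0)
        slopes = cutoff_slopes(s)
        assert slopes.size == 20
        np.testing.assert_allclose(slopes, 0.01)

    def test_returns_twenty_intervals(self):
        s = logistic_spectrum(lambda50=350.0, scale=5.0)
        assert cutoff_slopes(s).size == 20

    def test_logistic_slope_peaks_at_half_transmittance(self):
        s = logistic_spectrum(lambda50=350.0, scale=5.0)
        slopes = cutoff_slopes(s)
        finite = np.flatnonzero(np.isfinite(slopes[:-1]))  # last interval has 0 width
        # analytic logistic derivative is maximal at T = 0.5 (intervals 9 and 10)
        peak_interval = finite[np.argmax(slopes[finite])]
        assert peak_interval in (9, 10)

    def test_slopes_integrate_back_to_cutoff_width(self):
        wl = np.arange(300.0, 401.0)
        s = Spectrum(wl, (wl - 300.0) / 100.0)
        slopes = cutoff_slopes(s)
        assert np.nansum(0.05 / slopes) == pytest.approx(100.0)

    def test_requires_normalized_input(self):
        s = logistic_spectrum(plateau=0.5)
        with pytest.raises(ValueError, match="normalized"):
            cutoff_slopes(s)


class TestRetinalUvFraction:
    def test_fully_transparent(self, grid, d65):
        t = Spectrum(grid, np.ones(grid.size))
        assert retinal_uv_fraction(t, d65) == pytest.approx(1.0)

    def test_uv_opaque(self, grid, d65):
        vals = np.where(grid <= 400.0, 0.0, 1.0)
        t = Spectrum(grid, vals)
        assert retinal_uv_fraction(t, d65) == pytest.approx(0.0, abs=1e-12)

    def test_logistic_vs_fine_grid_oracle(self, grid):
        flat = Spectrum(grid, np.ones(grid.size), kind="illuminant-photon")
        t = logistic_spectrum(lambda50=350.0, scale=5.0)
        got = retinal_uv_fraction(t, flat)
        fine = np.arange(300.0, 400.0001, 0.01)
        tv = 1.0 / (1.0 + np.exp(-(fine - 350.0) / 5.0))
        oracle = np.trapezoid(tv, fine) / (fine[-1] - fine[0])
        assert got == pytest.approx(oracle, abs=1e-4)

    def test_decreasing_in_lambda_t50(self, d65):
        fractions = [retinal_uv_fraction(logistic_spectrum(l50, 8.0), d65)
                     for l50 in (320.0, 340.0, 360.0, 380.0)]
        assert all(a > b for a, b in zip(fractions, fractions[1:]))

    def test_grid_mismatch_rejected(self, d65):
        t = Spectrum(np.arange(310.0, 500.0), np.ones(190))
        with pytest.raises(ValueError, match="grid"):
            retinal_uv_fraction(t, d65)


def test_process_omt_recovers_logistic_midpoint():
    raw = logistic_spectrum(lambda50=350.0, scale=5.0)
    assert lambda_t50(process_omt(raw)) == pytest.approx(350.0, abs=0.1)
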