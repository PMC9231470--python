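"""Spectrum container, file round trips and preprocessing contracts."""

import numpy as np
import pytest

from pyrotrace import (
    PreprocessRecipe,
    Spectrum,
    estimate_noise,
    preprocess,
    read_spectrum,
    write_spectrum,
)
from pyrotrace.exceptions import InputError, SpectrumDataError, SpectrumParseError
from pyrotrace.spectra import make_grid


class TestSpectrum:
    def test_basic_invariants_enforced(self):
        with pytest.raises(SpectrumDataError):
            Spectrum([1.0, 2.0], [0.0])
        with pytest.raises(SpectrumDataError):
            Spectrum([2.0, 1.0], [0.0, 0.0])
        with pytest.raises(SpectrumDataError):
            Spectrum([1.0, 2.0], [0.0, np.nan])

    def test_crop_outside_axis_fails(self):
        sp = Spectrum(np.arange(10.0), np.zeros(10))
        with pytest.raises(InputError):
            sp.crop(100.0, 200.0)


class TestReadWrite:
    def test_csv_two_rows(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("400,0.1\n404,0.2\n")
        sp = read_spectrum(path)
        assert len(sp) == 2
        assert sp.intensities[1] == pytest.approx(0.2)

    def test_csv_header_skipped(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("wavenumber_cm1,intensity\n400,0.1\n404,0.2\n")
        assert len(read_spectrum(path)) == 2

    def test_jcamp_descending_axis_reversed(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=t\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n"
            "##XYDATA=(XY..XY)\n500, 1.0\n498, 2.0\n496, 3.0\n##END=\n"
        )
        sp = read_spectrum(path)
        assert np.all(np.diff(sp.wavenumbers) > 0)
        assert sp.intensities.tolist() == [3.0, 2.0, 1.0]

    def test_jcamp_xpp_block(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=t\n##DATA TYPE=INFRARED SPECTRUM\n##FIRSTX=400\n##LASTX=412\n"
            "##NPOINTS=4\n##XYDATA=(X++(Y..Y))\n400 1 2 3 4\n##END=\n"
        )
        sp = read_spectrum(path)
        assert sp.kind == "ftir_absorbance"
        assert sp.wavenumbers.tolist() == [400.0, 404.0, 408.0, 412.0]
        assert sp.intensities.tolist() == [1.0, 2.0, 3.0, 4.0]

    @pytest.mark.parametrize("fmt", ["csv", "jcampdx"])
    def test_round_trip(self, tmp_path, fmt, rng):
        x = make_grid(400.0, 1000.0, 4.0)
        y = rng.normal(size=x.size)
        sp = Spectrum(x, y, kind="ftir_absorbance", meta={"sample_id": "rt"})
        ext = ".csv" if fmt == "csv" else ".jdx"
        path = tmp_path / f"rt{ext}"
        write_spectrum(sp, path, format=fmt)
        back = read_spectrum(path, format=fmt)
        np.testing.assert_allclose(back.wavenumbers, x, rtol=1e-9)
        np.testing.assert_allclose(back.intensities, y, rtol=1e-9, atol=1e-9)

    def test_malformed_file_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("400,0.1\nnope,zzz\n")
        with pytest.raises(SpectrumParseError, match="line 2"):
            read_spectrum(path)


class TestPreprocess:
    def test_constant_spectrum_zero_after_baseline(self):
        grid = make_grid(200.0, 1800.0, 2.0)
        sp = Spectrum(grid, np.full(grid.size, 5.0))
        for baseline in ("als", "rolling_min"):
            out = preprocess(
                sp, PreprocessRecipe(baseline=baseline, normalization="none")
            )
            assert np.max(np.abs(out.intensities)) < 1e-6

    def test_max_normalization_invariant(self):
        grid = make_grid(200.0, 1800.0, 2.0)
        y = np.exp(-0.5 * ((grid - 800.0) / 20.0) ** 2)
        out = preprocess(Spectrum(grid, y), PreprocessRecipe(baseline="none"))
        assert out.intensities.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("norm,check", [
        ("area", lambda out: np.trapezoid(np.abs(out.intensities), out.wavenumbers)),
        ("vector", lambda out: np.linalg.norm(out.intensities)),
    ])
    def test_other_normalizations_exact(self, norm, check):
        grid = make_grid(200.0, 1800.0, 2.0)
        y = np.exp(-0.5 * ((grid - 800.0) / 20.0) ** 2)
        out = preprocess(
            Spectrum(grid, y), PreprocessRecipe(baseline="none", normalization=norm)
        )
        assert check(out) == pytest.approx(1.0)

    @pytest.mark.parametrize("norm", ["max", "area", "vector", "none"])
    def test_grid_idempotence(self, rng, norm):
        """Regridding plus normalization is a projection: applying the
        recipe to its own output changes nothing.  (Baseline fitting is
        excluded: iterated asymmetric least squares keeps chasing the
        lower noise envelope, which is inherent to the method.)"""
        grid = make_grid(150.0, 1900.0, 1.0)
        y = rng.normal(1.0, 0.1, size=grid.size)
        recipe = PreprocessRecipe(baseline="none", normalization=norm)
        once = preprocess(Spectrum(grid, y), recipe)
        twice = preprocess(once, recipe)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-9)

    def test_peak_area_recovered_on_linear_baseline(self):
        """ALS removal of a known linear baseline keeps the peak area."""
        grid = make_grid(200.0, 1800.0, 2.0)
        sigma = 12.0
        peak = 2.0 * np.exp(-0.5 * ((grid - 1000.0) / sigma) ** 2)
        baseline = 0.5 + 3e-4 * grid
        out = preprocess(
            Spectrum(grid, peak + baseline),
            # stiff smoothing penalty: the peak is broad (FWHM ~28 cm-1)
            # and a soft baseline would sag into it
            PreprocessRecipe(baseline="als", als_lam=1e7, normalization="none"),
        )
        window = (grid > 1000.0 - 6 * sigma) & (grid < 1000.0 + 6 * sigma)
        area = np.trapezoid(out.intensities[window], grid[window])
        truth = 2.0 * sigma * np.sqrt(2.0 * np.pi)
        assert area == pytest.approx(truth, rel=0.02)

    def test_coverage_gap_rejected(self):
        grid = make_grid(400.0, 1200.0, 2.0)
        sp = Spectrum(grid, np.zeros(grid.size))
        with pytest.raises(InputError, match="cm-1"):
            preprocess(sp, PreprocessRecipe())


class TestNormalizationProperty:
    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 2**31 - 1), norm=st.sampled_from(["max", "area", "vector"]))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_normalization_holds_for_random_spectra(self, seed, norm):
        """The declared normalization invariant holds exactly on every
        output, whatever the input spectrum."""
        r = np.random.default_rng(seed)
        grid = make_grid(200.0, 1800.0, 8.0)
        y = r.normal(1.0, 0.3, size=grid.size) + r.uniform(0.5, 3.0) * np.exp(
            -0.5 * ((grid - r.uniform(400, 1600)) / r.uniform(10, 60)) ** 2
        )
        out = preprocess(
            Spectrum(grid, y),
            PreprocessRecipe(target_grid=(200.0, 1800.0, 8.0), baseline="als",
                             normalization=norm),
        )
        if norm == "max":
            assert np.max(np.abs(out.intensities)) == pytest.approx(1.0, abs=1e-12)
        elif norm == "area":
            assert np.trapezoid(np.abs(out.intensities), out.wavenumbers) == pytest.approx(
                1.0, abs=1e-9)
        else:
            assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)


class TestEstimateNoise:
    def test_flat_window_zero(self):
        grid = make_grid(200.0, 1800.0, 2.0)
        sp = Spectrum(grid, np.ones(grid.size))
        assert estimate_noise(sp, (1650.0, 1800.0)) == 0.0

    def test_injected_sd_recovered(self, rng):
        grid = np.arange(500.0)
        sp = Spectrum(grid, rng.normal(0.0, 0.01, size=500))
        est = estimate_noise(sp, (0.0, 499.0))
        assert est == pytest.approx(0.01, rel=0.15)

    def test_peak_in_window_bounded_after_detrend(self, rng):
        grid = np.arange(500.0)
        y = rng.normal(0.0, 0.01, size=500) + np.exp(-0.5 * ((grid - 250) / 15.0) ** 2)
        est = estimate_noise(Spectrum(grid, y), (0.0, 499.0))
        assert est <= 2 * 0.01

    def test_too_few_points_rejected(self):
        sp = Spectrum(np.arange(30.0), np.zeros(30))
        with pytest.raises(InputError):
            estimate_noise(sp, (0.0, 10.0))
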