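"""Spectrum/series containers and plain-text I/O contracts."""

import numpy as np
import pytest

from lframan import spectra_io as sio
from lframan.exceptions import (
    DegenerateDataError,
    ExtrapolationError,
    GridError,
    OrderingError,
    ParseError,
)


def _spectrum(n=20, seed=0, **meta):
    rng = np.random.default_rng(seed)
    wn = np.sort(rng.uniform(5, 200, n))
    return sio.Spectrum(wn, rng.normal(10, 3, n), **meta)


class TestSpectrum:
    def test_rejects_short_and_unordered(self):
        with pytest.raises(DegenerateDataError):
            sio.Spectrum(np.arange(5.0), np.arange(5.0))
        wn = np.array([1.0, 2, 3, 3, 4, 5, 6, 7])
        with pytest.raises(OrderingError):
            sio.Spectrum(wn, np.ones(8))

    def test_nonraw_requires_temperature(self):
        from lframan.exceptions import MetadataError

        with pytest.raises(MetadataError):
            _spectrum(representation="reduced")
        _spectrum(representation="reduced", temperature=300.0)  # fine


class TestReadWrite:
    def test_round_trip_lossless(self, tmp_path):
        spec = _spectrum(
            50, representation="raw", temperature=296.15, time=12.5, rh=20.0,
            label="round trip",
        )
        path = tmp_path / "s.txt"
        sio.write_spectrum(spec, path)
        back = sio.read_spectrum(path)
        np.testing.assert_allclose(back.wavenumbers, spec.wavenumbers, rtol=1e-12)
        np.testing.assert_allclose(back.intensities, spec.intensities, rtol=1e-12)
        assert back.representation == spec.representation
        assert back.temperature == spec.temperature
        assert back.time == spec.time
        assert back.rh == spec.rh
        assert back.label == spec.label

    @pytest.mark.parametrize("delim", [" ", ",", ";"])
    def test_delimiters(self, tmp_path, delim):
        path = tmp_path / "s.txt"
        rows = [(10.0 + i, 5.0 + i) for i in range(10)]
        path.write_text("\n".join(f"{w}{delim}{i}" for w, i in rows))
        spec = sio.read_spectrum(path)
        np.testing.assert_array_equal(spec.wavenumbers, [r[0] for r in rows])
        np.testing.assert_array_equal(spec.intensities, [r[1] for r in rows])
        assert spec.representation == "raw"

    def test_descending_order_sorted(self, tmp_path):
        path = tmp_path / "desc.txt"
        path.write_text("\n".join(f"{w} {w * 2.0}" for w in range(20, 10, -1)))
        spec = sio.read_spectrum(path)
        assert np.all(np.diff(spec.wavenumbers) > 0)
        np.testing.assert_array_equal(spec.intensities, spec.wavenumbers * 2.0)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        lines = [f"{w} 1.0" for w in range(10, 20)]
        lines[4] = "12.5 banana"
        path.write_text("\n".join(lines))
        with pytest.raises(ParseError, match="line 5"):
            sio.read_spectrum(path)

    def test_too_few_points(self, tmp_path):
        path = tmp_path / "tiny.txt"
        path.write_text("1 1\n2 2\n3 3\n")
        with pytest.raises(DegenerateDataError):
            sio.read_spectrum(path)


def _write_series_files(tmp_path, times, grids=None):
    grids = grids or [np.arange(5.0, 25.0)] * len(times)
    names = []
    for i, g in enumerate(grids):
        p = tmp_path / f"f{i}.txt"
        sio.write_spectrum(sio.Spectrum(g, np.ones_like(g)), p)
        names.append(p.name)
    lines = ["file,time_min"] + [f"{n},{t}" for n, t in zip(names, times)]
    manifest = tmp_path / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


class TestSeries:
    def test_time_axis(self, tmp_path):
        manifest = _write_series_files(tmp_path, [0.0, 10.0, 20.0])
        series = sio.read_series(manifest)
        assert series.axis == "time"
        np.testing.assert_array_equal(series.axis_values, [0, 10, 20])

    def test_duplicate_time_rejected(self, tmp_path):
        manifest = _write_series_files(tmp_path, [0.0, 10.0, 10.0])
        with pytest.raises(OrderingError):
            sio.read_series(manifest)

    def test_temperature_axis_converted_to_kelvin(self, tmp_path):
        g = np.arange(5.0, 25.0)
        names = []
        for i in range(4):
            p = tmp_path / f"f{i}.txt"
            sio.write_spectrum(sio.Spectrum(g, np.ones_like(g)), p)
            names.append(p.name)
        temps_c = [23, 30, 35, 40]
        lines = ["file,temperature_C"] + [f"{n},{t}" for n, t in zip(names, temps_c)]
        manifest = tmp_path / "m.csv"
        manifest.write_text("\n".join(lines) + "\n")
        series = sio.read_series(manifest)
        assert series.axis == "temperature"
        np.testing.assert_allclose(
            series.axis_values, [296.15, 303.15, 308.15, 313.15]
        )

    def test_mismatched_grids_rejected(self, tmp_path):
        grids = [np.arange(5.0, 25.0), np.arange(5.5, 25.5)]
        manifest = _write_series_files(tmp_path, [0.0, 10.0], grids)
        with pytest.raises(GridError, match="resample"):
            sio.read_series(manifest)

    def test_reading_is_stable(self, tmp_path):
        manifest = _write_series_files(tmp_path, [0.0, 5.0, 9.0])
        s1 = sio.read_series(manifest)
        s2 = sio.read_series(manifest)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.wavenumbers, b.wavenumbers)
            np.testing.assert_array_equal(a.intensities, b.intensities)


class TestResample:
    def _series_of(self, func, grid):
        specs = [
            sio.Spectrum(grid, func(grid), time=float(t)) for t in range(3)
        ]
        return sio.SpectrumSeries(specs, axis="time")

    def test_identity_on_same_grid(self):
        grid = np.arange(5.0, 50.0)
        series = self._series_of(lambda w: w**2, grid)
        out = sio.resample_common_grid(series, grid)
        for s_in, s_out in zip(series, out):
            np.testing.assert_array_equal(s_in.intensities, s_out.intensities)
            assert s_out.time == s_in.time

    def test_linear_data_exact_anywhere(self):
        grid = np.arange(5.0, 50.0)
        series = self._series_of(lambda w: 2.0 * w, grid)
        target = np.linspace(6.3, 48.7, 37)
        out = sio.resample_common_grid(series, target)
        for s in out:
            np.testing.assert_allclose(s.intensities, 2.0 * target, rtol=1e-14)

    def test_gaussian_interpolation_error_bound(self):
        # grid step = FWHM/10 -> linear interpolation error < 1% of height
        fwhm, height, center = 10.0, 3.0, 80.0
        step = fwhm / 10.0
        grid = np.arange(40.0, 120.0 + step / 2, step)

        def gauss(w):
            return height * np.exp(-4 * np.log(2) * (w - center) ** 2 / fwhm**2)

        series = self._series_of(gauss, grid)
        dense = np.arange(grid[0], grid[-1] + step / 4, step / 2.0)
        out = sio.resample_common_grid(series, dense)
        err = np.max(np.abs(out.spectra[0].intensities - gauss(dense)))
        assert err < height * 1e-2

    def test_extrapolation_refused(self):
        grid = np.arange(5.0, 50.0)
        series = self._series_of(lambda w: w, grid)
        with pytest.raises(ExtrapolationError):
            sio.resample_common_grid(series, np.arange(4.0, 30.0))
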