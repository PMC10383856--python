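"""Transformation-rate estimators, half-time and master curves."""

import numpy as np
import pytest

from lframan import synthetic_data as sd
from lframan import transform_rate as tr
from lframan.decompose import PhononPeak, QESComponent
from lframan.exceptions import (
    DegenerateDataError,
    IncompleteTransformationError,
    NoContrastError,
)
from lframan.kinetics import model_rho
from lframan.spectra_io import Spectrum, SpectrumSeries


def _refs(grid):
    h = sd.make_endmember(sd.tp_hydrate(), grid)
    a = sd.make_endmember(sd.tp_anhydrate(), grid)
    return h, a


def _mixture_series(grid, rho_star, noise=0.0, seed=0):
    h, a = _refs(grid)
    rng = np.random.default_rng(seed)
    scale = max(h.intensities.max(), a.intensities.max())
    spectra = []
    for i, r in enumerate(rho_star):
        y = (1 - r) * h.intensities + r * a.intensities
        if noise:
            y = y + rng.normal(0, noise * scale, grid.size)
        spectra.append(
            Spectrum(grid, y, representation="susceptibility",
                     temperature=296.15, time=float(i))
        )
    return SpectrumSeries(spectra, axis="time"), h, a


class TestUnmix:
    def test_exact_mixture_recovery(self, grid):
        rho_star = np.array([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0])
        series, h, a = _mixture_series(grid, rho_star)
        curve = tr.transformation_rate_unmix(series, h, a)
        np.testing.assert_allclose(curve.rho, rho_star, atol=1e-10)

    def test_pure_endmembers(self, grid):
        series, h, a = _mixture_series(grid, [0.0] * 8)
        np.testing.assert_allclose(
            tr.transformation_rate_unmix(series, h, a).rho, 0.0, atol=1e-12
        )
        series, h, a = _mixture_series(grid, [1.0] * 8)
        np.testing.assert_allclose(
            tr.transformation_rate_unmix(series, h, a).rho, 1.0, atol=1e-12
        )

    def test_noisy_rmse_bound(self, grid):
        # 1% additive noise: RMSE(rho) < 0.02 pooled over 100 seeds
        rho_star = np.linspace(0.0, 1.0, 12)
        sq_errs = []
        for seed in range(100):
            series, h, a = _mixture_series(grid, rho_star, noise=0.01, seed=seed)
            curve = tr.transformation_rate_unmix(series, h, a)
            sq_errs.append((curve.rho - rho_star) ** 2)
        assert np.sqrt(np.mean(sq_errs)) < 0.02

    def test_scale_invariance(self, grid):
        rho_star = np.linspace(0.05, 0.95, 10)
        series, h, a = _mixture_series(grid, rho_star)
        scaled = series.map(
            lambda s: s.replace(intensities=s.intensities * 31.7)
        )
        c1 = tr.transformation_rate_unmix(series, h, a)
        c2 = tr.transformation_rate_unmix(scaled, h, a)
        np.testing.assert_allclose(c1.rho, c2.rho, atol=1e-12)

    def test_monotone_truth_gives_monotone_estimate_up_to_noise(self, grid):
        from sklearn.isotonic import IsotonicRegression

        rho_star = model_rho("avrami", np.log(2) / 50.0**2, np.linspace(1, 150, 40), n=2)
        devs = []
        for seed in range(20):
            series, h, a = _mixture_series(grid, rho_star, noise=0.01, seed=seed)
            rho = tr.transformation_rate_unmix(series, h, a).rho
            iso = IsotonicRegression().fit_transform(np.arange(rho.size), rho)
            devs.append(np.sqrt(np.mean((rho - iso) ** 2)))
        # isotonic deviation bounded by the per-point noise level on rho
        assert np.mean(devs) < 0.01


class TestBand:
    def test_linear_band_decay_gives_linear_rho(self, grid):
        rho_star = np.linspace(0.0, 1.0, 9)
        series, _, _ = _mixture_series(grid, rho_star)
        curve = tr.transformation_rate_band(series)
        np.testing.assert_allclose(curve.rho, rho_star, atol=1e-10)
        np.testing.assert_allclose(curve.water_escape, 1 - rho_star, atol=1e-10)

    def test_anchoring_first_zero_last_one(self, grid):
        rho_star = model_rho("avrami", np.log(2) / 30.0, np.geomspace(1, 300, 20), n=1)
        series, _, _ = _mixture_series(grid, rho_star)
        curve = tr.transformation_rate_band(series)
        assert curve.rho[0] == 0.0
        assert curve.rho[-1] == 1.0

    def test_avrami_driven_decay_matches_law(self, grid):
        t = np.geomspace(2, 400, 30)
        rho_star = model_rho("avrami", np.log(2) / 100.0**2, t, n=2)
        h, a = _refs(grid)
        spectra = [
            Spectrum(grid, (1 - r) * h.intensities + r * a.intensities,
                     representation="susceptibility", temperature=296.15,
                     time=float(tt))
            for tt, r in zip(t, rho_star)
        ]
        curve = tr.transformation_rate_band(SpectrumSeries(spectra, axis="time"))
        # anchored estimator rescales truth between its endpoint values
        expected = (rho_star - rho_star[0]) / (rho_star[-1] - rho_star[0])
        assert np.max(np.abs(curve.rho - np.clip(expected, 0, 1))) < 1e-10

    def test_no_contrast_error(self, grid):
        series, _, _ = _mixture_series(grid, [0.5] * 8)
        with pytest.raises(NoContrastError):
            tr.transformation_rate_band(series)

    def test_agrees_with_unmix_when_water_band_is_only_difference(self, grid):
        base = [PhononPeak(32.0, 1.0, 8.0, 0.4), PhononPeak(112.0, 0.7, 14.0, 0.4)]
        hyd = sd.EndmemberSpec("h", phonon_peaks=base + [PhononPeak(80.0, 2.0, 12.0, 0.5)],
                               qes=QESComponent(0.4, 9.0))
        anh = sd.EndmemberSpec("a", phonon_peaks=list(base), qes=QESComponent(0.4, 9.0))
        h = sd.make_endmember(hyd, grid)
        a = sd.make_endmember(anh, grid)
        rho_star = np.linspace(0.0, 1.0, 11)
        spectra = [
            Spectrum(grid, (1 - r) * h.intensities + r * a.intensities,
                     representation="susceptibility", temperature=296.15, time=float(i))
            for i, r in enumerate(rho_star)
        ]
        series = SpectrumSeries(spectra, axis="time")
        c_unmix = tr.transformation_rate_unmix(series, h, a)
        c_band = tr.transformation_rate_band(series)
        assert np.sqrt(np.mean((c_unmix.rho - c_band.rho) ** 2)) < 0.02


class TestHalfTime:
    def test_midpoint_interpolation(self):
        curve = tr.TransformationCurve(
            times=[10.0, 20.0], rho=[0.4, 0.6]
        )
        assert tr.half_time(curve) == pytest.approx(15.0)

    def test_exact_half_sample(self):
        curve = tr.TransformationCurve(times=[5.0, 7.0, 9.0], rho=[0.2, 0.5, 0.8])
        assert tr.half_time(curve) == pytest.approx(7.0)

    @pytest.mark.parametrize("k,n", [(np.log(2) / 100.0, 1.0), (2e-6, 2.95)])
    def test_avrami_closed_form(self, k, n):
        t_half_true = (np.log(2) / k) ** (1.0 / n)
        t = np.geomspace(t_half_true / 20, t_half_true * 4, 200)
        curve = tr.TransformationCurve(times=t, rho=model_rho("avrami", k, t, n=n))
        assert tr.half_time(curve) == pytest.approx(t_half_true, rel=1e-3)

    def test_incomplete_transformation(self):
        curve = tr.TransformationCurve(times=[1.0, 2.0, 3.0], rho=[0.1, 0.2, 0.3])
        with pytest.raises(IncompleteTransformationError):
            tr.half_time(curve)


class TestMasterCurve:
    def _avrami_curve(self, k, n, t):
        return tr.TransformationCurve(times=t, rho=model_rho("avrami", k, t, n=n))

    def test_rate_constant_collapses_out(self):
        # same n, k differing x10 -> identical master curves
        n = 2.0
        k1 = np.log(2) / 100.0**n
        t1 = np.geomspace(5, 400, 120)
        m1 = tr.master_curve(self._avrami_curve(k1, n, t1))
        m2 = tr.master_curve(self._avrami_curve(10 * k1, n, t1 / 10.0 ** (1 / n)))
        common = np.linspace(0.1, 3.5, 200)
        r1 = np.interp(common, m1.times, m1.rho)
        r2 = np.interp(common, m2.times, m2.rho)
        assert np.max(np.abs(r1 - r2)) < 1e-10

    def test_different_exponents_do_not_collapse(self):
        t = np.geomspace(1, 500, 300)
        m1 = tr.master_curve(self._avrami_curve(np.log(2) / 80.0, 1.0, t))
        m3 = tr.master_curve(self._avrami_curve(np.log(2) / 80.0**3, 3.0, t))
        common = np.linspace(0.2, 3.0, 200)
        diff = np.abs(
            np.interp(common, m1.times, m1.rho) - np.interp(common, m3.times, m3.rho)
        )
        assert diff.max() > 0.1

    def test_half_at_rescaled_time_one(self):
        t = np.geomspace(2, 600, 80)
        m = tr.master_curve(self._avrami_curve(np.log(2) / 90.0, 1.0, t))
        assert np.interp(1.0, m.times, m.rho) == pytest.approx(0.5, abs=1e-3)


def test_degenerate_curve_inputs_rejected():
    with pytest.raises(DegenerateDataError):
        tr.TransformationCurve(times=[1.0, 1.0], rho=[0.1, 0.2])
    with pytest.raises(DegenerateDataError):
        tr.TransformationCurve(times=[1.0, 2.0], rho=[0.1, 1.2])
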