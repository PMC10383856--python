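"""Transformation-rate extraction from dehydration spectral series.

During isothermal dehydration the spectrum at time t is, to first order,
a linear mixture of the hydrate and anhydrate endmember spectra. Two
estimators of the transformed fraction ρ(t) are provided:

* **unmix** — non-negative least squares of each spectrum against the two
  endmember references, ρ = b/(a+b) where a, b are the hydrate and
  anhydrate abundances. Closure a+b = 1 is deliberately not enforced
  (overall scattering efficiency may drift); the ratio removes any
  uniform intensity scale.
* **band** — trapezoidal area of the water-marker band (default
  60-100 cm⁻¹, the band near 80 cm⁻¹ present only in hydrates),
  anchored to the first and last spectra:
  ρ(t) = (A₀ − A(t)) / (A₀ − A_∞). The normalized remaining band area
  (A(t) − A_∞)/(A₀ − A_∞) is reported as the water-escape trace — it
  starts at 1 and decays to 0 as structural water leaves the lattice.

Both report ρ clipped to [0,1]. Derived quantities: the time to half
transformation t_1/2 (first upward crossing of ρ = 0.5, linearly
interpolated) and the master curve ρ(t/t_1/2), which collapses curves
sharing one mechanism regardless of the rate constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .exceptions import (
    DegenerateDataError,
    GridError,
    IncompleteTransformationError,
    NoContrastError,
    RepresentationError,
)
from .spectra_io import Spectrum, SpectrumSeries

__all__ = [
    "TransformationCurve",
    "transformation_rate_unmix",
    "transformation_rate_band",
    "half_time",
    "master_curve",
]


@dataclass
class TransformationCurve:
    """Transformed fraction ρ against time, with optional water-escape trace."""

    times: np.ndarray
    rho: np.ndarray
    water_escape: np.ndarray | None = None
    method: str = "unmix"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.times.size != self.rho.size:
            raise DegenerateDataError("times and rho must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise DegenerateDataError("times must be strictly increasing")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise DegenerateDataError("rho must lie in [0, 1] (clip before constructing)")
        if self.water_escape is not None:
            self.water_escape = np.asarray(self.water_escape, dtype=float)
            if self.water_escape.size != self.times.size:
                raise DegenerateDataError("water_escape length must match times")

    def __len__(self) -> int:
        return self.times.size


def _common_grid_check(series: SpectrumSeries, *refs: Spectrum) -> None:
    grid = series.wavenumbers
    for r in refs:
        if r.wavenumbers.size != grid.size or not np.array_equal(r.wavenumbers, grid):
            raise GridError(
                "reference spectra must share the series wavenumber grid; "
                "use resample_common_grid"
            )
        if r.representation != series.spectra[0].representation:
            raise RepresentationError(
                f"reference representation {r.representation!r} differs from the "
                f"series representation {series.spectra[0].representation!r}"
            )


def transformation_rate_unmix(
    series: SpectrumSeries,
    ref_hydrate: Spectrum,
    ref_anhydrate: Spectrum,
) -> TransformationCurve:
    """Two-endmember non-negative unmixing of a dehydration series.

    Each spectrum I_t is fitted as a·S_h + b·S_a with a, b ≥ 0 (NNLS);
    ρ(t) = b/(a+b), clipped to [0,1]. Series and references must share a
    grid and representation.
    """
    _common_grid_check(series, ref_hydrate, ref_anhydrate)
    A = np.column_stack([ref_hydrate.intensities, ref_anhydrate.intensities])
    rho = np.empty(len(series))
    for i, s in enumerate(series):
        (a, b), _ = nnls(A, s.intensities)
        total = a + b
        if total <= 0:
            raise DegenerateDataError(
                f"spectrum {i}: zero abundance for both endmembers (empty spectrum?)"
            )
        rho[i] = b / total
    return TransformationCurve(
        times=series.axis_values,
        rho=np.clip(rho, 0.0, 1.0),
        water_escape=None,
        method="unmix",
    )


def transformation_rate_band(
    series: SpectrumSeries,
    band_window: tuple[float, float] = (60.0, 100.0),
) -> TransformationCurve:
    """Water-marker band-area tracking of a dehydration series.

    The trapezoidal band area A(t) over ``band_window`` is anchored to the
    first (A₀, pure hydrate) and last (A_∞, fully dehydrated) spectra:
    ρ = (A₀ − A)/(A₀ − A_∞), water_escape = (A − A_∞)/(A₀ − A_∞).
    """
    lo, hi = band_window
    grid = series.wavenumbers
    if lo < grid[0] or hi > grid[-1]:
        raise GridError(
            f"band window [{lo}, {hi}] outside the grid range "
            f"[{grid[0]}, {grid[-1]}]"
        )
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        raise DegenerateDataError("band window covers fewer than 2 grid points")
    omega = grid[mask]
    areas = np.array([np.trapezoid(s.intensities[mask], omega) for s in series])
    a0, a_inf = areas[0], areas[-1]
    if a0 == a_inf:
        raise NoContrastError(
            "first and last band areas are identical; no transformation contrast"
        )
    rho = (a0 - areas) / (a0 - a_inf)
    escape = (areas - a_inf) / (a0 - a_inf)
    return TransformationCurve(
        times=series.axis_values,
        rho=np.clip(rho, 0.0, 1.0),
        water_escape=np.clip(escape, 0.0, 1.0),
        method="band",
    )


def half_time(curve: TransformationCurve) -> float:
    """Time to half transformation t_1/2.

    Linear interpolation between the samples bracketing the FIRST upward
    crossing of ρ = 0.5; a sample exactly at 0.5 is returned as-is.
    """
    t = curve.times
    rho = curve.rho
    exact = np.nonzero(rho == 0.5)[0]
    crossings = np.nonzero((rho[:-1] < 0.5) & (rho[1:] > 0.5))[0]
    candidates = []
    if exact.size:
        candidates.append((exact[0], float(t[exact[0]])))
    if crossings.size:
        i = crossings[0]
        frac = (0.5 - rho[i]) / (rho[i + 1] - rho[i])
        candidates.append((i, float(t[i] + frac * (t[i + 1] - t[i]))))
    if not candidates:
        raise IncompleteTransformationError(
            f"rho never crosses 0.5 (max {rho.max():.3f}); transformation incomplete"
        )
    candidates.sort()
    return candidates[0][1]


def master_curve(curve: TransformationCurve) -> TransformationCurve:
    """Rescale the time axis by t_1/2: returns ρ against t/t_1/2.

    ρ values are unchanged; by construction the interpolated curve passes
    through ρ = 0.5 at rescaled time 1.
    """
    t_half = half_time(curve)
    return TransformationCurve(
        times=curve.times / t_half,
        rho=curve.rho.copy(),
        water_escape=None if curve.water_escape is None else curve.water_escape.copy(),
        method=curve.method,
    )
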