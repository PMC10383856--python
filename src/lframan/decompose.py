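"""Decomposition of low-frequency spectra into QES, VDOS and phonon parts.

In reduced intensity or susceptibility representation the low-frequency
spectrum of a disordered molecular solid is modeled as the sum of

* quasi-elastic scattering (QES): a Lorentzian centered at ω = 0,
  evaluated on the Stokes half ω > 0 —
  L(ω) = A · Γ² / (ω² + Γ²), amplitude A and half-width Γ;
* a vibrational density of states (VDOS) envelope: a lognormal band
  V(ω) = A · exp(−[ln(ω/ω_c)]² / (2σ²)) with mode position ω_c and
  log-width σ, vanishing at both ω → 0⁺ and ω → ∞;
* optional sharp phonon peaks, as pseudo-Voigt profiles (Lorentzian
  fraction η ∈ [0,1], common FWHM, amplitude = peak height).

The intensity of the QES component, I_QES, tracks the thermal activation
of fast local (relaxational) motions and is the quantity followed along
temperature or time ramps to locate phase transformations. It is
reported as the *integrated Lorentzian area over the fit window* (robust
to the amplitude/half-width trade-off), computed in closed form:
∫ A·Γ²/(ω²+Γ²) dω = A·Γ·[arctan(ω_hi/Γ) − arctan(ω_lo/Γ)].

Fitting is bounded nonlinear least squares (lmfit); the component
template — initial values and bounds — is supplied by the caller, never
auto-detected. Along a series each fit is warm-started from the previous
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .exceptions import DomainError, FitError, RepresentationError
from .spectra_io import Spectrum, SpectrumSeries

__all__ = [
    "QESComponent",
    "LognormalVDOS",
    "PhononPeak",
    "DecompositionFit",
    "fit_decomposition",
    "qes_trace",
]

DEFAULT_WINDOW = (5.0, 150.0)

_MAX_ITER = 500


@dataclass
class QESComponent:
    """Zero-centered Lorentzian quasi-elastic component (Stokes half).

    ``amplitude`` is the ω→0 height, ``hwhm`` the half width at half
    maximum Γ in cm⁻¹.
    """

    amplitude: float
    hwhm: float

    def __call__(self, omega: np.ndarray) -> np.ndarray:
        return self.amplitude * self.hwhm**2 / (omega**2 + self.hwhm**2)

    def area(self, lo: float, hi: float) -> float:
        """Integrated intensity over [lo, hi] in closed form."""
        return (
            self.amplitude
            * self.hwhm
            * (math.atan(hi / self.hwhm) - math.atan(lo / self.hwhm))
        )


@dataclass
class LognormalVDOS:
    """Lognormal vibrational density-of-states envelope.

    ``center_omega`` is the mode position in cm⁻¹ (peak of the band),
    ``sigma`` the dimensionless logarithmic width.
    """

    amplitude: float
    center_omega: float
    sigma: float

    def __call__(self, omega: np.ndarray) -> np.ndarray:
        out = np.zeros_like(omega, dtype=float)
        pos = omega > 0
        out[pos] = self.amplitude * np.exp(
            -np.log(omega[pos] / self.center_omega) ** 2 / (2.0 * self.sigma**2)
        )
        return out


@dataclass
class PhononPeak:
    """Sharp lattice-mode peak as a pseudo-Voigt profile.

    ``eta`` is the Lorentzian fraction (η=0 pure Gaussian, η=1 pure
    Lorentzian); Gaussian and Lorentzian parts share the FWHM and the
    amplitude is the peak height.
    """

    position: float
    amplitude: float
    fwhm: float
    eta: float = 0.5

    def __call__(self, omega: np.ndarray) -> np.ndarray:
        half = self.fwhm / 2.0
        d = omega - self.position
        lor = half**2 / (d**2 + half**2)
        gau = np.exp(-4.0 * math.log(2.0) * d**2 / self.fwhm**2)
        return self.amplitude * (self.eta * lor + (1.0 - self.eta) * gau)


Component = QESComponent | LognormalVDOS | PhononPeak

# parameter names, defaults for bounds, per component class
_PARAM_SPEC: dict[type, list[str]] = {
    QESComponent: ["amplitude", "hwhm"],
    LognormalVDOS: ["amplitude", "center_omega", "sigma"],
    PhononPeak: ["position", "amplitude", "fwhm", "eta"],
}


def _default_bounds(comp: Component, name: str, window: tuple[float, float]):
    lo, hi = window
    span = hi - lo
    if name == "amplitude":
        return (0.0, np.inf)
    if name == "hwhm":
        return (1e-3, 10.0 * span)
    if name == "center_omega":
        return (max(lo, 1e-3), hi)
    if name == "sigma":
        return (0.02, 3.0)
    if name == "position":
        return (lo, hi)
    if name == "fwhm":
        return (1e-3, span)
    if name == "eta":
        return (0.0, 1.0)
    raise KeyError(name)


@dataclass
class DecompositionFit:
    """Fitted components with uncertainties, residual level and I_QES."""

    components: list[Component]
    stderr: list[dict[str, float | None]]
    residual_rms: float
    converged: bool
    window: tuple[float, float]
    covar: np.ndarray | None = None
    _qes_index: list[int] | None = None

    @property
    def i_qes(self) -> float:
        """Integrated QES (Lorentzian) area over the fit window; 0 if no QES."""
        return sum(
            c.area(*self.window) for c in self.components if isinstance(c, QESComponent)
        )

    def i_qes_stderr(self) -> float | None:
        """First-order (delta-method) uncertainty of I_QES.

        Uses the full covariance of each QES component's (amplitude, hwhm)
        pair when available.
        """
        total_var = 0.0
        any_err = False
        for idx, c in enumerate(self.components):
            if not isinstance(c, QESComponent):
                continue
            err = self.stderr[idx]
            sa, sg = err.get("amplitude"), err.get("hwhm")
            if sa is None or sg is None:
                continue
            any_err = True
            lo, hi = self.window
            g = c.hwhm
            atan_term = math.atan(hi / g) - math.atan(lo / g)
            dA = g * atan_term
            dG = c.amplitude * (
                atan_term
                + g * (-hi / (hi**2 + g**2) + lo / (lo**2 + g**2))
            )
            total_var += (dA * sa) ** 2 + (dG * sg) ** 2
        return math.sqrt(total_var) if any_err else None


def _build_params(
    template: Sequence[Component],
    window: tuple[float, float],
    bounds: Sequence[dict[str, tuple[float, float]]] | None,
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for i, comp in enumerate(template):
        names = _PARAM_SPEC[type(comp)]
        user = bounds[i] if bounds is not None else {}
        for name in names:
            lo, hi = user.get(name, _default_bounds(comp, name, window))
            init = float(getattr(comp, name))
            init = min(max(init, lo), hi) if np.isfinite(hi) else max(init, lo)
            params.add(f"c{i}_{name}", value=init, min=lo, max=hi)
    return params


def _components_from_params(
    template: Sequence[Component], params: lmfit.Parameters
) -> list[Component]:
    out = []
    for i, comp in enumerate(template):
        kwargs = {
            name: float(params[f"c{i}_{name}"].value)
            for name in _PARAM_SPEC[type(comp)]
        }
        out.append(type(comp)(**kwargs))
    return out


def _model_eval(params: lmfit.Parameters, template, omega):
    total = np.zeros_like(omega)
    for i, comp in enumerate(template):
        kwargs = {
            name: params[f"c{i}_{name}"].value for name in _PARAM_SPEC[type(comp)]
        }
        total += type(comp)(**kwargs)(omega)
    return total


def fit_decomposition(
    spectrum: Spectrum,
    template: Sequence[Component],
    window: tuple[float, float] = DEFAULT_WINDOW,
    bounds: Sequence[dict[str, tuple[float, float]]] | None = None,
    weights: np.ndarray | None = None,
) -> DecompositionFit:
    """Fit a component template to a reduced/susceptibility spectrum.

    ``template`` carries the initial values; ``bounds`` optionally
    overrides the per-parameter default bounds (list of dicts parallel to
    the template). Weighted least squares with uniform weights by
    default. Parameter standard errors come from the local curvature of
    the objective.
    """
    if spectrum.representation not in ("reduced", "susceptibility"):
        raise RepresentationError(
            "fit_decomposition expects reduced or susceptibility representation, "
            f"got {spectrum.representation!r}"
        )
    if not template:
        raise FitError("component template is empty")
    lo, hi = window
    grid = spectrum.wavenumbers
    if lo < grid[0] - 1e-9 or hi > grid[-1] + 1e-9:
        raise DomainError(
            f"fit window [{lo}, {hi}] outside the data range [{grid[0]}, {grid[-1]}]"
        )
    mask = (grid >= lo) & (grid <= hi)
    omega = grid[mask]
    y = spectrum.intensities[mask]
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite intensities inside the fit window")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)[mask]

    params = _build_params(template, window, bounds)

    def residual(p):
        return w * (_model_eval(p, template, omega) - y)

    result = lmfit.minimize(
        residual,
        params,
        method="least_squares",
        max_nfev=_MAX_ITER * (len(params) + 1),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    fitted = _components_from_params(template, result.params)
    stderr = []
    for i, comp in enumerate(template):
        errs = {}
        for name in _PARAM_SPEC[type(comp)]:
            p = result.params[f"c{i}_{name}"]
            errs[name] = float(p.stderr) if p.stderr is not None else None
        stderr.append(errs)
    resid = _model_eval(result.params, template, omega) - y
    return DecompositionFit(
        components=fitted,
        stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=bool(result.success) and result.nfev < _MAX_ITER * (len(params) + 1),
        window=window,
        covar=getattr(result, "covar", None),
    )


def qes_trace(
    series: SpectrumSeries,
    template: Sequence[Component],
    window: tuple[float, float] = DEFAULT_WINDOW,
    bounds: Sequence[dict[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Fit every spectrum of a series and tabulate I_QES along the axis.

    Each fit is warm-started from the previous spectrum's solution.
    Returns a DataFrame with columns ``axis_value``, ``i_qes``,
    ``i_qes_err``, ``residual_rms``, ``converged``; a non-converged fit is
    flagged in its row rather than aborting the trace.
    """
    rows = []
    current = list(template)
    axis_vals = series.axis_values
    for val, spec in zip(axis_vals, series):
        try:
            fit = fit_decomposition(spec, current, window=window, bounds=bounds)
            rows.append(
                {
                    "axis_value": float(val),
                    "i_qes": fit.i_qes,
                    "i_qes_err": fit.i_qes_stderr(),
                    "residual_rms": fit.residual_rms,
                    "converged": fit.converged,
                }
            )
            if fit.converged:
                current = [replace(c) for c in fit.components]
        except FitError:
            rows.append(
                {
                    "axis_value": float(val),
                    "i_qes": np.nan,
                    "i_qes_err": np.nan,
                    "residual_rms": np.nan,
                    "converged": False,
                }
            )
    return pd.DataFrame(rows)
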