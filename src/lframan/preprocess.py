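"""Intensity transforms for low-frequency Raman spectra.

The Stokes intensity of a low-frequency Raman band rides on the thermal
occupation of the mode: I(ω,T) ∝ (ω0−ω)⁴ · (n(ω,T)+1) · S, where
n(ω,T)+1 = 1/(1−exp(−c₂ω/T)) is the Bose factor (c₂ = hc/k_B the second
radiation constant) and ω0 the absolute laser wavenumber. Below
~150 cm⁻¹ the Bose factor varies strongly across the band and distorts
broad features, so spectra are transformed before any fitting:

* reduced intensity  Ir(ω) = I(ω,T) / [(n(ω,T)+1) · ω]
* Raman susceptibility  χ″(ω) = ω · Ir(ω) = I(ω,T) / (n(ω,T)+1)

Only the Stokes side is handled. The 1/ω divergence of the reduction at
zero shift is handled by a hard low-frequency cutoff (default 5 cm⁻¹, a
typical elastic-rejection limit), never by regularization. The (ω0−ω)⁴
throughput correction is available but off by default, normalized to 1
at ω = 0 so corrected and uncorrected spectra share an intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateDataError,
    DomainError,
    MetadataError,
    RepresentationError,
)
from .spectra_io import Spectrum

#: Second radiation constant hc/k_B in cm·K (CODATA).
SECOND_RADIATION_CONSTANT = 1.4387769


@dataclass(frozen=True)
class BoseParams:
    """Constants of the Bose-factor reduction.

    ``cutoff`` is the low-frequency limit in cm⁻¹ below which points are
    dropped before dividing by ω.
    """

    second_radiation_constant: float = SECOND_RADIATION_CONSTANT
    cutoff: float = 5.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise DomainError(f"cutoff must be > 0, got {self.cutoff}")


@dataclass(frozen=True)
class LaserConfig:
    """Excitation line for the (ω0−ω)⁴ correction.

    ``omega0`` is the absolute laser wavenumber in cm⁻¹
    (e.g. 1e7/660 ≈ 15152 for a 660 nm line).
    """

    omega0: float

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise DomainError(f"omega0 must be > 0, got {self.omega0}")

    @classmethod
    def from_nm(cls, wavelength_nm: float) -> "LaserConfig":
        return cls(omega0=1.0e7 / wavelength_nm)


def bose_factor(omega, temperature):
    """Thermal occupation factor n(ω,T)+1 = 1/(1−exp(−c₂ω/T)).

    Vectorized over ``omega`` and ``temperature`` (cm⁻¹ and kelvin). The
    factor is always > 1, decreases with ω and increases with T; for
    c₂ω/T ≫ 1 it tends to 1 and for c₂ω/T ≪ 1 it diverges as T/(c₂ω).
    """
    omega = np.asarray(omega, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(omega <= 0):
        raise DomainError("bose_factor requires omega > 0 (Stokes side)")
    if np.any(temperature <= 0):
        raise DomainError("bose_factor requires temperature > 0 K")
    x = SECOND_RADIATION_CONSTANT * omega / temperature
    out = 1.0 / (-np.expm1(-x))
    if out.ndim == 0:
        return float(out)
    return out


def reduce_intensity(
    spectrum: Spectrum,
    temperature: float | None = None,
    params: BoseParams = BoseParams(),
) -> Spectrum:
    """Transform a raw spectrum to reduced intensity Ir = I/[(n+1)·ω].

    ``temperature`` (kelvin) falls back to the spectrum's own metadata.
    Points below ``params.cutoff`` are dropped; the result is tagged
    ``reduced`` and carries the temperature used.
    """
    if spectrum.representation != "raw":
        raise RepresentationError(
            f"reduce_intensity expects a raw spectrum, got {spectrum.representation!r}"
        )
    T = temperature if temperature is not None else spectrum.temperature
    if T is None:
        raise MetadataError(
            "reduce_intensity needs a temperature (argument or spectrum metadata)"
        )
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    mask = spectrum.wavenumbers >= params.cutoff
    if not np.any(mask):
        raise DegenerateDataError(
            f"all points below the {params.cutoff} cm^-1 cutoff"
        )
    omega = spectrum.wavenumbers[mask]
    if omega.size < 8:
        raise DegenerateDataError(
            f"only {omega.size} points above the {params.cutoff} cm^-1 cutoff"
        )
    factor = bose_factor(omega, T)
    out = spectrum.replace(temperature=float(T), representation="raw")
    out.wavenumbers = omega
    out.intensities = spectrum.intensities[mask] / (factor * omega)
    out.representation = "reduced"
    return out


def unreduce_intensity(spectrum: Spectrum) -> Spectrum:
    """Exact inverse of :func:`reduce_intensity` on the retained grid."""
    if spectrum.representation != "reduced":
        raise RepresentationError(
            f"unreduce_intensity expects a reduced spectrum, got {spectrum.representation!r}"
        )
    omega = spectrum.wavenumbers
    factor = bose_factor(omega, spectrum.temperature)
    out = spectrum.replace()
    out.intensities = spectrum.intensities * factor * omega
    out.representation = "raw"
    return out


def to_susceptibility(spectrum: Spectrum) -> Spectrum:
    """Convert reduced intensity to Raman susceptibility χ″(ω) = ω·Ir(ω)."""
    if spectrum.representation != "reduced":
        raise RepresentationError(
            f"to_susceptibility expects a reduced spectrum, got {spectrum.representation!r}"
        )
    out = spectrum.replace()
    out.intensities = spectrum.wavenumbers * spectrum.intensities
    out.representation = "susceptibility"
    return out


def susceptibility_to_reduced(spectrum: Spectrum) -> Spectrum:
    """Inverse of :func:`to_susceptibility`: Ir(ω) = χ″(ω)/ω."""
    if spectrum.representation != "susceptibility":
        raise RepresentationError(
            "susceptibility_to_reduced expects a susceptibility spectrum, "
            f"got {spectrum.representation!r}"
        )
    out = spectrum.replace()
    out.intensities = spectrum.intensities / spectrum.wavenumbers
    out.representation = "reduced"
    return out


def omega4_correct(spectrum: Spectrum, laser: LaserConfig, undo: bool = False) -> Spectrum:
    """Remove (or reapply) the (ω0−ω)⁴ throughput factor.

    Intensities are divided by ((ω0−ω)/ω0)⁴, which equals 1 at ω = 0 so
    the overall intensity scale is preserved. ``undo=True`` multiplies
    instead, restoring the original spectrum exactly. The representation
    tag is unchanged.
    """
    omega = spectrum.wavenumbers
    if laser.omega0 <= omega.max():
        raise DomainError(
            f"laser omega0 = {laser.omega0} cm^-1 must exceed the maximum "
            f"analyzed Raman shift ({omega.max()} cm^-1)"
        )
    correction = ((laser.omega0 - omega) / laser.omega0) ** 4
    out = spectrum.replace()
    if undo:
        out.intensities = spectrum.intensities * correction
    else:
        out.intensities = spectrum.intensities / correction
    return out
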