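"""Synthetic dehydration series with known ground truth.

Real in-situ dehydration data for this kind of experiment are rarely
deposited, so every pipeline stage is validated against simulated series
whose ground truth is known exactly. An endmember spectrum (hydrate or
anhydrate) is a deterministic sum of pseudo-Voigt phonon peaks, an
optional lognormal VDOS envelope and an optional zero-centered
Lorentzian QES component, built in susceptibility units. The hydrate
endmembers carry the water-marker band near 80 cm⁻¹; the
dehydration-product endmember of the theophylline-style pair carries the
extra phonon peak near 25 cm⁻¹ that distinguishes it from the marketed
form.

A simulated dehydration evolves the hydrate fraction under a chosen
kinetic law ρ*(t), mixes the endmembers in susceptibility —
χ_t = (1−ρ*)·χ_h + ρ*·χ_a — adds homoscedastic Gaussian noise in
susceptibility units, and converts to raw counts by the exact inverse of
the Bose reduction (I = χ·(n(ω,T)+1)), so that running the preprocessing
forward recovers the noiseless mixture at machine precision when σ = 0.

Three named fixtures reproduce the study conditions of the two model
hydrates:

* ``tp_noRH``   — theophylline-style, Avrami law, n = 2.95 (nucleation
  and growth, no humidity control), t_1/2 = 100 min, seed 42;
* ``tp_1RH_23C`` — theophylline-style at 23 °C / 1 % RH, Jander (D3)
  three-dimensional diffusion law, t_1/2 = 600 min, seed 44;
* ``caf_20RH``  — caffeine-style at 23 °C / 20 % RH, Avrami law,
  n = 1.410 (nucleation with quasi-absent growth), t_1/2 = 200 min,
  seed 43.

The exponents and mechanisms are the literature values for these
systems; the t_1/2 anchors and endmember peak tables are package
conventions chosen for desk-scale runs (no rate constants are tabulated
in the source experiments). All fixtures use 60 log-spaced time points
from t_1/2/50 to 4·t_1/2 and noise σ = 0.005 of the maximum endmember
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import LognormalVDOS, PhononPeak, QESComponent
from .exceptions import DomainError, ParseError
from .kinetics import get_model, model_g
from .preprocess import bose_factor
from .spectra_io import (
    CELSIUS_OFFSET,
    Spectrum,
    SpectrumSeries,
    write_series,
    write_spectrum,
)
from .transform_rate import TransformationCurve

__all__ = [
    "EndmemberSpec",
    "SimulationSpec",
    "make_endmember",
    "simulate_dehydration",
    "fixture",
    "FIXTURE_NAMES",
    "default_grid",
    "write_fixture_dir",
]


def default_grid(lo: float = 5.0, hi: float = 200.0, step: float = 0.5) -> np.ndarray:
    """Default wavenumber grid: 5-200 cm⁻¹ in 0.5 cm⁻¹ steps."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass
class EndmemberSpec:
    """Recipe for one endmember spectrum (susceptibility units)."""

    label: str
    phonon_peaks: list[PhononPeak] = field(default_factory=list)
    vdos: LognormalVDOS | None = None
    qes: QESComponent | None = None

    def components(self):
        out = list(self.phonon_peaks)
        if self.vdos is not None:
            out.append(self.vdos)
        if self.qes is not None:
            out.append(self.qes)
        return out


@dataclass
class SimulationSpec:
    """Conditions of one simulated isothermal dehydration run."""

    times: np.ndarray  # minutes, strictly increasing
    temperature: float  # kelvin
    model_id: str = "avrami"
    k: float = 1.0
    n: float | None = None
    rh: float | None = None
    noise_sigma: float = 0.005  # fraction of max endmember intensity
    seed: int = 0
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise DomainError("simulation times must be strictly increasing")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0 K")


def make_endmember(spec: EndmemberSpec, grid: np.ndarray) -> Spectrum:
    """Evaluate an endmember recipe on a grid (susceptibility, 295.15 K tag).

    Deterministic: two calls with the same spec yield identical arrays.
    """
    grid = np.asarray(grid, dtype=float)
    comps = spec.components()
    if not comps:
        raise ParseError(f"endmember {spec.label!r} has no components")
    for p in spec.phonon_peaks:
        if not (grid[0] <= p.position <= grid[-1]):
            raise DomainError(
                f"peak position {p.position} cm^-1 outside grid "
                f"[{grid[0]}, {grid[-1]}]"
            )
    total = np.zeros_like(grid)
    for c in comps:
        total += c(grid)
    return Spectrum(
        wavenumbers=grid.copy(),
        intensities=total,
        representation="susceptibility",
        temperature=295.15,
        label=spec.label,
    )


# --- endmember recipes -----------------------------------------------------
# Peak tables are loosely styled on the low-frequency spectra of the two
# xanthine hydrates: sharp lattice modes below 150 cm^-1, the 80 cm^-1
# water band in the hydrates, an extra 25 cm^-1 peak in the theophylline
# dehydration product, and broad librational bands in the caffeine
# anhydrate. They make no claim of spectroscopic accuracy.

def tp_hydrate() -> EndmemberSpec:
    return EndmemberSpec(
        label="tp_hydrate",
        phonon_peaks=[
            PhononPeak(32.0, 1.00, 8.0, 0.4),
            PhononPeak(52.0, 0.90, 9.0, 0.4),
            PhononPeak(80.0, 2.00, 12.0, 0.5),  # water-marker band
            PhononPeak(112.0, 0.70, 14.0, 0.4),
            PhononPeak(140.0, 0.45, 16.0, 0.4),
        ],
        vdos=LognormalVDOS(0.25, 60.0, 0.55),
        qes=QESComponent(0.35, 9.0),
    )


def tp_anhydrate() -> EndmemberSpec:
    return EndmemberSpec(
        label="tp_anhydrate",
        phonon_peaks=[
            PhononPeak(25.0, 0.90, 8.0, 0.4),  # extra lattice mode of the product
            PhononPeak(43.0, 1.00, 9.0, 0.4),
            PhononPeak(55.0, 0.60, 10.0, 0.4),
            PhononPeak(115.0, 0.70, 14.0, 0.4),
            PhononPeak(145.0, 0.50, 16.0, 0.4),
        ],
        vdos=LognormalVDOS(0.18, 45.0, 0.45),
        qes=QESComponent(0.55, 11.0),  # more disorder once water has left
    )


def caf_hydrate() -> EndmemberSpec:
    return EndmemberSpec(
        label="caf_hydrate",
        phonon_peaks=[
            PhononPeak(30.0, 0.95, 9.0, 0.4),
            PhononPeak(48.0, 0.85, 10.0, 0.4),
            PhononPeak(80.0, 2.00, 12.0, 0.5),  # water-marker band
            PhononPeak(118.0, 0.60, 15.0, 0.4),
        ],
        vdos=LognormalVDOS(0.22, 55.0, 0.55),
        qes=QESComponent(0.40, 9.0),
    )


def caf_anhydrate() -> EndmemberSpec:
    # two broad librational bands, no sharp phonons (orientational disorder)
    return EndmemberSpec(
        label="caf_anhydrate",
        phonon_peaks=[
            PhononPeak(40.0, 0.90, 24.0, 0.7),
            PhononPeak(125.0, 0.80, 30.0, 0.7),
        ],
        vdos=None,
        qes=QESComponent(0.60, 12.0),
    )


def simulate_dehydration(
    hydrate: EndmemberSpec,
    anhydrate: EndmemberSpec,
    sim: SimulationSpec,
) -> tuple[SpectrumSeries, TransformationCurve]:
    """Simulate a raw dehydration series plus its ground-truth ρ*(t).

    The mixture is formed in susceptibility, noise (σ × max endmember
    intensity, Gaussian, seeded) is added there, and each spectrum is
    converted to raw counts via I = χ·(n(ω,T)+1) — the exact inverse of
    the reduced-intensity/susceptibility transforms on this grid.
    """
    grid = sim.grid
    s_h = make_endmember(hydrate, grid).intensities
    s_a = make_endmember(anhydrate, grid).intensities
    model = get_model(sim.model_id)
    rho_star = np.asarray(model.rho_of_t(sim.times, sim.k, sim.n), dtype=float)
    rng = np.random.default_rng(sim.seed)
    scale = max(s_h.max(), s_a.max())
    factor = bose_factor(grid, sim.temperature)
    spectra = []
    for i, (t, r) in enumerate(zip(sim.times, rho_star)):
        chi = (1.0 - r) * s_h + r * s_a
        if sim.noise_sigma > 0:
            chi = chi + rng.normal(0.0, sim.noise_sigma * scale, size=grid.size)
        raw = chi * factor
        spectra.append(
            Spectrum(
                wavenumbers=grid.copy(),
                intensities=raw,
                representation="raw",
                temperature=sim.temperature,
                time=float(t),
                rh=sim.rh,
                label=f"t{i:04d}",
            )
        )
    series = SpectrumSeries(spectra=spectra, axis="time")
    truth = TransformationCurve(
        times=sim.times.copy(),
        rho=np.clip(rho_star, 0.0, 1.0),
        water_escape=1.0 - np.clip(rho_star, 0.0, 1.0),
        method="truth",
    )
    return series, truth


# --- named fixtures --------------------------------------------------------

FIXTURE_NAMES = ("tp_noRH", "tp_1RH_23C", "caf_20RH")

_N_TIMES = 60
_T_SPAN = 4.0  # simulate out to 4 x t_half
_T_START_FRACTION = 1.0 / 50.0
_NOISE_SIGMA = 0.005


def _times_for(t_half: float) -> np.ndarray:
    return np.geomspace(_T_START_FRACTION * t_half, _T_SPAN * t_half, _N_TIMES)


def _k_for_half_time(model_id: str, t_half: float, n: float | None) -> float:
    g_half = float(model_g(model_id, 0.5))
    if model_id == "avrami":
        return g_half / t_half**n
    return g_half / t_half


def fixture(name: str) -> tuple[EndmemberSpec, EndmemberSpec, SimulationSpec]:
    """Return (hydrate, anhydrate, simulation) specs for a named fixture."""
    if name == "tp_noRH":
        n = 2.95
        sim = SimulationSpec(
            times=_times_for(100.0),
            temperature=CELSIUS_OFFSET + 35.0,
            model_id="avrami",
            k=_k_for_half_time("avrami", 100.0, n),
            n=n,
            rh=None,
            noise_sigma=_NOISE_SIGMA,
            seed=42,
        )
        return tp_hydrate(), tp_anhydrate(), sim
    if name == "tp_1RH_23C":
        sim = SimulationSpec(
            times=_times_for(600.0),
            temperature=CELSIUS_OFFSET + 23.0,
            model_id="d3",
            k=_k_for_half_time("d3", 600.0, None),
            n=None,
            rh=1.0,
            noise_sigma=_NOISE_SIGMA,
            seed=44,
        )
        return tp_hydrate(), tp_anhydrate(), sim
    if name == "caf_20RH":
        n = 1.410
        sim = SimulationSpec(
            times=_times_for(200.0),
            temperature=CELSIUS_OFFSET + 23.0,
            model_id="avrami",
            k=_k_for_half_time("avrami", 200.0, n),
            n=n,
            rh=20.0,
            noise_sigma=_NOISE_SIGMA,
            seed=43,
        )
        return caf_hydrate(), caf_anhydrate(), sim
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")


def write_fixture_dir(name: str, out_dir: str | Path, seed: int | None = None) -> Path:
    """Materialize a fixture on disk: spectra + manifest + refs + ground truth.

    Writes ``spec_*.txt``, ``manifest.csv``, ``ground_truth.csv`` and the
    two endmember reference spectra (reduced representation, for
    unmixing) into ``out_dir``; returns the manifest path. ``seed``
    overrides the fixture's documented noise seed.
    """
    hyd, anh, sim = fixture(name)
    if seed is not None:
        sim = replace(sim, seed=seed)
    series, truth = simulate_dehydration(hyd, anh, sim)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = write_series(series, out_dir)
    for spec in (hyd, anh):
        chi = make_endmember(spec, sim.grid)
        reduced = chi.replace()
        reduced.intensities = chi.intensities / chi.wavenumbers
        reduced.representation = "reduced"
        reduced.temperature = sim.temperature
        write_spectrum(reduced, out_dir / f"ref_{spec.label}.txt")
    pd.DataFrame(
        {
            "time_min": truth.times,
            "rho": truth.rho,
            "water_escape": truth.water_escape,
        }
    ).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
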