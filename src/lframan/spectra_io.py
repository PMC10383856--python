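"""Spectrum and spectral-series containers with plain-text I/O.

A :class:`Spectrum` is a single one-dimensional Raman trace on a strictly
increasing wavenumber grid (cm^-1), carrying its representation tag
(``raw`` counts, Bose-``reduced`` intensity, or Raman ``susceptibility``)
and environment metadata (temperature in kelvin, elapsed time in minutes,
relative humidity in percent).

A :class:`SpectrumSeries` is an ordered collection of spectra sharing one
wavenumber grid, indexed along a time or temperature axis — the in-memory
form of an in-situ dehydration run.

Files are two-column ASCII (wavenumber, intensity) with ``#`` comments;
series manifests are CSV tables with a ``file`` column plus ``time_min``
and/or ``temperature_C`` columns. Temperatures are accepted in Celsius in
manifests and carried in kelvin internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDataError,
    ExtrapolationError,
    GridError,
    MetadataError,
    OrderingError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Valid representation tags, in pipeline order.
REPRESENTATIONS = ("raw", "reduced", "susceptibility")

#: Minimum number of grid points for a spectrum to be meaningful.
MIN_POINTS = 8

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return float(t_c) + CELSIUS_OFFSET


@dataclass
class Spectrum:
    """One spectral trace with its wavenumber grid and metadata.

    Parameters
    ----------
    wavenumbers : array-like
        Raman shifts in cm^-1, strictly increasing, length >= 8.
    intensities : array-like
        Intensities (counts or transformed units), same length.
    representation : {'raw', 'reduced', 'susceptibility'}
    temperature : float, optional
        Sample temperature in kelvin. Required before Bose reduction.
    time : float, optional
        Elapsed time in minutes (for kinetic series).
    rh : float, optional
        Relative humidity in percent.
    label : str
        Free-text identifier.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    representation: str = "raw"
    temperature: float | None = None
    time: float | None = None
    rh: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ParseError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ParseError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size < MIN_POINTS:
            raise DegenerateDataError(
                f"spectrum has {self.wavenumbers.size} points; need >= {MIN_POINTS}"
            )
        if not np.all(np.diff(self.wavenumbers) > 0):
            raise OrderingError("wavenumbers must be strictly increasing")
        if self.representation not in REPRESENTATIONS:
            raise ParseError(
                f"unknown representation {self.representation!r}; "
                f"expected one of {REPRESENTATIONS}"
            )
        if self.representation != "raw" and self.temperature is None:
            raise MetadataError(
                f"representation {self.representation!r} requires the temperature "
                "used at transform time"
            )

    def __len__(self) -> int:
        return self.wavenumbers.size

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced (arrays are copied)."""
        out = replace(self, **changes)
        out.wavenumbers = out.wavenumbers.copy()
        out.intensities = out.intensities.copy()
        return out


@dataclass
class SpectrumSeries:
    """Ordered spectra along a time or temperature axis on one common grid."""

    spectra: list[Spectrum]
    axis: str  # 'time' or 'temperature'
    manifest_path: str = ""

    def __post_init__(self) -> None:
        if self.axis not in ("time", "temperature"):
            raise OrderingError(f"axis must be 'time' or 'temperature', got {self.axis!r}")
        if not self.spectra:
            raise DegenerateDataError("series contains no spectra")
        vals = self.axis_values
        if np.any(~np.isfinite(vals)):
            raise MetadataError(f"every spectrum needs a finite {self.axis} value")
        if not np.all(np.diff(vals) > 0):
            raise OrderingError(f"{self.axis} axis must be strictly increasing")
        grid = self.spectra[0].wavenumbers
        for i, s in enumerate(self.spectra[1:], start=1):
            if s.wavenumbers.size != grid.size or not np.array_equal(s.wavenumbers, grid):
                raise GridError(
                    f"spectrum {i} is on a different wavenumber grid; "
                    "use resample_common_grid first (resampling is never implicit)"
                )

    @property
    def axis_values(self) -> np.ndarray:
        attr = "time" if self.axis == "time" else "temperature"
        return np.array(
            [getattr(s, attr) if getattr(s, attr) is not None else np.nan for s in self.spectra]
        )

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities as an (n_spectra, n_points) array."""
        return np.vstack([s.intensities for s in self.spectra])

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def map(self, func) -> "SpectrumSeries":
        """Apply ``func`` to every spectrum, returning a new series."""
        return SpectrumSeries(
            spectra=[func(s) for s in self.spectra],
            axis=self.axis,
            manifest_path=self.manifest_path,
        )


_META_KEYS = ("representation", "temperature", "time", "rh", "label")


def _split_row(line: str) -> list[str]:
    # auto-detect delimiter: comma, semicolon, else whitespace
    if "," in line:
        return [p.strip() for p in line.split(",")]
    if ";" in line:
        return [p.strip() for p in line.split(";")]
    return line.split()


def read_spectrum(path: str | Path, **metadata) -> Spectrum:
    """Read a two-column ASCII spectrum file.

    Comment lines start with ``#``; metadata comments of the form
    ``# key: value`` written by :func:`write_spectrum` are recovered.
    Keyword arguments override file metadata. Files stored in descending
    wavenumber order are sorted ascending (with a log notice).
    """
    path = Path(path)
    wn: list[float] = []
    inten: list[float] = []
    file_meta: dict = {}
    with open(path) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key in _META_KEYS:
                        val = val.strip()
                        if key in ("temperature", "time", "rh"):
                            file_meta[key] = None if val == "None" else float(val)
                        else:
                            file_meta[key] = val
                continue
            parts = _split_row(line)
            if len(parts) < 2:
                raise ParseError(f"{path}, line {lineno}: expected two columns, got {line!r}")
            try:
                w = float(parts[0])
                i = float(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric row {line!r}"
                ) from None
            if not (math.isfinite(w) and math.isfinite(i)):
                raise ParseError(f"{path}, line {lineno}: non-finite value in {line!r}")
            wn.append(w)
            inten.append(i)
    if len(wn) < MIN_POINTS:
        raise DegenerateDataError(
            f"{path}: only {len(wn)} data points; need >= {MIN_POINTS}"
        )
    w_arr = np.array(wn)
    i_arr = np.array(inten)
    if np.all(np.diff(w_arr) < 0):
        logger.info("%s: wavenumbers stored descending; sorting ascending", path)
        w_arr = w_arr[::-1]
        i_arr = i_arr[::-1]
    elif not np.all(np.diff(w_arr) > 0):
        order = np.argsort(w_arr)
        w_arr = w_arr[order]
        i_arr = i_arr[order]
        if np.any(np.diff(w_arr) == 0):
            raise ParseError(f"{path}: duplicate wavenumber values")
        logger.info("%s: wavenumbers unordered; sorted ascending", path)
    file_meta.setdefault("representation", "raw")
    file_meta.setdefault("label", path.stem)
    file_meta.update(metadata)
    return Spectrum(wavenumbers=w_arr, intensities=i_arr, **file_meta)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column ASCII with metadata in ``#`` comments.

    Values use 17 significant digits so a write -> read round trip is
    lossless at double precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# representation: {spectrum.representation}\n")
        fh.write(f"# temperature: {spectrum.temperature!r}\n")
        fh.write(f"# time: {spectrum.time!r}\n")
        fh.write(f"# rh: {spectrum.rh!r}\n")
        fh.write(f"# label: {spectrum.label}\n")
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{w:.17g} {i:.17g}\n")


def read_series(manifest: str | Path) -> SpectrumSeries:
    """Read an ordered spectral series from a CSV manifest.

    The manifest must have a ``file`` column (paths relative to the
    manifest's directory) and at least one of ``time_min`` /
    ``temperature_C``; ``rh_percent`` is optional. The series axis is the
    column that varies across rows — time takes precedence when both vary.
    Temperatures are converted to kelvin on read.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    if "file" not in table.columns:
        raise ParseError(f"{manifest}: manifest needs a 'file' column")
    has_time = "time_min" in table.columns
    has_temp = "temperature_C" in table.columns
    if not (has_time or has_temp):
        raise ParseError(f"{manifest}: need a 'time_min' or 'temperature_C' column")

    def _varies(col: str) -> bool:
        vals = table[col].to_numpy(dtype=float)
        return bool(np.any(vals != vals[0]))

    if has_time and _varies("time_min"):
        axis = "time"
        axis_vals = table["time_min"].to_numpy(dtype=float)
    elif has_temp and _varies("temperature_C"):
        axis = "temperature"
        axis_vals = table["temperature_C"].to_numpy(dtype=float)
    elif has_time:
        axis = "time"
        axis_vals = table["time_min"].to_numpy(dtype=float)
    else:
        axis = "temperature"
        axis_vals = table["temperature_C"].to_numpy(dtype=float)

    if not np.all(np.diff(axis_vals) > 0):
        raise OrderingError(
            f"{manifest}: {axis} axis is not strictly increasing "
            f"(values {axis_vals.tolist()})"
        )

    spectra = []
    for _, row in table.iterrows():
        meta = {}
        if has_time and not pd.isna(row.get("time_min")):
            meta["time"] = float(row["time_min"])
        if has_temp and not pd.isna(row.get("temperature_C")):
            meta["temperature"] = celsius_to_kelvin(float(row["temperature_C"]))
        if "rh_percent" in table.columns and not pd.isna(row.get("rh_percent")):
            meta["rh"] = float(row["rh_percent"])
        fpath = Path(row["file"])
        if not fpath.is_absolute():
            fpath = manifest.parent / fpath
        spectra.append(read_spectrum(fpath, **meta))
    return SpectrumSeries(spectra=spectra, axis=axis, manifest_path=str(manifest))


def write_series(series: SpectrumSeries, out_dir: str | Path,
                 manifest_name: str = "manifest.csv") -> Path:
    """Write every spectrum plus a manifest CSV into ``out_dir``.

    Returns the manifest path. Spectrum files are named ``spec_0000.txt`` …
    in axis order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(series):
        fname = f"spec_{i:04d}.txt"
        write_spectrum(s, out_dir / fname)
        rows.append(
            {
                "file": fname,
                "time_min": s.time if s.time is not None else np.nan,
                "temperature_C": (s.temperature - CELSIUS_OFFSET)
                if s.temperature is not None
                else np.nan,
                "rh_percent": s.rh if s.rh is not None else np.nan,
            }
        )
    manifest = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def resample_common_grid(series: SpectrumSeries, grid: Sequence[float]) -> SpectrumSeries:
    """Linearly interpolate every spectrum onto ``grid``.

    The grid must lie within the wavenumber range of every spectrum —
    extrapolation is refused. Metadata is preserved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not np.all(np.diff(grid) > 0):
        raise GridError("target grid must be 1-D and strictly increasing")
    for i, s in enumerate(series):
        if grid[0] < s.wavenumbers[0] or grid[-1] > s.wavenumbers[-1]:
            raise ExtrapolationError(
                f"grid [{grid[0]}, {grid[-1]}] exceeds the range "
                f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}] of spectrum {i}"
            )

    def _resample(s: Spectrum) -> Spectrum:
        out = s.replace()
        out.wavenumbers = grid.copy()
        out.intensities = np.interp(grid, s.wavenumbers, s.intensities)
        return out

    return series.map(_resample)
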