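"""Pigment absorption and LED emission spectra, and their overlap.

The pH actuator is color-selective because the two rhodopsin pumps absorb in
different bands: blue-absorbing proteorhodopsin (BPR, max ~498 nm) and
bacteriorhodopsin (BR, max ~568 nm). An LED drives a pump in proportion to
the overlap between its emission spectrum and the pump's absorption band.
This module provides parametric Gaussian stand-ins for the four measured
curves, and the overlap-derived *activation coefficient* that feeds the
pump-flux law in :mod:`chromostat.plant`.

Conventions
-----------
* Pump absorption spectra are normalized to unit peak (dimensionless).
* LED emission spectra are normalized to unit area (trapezoid rule), so the
  activation coefficient is an emission-weighted mean absorbance in [0, 1].
* Wavelength grids are 1-nm, 350-750 nm by default; grids must match exactly
  between the two factors of an overlap integral (no silent regridding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateSpectrumError, GridError, ParameterError

__all__ = [
    "Spectrum",
    "PumpPhotoModel",
    "LightSourceModel",
    "default_grid",
    "gaussian_spectrum",
    "peak_wavelength",
    "overlap_integral",
    "activation_coefficient",
    "default_br",
    "default_bpr",
    "default_led",
    "BR_PEAK_NM",
    "BR_FWHM_NM",
    "BPR_PEAK_NM",
    "BPR_FWHM_NM",
    "BLUE_PEAK_NM",
    "BLUE_FWHM_NM",
    "RED_PEAK_NM",
    "RED_FWHM_NM",
]

# Default spectral parameters (nm). The pigment maxima are the measured ones;
# LED peaks/bandwidths are typical 5 mm indicator-LED values. The BR band is
# modeled wide (real BR absorption has a pronounced blue shoulder), which is
# what makes blue light partially cross-activate BR while red light leaves
# BPR essentially dark.
BPR_PEAK_NM = 498.0
BPR_FWHM_NM = 90.0
BR_PEAK_NM = 568.0
BR_FWHM_NM = 150.0
BLUE_PEAK_NM = 465.0
BLUE_FWHM_NM = 25.0
RED_PEAK_NM = 635.0
RED_FWHM_NM = 20.0

_GRID_MIN_NM = 200.0
_GRID_MAX_NM = 900.0


def default_grid(lo: float = 350.0, hi: float = 750.0, step: float = 1.0) -> np.ndarray:
    """Closed-interval wavelength grid in nm (default 350-750 at 1 nm)."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-gridded, nonnegative curve (absorbance or intensity).

    Parameters
    ----------
    wavelengths
        Strictly increasing grid in nm.
    values
        Nonnegative, same length as ``wavelengths``.
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ParameterError("spectrum grid must be a non-empty 1-D array")
        if wl.size != vals.size:
            raise ParameterError(
                f"grid and values differ in length ({wl.size} vs {vals.size})"
            )
        if np.any(np.diff(wl) <= 0):
            raise ParameterError("wavelength grid must be strictly increasing")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ParameterError("spectrum values must be finite and >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def value_at(self, nm: float) -> float:
        """Value at an exact grid wavelength (no interpolation)."""
        idx = np.nonzero(np.isclose(self.wavelengths, nm, rtol=0.0, atol=1e-9))[0]
        if idx.size == 0:
            raise GridError(f"wavelength {nm} nm is not on the grid")
        return float(self.values[idx[0]])

    def scaled(self, factor: float) -> "Spectrum":
        if factor < 0:
            raise ParameterError("scale factor must be >= 0")
        return Spectrum(self.wavelengths, self.values * factor)

    def area(self) -> float:
        """Trapezoid-rule integral over the grid."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def normalized_to_peak(self) -> "Spectrum":
        peak = float(self.values.max())
        if peak <= 0:
            raise DegenerateSpectrumError("cannot peak-normalize an all-zero spectrum")
        return Spectrum(self.wavelengths, self.values / peak)

    def normalized_to_area(self) -> "Spectrum":
        a = self.area()
        if a <= 0:
            raise DegenerateSpectrumError("cannot area-normalize an all-zero spectrum")
        return Spectrum(self.wavelengths, self.values / a)

    # -- two-column CSV interface ------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        expected = ["wavelength_nm", "value"]
        if list(df.columns) != expected:
            raise GridError(
                f"{path}: expected columns {expected}, found {list(df.columns)}"
            )
        return cls(df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float))


def gaussian_spectrum(
    center: float, fwhm: float, grid: np.ndarray | None = None
) -> Spectrum:
    """Unit-peak Gaussian band centred at ``center`` with the given FWHM.

    The curve attains exactly 1 at its analytic centre; on-grid the maximum
    sits at the grid point nearest ``center``.
    """
    if fwhm <= 0:
        raise ParameterError(f"fwhm must be > 0 (got {fwhm})")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("empty wavelength grid")
    if grid.min() < _GRID_MIN_NM or grid.max() > _GRID_MAX_NM:
        raise ParameterError(
            f"grid must lie within {_GRID_MIN_NM:g}-{_GRID_MAX_NM:g} nm"
        )
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return Spectrum(grid, values)


def peak_wavelength(s: Spectrum) -> float:
    """Grid wavelength of the spectrum maximum; ties break to the shortest."""
    if not np.any(s.values > 0):
        raise DegenerateSpectrumError("all-zero spectrum has no peak")
    return float(s.wavelengths[int(np.argmax(s.values))])


@dataclass(frozen=True)
class PumpPhotoModel:
    """Photophysics of one light-driven proton pump.

    ``direction`` is the pumping sign convention on the extravesicular
    solution: +1 adds protons outside (acidifies), -1 removes them. In the
    co-reconstituted vesicles BPR acidifies the outside (+1) and BR
    alkalinizes it (-1).
    """

    name: str
    absorption: Spectrum
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ParameterError("direction must be +1 or -1")
        if self.name == "BR" and self.direction != -1:
            raise ParameterError("BR removes extravesicular protons (direction -1)")
        if self.name == "BPR" and self.direction != +1:
            raise ParameterError("BPR adds extravesicular protons (direction +1)")
        if abs(float(self.absorption.values.max()) - 1.0) > 1e-6:
            raise ParameterError("pump absorption must be normalized to unit peak")

    @property
    def peak_nm(self) -> float:
        return peak_wavelength(self.absorption)


@dataclass(frozen=True)
class LightSourceModel:
    """An LED: color label plus unit-area emission spectrum."""

    color: str
    emission: Spectrum = field(repr=False)

    def __post_init__(self) -> None:
        if self.color not in ("red", "blue"):
            raise ParameterError("color must be 'red' or 'blue'")
        # Normalize at construction: scaling the input emission by any c > 0
        # leaves the model (and every overlap computed from it) unchanged.
        object.__setattr__(self, "emission", self.emission.normalized_to_area())
        if abs(self.emission.area() - 1.0) > 1e-6:
            raise DegenerateSpectrumError("emission cannot be area-normalized")

    @property
    def peak_nm(self) -> float:
        return peak_wavelength(self.emission)


def overlap_integral(a: Spectrum, b: Spectrum) -> float:
    """Trapezoid-rule integral of the pointwise product of two spectra.

    Grids must be identical; non-overlapping or mismatched grids raise
    :class:`GridError` rather than being silently resampled.
    """
    if a.wavelengths.size != b.wavelengths.size or not np.allclose(
        a.wavelengths, b.wavelengths, rtol=0.0, atol=1e-9
    ):
        raise GridError("spectra are on different wavelength grids")
    return float(np.trapezoid(a.values * b.values, a.wavelengths))


def activation_coefficient(pump: PumpPhotoModel, light: LightSourceModel) -> float:
    """Dimensionless drive of ``pump`` by ``light`` in [0, 1].

    The emission-weighted mean of the unit-peak absorption band:
    ``integral absorption(lambda) * emission(lambda) dlambda`` with emission
    of unit area. 1 means the LED sits exactly on the absorption maximum;
    0 means no spectral overlap.
    """
    return float(np.clip(overlap_integral(pump.absorption, light.emission), 0.0, 1.0))


def default_bpr(
    center: float = BPR_PEAK_NM,
    fwhm: float = BPR_FWHM_NM,
    grid: np.ndarray | None = None,
) -> PumpPhotoModel:
    return PumpPhotoModel("BPR", gaussian_spectrum(center, fwhm, grid), +1)


def default_br(
    center: float = BR_PEAK_NM,
    fwhm: float = BR_FWHM_NM,
    grid: np.ndarray | None = None,
) -> PumpPhotoModel:
    return PumpPhotoModel("BR", gaussian_spectrum(center, fwhm, grid), -1)


def default_led(
    color: str,
    center: float | None = None,
    fwhm: float | None = None,
    grid: np.ndarray | None = None,
) -> LightSourceModel:
    if color == "blue":
        center = BLUE_PEAK_NM if center is None else center
        fwhm = BLUE_FWHM_NM if fwhm is None else fwhm
    elif color == "red":
        center = RED_PEAK_NM if center is None else center
        fwhm = RED_FWHM_NM if fwhm is None else fwhm
    else:
        raise ParameterError("color must be 'red' or 'blue'")
    return LightSourceModel(color, gaussian_spectrum(center, fwhm, grid))
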