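"""Spectral building blocks for the four-primary stimulator model.

Everything downstream of the device model works on :class:`SpectralFunction`
objects: non-negative quantities (LED radiance shapes, photoreceptor
sensitivities, density templates) tabulated on a strictly increasing
wavelength grid.  The canonical grid is 390-780 nm at 1-nm steps; combining
two functions resamples by linear interpolation with zero outside support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default wavelength grid (nm): 390-780 at 1-nm steps.
DEFAULT_GRID = np.arange(390.0, 781.0, 1.0)

#: Primary order used throughout the package.
PRIMARY_NAMES = ("red", "green", "cyan", "blue")

#: Nominal emission peaks of the four interference-filtered LEDs (nm).
DEFAULT_PEAKS_NM = (660.0, 558.0, 516.0, 460.0)

#: Default full width at half maximum of each primary (nm).  The physical
#: device narrows its LEDs to 8-10 nm; 9 nm is the modelling default.
DEFAULT_FWHM_NM = 9.0


@dataclass(frozen=True)
class SpectralFunction:
    """A non-negative function of wavelength on a strictly increasing grid."""

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        va = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or wl.shape != va.shape:
            raise ValueError("wavelength and value must be 1-D arrays of equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing with >= 2 points")
        if not np.all(np.isfinite(va)) or np.any(va < 0):
            raise ValueError("spectral values must be finite and non-negative")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", va)

    def resample(self, grid: np.ndarray) -> "SpectralFunction":
        """Linear interpolation onto ``grid``; zero outside the support."""
        grid = np.asarray(grid, dtype=float)
        v = np.interp(grid, self.wavelength_nm, self.value, left=0.0, right=0.0)
        return SpectralFunction(grid, v)

    def integrate(self) -> float:
        """Trapezoid-rule integral over the grid."""
        return float(np.trapezoid(self.value, self.wavelength_nm))

    def peak_normalized(self) -> "SpectralFunction":
        peak = self.value.max()
        if peak <= 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return SpectralFunction(self.wavelength_nm, self.value / peak)

    def __mul__(self, other: "SpectralFunction") -> "SpectralFunction":
        if not np.array_equal(self.wavelength_nm, other.wavelength_nm):
            raise ValueError("spectral functions combine only on a shared grid; resample first")
        return SpectralFunction(self.wavelength_nm, self.value * other.value)


def gaussian_primary(peak_nm: float, fwhm_nm: float = DEFAULT_FWHM_NM,
                     grid: np.ndarray | None = None) -> SpectralFunction:
    """Unit-peak Gaussian emission spectrum for an interference-filtered LED."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return SpectralFunction(grid, np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2))


@dataclass
class PrimarySet:
    """The four-primary device model: spectra plus intensity operating range.

    ``max_intensity`` is the per-primary device ceiling; ``mean_intensity``
    the operating point the sinusoidal modulation swings around.  Both are in
    arbitrary device units; only their ratio (headroom) and the products
    spectrum x intensity matter downstream.
    """

    primaries: tuple[SpectralFunction, SpectralFunction, SpectralFunction, SpectralFunction]
    peak_nm: tuple[float, float, float, float] = DEFAULT_PEAKS_NM
    fwhm_nm: tuple[float, float, float, float] = (DEFAULT_FWHM_NM,) * 4
    max_intensity: np.ndarray = field(default_factory=lambda: np.ones(4))
    mean_intensity: np.ndarray = field(default_factory=lambda: 0.5 * np.ones(4))
    names: tuple[str, ...] = PRIMARY_NAMES

    def __post_init__(self) -> None:
        self.max_intensity = np.asarray(self.max_intensity, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        if len(self.primaries) != 4:
            raise ValueError("exactly four primaries required")
        if self.max_intensity.shape != (4,) or self.mean_intensity.shape != (4,):
            raise ValueError("intensity vectors must have length 4")
        if np.any(self.mean_intensity < 0) or np.any(self.mean_intensity > self.max_intensity):
            raise ValueError("require 0 <= mean_intensity <= max_intensity per primary")

    @property
    def grid(self) -> np.ndarray:
        return self.primaries[0].wavelength_nm

    def headroom(self) -> np.ndarray:
        """Largest |Michelson contrast| each primary supports around its mean.

        The sinusoid ``I0 * (1 + m sin wt)`` must stay inside [0, Imax]:
        the lower rail caps |m| at 1, the upper rail at Imax/I0 - 1.
        """
        with np.errstate(divide="ignore"):
            up = np.where(self.mean_intensity > 0,
                          self.max_intensity / self.mean_intensity - 1.0, 0.0)
        return np.minimum(1.0, up)

    def with_intensities(self, mean_intensity: np.ndarray,
                         max_intensity: np.ndarray | None = None) -> "PrimarySet":
        return PrimarySet(
            primaries=self.primaries,
            peak_nm=self.peak_nm,
            fwhm_nm=self.fwhm_nm,
            max_intensity=self.max_intensity if max_intensity is None else np.asarray(max_intensity, float),
            mean_intensity=np.asarray(mean_intensity, float),
            names=self.names,
        )


def default_primary_set(fwhm_nm: float = DEFAULT_FWHM_NM,
                        grid: np.ndarray | None = None) -> PrimarySet:
    """Gaussian model of the four-primary stimulator (660/558/516/460 nm)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    prims = tuple(gaussian_primary(p, fwhm_nm, grid) for p in DEFAULT_PEAKS_NM)
    return PrimarySet(primaries=prims, fwhm_nm=(fwhm_nm,) * 4)


def primary_set_from_spectra(spectra: list[np.ndarray], wavelengths: list[np.ndarray],
                             max_intensity: np.ndarray, mean_intensity: np.ndarray,
                             grid: np.ndarray | None = None) -> PrimarySet:
    """Build a PrimarySet from measured two-column spectra (wavelength, value)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    prims = []
    peaks = []
    for wl, va in zip(wavelengths, spectra):
        sf = SpectralFunction(np.asarray(wl, float), np.asarray(va, float)).resample(grid)
        prims.append(sf.peak_normalized())
        peaks.append(float(grid[np.argmax(sf.value)]))
    return PrimarySet(primaries=tuple(prims), peak_nm=tuple(peaks),
                      fwhm_nm=(float("nan"),) * 4,
                      max_intensity=max_intensity, mean_intensity=mean_intensity)
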