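"""Photoreceptor spectral sensitivities and prereceptoral filters.

Corneal-referenced fundamentals for L-, M-, S-cones and rods are built from
the Govardovskii et al. (2000) A1 visual-pigment template (alpha plus beta
band) multiplied by the transmission of two prereceptoral filters -- an
ageing-lens density template and a macular-pigment template -- and
normalized to unit peak.  Template peak wavelengths default to the
Stockman-Sharpe pigment maxima (L 559, M 530, S 419 nm) and rhodopsin
(493 nm); with the standard filters the corneal peaks land near 566, 541,
441 and 504 nm, i.e. close to the conventional 10-degree fundamentals and
the scotopic luminosity function.

Both filter densities carry a scalar scale (1 = standard observer), which is
also the knob used to model individual deviations from the standard observer
when quantifying isolation errors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spectra import DEFAULT_GRID, SpectralFunction

#: Receptor order used throughout the package.
RECEPTOR_NAMES = ("L", "M", "S", "rod")

#: Visual-pigment template maxima (nm) for the default observer.
DEFAULT_LAMBDA_MAX = {"L": 559.0, "M": 530.0, "S": 419.0, "rod": 493.0}


def pigment_template(lambda_max: float, grid: np.ndarray | None = None) -> SpectralFunction:
    """Govardovskii A1 pigment absorbance template (alpha + beta band)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lm_beta) / b_beta) ** 2))
    return SpectralFunction(grid, alpha + beta)


def lens_density(grid: np.ndarray | None = None, scale: float = 1.0) -> SpectralFunction:
    """Optical density of the ageing lens (standard observer at scale 1).

    Single-exponential model: density ~1.8 at 400 nm falling to <0.01 in the
    red, which reproduces the familiar short-wavelength attenuation without
    tabulated data.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    d = 1.76 * np.exp(-0.021 * (grid - 400.0))
    d = np.where(grid < 400.0, 1.76, d)
    return SpectralFunction(grid, scale * d)


def macular_density(grid: np.ndarray | None = None, scale: float = 1.0) -> SpectralFunction:
    """Macular pigment optical density: Gaussian peaking at 460 nm (0.35)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    d = 0.35 * np.exp(-0.5 * ((grid - 460.0) / 25.0) ** 2)
    return SpectralFunction(grid, scale * d)


@dataclass
class ReceptorFundamentals:
    """Corneal spectral sensitivities of L, M, S and rods, unit peak each."""

    sensitivities: tuple[SpectralFunction, SpectralFunction, SpectralFunction, SpectralFunction]
    lens_scale: float = 1.0
    macular_scale: float = 1.0
    lambda_max: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.sensitivities) != 4:
            raise ValueError("need exactly four sensitivities (L, M, S, rod)")
        if self.lens_scale < 0 or self.macular_scale < 0:
            raise ValueError("filter scales must be >= 0")
        for s in self.sensitivities:
            if not np.isclose(s.value.max(), 1.0):
                raise ValueError("each sensitivity must be normalized to unit peak")

    @property
    def grid(self) -> np.ndarray:
        return self.sensitivities[0].wavelength_nm


def build_fundamentals(lens_scale: float = 1.0, macular_scale: float = 1.0,
                       lambda_max: dict[str, float] | None = None,
                       grid: np.ndarray | None = None) -> ReceptorFundamentals:
    """Assemble fundamentals = pigment template x prereceptoral transmission."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    lmax = dict(DEFAULT_LAMBDA_MAX if lambda_max is None else lambda_max)
    dens = lens_density(grid, lens_scale).value + macular_density(grid, macular_scale).value
    trans = 10.0 ** (-dens)
    sens = []
    for name in RECEPTOR_NAMES:
        pig = pigment_template(lmax[name], grid)
        # Rods sit outside the macula: macular pigment does not filter them.
        t = 10.0 ** (-lens_density(grid, lens_scale).value) if name == "rod" else trans
        sens.append(SpectralFunction(grid, pig.value * t).peak_normalized())
    return ReceptorFundamentals(sensitivities=tuple(sens), lens_scale=lens_scale,
                                macular_scale=macular_scale, lambda_max=lmax)


def perturb_fundamentals(base: ReceptorFundamentals, d_lens: float = 0.0,
                         d_macular: float = 0.0) -> ReceptorFundamentals:
    """Return fundamentals for an observer deviating from the standard one.

    ``d_lens`` and ``d_macular`` are additive changes to the filter scales
    (e.g. +0.5 for a 50% denser lens).  Zero deviation returns an observer
    spectrally identical to ``base``.
    """
    return build_fundamentals(lens_scale=base.lens_scale + d_lens,
                              macular_scale=base.macular_scale + d_macular,
                              lambda_max=base.lambda_max, grid=base.grid)


def fundamentals_to_table(f: ReceptorFundamentals) -> "np.ndarray":
    """(n, 5) array: wavelength plus the four sensitivities (CSV-ready)."""
    cols = [f.grid] + [s.value for s in f.sensitivities]
    return np.column_stack(cols)


def fundamentals_from_table(table: np.ndarray) -> ReceptorFundamentals:
    """Inverse of :func:`fundamentals_to_table` (columns: wl, L, M, S, rod)."""
    table = np.asarray(table, dtype=float)
    grid = table[:, 0]
    sens = tuple(SpectralFunction(grid, table[:, i + 1]).peak_normalized() for i in range(4))
    return ReceptorFundamentals(sensitivities=sens, lambda_max=None)
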