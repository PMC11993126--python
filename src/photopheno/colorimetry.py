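"""CIE 1931 colorimetry helpers for the stimulator background.

The 2-degree colour-matching functions are evaluated with the multi-lobe
piecewise-Gaussian analytic fit of Wyman, Sloan & Shirley (2013), accurate
to well under 1% of peak -- ample for solving a four-primary background for
a target chromaticity and retinal illuminance.
"""

from __future__ import annotations

import numpy as np

#: Maximum luminous efficacy of photopic vision (lm/W).
KM = 683.0

#: Default artificial-pupil diameter of the Maxwellian-view stimulator (mm).
DEFAULT_PUPIL_MM = 3.0


def _gauss_piecewise(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_xyz_cmfs(wavelength_nm: np.ndarray) -> np.ndarray:
    """(3, n) array of the CIE 1931 x̄, ȳ, z̄ colour-matching functions."""
    wl = np.asarray(wavelength_nm, dtype=float)
    xbar = (1.056 * _gauss_piecewise(wl, 599.8, 37.9, 31.0)
            + 0.362 * _gauss_piecewise(wl, 442.0, 16.0, 26.7)
            - 0.065 * _gauss_piecewise(wl, 501.1, 20.4, 26.2))
    ybar = (0.821 * _gauss_piecewise(wl, 568.8, 46.9, 40.5)
            + 0.286 * _gauss_piecewise(wl, 530.9, 16.3, 31.1))
    zbar = (1.217 * _gauss_piecewise(wl, 437.0, 11.8, 36.0)
            + 0.681 * _gauss_piecewise(wl, 459.0, 26.0, 13.8))
    return np.clip(np.vstack([xbar, ybar, zbar]), 0.0, None)


def xyz_of_spectrum(wavelength_nm: np.ndarray, radiance: np.ndarray) -> np.ndarray:
    """Tristimulus (X, Y, Z) of a spectral radiance via trapezoid integration."""
    cmf = cie_xyz_cmfs(wavelength_nm)
    return np.array([KM * np.trapezoid(cmf[i] * radiance, wavelength_nm) for i in range(3)])


def chromaticity(xyz: np.ndarray) -> tuple[float, float]:
    total = float(np.sum(xyz))
    if total <= 0:
        raise ValueError("zero tristimulus sum has no chromaticity")
    return float(xyz[0] / total), float(xyz[1] / total)


def pupil_area_mm2(pupil_mm: float = DEFAULT_PUPIL_MM) -> float:
    return float(np.pi * (pupil_mm / 2.0) ** 2)


def trolands_from_luminance(luminance_cd_m2: float, pupil_mm: float = DEFAULT_PUPIL_MM) -> float:
    """Photopic retinal illuminance (Td) = luminance x pupil area."""
    return luminance_cd_m2 * pupil_area_mm2(pupil_mm)


def luminance_from_trolands(trolands: float, pupil_mm: float = DEFAULT_PUPIL_MM) -> float:
    return trolands / pupil_area_mm2(pupil_mm)
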