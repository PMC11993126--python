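"""Silent-substitution engine for the four-primary stimulator.

The A-matrix relates the intensities of the four primaries to the
excitations of the four photoreceptor classes,

    A[i, j] = integral( fundamental_i(lambda) * spectrum_j(lambda) ) * I_j,

evaluated at the mean (background) intensities ``I_j``.  Sinusoidal
modulation of the primaries with Michelson contrasts ``m`` produces
receptor excitation contrasts

    c_i = (A m)_i / E0_i,      E0 = A . 1  (background excitations),

so the primary contrasts that modulate exactly one receptor class at
contrast ``c`` while silencing the others are

    m = A^{-1} diag(E0) (c e_target).

Feasibility is a box constraint: each primary must keep its sinusoid
inside [0, max_intensity], which caps |m_j| by the per-primary headroom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import cie_xyz_cmfs, KM, luminance_from_trolands
from .fundamentals import RECEPTOR_NAMES, ReceptorFundamentals, build_fundamentals
from .spectra import PrimarySet, default_primary_set

#: Temporal frequencies of the measurement protocol (Hz).
PROTOCOL_FREQUENCIES_HZ = (1, 2, 4, 6, 8, 10, 12, 16, 20)

#: Residual receptor contrast below which a modulation counts as silent.
SILENT_TOL = 1e-10

#: Background of the standard protocol: chromaticity and surround illuminance.
DEFAULT_BACKGROUND_XY = (0.38, 0.28)
DEFAULT_SURROUND_TD = 289.0


class SingularAMatrixError(ValueError):
    """Raised when the primaries cannot independently drive the receptors."""


class InfeasibleContrastError(ValueError):
    """Requested receptor contrast exceeds the device gamut."""

    def __init__(self, requested: float, maximum: float, target: str):
        self.requested = requested
        self.maximum = maximum
        self.target = target
        super().__init__(
            f"receptor contrast {requested:.4f} for {target} is infeasible; "
            f"maximum achievable is {maximum:.4f}")


class GamutError(ValueError):
    """Target chromaticity lies outside the primaries' gamut."""


@dataclass
class AMatrix:
    """4x4 map from primary Michelson contrasts to receptor excitations.

    Rows follow :data:`~photopheno.fundamentals.RECEPTOR_NAMES`
    (L, M, S, rod); columns the primary order (red, green, cyan, blue).
    """

    entries: np.ndarray
    receptor_names: tuple[str, ...] = RECEPTOR_NAMES

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (4, 4):
            raise ValueError("A-matrix must be 4x4")
        if np.any(self.entries < 0):
            raise ValueError("A-matrix entries must be non-negative")

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.entries))

    def background_excitations(self) -> np.ndarray:
        """Receptor excitations of the unmodulated background, E0 = A . 1."""
        return self.entries @ np.ones(4)

    def receptor_contrasts(self, led_contrasts: np.ndarray) -> np.ndarray:
        """Michelson receptor contrasts produced by primary contrasts."""
        e0 = self.background_excitations()
        return (self.entries @ np.asarray(led_contrasts, dtype=float)) / e0


@dataclass
class ModulationSpec:
    """A solved photoreceptor-isolating stimulus."""

    target_receptor: str
    receptor_contrast: float
    led_contrasts: np.ndarray
    frequency_hz: float | None = None

    def __post_init__(self) -> None:
        if self.target_receptor not in RECEPTOR_NAMES:
            raise ValueError(f"unknown receptor {self.target_receptor!r}")
        self.led_contrasts = np.asarray(self.led_contrasts, dtype=float)
        if np.any(np.abs(self.led_contrasts) > 1.0 + 1e-12):
            raise ValueError("|led_contrast| must be <= 1 per primary")

    def to_dict(self) -> dict:
        return {
            "target_receptor": self.target_receptor,
            "receptor_contrast": float(self.receptor_contrast),
            "led_contrasts": [float(v) for v in self.led_contrasts],
            "frequency_hz": self.frequency_hz,
        }


def build_a_matrix(primaries: PrimarySet, fundamentals: ReceptorFundamentals,
                   condition_cap: float = 1e8) -> AMatrix:
    """Integrate fundamentals against the primary spectra at mean intensity."""
    grid = primaries.grid
    if not np.array_equal(grid, fundamentals.grid):
        raise ValueError("primaries and fundamentals must share a wavelength grid; resample first")
    entries = np.empty((4, 4))
    for i, fund in enumerate(fundamentals.sensitivities):
        for j, prim in enumerate(primaries.primaries):
            entries[i, j] = np.trapezoid(fund.value * prim.value, grid) * primaries.mean_intensity[j]
    a = AMatrix(entries)
    cond = a.condition_number
    if not np.isfinite(cond) or cond > condition_cap:
        weak = [primaries.names[j] for j in range(4) if entries[:, j].max() <= 0]
        detail = f" (dark primaries: {', '.join(weak)})" if weak else ""
        raise SingularAMatrixError(
            f"A-matrix is singular or badly conditioned (cond={cond:.3g}){detail}")
    return a


def solve_isolating_modulation(a: AMatrix, target: str, contrast: float,
                               headroom: np.ndarray | None = None) -> ModulationSpec:
    """Primary contrasts that modulate ``target`` at ``contrast``, silencing the rest."""
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("receptor contrast must be in [0, 1]")
    idx = RECEPTOR_NAMES.index(target)
    e0 = a.background_excitations()
    rhs = np.zeros(4)
    rhs[idx] = contrast * e0[idx]
    m = np.linalg.solve(a.entries, rhs)
    cap = np.ones(4) if headroom is None else np.asarray(headroom, dtype=float)
    if np.any(np.abs(m) > cap + 1e-12):
        unit = np.linalg.solve(a.entries, np.eye(4)[idx] * e0[idx])
        with np.errstate(divide="ignore"):
            cmax = float(np.min(np.where(np.abs(unit) > 0, cap / np.abs(unit), np.inf)))
        raise InfeasibleContrastError(contrast, cmax, target)
    return ModulationSpec(target_receptor=target, receptor_contrast=contrast, led_contrasts=m)


def max_achievable_contrast(a: AMatrix, target: str,
                            headroom: np.ndarray | None = None) -> float:
    """Largest silent-substitution contrast inside the intensity box.

    The solution scales linearly with the requested contrast, so the binding
    primary is the one whose |m_j| per unit receptor contrast exhausts its
    headroom first.
    """
    idx = RECEPTOR_NAMES.index(target)
    e0 = a.background_excitations()
    unit = np.linalg.solve(a.entries, np.eye(4)[idx] * e0[idx])
    cap = np.ones(4) if headroom is None else np.asarray(headroom, dtype=float)
    if np.any(cap <= 0):
        return 0.0
    with np.errstate(divide="ignore"):
        ratios = np.where(np.abs(unit) > 0, cap / np.abs(unit), np.inf)
    return float(min(1.0, np.min(ratios)))


def device_max_contrasts(primaries: PrimarySet, a: AMatrix) -> dict[str, float]:
    """Gamut-limited maximum contrast per receptor for this operating point."""
    cap = primaries.headroom()
    return {r: max_achievable_contrast(a, r, cap) for r in RECEPTOR_NAMES}


def background_from_spec(primaries: PrimarySet, chromaticity_xy: tuple[float, float],
                         illuminance_td: float, pupil_mm: float = 3.0) -> np.ndarray:
    """Mean intensities reproducing a target chromaticity and illuminance.

    Solves the three tristimulus equations for the four unknown intensities;
    the remaining degree of freedom is fixed by maximizing the smallest
    primary intensity, which keeps all four channels lit and leaves the
    modulation solver the most balanced operating point.
    """
    grid = primaries.grid
    cmf = cie_xyz_cmfs(grid)
    # XYZ per unit intensity of each primary.
    p = np.empty((3, 4))
    for j, prim in enumerate(primaries.primaries):
        for i in range(3):
            p[i, j] = KM * np.trapezoid(cmf[i] * prim.value, grid)

    x, y = chromaticity_xy
    # Gamut check in chromaticity space.
    prim_chroma = [(p[0, j] / p[:, j].sum(), p[1, j] / p[:, j].sum()) for j in range(4)]
    if not _in_hull(x, y, prim_chroma):
        verts = ", ".join(f"({a:.3f}, {b:.3f})" for a, b in prim_chroma)
        raise GamutError(f"target ({x}, {y}) outside primary gamut with vertices {verts}")

    y_lum = luminance_from_trolands(illuminance_td, pupil_mm)
    xyz_target = np.array([x / y * y_lum, y_lum, (1.0 - x - y) / y * y_lum])
    particular = np.linalg.lstsq(p, xyz_target, rcond=None)[0]
    null = _null_vector(p)
    # I(t) = particular + t * null; maximize min_j I_j(t) (concave, piecewise
    # linear in t) over the crossing points of the component lines.
    ts = [0.0]
    for j in range(4):
        for k in range(j + 1, 4):
            dn = null[j] - null[k]
            if abs(dn) > 1e-15:
                ts.append((particular[k] - particular[j]) / dn)
    best = max(ts, key=lambda t: np.min(particular + t * null))
    intensities = particular + best * null
    if np.min(intensities) < 0:
        raise GamutError("no positive intensity mixture reproduces the target background")
    resid = p @ intensities - xyz_target
    if np.linalg.norm(resid) > 1e-6 * np.linalg.norm(xyz_target):
        raise GamutError("no non-negative intensity mixture reproduces the target background")
    return intensities


def _null_vector(p: np.ndarray) -> np.ndarray:
    """Unit vector spanning the null space of the 3x4 tristimulus map."""
    _, _, vt = np.linalg.svd(p)
    return vt[-1]


def _in_hull(x: float, y: float, pts: list[tuple[float, float]]) -> bool:
    """Point-in-convex-hull test for the (tiny) chromaticity gamut."""
    from scipy.spatial import ConvexHull, QhullError  # type: ignore[attr-defined]

    try:
        hull = ConvexHull(np.array(pts))
    except QhullError:  # degenerate gamut (collinear primaries)
        return False
    eqs = hull.equations
    return bool(np.all(eqs[:, 0] * x + eqs[:, 1] * y + eqs[:, 2] <= 1e-9))


def isolation_error(nominal: AMatrix, perturbed: AMatrix, mod: ModulationSpec) -> np.ndarray:
    """Residual receptor contrasts for a deviating observer.

    The modulation was solved against the nominal A-matrix; this returns the
    contrasts the perturbed observer actually experiences minus the intended
    target vector.  Zero perturbation gives zeros (to solver tolerance).
    """
    intended = np.zeros(4)
    intended[RECEPTOR_NAMES.index(mod.target_receptor)] = mod.receptor_contrast
    actual = perturbed.receptor_contrasts(mod.led_contrasts)
    return actual - intended


@dataclass
class Device:
    """Bundle of the solved stimulator model used by the simulator."""

    primaries: PrimarySet
    fundamentals: ReceptorFundamentals
    a_matrix: AMatrix
    max_contrasts: dict[str, float]
    background_xy: tuple[float, float]
    surround_td: float


def default_device(background_xy: tuple[float, float] = DEFAULT_BACKGROUND_XY,
                   surround_td: float = DEFAULT_SURROUND_TD,
                   fwhm_nm: float = 9.0) -> Device:
    """Standard protocol device: Gaussian primaries, background solved for the
    protocol chromaticity/illuminance, ceilings at twice the operating point."""
    base = default_primary_set(fwhm_nm=fwhm_nm)
    mean = background_from_spec(base, background_xy, surround_td)
    primaries = base.with_intensities(mean, max_intensity=2.0 * mean)
    fund = build_fundamentals(grid=primaries.grid)
    a = build_a_matrix(primaries, fund)
    return Device(primaries=primaries, fundamentals=fund, a_matrix=a,
                  max_contrasts=device_max_contrasts(primaries, a),
                  background_xy=background_xy, surround_td=surround_td)
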