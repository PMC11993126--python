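"""Synthetic cohort generator for photoreceptor-directed tCS phenotyping.

The generator plays the role of the (non-public) patient data: it draws
per-patient *true* band-level sensitivity defects for the four diagnostic
groups -- normal controls, retinitis pigmentosa (RP), Stargardt disease
(STGD) and occult macular dystrophy (OMD) -- from correlated multivariate
normal templates, expands them to per-frequency defects, and then simulates
the adaptive-staircase measurement including the floor rule (censoring at
the device's maximum producible contrast).

The default templates encode the qualitative structure the phenotyping
method relies on: all patient groups lose L/M-cone-driven sensitivity,
rod-driven loss is severe in RP, moderate in STGD and absent in OMD,
S-cone-driven loss is largest in RP, and low-frequency L/M loss (red-green
discrimination) is deepest in OMD.  Group sizes default to 9/16/14/11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fundamentals import RECEPTOR_NAMES
from .normative import NormativeModel, default_normative_model
from .stimulus import PROTOCOL_FREQUENCIES_HZ

#: The six mean-defect features, in canonical order.
MD_FEATURES = ("LMD_low", "LMD_high", "MMD_low", "MMD_high", "SMD", "RMD")

GROUPS = ("normal", "RP", "STGD", "OMD")

#: Default group sizes of the study cohort.
DEFAULT_GROUP_SIZES = {"normal": 9, "RP": 16, "STGD": 14, "OMD": 11}

#: Age distributions per group: (mean, sd), truncated to [18, 90] years.
DEFAULT_AGES = {
    "normal": (35.33, 14.48),
    "RP": (40.06, 16.40),
    "STGD": (47.20, 12.50),
    "OMD": (52.45, 14.66),
}

#: Default inter-feature correlation shared by all groups: L/M defects at the
#: same temporal band are nearly collinear (common postreceptoral pathway),
#: low and high bands within a cone class correlate strongly, and S-cone and
#: rod losses travel together.
DEFAULT_CORRELATION = np.array([
    #  Ll    Lh    Ml    Mh    S     R
    [1.00, 0.65, 0.90, 0.60, 0.35, 0.30],
    [0.65, 1.00, 0.60, 0.85, 0.35, 0.35],
    [0.90, 0.60, 1.00, 0.65, 0.35, 0.30],
    [0.60, 0.85, 0.65, 1.00, 0.35, 0.35],
    [0.35, 0.35, 0.35, 0.35, 1.00, 0.60],
    [0.30, 0.35, 0.30, 0.35, 0.60, 1.00],
])


@dataclass
class PhenotypeTemplate:
    """Band-level defect distribution of one diagnostic group (dB).

    ``band_defect_mean``/``band_defect_sd`` follow :data:`MD_FEATURES` order.
    An optional second mixture component (same correlation structure) models
    bimodal groups; ``mixture_weight`` is the probability of the second
    component.
    """

    group: str
    band_defect_mean: np.ndarray
    band_defect_sd: np.ndarray
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    mixture_weight: float = 0.0
    band_defect_mean2: np.ndarray | None = None
    band_defect_sd2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.band_defect_mean = np.asarray(self.band_defect_mean, dtype=float)
        self.band_defect_sd = np.asarray(self.band_defect_sd, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.band_defect_mean.shape != (6,) or self.band_defect_sd.shape != (6,):
            raise ValueError("templates need six band means and six band sds")
        if np.any(self.band_defect_sd < 0):
            raise ValueError("band sds must be >= 0")
        c = self.correlation
        if c.shape != (6, 6) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation must be symmetric 6x6 with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must be in [0, 1]")
        if self.mixture_weight > 0 and self.band_defect_mean2 is None:
            raise ValueError("second mixture component requires band_defect_mean2")
        if self.band_defect_mean2 is not None:
            self.band_defect_mean2 = np.asarray(self.band_defect_mean2, dtype=float)
            self.band_defect_sd2 = np.asarray(
                self.band_defect_sd if self.band_defect_sd2 is None else self.band_defect_sd2,
                dtype=float)

    def covariance(self, component: int = 0) -> np.ndarray:
        sd = self.band_defect_sd if component == 0 else self.band_defect_sd2
        return np.outer(sd, sd) * self.correlation


def default_templates() -> dict[str, PhenotypeTemplate]:
    """Baseline study conditions: unimodal templates per diagnostic group."""
    spec = {
        #         LMD_low LMD_high MMD_low MMD_high  SMD   RMD
        "normal": ((1.2, 0.8, 1.2, 0.8, 0.5, 1.2),
                   (0.5, 0.5, 0.5, 0.5, 0.6, 0.35)),
        "RP":     ((-2.4, -1.9, -2.4, -1.9, -5.4, -4.1),
                   (0.8, 0.75, 0.8, 0.75, 1.25, 1.0)),
        "STGD":   ((-4.1, -3.5, -4.1, -3.5, -2.3, -2.1),
                   (0.7, 0.7, 0.7, 0.7, 1.0, 0.75)),
        "OMD":    ((-8.0, -4.5, -8.0, -4.5, -2.9, 1.2),
                   (1.2, 1.0, 1.2, 1.0, 1.0, 0.35)),
    }
    return {g: PhenotypeTemplate(group=g, band_defect_mean=m, band_defect_sd=s)
            for g, (m, s) in spec.items()}


def bimodal_templates() -> dict[str, PhenotypeTemplate]:
    """Variant conditions with the bimodal subgroups seen clinically:
    an RP subset with deep red-green loss and an OMD subset with
    dichromat-like colour discrimination (LMD_low below -10 dB)."""
    t = default_templates()
    rp = t["RP"]
    t["RP"] = PhenotypeTemplate(
        group="RP", band_defect_mean=rp.band_defect_mean, band_defect_sd=rp.band_defect_sd,
        correlation=rp.correlation, mixture_weight=0.3,
        band_defect_mean2=np.array([-7.0, -4.0, -7.0, -4.0, -5.8, -7.0]),
        band_defect_sd2=np.array([1.2, 1.0, 1.2, 1.0, 1.5, 1.3]))
    omd = t["OMD"]
    t["OMD"] = PhenotypeTemplate(
        group="OMD", band_defect_mean=omd.band_defect_mean, band_defect_sd=omd.band_defect_sd,
        correlation=omd.correlation, mixture_weight=0.18,
        band_defect_mean2=np.array([-12.0, -6.0, -12.0, -6.0, -2.0, 1.2]),
        band_defect_sd2=np.array([1.2, 1.0, 1.2, 1.0, 0.9, 0.35]))
    return t


@dataclass
class SimObserver:
    """One simulated patient: latent truth the staircases try to estimate."""

    patient_id: str
    group: str
    age_years: float
    band_defects: np.ndarray          # six values, MD_FEATURES order (dB)
    true_defect: dict[str, np.ndarray]  # receptor -> defect at the 9 frequencies
    psychometric_slope: float = 8.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must be in [0, 0.1]")


#: Band membership used when expanding band defects to frequencies.  16 Hz is
#: flicker-mediated like the rest of the high band even though the default MD
#: high band excludes it.
_EXPAND_BANDS = {
    "L": {1: 0, 2: 0, 4: 0, 6: 0, 8: 1, 10: 1, 12: 1, 16: 1, 20: 1},
    "M": {1: 2, 2: 2, 4: 2, 6: 2, 8: 3, 10: 3, 12: 3, 16: 3, 20: 3},
    "S": {f: 4 for f in PROTOCOL_FREQUENCIES_HZ},
    "rod": {f: 5 for f in PROTOCOL_FREQUENCIES_HZ},
}


def expand_band_defects(band_defects: np.ndarray, rng: np.random.Generator,
                        within_band_jitter_db: float = 0.3) -> dict[str, np.ndarray]:
    """Constant-within-band per-frequency defects plus small jitter."""
    out = {}
    for receptor in RECEPTOR_NAMES:
        idx = np.array([_EXPAND_BANDS[receptor][f] for f in PROTOCOL_FREQUENCIES_HZ])
        base = band_defects[idx]
        jitter = rng.normal(0.0, within_band_jitter_db, size=base.shape)
        # Keep the band average at the drawn band value: centre the jitter.
        for b in np.unique(idx):
            sel = idx == b
            jitter[sel] -= jitter[sel].mean()
        out[receptor] = base + jitter
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_cohort(templates: dict[str, PhenotypeTemplate] | None = None,
                    group_sizes: dict[str, int] | None = None,
                    normative: NormativeModel | None = None,
                    seed: int | np.random.SeedSequence = 0,
                    within_band_jitter_db: float = 0.3,
                    psychometric_slope: float = 8.0,
                    lapse_rate: float = 0.02) -> list[SimObserver]:
    """Draw a reproducible cohort of :class:`SimObserver` from the templates."""
    templates = default_templates() if templates is None else templates
    group_sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    normative = default_normative_model() if normative is None else normative
    rng = np.random.default_rng(seed)
    observers: list[SimObserver] = []
    counter = 0
    for group in GROUPS:
        n = int(group_sizes.get(group, 0))
        if n < 0:
            raise ValueError("group sizes must be >= 0")
        if n == 0:
            continue
        if group not in templates:
            raise ValueError(f"no template for requested group {group!r}")
        t = templates[group]
        age_mean, age_sd = DEFAULT_AGES[group]
        lo, hi = normative.age_window
        for _ in range(n):
            counter += 1
            use_second = t.mixture_weight > 0 and rng.random() < t.mixture_weight
            mean = t.band_defect_mean2 if use_second else t.band_defect_mean
            cov = t.covariance(component=1 if use_second else 0)
            try:
                band = rng.multivariate_normal(mean, cov, method="cholesky")
            except np.linalg.LinAlgError:  # semidefinite (e.g. zero sds)
                band = rng.multivariate_normal(mean, cov, method="eigh")
            age = _truncated_normal(rng, age_mean, age_sd, lo, hi)
            observers.append(SimObserver(
                patient_id=f"P{counter:03d}", group=group, age_years=age,
                band_defects=band,
                true_defect=expand_band_defects(band, rng, within_band_jitter_db),
                psychometric_slope=psychometric_slope, lapse_rate=lapse_rate))
    return observers


@dataclass
class StaircaseResult:
    receptor: str
    frequency_hz: float
    threshold_contrast: float
    censored: bool
    n_trials: int
    seed: int


def _run_track(rng: np.random.Generator, true_threshold: float, start: float,
               max_contrast: float, slope: float, lapse: float,
               n_reversals: int = 8, max_trials: int = 80) -> tuple[list[float], int]:
    """One 1-up/1-down track in log-contrast with halving step sizes."""
    floor = max_contrast * 1e-3
    level = float(np.clip(start, floor, max_contrast))
    step_db = 4.0
    last_direction = 0
    reversals: list[float] = []
    trials = 0
    while trials < max_trials and len(reversals) < n_reversals:
        trials += 1
        p = (1.0 - lapse) / (1.0 + np.exp(-slope * np.log(level / true_threshold)))
        detected = rng.random() < p
        direction = -1 if detected else +1
        if last_direction != 0 and direction != last_direction:
            reversals.append(level)
            step_db = max(1.0, step_db / 2.0)
        last_direction = direction
        level = float(np.clip(level * 10.0 ** (direction * step_db / 20.0),
                              floor, max_contrast))
    return reversals, trials


def simulate_staircase(true_threshold: float, max_contrast: float,
                       slope: float = 8.0, lapse: float = 0.02,
                       seed: int | np.random.SeedSequence = 0,
                       receptor: str = "L", frequency_hz: float = 1.0) -> StaircaseResult:
    """Two randomly interleaved staircases against a logistic observer.

    One track starts at the maximal producible contrast, the other at
    (effectively) zero contrast.  Each track is a 1-up/1-down rule on log
    contrast with step sizes halving from 4 dB to 1 dB at reversals; the
    threshold estimate is the geometric mean of the late reversal levels of
    both tracks.  If the estimate reaches the device maximum the result is
    censored and the maximum is reported as the conservative threshold.
    """
    if true_threshold <= 0:
        raise ValueError("true_threshold must be > 0")
    if not 0 < max_contrast <= 1:
        raise ValueError("max_contrast must be in (0, 1]")
    seed_int = int(np.random.default_rng(seed).integers(2 ** 31)) if not isinstance(seed, int) else seed
    rng = np.random.default_rng(seed_int)
    levels: list[float] = []
    total_trials = 0
    for start in (max_contrast, 0.0):
        reversals, trials = _run_track(rng, true_threshold, start, max_contrast, slope, lapse)
        total_trials += trials
        if len(reversals) >= 4:
            levels.extend(reversals[-6:])
        else:  # track never converged: pinned at a rail
            levels.append(max_contrast if start == max_contrast else max_contrast)
    est = float(np.exp(np.mean(np.log(levels))))
    censored = est >= max_contrast * (1.0 - 1e-9)
    return StaircaseResult(receptor=receptor, frequency_hz=frequency_hz,
                           threshold_contrast=max_contrast if censored else est,
                           censored=censored, n_trials=total_trials, seed=seed_int)


def true_threshold_contrast(observer: SimObserver, normative: NormativeModel,
                            receptor: str, freq_index: int) -> float:
    """Latent threshold contrast from the defect and the age norm."""
    f = PROTOCOL_FREQUENCIES_HZ[freq_index]
    sens = normative.norm_db(receptor, f, observer.age_years) + observer.true_defect[receptor][freq_index]
    return float(10.0 ** (-sens / 10.0))


def measure_cohort(observers: list[SimObserver],
                   max_contrasts: dict[str, float],
                   normative: NormativeModel | None = None,
                   frequencies_hz: tuple = PROTOCOL_FREQUENCIES_HZ,
                   n_eyes: int = 1, sessions_per_eye: int = 1,
                   seed: int | np.random.SeedSequence = 0,
                   method: str = "staircase",
                   ideal_noise_db: float = 0.5,
                   eye_noise_db: float = 0.0) -> pd.DataFrame:
    """Simulate the full measurement protocol; returns the long raw table.

    One row per observer x eye x session x receptor x frequency.  With
    ``method="staircase"`` every threshold runs the two-track adaptive
    procedure; ``method="ideal"`` replaces it by an unbiased estimate with
    Gaussian noise of ``ideal_noise_db`` on the dB scale (fast path for
    large simulation studies).  Both apply the floor rule: estimates at or
    above the device maximum are censored at the maximum.
    """
    if method not in ("staircase", "ideal"):
        raise ValueError("method must be 'staircase' or 'ideal'")
    normative = default_normative_model() if normative is None else normative
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    rows = []
    for obs in observers:
        for eye in range(1, n_eyes + 1):
            # Second-eye measurements share the latent observer; optional
            # small systematic inter-eye offset plus independent noise.
            eye_offset = rng.normal(0.0, eye_noise_db) if n_eyes > 1 else 0.0
            for session in range(1, sessions_per_eye + 1):
                for receptor in RECEPTOR_NAMES:
                    cmax = float(max_contrasts[receptor])
                    for k, f in enumerate(frequencies_hz):
                        idx = PROTOCOL_FREQUENCIES_HZ.index(f)
                        sens_true = (normative.norm_db(receptor, f, obs.age_years)
                                     + obs.true_defect[receptor][idx] + eye_offset)
                        c_true = 10.0 ** (-sens_true / 10.0)
                        if method == "staircase":
                            res = simulate_staircase(
                                c_true, cmax, obs.psychometric_slope, obs.lapse_rate,
                                seed=int(rng.integers(2 ** 31)),
                                receptor=receptor, frequency_hz=f)
                            c_est, censored = res.threshold_contrast, res.censored
                        else:
                            sens_est = sens_true + rng.normal(0.0, ideal_noise_db)
                            c_est = 10.0 ** (-sens_est / 10.0)
                            censored = c_est >= cmax
                            if censored:
                                c_est = cmax
                        rows.append((obs.patient_id, obs.group, obs.age_years, eye,
                                     session, receptor, f, c_est, censored, c_true))
    return pd.DataFrame(rows, columns=[
        "patient_id", "group", "age", "eye", "session", "receptor",
        "frequency_hz", "threshold_contrast", "censored", "true_contrast"])
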