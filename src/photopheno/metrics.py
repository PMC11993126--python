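"""From raw thresholds to six-dimensional mean-defect (MD) profiles.

Sensitivity is ``10 * log10(1 / C_threshold)`` dB.  Defects are sensitivity
minus the age-correlated norm (negative = loss).  Per-frequency defects are
averaged over fixed temporal-frequency bands, each dominated by a single
postreceptoral pathway:

* ``LMD_low`` / ``MMD_low``  -- L/M cones at 1, 2, 4, 6 Hz (parvocellular,
  red-green opponency),
* ``LMD_high`` / ``MMD_high`` -- L/M cones at 8, 10, 12, 20 Hz
  (magnocellular, achromatic flicker),
* ``SMD`` -- S-cones at 1, 2, 4, 6 Hz (koniocellular),
* ``RMD`` -- rods at 6, 8, 10, 12 Hz.

Missing frequencies are simply dropped from the band mean; censored
thresholds enter at their conservative floor value and are counted.
Repeated sessions are averaged within each eye, then across eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MD_FEATURES
from .normative import NormativeModel, default_normative_model

#: Default band membership per MD feature: (receptor, frequencies).
DEFAULT_BANDS: dict[str, tuple[str, tuple[int, ...]]] = {
    "LMD_low": ("L", (1, 2, 4, 6)),
    "LMD_high": ("L", (8, 10, 12, 20)),
    "MMD_low": ("M", (1, 2, 4, 6)),
    "MMD_high": ("M", (8, 10, 12, 20)),
    "SMD": ("S", (1, 2, 4, 6)),
    "RMD": ("rod", (6, 8, 10, 12)),
}


def contrast_to_db(c: float | np.ndarray) -> float | np.ndarray:
    """Sensitivity in dB from a Michelson threshold contrast in (0, 1]."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0) or np.any(c > 1):
        raise ValueError("threshold contrast must be in (0, 1]")
    out = 10.0 * np.log10(1.0 / c)
    return float(out) if out.ndim == 0 else out


@dataclass
class TCSCurve:
    """Measured sensitivities (dB) vs temporal frequency for one receptor."""

    receptor: str
    frequency_hz: np.ndarray
    sensitivity_db: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.sensitivity_db = np.asarray(self.sensitivity_db, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (self.frequency_hz.shape == self.sensitivity_db.shape == self.censored.shape):
            raise ValueError("frequency, sensitivity and censored must align")
        if not np.all(np.isfinite(self.sensitivity_db)):
            raise ValueError("sensitivities must be finite")


def defect_curve(tcs: TCSCurve, norm: NormativeModel, age_years: float) -> pd.DataFrame:
    """Per-frequency defects: measured minus age-normative sensitivity."""
    defects = np.array([
        s - norm.norm_db(tcs.receptor, f, age_years)
        for f, s in zip(tcs.frequency_hz, tcs.sensitivity_db)])
    return pd.DataFrame({
        "receptor": tcs.receptor,
        "frequency_hz": tcs.frequency_hz,
        "defect_db": defects,
        "censored": tcs.censored,
    })


@dataclass
class MDProfile:
    """The six MD features of one patient (or one eye/session thereof)."""

    patient_id: str
    values: dict[str, float]
    n_censored_inputs: dict[str, int] = field(default_factory=dict)
    group: str | None = None
    age_years: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.values.get(f, np.nan) for f in MD_FEATURES])

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.as_array())))


def compute_md_profile(defects: pd.DataFrame, patient_id: str = "",
                       bands: dict | None = None, group: str | None = None,
                       age_years: float | None = None) -> MDProfile:
    """Band averages of per-frequency defects.

    ``defects`` is a frame with columns receptor, frequency_hz, defect_db,
    censored (the output of :func:`defect_curve`, possibly concatenated over
    receptors).  A feature whose band has no measured frequency at all is
    returned as NaN ("missing"); otherwise it is the plain mean of whatever
    band frequencies are present, censored values included at their
    conservative floor defects.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    values: dict[str, float] = {}
    ncens: dict[str, int] = {}
    for feature, (receptor, freqs) in bands.items():
        sel = defects[(defects["receptor"] == receptor)
                      & defects["frequency_hz"].isin(freqs)
                      & np.isfinite(defects["defect_db"])]
        if len(sel) == 0:
            values[feature] = float("nan")
            ncens[feature] = 0
        else:
            values[feature] = float(sel["defect_db"].mean())
            ncens[feature] = int(sel["censored"].sum())
    return MDProfile(patient_id=patient_id, values=values, n_censored_inputs=ncens,
                     group=group, age_years=age_years)


def aggregate_patient(profiles: list[MDProfile], eyes: list[int] | None = None) -> MDProfile:
    """Two-stage mean: average sessions within each eye, then across eyes.

    ``eyes[i]`` labels the eye of ``profiles[i]``; omitted means one eye.
    NaN features propagate through plain means (a feature missing in any
    averaged session stays conservative: we use nan-aware means so a feature
    present in at least one session contributes).
    """
    if not profiles:
        raise ValueError("aggregate_patient needs at least one profile")
    pid = profiles[0].patient_id
    if any(p.patient_id != pid for p in profiles):
        raise ValueError("all profiles must share one patient_id")
    eyes = [1] * len(profiles) if eyes is None else list(eyes)
    if len(eyes) != len(profiles):
        raise ValueError("eyes must align with profiles")
    per_eye: dict[int, list[MDProfile]] = {}
    for e, p in zip(eyes, profiles):
        per_eye.setdefault(e, []).append(p)
    import warnings

    eye_means = []
    ncens: dict[str, int] = {f: 0 for f in MD_FEATURES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN feature slices
        for plist in per_eye.values():
            arr = np.vstack([p.as_array() for p in plist])
            eye_means.append(np.nanmean(arr, axis=0))
            for p in plist:
                for f in MD_FEATURES:
                    ncens[f] += p.n_censored_inputs.get(f, 0)
        final = np.nanmean(np.vstack(eye_means), axis=0)
    values = {f: float(v) for f, v in zip(MD_FEATURES, final)}
    first = profiles[0]
    return MDProfile(patient_id=pid, values=values, n_censored_inputs=ncens,
                     group=first.group, age_years=first.age_years)


def cohort_md_profiles(raw: pd.DataFrame, normative: NormativeModel | None = None,
                       bands: dict | None = None,
                       missing_policy: str = "drop") -> pd.DataFrame:
    """Full metrics pipeline on a long measurement table.

    Input columns: patient_id, group, age, eye, session, receptor,
    frequency_hz, threshold_contrast, censored.  Output: one row per
    patient with the six MD features (wide format).

    ``missing_policy``: "drop" removes patients with any fully missing
    feature; "impute" fills missing features with the cohort mean of that
    feature; "keep" leaves NaNs in place.
    """
    if missing_policy not in ("drop", "impute", "keep"):
        raise ValueError("missing_policy must be drop, impute or keep")
    normative = default_normative_model() if normative is None else normative
    raw = raw.copy()
    raw["sensitivity_db"] = contrast_to_db(raw["threshold_contrast"].to_numpy())

    out_rows = []
    for pid, g in raw.groupby("patient_id", sort=True):
        session_profiles = []
        session_eyes = []
        for (eye, session), gg in g.groupby(["eye", "session"], sort=True):
            age = float(gg["age"].iloc[0])
            defects = pd.DataFrame({
                "receptor": gg["receptor"].to_numpy(),
                "frequency_hz": gg["frequency_hz"].to_numpy(dtype=float),
                "defect_db": gg["sensitivity_db"].to_numpy()
                - np.array([normative.norm_db(r, f, age)
                            for r, f in zip(gg["receptor"], gg["frequency_hz"])]),
                "censored": gg["censored"].to_numpy(dtype=bool),
            })
            session_profiles.append(compute_md_profile(
                defects, patient_id=pid, bands=bands,
                group=str(g["group"].iloc[0]), age_years=age))
            session_eyes.append(int(eye))
        prof = aggregate_patient(session_profiles, session_eyes)
        row = {"patient_id": pid, "group": prof.group, "age": prof.age_years}
        row.update(prof.values)
        row.update({f"n_censored_{f}": prof.n_censored_inputs[f] for f in MD_FEATURES})
        out_rows.append(row)
    table = pd.DataFrame(out_rows)

    feat_cols = list(MD_FEATURES)
    if missing_policy == "drop":
        table = table.dropna(subset=feat_cols).reset_index(drop=True)
    elif missing_policy == "impute":
        for c in feat_cols:
            table[c] = table[c].fillna(table[c].mean())
    return table
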