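"""Age-normative temporal contrast sensitivity model.

Defects are defined against an age-correlated norm: for each receptor and
protocol frequency the model stores the expected sensitivity (dB) at a
reference age plus a linear ageing slope (dB per decade, negative = loss
with age).  The default coefficients describe plausible healthy tCS curves
on the modelled device -- low-pass for L/M, low sensitivities for S-cones,
band-pass peaking near 8-10 Hz for rods -- and the synthetic cohort
generator uses the *same* model, so simulated defects are exactly defined.
The coefficients are fully configurable (YAML) for use with real normative
data sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .fundamentals import RECEPTOR_NAMES
from .stimulus import PROTOCOL_FREQUENCIES_HZ

#: Default healthy sensitivities (dB) at the reference age, per receptor,
#: on the nine protocol frequencies (1, 2, 4, 6, 8, 10, 12, 16, 20 Hz).
_DEFAULT_INTERCEPTS = {
    "L":   [13.5, 14.0, 14.5, 14.0, 13.5, 13.0, 12.0, 10.5, 9.0],
    "M":   [13.0, 13.5, 14.0, 13.5, 13.0, 12.5, 11.5, 10.0, 8.5],
    "S":   [7.5, 7.5, 7.0, 6.5, 5.5, 4.5, 3.5, 2.5, 1.5],
    "rod": [8.0, 9.0, 10.0, 11.0, 11.5, 11.0, 10.0, 8.0, 6.0],
}

#: Default ageing slopes (dB per decade of age beyond the reference age).
_DEFAULT_SLOPES = {"L": -0.30, "M": -0.30, "S": -0.40, "rod": -0.50}


@dataclass
class NormativeModel:
    """Per receptor x frequency normative sensitivity with linear ageing."""

    intercept_db: dict[str, dict[float, float]]
    age_slope_db_per_decade: dict[str, float]
    reference_age_years: float = 40.0
    age_window: tuple[float, float] = (18.0, 90.0)

    def __post_init__(self) -> None:
        for r in RECEPTOR_NAMES:
            if r not in self.intercept_db:
                raise ValueError(f"normative model missing receptor {r!r}")
            freqs = set(self.intercept_db[r])
            if freqs != set(float(f) for f in PROTOCOL_FREQUENCIES_HZ):
                raise ValueError(
                    f"normative model for {r!r} must cover exactly the protocol "
                    f"frequencies {PROTOCOL_FREQUENCIES_HZ}")

    def norm_db(self, receptor: str, frequency_hz: float, age_years: float) -> float:
        """Expected healthy sensitivity (dB) at this age."""
        lo, hi = self.age_window
        if not lo <= age_years <= hi:
            raise ValueError(f"age {age_years} outside validity window [{lo}, {hi}]")
        try:
            base = self.intercept_db[receptor][float(frequency_hz)]
        except KeyError:
            raise KeyError(
                f"frequency {frequency_hz} Hz absent from normative model for {receptor!r}")
        decades = (age_years - self.reference_age_years) / 10.0
        return base + self.age_slope_db_per_decade[receptor] * decades

    def norm_array(self, receptor: str, age_years: float) -> np.ndarray:
        """Norms on the nine protocol frequencies, in protocol order."""
        return np.array([self.norm_db(receptor, f, age_years)
                         for f in PROTOCOL_FREQUENCIES_HZ])

    def to_yaml(self, path: str) -> None:
        doc = {
            "reference_age_years": self.reference_age_years,
            "age_window": list(self.age_window),
            "age_slope_db_per_decade": dict(self.age_slope_db_per_decade),
            "intercept_db": {r: {float(f): float(v) for f, v in d.items()}
                             for r, d in self.intercept_db.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "NormativeModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            intercept_db={r: {float(f): float(v) for f, v in d.items()}
                          for r, d in doc["intercept_db"].items()},
            age_slope_db_per_decade={r: float(v)
                                     for r, v in doc["age_slope_db_per_decade"].items()},
            reference_age_years=float(doc.get("reference_age_years", 40.0)),
            age_window=tuple(doc.get("age_window", (18.0, 90.0))),
        )


def default_normative_model() -> NormativeModel:
    intercepts = {r: {float(f): v for f, v in zip(PROTOCOL_FREQUENCIES_HZ, vals)}
                  for r, vals in _DEFAULT_INTERCEPTS.items()}
    return NormativeModel(intercept_db=intercepts,
                          age_slope_db_per_decade=dict(_DEFAULT_SLOPES))
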