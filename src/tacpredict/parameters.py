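"""The ten adjustable model parameters.

Six receptor densities (two index tumours, kidneys, liver, spleen, muscle
with fat), the serum flows of the two index tumours, and the shared sorting
and degradation rates.  All are positive scale quantities; fitting is done
on their logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical parameter ordering used throughout the package
PARAMETER_NAMES = (
    "rd_tumour1",
    "rd_tumour2",
    "rd_kidneys",
    "rd_liver",
    "rd_spleen",
    "rd_muscle_fat",
    "flow_tumour1",
    "flow_tumour2",
    "sorting_rate",
    "degradation_rate",
)

#: printed population spread of the fitted parameters (element-wise envelope
#: over the three reported estimation variants); used as sampling ranges for
#: virtual patients and as the default multi-start box.  Receptor densities
#: nmol/L, flows 1/s, sorting and degradation 1/s.
PARAMETER_RANGES: dict[str, tuple[float, float]] = {
    "rd_tumour1": (5.0, 120.0),
    "rd_tumour2": (5.0, 120.0),
    "rd_kidneys": (4.0, 10.1),
    "rd_liver": (1.0, 5.0),
    "rd_spleen": (4.0, 15.0),
    "rd_muscle_fat": (0.1, 1.5),
    "flow_tumour1": (0.05, 1.9),
    "flow_tumour2": (0.05, 1.9),
    "sorting_rate": (2.0e-3, 5.0e-3),
    "degradation_rate": (2.0e-5, 9.0e-5),
}

#: reported central values (data-based estimation variant); default initial guess
DEFAULT_PARAMETERS = {
    "rd_tumour1": 43.0,
    "rd_tumour2": 43.0,
    "rd_kidneys": 9.9,
    "rd_liver": 3.0,
    "rd_spleen": 11.0,
    "rd_muscle_fat": 0.3,
    "flow_tumour1": 0.4,
    "flow_tumour2": 0.4,
    "sorting_rate": 2.8e-3,
    "degradation_rate": 8.5e-5,
}


@dataclass(frozen=True)
class FitParameters:
    """Exactly ten strictly positive scalars (see PARAMETER_NAMES)."""

    rd_tumour1: float
    rd_tumour2: float
    rd_kidneys: float
    rd_liver: float
    rd_spleen: float
    rd_muscle_fat: float
    flow_tumour1: float
    flow_tumour2: float
    sorting_rate: float
    degradation_rate: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"fit parameter {name!r} must be strictly positive")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "FitParameters":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAMETER_NAMES),):
            raise ValueError("expected exactly 10 parameter values")
        return cls(**dict(zip(PARAMETER_NAMES, values)))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "FitParameters":
        return cls(**{n: float(d[n]) for n in PARAMETER_NAMES})

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAMETER_NAMES}

    @classmethod
    def default(cls) -> "FitParameters":
        return cls.from_dict(DEFAULT_PARAMETERS)

    def receptor_density(self, organ: str) -> float:
        """Receptor density for a fitted organ, with the lumped-lesion rule:
        liver and rest-of-body lesions use the mean of the two index tumours."""
        if organ in ("tumour_liver", "tumour_rob"):
            return 0.5 * (self.rd_tumour1 + self.rd_tumour2)
        return getattr(self, f"rd_{organ}")

    def tumour_flow(self, organ: str) -> float:
        if organ in ("tumour_liver", "tumour_rob"):
            return 0.5 * (self.flow_tumour1 + self.flow_tumour2)
        return getattr(self, f"flow_{organ}")
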