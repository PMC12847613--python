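"""Patient-level fixed quantities: anthropometry, organ volumes, dosing.

These are the measured, non-fitted inputs of the model: body size, GFR,
the organ and lesion volumes segmented from imaging, and the administration
schedule of the diagnostic injection and the therapeutic infusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import LiteratureConstants, AVOGADRO

#: regions whose volumes are measured per patient
MEASURED_VOLUME_REGIONS = ("kidneys", "spleen", "liver", "tumour1", "tumour2")

#: lesion volume below which a tumour is not modelled individually
MIN_MODELLED_TUMOUR_VOLUME_L = 0.005


class ConfigurationError(ValueError):
    """Missing or inconsistent patient configuration."""


@dataclass(frozen=True)
class DoseEvent:
    """One administration: bolus (duration 0) or constant-rate infusion.

    Amounts are peptide amounts in nmol; the labelled amount determines the
    administered activity through the nuclide's decay constant.
    """

    start_min: float
    duration_min: float
    labelled_nmol: float
    unlabelled_nmol: float
    nuclide: str

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ConfigurationError("event duration must be >= 0")
        if self.labelled_nmol < 0 or self.unlabelled_nmol < 0:
            raise ConfigurationError("administered amounts must be >= 0")

    @property
    def total_nmol(self) -> float:
        return self.labelled_nmol + self.unlabelled_nmol

    @property
    def labelled_fraction(self) -> float:
        return self.labelled_nmol / self.total_nmol if self.total_nmol > 0 else 0.0

    def administered_activity_mbq(self, constants: LiteratureConstants) -> float:
        """Activity at administration implied by the labelled amount."""
        nuc = constants.nuclides[self.nuclide]
        return self.labelled_nmol * nuc.mbq_per_nmol


@dataclass
class DosingSchedule:
    events: list[DoseEvent]

    def __post_init__(self) -> None:
        starts = [e.start_min for e in self.events]
        if starts != sorted(starts):
            raise ConfigurationError("dose events must be time-ordered")

    @property
    def end_min(self) -> float:
        return max((e.start_min + e.duration_min for e in self.events), default=0.0)

    def administered_nmol(self, t_min: float) -> list[float]:
        """Cumulative administered total peptide per event at time t."""
        out = []
        for e in self.events:
            if t_min <= e.start_min:
                out.append(0.0)
            elif e.duration_min == 0 or t_min >= e.start_min + e.duration_min:
                out.append(e.total_nmol)
            else:
                out.append(e.total_nmol * (t_min - e.start_min) / e.duration_min)
        return out

    def event_for_nuclide(self, nuclide: str) -> DoseEvent:
        for e in self.events:
            if e.nuclide == nuclide:
                return e
        raise KeyError(f"no dose event for nuclide {nuclide!r}")


def body_surface_area_m2(weight_kg: float, height_cm: float) -> float:
    """DuBois-DuBois body surface area."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


@dataclass
class PatientPhysiology:
    """Fixed, measured per-patient quantities.

    ``gfr_ml_min_1p73m2`` is the body-surface-normalised GFR; the absolute
    filtration flow used by the kidney submodel is obtained by scaling with
    the DuBois body surface area.  ``tumour_liver_fraction`` is the fraction
    of the total tumour burden located in the liver, per phase.
    """

    weight_kg: float
    height_cm: float
    gfr_ml_min_1p73m2: float
    volumes_l: dict[str, float]
    total_tumour_volume_l: float = 0.0
    tumour_liver_fraction: dict[str, float] = field(
        default_factory=lambda: {"diagnostic": 0.02, "therapeutic": 0.08}
    )
    serum_volume_l: float | None = None  # haematocrit-adjusted; default from weight

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ConfigurationError("body weight and height must be positive")
        if self.gfr_ml_min_1p73m2 <= 0:
            raise ConfigurationError("GFR must be positive")
        for region in MEASURED_VOLUME_REGIONS:
            if region not in self.volumes_l:
                raise ConfigurationError(f"missing organ volume for region {region!r}")
            if self.volumes_l[region] <= 0:
                raise ConfigurationError(f"non-positive volume for region {region!r}")
        for tu in ("tumour1", "tumour2"):
            if self.volumes_l[tu] < MIN_MODELLED_TUMOUR_VOLUME_L:
                raise ConfigurationError(
                    f"{tu} volume {self.volumes_l[tu]} L below the 5 mL modelling threshold"
                )
        if self.total_tumour_volume_l <= 0:
            self.total_tumour_volume_l = (
                self.volumes_l["tumour1"] + self.volumes_l["tumour2"]
            )
        for phase, frac in self.tumour_liver_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"tumour_liver_fraction[{phase}] outside [0, 1]")

    @property
    def bsa_m2(self) -> float:
        return body_surface_area_m2(self.weight_kg, self.height_cm)

    @property
    def gfr_l_min(self) -> float:
        """Absolute GFR in L/min."""
        return self.gfr_ml_min_1p73m2 * (self.bsa_m2 / 1.73) / 1000.0

    def serum_volume(self, constants: LiteratureConstants) -> float:
        if self.serum_volume_l is not None:
            return self.serum_volume_l
        return constants.serum_volume_l_per_kg * self.weight_kg

    def derived_tumour_volumes(self) -> dict[str, float]:
        """Volumes of the lumped liver / rest-of-body lesions.

        The therapeutic tumour-in-liver fraction applies for the whole
        simulation; the diagnostic fraction is metadata only.
        """
        v_tul = self.tumour_liver_fraction["therapeutic"] * self.total_tumour_volume_l
        v_rest = self.total_tumour_volume_l - self.volumes_l["tumour1"] - self.volumes_l["tumour2"] - v_tul
        floor = 1e-4  # 0.1 mL floor keeps lumped compartments well-posed
        return {"tumour_liver": max(v_tul, floor), "tumour_rob": max(v_rest, floor)}


def study_dosing(
    *,
    diagnostic_labelled_nmol: float = 1.7e-3,
    diagnostic_unlabelled_nmol: float = 13.0,
    therapy_labelled_nmol: float = 10.28,
    therapy_unlabelled_nmol: float = 123.0,
    infusion_start_min: float = 10080.0,
    infusion_duration_min: float = 36.0,
) -> DosingSchedule:
    """The study timeline: diagnostic bolus at t = 0, therapy infusion on day 7."""
    return DosingSchedule(
        events=[
            DoseEvent(0.0, 0.0, diagnostic_labelled_nmol, diagnostic_unlabelled_nmol, "ga68"),
            DoseEvent(
                infusion_start_min,
                infusion_duration_min,
                therapy_labelled_nmol,
                therapy_unlabelled_nmol,
                "lu177",
            ),
        ]
    )
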