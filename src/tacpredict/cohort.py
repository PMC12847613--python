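"""Seeded virtual patients mirroring the study's sampling design.

Each virtual patient gets physiology drawn log-uniformly within the
reported population ranges, true model parameters drawn log-uniformly
within the reported fitted-parameter spread, the study dosing timeline
(diagnostic bolus at t = 0, therapeutic infusion on day 7), and a noisy
measurement set with the study's schedule: one diagnostic PET at ~63 min
(5 organ + 3 tumour values) and therapeutic planar/SPECT measurements at
1 h, 1 d, 4 d and 7 d after the infusion start (24 organ + 9 tumour
values).  Noise is multiplicative Gaussian with a class-specific
proportionality constant, y = f * (1 + b * eps); non-positive draws are
redrawn (no point mass at zero).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .constants import LiteratureConstants, DEFAULT_CONSTANTS
from .measurements import MeasurementSet, measurement_set_from_records
from .parameters import FitParameters, PARAMETER_NAMES, PARAMETER_RANGES
from .pbpk import build_model, simulate, Trajectory, default_output_grid
from .physiology import PatientPhysiology, DosingSchedule, DoseEvent

DIAGNOSTIC_ORGAN_REGIONS = ("kidneys", "liver", "spleen", "muscle_fat", "whole_body")
DIAGNOSTIC_TUMOUR_REGIONS = ("tumour1", "tumour2", "tumour_liver")
PLANAR_ORGAN_REGIONS = ("kidneys", "liver", "spleen", "muscle_fat", "whole_body")
PLANAR_TUMOUR_REGIONS = ("tumour1", "tumour2")
SPECT_ORGAN_REGIONS = ("kidneys", "liver", "spleen", "whole_body")
SPECT_TUMOUR_REGIONS = ("tumour1",)

#: offsets of the therapeutic measurements from the infusion start (min)
PLANAR_OFFSETS_MIN = (60.0, 1440.0, 5760.0, 10080.0)
SPECT_OFFSET_MIN = 1440.0


@dataclass
class CohortConfig:
    """Sampling ranges (population min/max) and the measurement design."""

    n_patients: int = 12
    seed: int = 0
    # physiology ranges
    weight_kg: tuple[float, float] = (56.0, 124.0)
    height_cm: tuple[float, float] = (157.0, 193.0)
    gfr_ml_min_1p73m2: tuple[float, float] = (60.0, 110.0)
    kidneys_l: tuple[float, float] = (0.20, 0.41)
    spleen_l: tuple[float, float] = (0.07, 0.35)
    liver_l: tuple[float, float] = (1.25, 3.31)
    tumour_l: tuple[float, float] = (0.01, 0.06)
    total_tumour_l: tuple[float, float] = (0.03, 0.29)
    tumour_liver_fraction_ther: tuple[float, float] = (0.0099, 0.3573)
    tumour_liver_fraction_diag: tuple[float, float] = (1e-6, 0.1502)
    # dosing ranges
    diag_labelled_nmol: tuple[float, float] = (1.1e-3, 2.8e-3)
    diag_unlabelled_nmol: tuple[float, float] = (9.0, 36.0)
    ther_labelled_nmol: tuple[float, float] = (10.07, 10.37)
    ther_unlabelled_nmol: tuple[float, float] = (104.0, 141.0)
    infusion_duration_min: tuple[float, float] = (34.0, 38.0)
    infusion_start_min: float = 10080.0
    pet_time_min: float = 63.0
    # true parameter ranges (fitted-parameter population spread)
    parameter_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PARAMETER_RANGES)
    )
    # generative error constants per partition class
    b_true: dict[str, float] = field(
        default_factory=lambda: {
            "D_organ": 0.35,
            "D_tumour": 0.27,
            "T_organ": 0.16,
            "T_tumour": 0.39,
        }
    )

    def validate(self) -> None:
        for name, rng in vars(self).items():
            if isinstance(rng, tuple):
                lo, hi = rng
                if not (0 <= lo <= hi):
                    raise ValueError(f"degenerate sampling range for {name}: {rng}")
        for cls, b in self.b_true.items():
            if b <= 0:
                raise ValueError(f"b_true[{cls}] must be positive")


@dataclass
class VirtualPatient:
    patient_id: str
    physiology: PatientPhysiology
    true_parameters: FitParameters
    dosing: DosingSchedule
    measurements: MeasurementSet | None = None
    truth_values: np.ndarray | None = None  # noise-free f at the measurement records
    seed: int = 0
    n_redraws: int = 0


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def sample_patient(config: CohortConfig, index: int) -> VirtualPatient:
    """Draw one virtual patient; deterministic given (config.seed, index)."""
    config.validate()
    if not (0 <= index < config.n_patients):
        raise IndexError(f"patient index {index} outside cohort of {config.n_patients}")
    rng = np.random.default_rng([config.seed, index])

    v_tu1 = _loguniform(rng, *config.tumour_l)
    v_tu2 = _loguniform(rng, *config.tumour_l)
    total_tu = max(_loguniform(rng, *config.total_tumour_l), v_tu1 + v_tu2)
    phys = PatientPhysiology(
        weight_kg=_loguniform(rng, *config.weight_kg),
        height_cm=_loguniform(rng, *config.height_cm),
        gfr_ml_min_1p73m2=_loguniform(rng, *config.gfr_ml_min_1p73m2),
        volumes_l={
            "kidneys": _loguniform(rng, *config.kidneys_l),
            "spleen": _loguniform(rng, *config.spleen_l),
            "liver": _loguniform(rng, *config.liver_l),
            "tumour1": v_tu1,
            "tumour2": v_tu2,
        },
        total_tumour_volume_l=total_tu,
        tumour_liver_fraction={
            "diagnostic": _loguniform(rng, *config.tumour_liver_fraction_diag),
            "therapeutic": _loguniform(rng, *config.tumour_liver_fraction_ther),
        },
    )
    params = FitParameters.from_dict(
        {n: _loguniform(rng, *config.parameter_ranges[n]) for n in PARAMETER_NAMES}
    )
    dosing = DosingSchedule(
        events=[
            DoseEvent(
                0.0,
                0.0,
                _loguniform(rng, *config.diag_labelled_nmol),
                _loguniform(rng, *config.diag_unlabelled_nmol),
                "ga68",
            ),
            DoseEvent(
                config.infusion_start_min,
                _loguniform(rng, *config.infusion_duration_min),
                _loguniform(rng, *config.ther_labelled_nmol),
                _loguniform(rng, *config.ther_unlabelled_nmol),
                "lu177",
            ),
        ]
    )
    return VirtualPatient(
        patient_id=f"vp{index:03d}",
        physiology=phys,
        true_parameters=params,
        dosing=dosing,
        seed=config.seed,
    )


def measurement_schedule(config: CohortConfig) -> list[dict]:
    """The per-patient record skeleton of the study design (no values yet)."""
    rows = []

    def add(region, cls, phase, modality, t):
        rows.append(
            {
                "region": region,
                "tissue_class": cls,
                "phase": phase,
                "modality": modality,
                "time_min": t,
                "activity_MBq": np.nan,
            }
        )

    for r in DIAGNOSTIC_ORGAN_REGIONS:
        add(r, "organ", "diagnostic", "PET", config.pet_time_min)
    for r in DIAGNOSTIC_TUMOUR_REGIONS:
        add(r, "tumour", "diagnostic", "PET", config.pet_time_min)
    for off in PLANAR_OFFSETS_MIN:
        t = config.infusion_start_min + off
        for r in PLANAR_ORGAN_REGIONS:
            add(r, "organ", "therapeutic", "planar", t)
        for r in PLANAR_TUMOUR_REGIONS:
            add(r, "tumour", "therapeutic", "planar", t)
    t_spect = config.infusion_start_min + SPECT_OFFSET_MIN
    for r in SPECT_ORGAN_REGIONS:
        add(r, "organ", "therapeutic", "SPECT", t_spect)
    for r in SPECT_TUMOUR_REGIONS:
        add(r, "tumour", "therapeutic", "SPECT", t_spect)
    return rows


def simulate_measurements(
    patient: VirtualPatient,
    config: CohortConfig,
    seed: int,
    constants: LiteratureConstants = DEFAULT_CONSTANTS,
    truth: Trajectory | None = None,
    b_true: dict[str, float] | None = None,
) -> MeasurementSet:
    """Simulate the noise-free truth and overlay multiplicative noise.

    A precomputed truth trajectory may be passed to amortise the ODE solve
    across repeated noise realisations of the same patient.
    """
    b_true = dict(b_true or config.b_true)
    for cls, b in b_true.items():
        if b < 0:
            raise ValueError(f"b_true[{cls}] must be >= 0")
    rows = measurement_schedule(config)
    times = sorted({r["time_min"] for r in rows})
    if truth is None:
        model = build_model(patient.physiology, constants, patient.true_parameters)
        truth = simulate(
            model,
            patient.dosing,
            t_end=max(times),
            grid=np.array(times),
            rtol=1e-8,
            atol=1e-11,
        )
    rng = np.random.default_rng([seed, zlib.crc32(patient.patient_id.encode())])
    nuclide = {"diagnostic": "ga68", "therapeutic": "lu177"}
    f_true = np.empty(len(rows))
    n_redraws = 0
    for i, row in enumerate(rows):
        f = truth.activity_at(row["region"], row["time_min"], nuclide[row["phase"]])
        f_true[i] = f
        cls = ("D" if row["phase"] == "diagnostic" else "T") + "_" + row["tissue_class"]
        b = b_true[cls]
        if b == 0 or f == 0:
            y = f
        else:
            y = f * (1.0 + b * rng.standard_normal())
            while y <= 0:
                n_redraws += 1
                y = f * (1.0 + b * rng.standard_normal())
        row["activity_MBq"] = y
    ms = measurement_set_from_records(rows, infusion_start_min=config.infusion_start_min)
    patient.truth_values = f_true
    patient.n_redraws = n_redraws
    return ms


def generate_cohort(
    config: CohortConfig,
    constants: LiteratureConstants = DEFAULT_CONSTANTS,
) -> list[VirtualPatient]:
    """Sample and measure a full virtual cohort (deterministic in config.seed)."""
    patients = []
    for i in range(config.n_patients):
        p = sample_patient(config, i)
        p.measurements = simulate_measurements(p, config, seed=config.seed, constants=constants)
        patients.append(p)
    return patients
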