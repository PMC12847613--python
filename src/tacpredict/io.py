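"""File formats: per-patient YAML physiology/dosing, measurement CSV,
constants JSON, priors JSON, and the cohort manifest."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd
import yaml

from .constants import LiteratureConstants, DEFAULT_CONSTANTS
from .estimation import BayesPrior
from .measurements import MeasurementSet, MeasurementValidationError, COLUMNS
from .parameters import PARAMETER_NAMES
from .physiology import PatientPhysiology, DosingSchedule, DoseEvent
from .workflow import Cohort, PatientRecord

MEASUREMENT_HEADER = ["patient_id"] + COLUMNS


# -- measurements -----------------------------------------------------------

def read_measurements(path: str | Path, infusion_start_min: float | None = None) -> MeasurementSet:
    """Read a measurement CSV (header patient_id,region,tissue_class,phase,
    modality,time_min,activity_MBq); malformed rows raise with their line."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MEASUREMENT_HEADER if c not in df.columns]
    if missing:
        raise MeasurementValidationError(f"{path}: missing columns {missing}")
    try:
        table = df[COLUMNS].copy()
        table["time_min"] = table["time_min"].astype(float)
        table["activity_MBq"] = table["activity_MBq"].astype(float)
        return MeasurementSet(table, infusion_start_min=infusion_start_min)
    except MeasurementValidationError as exc:
        raise MeasurementValidationError(f"{path}: {exc}") from exc


def write_measurements(ms: MeasurementSet, patient_id: str, path: str | Path) -> None:
    out = ms.table[COLUMNS].copy()
    out.insert(0, "patient_id", patient_id)
    # %.17g round-trips float64 exactly
    out.to_csv(path, index=False, float_format="%.17g")


# -- physiology + dosing YAML ----------------------------------------------

def physiology_to_dict(phys: PatientPhysiology, dosing: DosingSchedule) -> dict:
    return {
        "weight_kg": float(phys.weight_kg),
        "height_cm": float(phys.height_cm),
        "gfr_ml_min_1p73m2": float(phys.gfr_ml_min_1p73m2),
        "volumes_l": {k: float(v) for k, v in phys.volumes_l.items()},
        "total_tumour_volume_l": float(phys.total_tumour_volume_l),
        "tumour_liver_fraction": {k: float(v) for k, v in phys.tumour_liver_fraction.items()},
        "dosing": [
            {
                "start_min": e.start_min,
                "duration_min": e.duration_min,
                "labelled_nmol": e.labelled_nmol,
                "unlabelled_nmol": e.unlabelled_nmol,
                "nuclide": e.nuclide,
            }
            for e in dosing.events
        ],
    }


def write_physiology(phys: PatientPhysiology, dosing: DosingSchedule, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(physiology_to_dict(phys, dosing), sort_keys=False))


def read_physiology(path: str | Path) -> tuple[PatientPhysiology, DosingSchedule]:
    raw = yaml.safe_load(Path(path).read_text())
    dosing = DosingSchedule(events=[DoseEvent(**e) for e in raw.pop("dosing")])
    phys = PatientPhysiology(**raw)
    return phys, dosing


# -- priors -----------------------------------------------------------------

def write_priors(priors: dict[str, BayesPrior], path: str | Path) -> None:
    payload = {
        pid: {"mean": p.mean, "sd": p.sd, "provenance": list(p.provenance)}
        for pid, p in priors.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_priors(path: str | Path) -> dict[str, BayesPrior]:
    payload = json.loads(Path(path).read_text())
    return {
        pid: BayesPrior(
            mean={k: float(v) for k, v in d["mean"].items()},
            sd={k: float(v) for k, v in d["sd"].items()},
            provenance=tuple(d.get("provenance", ())),
        )
        for pid, d in payload.items()
    }


# -- cohort manifest --------------------------------------------------------

@dataclass
class CohortManifest:
    patients: list[dict]  # id, physiology, measurements (paths)
    constants: str | None
    seed: int
    root: Path

    @classmethod
    def read(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        ids = [p["id"] for p in raw["patients"]]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate patient ids")
        return cls(
            patients=raw["patients"],
            constants=raw.get("constants"),
            seed=int(raw.get("seed", 0)),
            root=path.parent,
        )

    def load_cohort(self) -> Cohort:
        constants = (
            LiteratureConstants.from_json(self.root / self.constants)
            if self.constants
            else DEFAULT_CONSTANTS
        )
        records = []
        for entry in self.patients:
            pid = entry["id"]
            try:
                phys, dosing = read_physiology(self.root / entry["physiology"])
                infusion = dosing.event_for_nuclide("lu177").start_min
                ms = read_measurements(self.root / entry["measurements"], infusion_start_min=infusion)
            except FileNotFoundError as exc:
                raise FileNotFoundError(f"patient {pid!r}: {exc}") from exc
            records.append(PatientRecord(pid, phys, dosing, ms))
        return Cohort(patients=records, constants=constants)


def write_cohort(patients, out_dir: str | Path, constants: LiteratureConstants | None = None, seed: int = 0) -> Path:
    """Write per-patient YAML + CSV and a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for p in patients:
        phys_file = f"{p.patient_id}_physiology.yaml"
        meas_file = f"{p.patient_id}_measurements.csv"
        write_physiology(p.physiology, p.dosing, out / phys_file)
        write_measurements(p.measurements, p.patient_id, out / meas_file)
        entries.append({"id": p.patient_id, "physiology": phys_file, "measurements": meas_file})
    manifest: dict = {"patients": entries, "seed": seed}
    if constants is not None:
        constants.to_json(out / "constants.json")
        manifest["constants"] = "constants.json"
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def write_trajectory_csv(traj, regions, path: str | Path, nuclide: str | None = None) -> None:
    rows = []
    for region in regions:
        act = traj.activity_series(region, nuclide)
        for t, a in zip(traj.times, act):
            rows.append({"time_min": t, "region": region, "activity_MBq": a, "nuclide": nuclide or "all"})
    pd.DataFrame(rows).to_csv(path, index=False)
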