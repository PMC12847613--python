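"""Measured time-activity data with phase and tissue-class labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("diagnostic", "therapeutic")
TISSUE_CLASSES = ("organ", "tumour")
MODALITIES = ("PET", "SPECT", "planar")

COLUMNS = ["region", "tissue_class", "phase", "modality", "time_min", "activity_MBq"]


class MeasurementValidationError(ValueError):
    pass


@dataclass
class MeasurementSet:
    """A table of (t_i, y_i) pairs with region/phase/class/modality labels.

    Wraps a :class:`pandas.DataFrame` with the canonical columns; rows keep
    their file order.
    """

    table: pd.DataFrame
    infusion_start_min: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise MeasurementValidationError(f"missing columns: {missing}")
        t = self.table
        for col, allowed in (("phase", PHASES), ("tissue_class", TISSUE_CLASSES), ("modality", MODALITIES)):
            bad = ~t[col].isin(allowed)
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0])
                raise MeasurementValidationError(
                    f"row {line}: invalid {col} {t[col].iloc[line]!r} (allowed: {allowed})"
                )
        if (t["activity_MBq"] < 0).any():
            raise MeasurementValidationError("negative activity value")
        if self.infusion_start_min is not None:
            diag = t[t["phase"] == "diagnostic"]
            if (diag["time_min"] >= self.infusion_start_min).any():
                raise MeasurementValidationError(
                    "diagnostic measurement at or after the infusion start"
                )
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def times(self) -> np.ndarray:
        return self.table["time_min"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.table["activity_MBq"].to_numpy(dtype=float)

    def subset(self, *, phase: str | None = None, tissue_class: str | None = None) -> "MeasurementSet":
        t = self.table
        if phase is not None:
            t = t[t["phase"] == phase]
        if tissue_class is not None:
            t = t[t["tissue_class"] == tissue_class]
        return MeasurementSet(t.copy(), infusion_start_min=self.infusion_start_min)

    def class_labels(self, partition: str) -> np.ndarray:
        """Per-record partition-class key ('D'/'T' or 'D_organ', ...)."""
        phase_key = self.table["phase"].map({"diagnostic": "D", "therapeutic": "T"})
        if partition == "two_b":
            return phase_key.to_numpy()
        return (phase_key + "_" + self.table["tissue_class"]).to_numpy()


def measurement_set_from_records(records: list[dict], infusion_start_min: float | None = None) -> MeasurementSet:
    return MeasurementSet(pd.DataFrame.from_records(records, columns=COLUMNS), infusion_start_min)
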