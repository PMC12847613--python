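"""Time-integrated activity and prediction-error summaries.

TIA is the integral of a region's therapeutic time-activity curve over the
evaluation window (infusion start to the end of the simulation).  Predicted
and reference TIAs are compared by the relative prediction error
RPE = (TIA_pred - TIA_ref) / TIA_ref, summarised per tissue class by
median [min, max], mean, population SD, RMSE = sqrt(mean^2 + SD^2) and
MAPE = mean(|RPE|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .pbpk import Trajectory

__all__ = ["TIAResult", "tia", "rpe", "rmse", "mape", "summary_row", "evaluation_table"]

#: report rows, in table order; the two index tumours are pooled
REPORT_CLASSES = ("tumours", "kidney", "liver", "spleen")

REGION_TO_CLASS = {
    "tumour1": "tumours",
    "tumour2": "tumours",
    "kidneys": "kidney",
    "liver": "liver",
    "spleen": "spleen",
}


@dataclass(frozen=True)
class TIAResult:
    region: str
    tia_mbq_min: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.tia_mbq_min < 0:
            raise ValueError("TIA must be non-negative")


def tia(
    traj: Trajectory,
    region: str,
    window: tuple[float, float],
    nuclide: str = "lu177",
) -> TIAResult:
    """Adaptive quadrature of the region TAC over ``window`` (MBq * min)."""
    t0, t1 = window
    if not (traj.times[0] <= t0 <= t1 <= traj.times[-1]):
        raise ValueError(f"window {window} outside trajectory span")
    breakpoints = [b for b in (e.start_min for e in traj.dosing.events) if t0 < b < t1]
    for seg0, seg1, _ in traj._dense:
        if t0 < seg1 < t1:
            breakpoints.append(seg1)
    val, _ = quad(
        lambda t: traj.activity_dense(region, t, nuclide),
        t0,
        t1,
        points=sorted(set(breakpoints)) or None,
        limit=200,
    )
    return TIAResult(region=region, tia_mbq_min=max(val, 0.0), window=(t0, t1))


def rpe(tia_pred: float, tia_ref: float) -> float:
    """Signed relative prediction error (fraction)."""
    if tia_ref <= 0:
        raise ValueError("reference TIA must be positive")
    return (tia_pred - tia_ref) / tia_ref


def rmse(rpes) -> float:
    """sqrt(mean^2 + sd^2) of an RPE list, with population (1/M) sd."""
    r = np.asarray(list(rpes), dtype=float)
    if r.size == 0:
        raise ValueError("empty RPE list")
    return float(np.sqrt(np.mean(r) ** 2 + np.std(r) ** 2))


def mape(pairs) -> float:
    """Mean absolute percentage error over (TIA_pred, TIA_ref) pairs (fraction)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty TIA pair list")
    return float(np.mean([abs(rpe(p, r)) for p, r in pairs]))


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report formatting)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def summary_row(rpes) -> dict[str, float]:
    """Summary statistics of one tissue class's RPE list (all in fractions)."""
    r = np.asarray(list(rpes), dtype=float)
    return {
        "median": float(np.median(r)),
        "min": float(r.min()),
        "max": float(r.max()),
        "mean": float(r.mean()),
        "sd": float(np.std(r)),
        "rmse": rmse(r),
        "mape": float(np.mean(np.abs(r))),
    }


def evaluation_table(per_region_rpes: dict[str, list[float]]) -> pd.DataFrame:
    """Assemble the per-class evaluation report.

    ``per_region_rpes`` maps region ids (tumour1, tumour2, kidneys, liver,
    spleen) to RPE lists; index tumours are pooled into one 'tumours' class.
    Values are fractions; a '*_pct' integer-rounded view is appended.
    """
    pooled: dict[str, list[float]] = {c: [] for c in REPORT_CLASSES}
    for region, values in per_region_rpes.items():
        cls = REGION_TO_CLASS.get(region)
        if cls is not None:
            pooled[cls].extend(values)
    rows = {}
    for cls in REPORT_CLASSES:
        if pooled[cls]:
            rows[cls] = summary_row(pooled[cls])
    df = pd.DataFrame.from_dict(rows, orient="index")
    for col in df.columns:
        df[col + "_pct"] = [round_half_away(100.0 * v) for v in df[col]]
    df.index.name = "tissue"
    return df
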