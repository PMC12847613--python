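"""Population workflow: iterative error-constant estimation, leave-one-out
priors, reference fits, and single-time-point therapy prediction.

Three estimation variants are supported:

* Method I   - model-based proportional error, one b per phase (b_D, b_T);
* Method II  - model-based proportional error, phase x tissue-class split
  (b_D,organ, b_D,tumour, b_T,organ, b_T,tumour);
* Method III - as II but with the data-based error model; in prediction the
  diagnostic b classes are patient-specific (from the patient's own
  diagnostic residuals) while the therapeutic classes stay at the cohort
  median.

The iterative loop alternates, per patient, a diagnostic-only fit (yielding
b_D), a therapeutic-only fit (yielding b_T), and an all-data fit whose
estimates feed the next iteration's leave-one-out priors; cohort medians of
the per-patient b values close the loop.  Iteration stops when the
therapeutic-median fluctuation falls below a tolerance (default 0.005) or
at the iteration cap (default 28 for Method I; the four-b variants stop
after one iteration by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import LiteratureConstants, DEFAULT_CONSTANTS
from .errors import (
    ErrorModelSpec,
    PARTITION_CLASSES,
    estimate_b_data_based,
    estimate_b_model_based,
)
from .estimation import (
    BayesPrior,
    FitOptions,
    FitResult,
    PatientModelContext,
    fit_map,
)
from .measurements import MeasurementSet
from .metrics import TIAResult, evaluation_table, rpe, tia
from .parameters import FitParameters, PARAMETER_NAMES
from .pbpk import build_model, simulate
from .physiology import DosingSchedule, PatientPhysiology

METHOD_FAMILY = {"I": "model_based", "II": "model_based", "III": "data_based"}
METHOD_PARTITION = {"I": "two_b", "II": "four_b", "III": "four_b"}
METHOD_DEFAULT_MAX_ITER = {"I": 28, "II": 1, "III": 1}

#: regions whose TIA enters the evaluation tables
TIA_REGIONS = ("kidneys", "liver", "spleen", "tumour1", "tumour2")

DEFAULT_T_END_MIN = 40000.0


class ContaminationError(RuntimeError):
    """Therapeutic data reached a diagnostic-only prediction path."""


@dataclass
class PatientRecord:
    patient_id: str
    physiology: PatientPhysiology
    dosing: DosingSchedule
    measurements: MeasurementSet


@dataclass
class Cohort:
    patients: list[PatientRecord]
    constants: LiteratureConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    @classmethod
    def from_virtual(cls, patients, constants: LiteratureConstants = DEFAULT_CONSTANTS) -> "Cohort":
        return cls(
            patients=[
                PatientRecord(p.patient_id, p.physiology, p.dosing, p.measurements)
                for p in patients
            ],
            constants=constants,
        )


@dataclass
class BTrace:
    """Per-iteration b values and cohort medians of the estimation loop."""

    method: str
    per_patient: list[dict[str, dict[str, float]]] = field(default_factory=list)
    medians: list[dict[str, float]] = field(default_factory=list)
    fluctuations: list[float] = field(default_factory=list)
    converged: bool = False
    final_medians: dict[str, float] = field(default_factory=dict)
    final_priors: dict[str, BayesPrior] = field(default_factory=dict)
    final_estimates: dict[str, FitParameters] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.medians)


def lower_median(values) -> float:
    """Sample median with lower interpolation (tie-break convention)."""
    return float(np.percentile(np.asarray(list(values), dtype=float), 50, method="lower"))


def loo_priors(estimates: dict[str, FitParameters]) -> dict[str, BayesPrior]:
    """Leave-one-out priors: for each patient, mean/sd over all the others."""
    ids = list(estimates)
    if len(ids) < 2:
        raise ValueError("leave-one-out priors require at least 2 patients")
    arrays = {pid: estimates[pid].to_array() for pid in ids}
    priors = {}
    for pid in ids:
        others = np.array([arrays[q] for q in ids if q != pid])
        mean = others.mean(axis=0)
        sd = others.std(axis=0, ddof=1) if len(others) > 1 else np.zeros_like(mean)
        priors[pid] = BayesPrior(
            mean=dict(zip(PARAMETER_NAMES, mean)),
            sd=dict(zip(PARAMETER_NAMES, sd)),
            provenance=tuple(q for q in ids if q != pid),
        )
    return priors


def _b_estimator(method: str):
    return estimate_b_model_based if method in ("I", "II") else estimate_b_data_based


def _class_b(method: str, data: MeasurementSet, f: np.ndarray, phase_key: str) -> dict[str, float]:
    """Per-class b estimates from one fit's measured/model values."""
    partition = METHOD_PARTITION[method]
    estimator = _b_estimator(method)
    labels = data.class_labels(partition)
    out = {}
    for cls in PARTITION_CLASSES[partition]:
        if not cls.startswith(phase_key):
            continue
        mask = labels == cls
        if mask.any():
            out[cls] = estimator(data.values[mask], f[mask])
    return out


def _contexts(cohort: Cohort, options: FitOptions) -> dict[str, PatientModelContext]:
    return {
        p.patient_id: PatientModelContext(
            p.physiology, cohort.constants, p.dosing, rtol=options.rtol, atol=options.atol
        )
        for p in cohort.patients
    }


def bootstrap_estimates(
    cohort: Cohort,
    method: str,
    b_init: float = 0.2,
    options: FitOptions | None = None,
    contexts: dict[str, PatientModelContext] | None = None,
) -> dict[str, FitParameters]:
    """Initial all-data fits (uniform b, no prior) that seed the first
    iteration's priors and warm starts.

    The bootstrap always uses the data-based weighting: it is only an
    initialisation and the data-based objective is far better conditioned
    over the full dynamic range of the measurements.
    """
    options = options or FitOptions()
    contexts = contexts or _contexts(cohort, options)
    spec = ErrorModelSpec.uniform("data_based", METHOD_PARTITION[method], b_init)
    out = {}
    for p in cohort.patients:
        res = fit_map(p.measurements, spec, None, FitParameters.default(), contexts[p.patient_id], options)
        out[p.patient_id] = res.estimates
    return out


def iterate_b(
    cohort: Cohort,
    method: str,
    max_iter: int | None = None,
    tol: float = 0.005,
    b_init: float = 0.2,
    options: FitOptions | None = None,
    initial_estimates: dict[str, FitParameters] | None = None,
) -> BTrace:
    """Run the iterative b-estimation loop (see module docstring)."""
    if method not in METHOD_FAMILY:
        raise ValueError(f"unknown method {method!r}")
    if len(cohort) < 2:
        raise ValueError("the iterative workflow needs at least 2 patients")
    max_iter = METHOD_DEFAULT_MAX_ITER[method] if max_iter is None else max_iter
    options = options or FitOptions()
    partition = METHOD_PARTITION[method]
    family = METHOD_FAMILY[method]
    classes = PARTITION_CLASSES[partition]
    ther_classes = [c for c in classes if c.startswith("T")]

    contexts = _contexts(cohort, options)
    estimates = initial_estimates or bootstrap_estimates(cohort, method, b_init, options, contexts)
    priors = loo_priors(estimates)
    medians = {c: b_init for c in classes}

    trace = BTrace(method=method)
    for _it in range(max_iter):
        iter_b: dict[str, dict[str, float]] = {}
        new_estimates: dict[str, FitParameters] = {}
        # floor keeps the weighting spec valid on degenerate (noise-free)
        # cohorts whose b medians collapse to zero
        b_weight = {c: max(v, 1e-9) for c, v in medians.items()}
        for p in cohort.patients:
            pid = p.patient_id
            ctx = contexts[pid]
            spec = ErrorModelSpec(family, partition, 0.0, dict(b_weight))
            prior = priors[pid]
            warm = estimates[pid]
            diag = p.measurements.subset(phase="diagnostic")
            ther = p.measurements.subset(phase="therapeutic")
            pb: dict[str, float] = {}
            if len(diag):
                fit1 = fit_map(diag, spec, prior, warm, ctx, options)
                pb.update(_class_b(method, diag, fit1.residuals["f"].to_numpy(), "D"))
            if len(ther):
                fit2 = fit_map(ther, spec, prior, warm, ctx, options)
                pb.update(_class_b(method, ther, fit2.residuals["f"].to_numpy(), "T"))
            fit3 = fit_map(p.measurements, spec, prior, warm, ctx, options)
            new_estimates[pid] = fit3.estimates
            iter_b[pid] = pb

        new_medians = {}
        for cls in classes:
            vals = [pb[cls] for pb in iter_b.values() if cls in pb]
            new_medians[cls] = lower_median(vals) if vals else medians[cls]
        fluct = max(abs(new_medians[c] - medians[c]) for c in ther_classes)

        trace.per_patient.append(iter_b)
        trace.medians.append(dict(new_medians))
        trace.fluctuations.append(fluct)

        medians = new_medians
        estimates = new_estimates
        priors = loo_priors(estimates)

        if trace.n_iterations >= 2 and fluct < tol:
            trace.converged = True
            break

    trace.final_medians = dict(medians)
    trace.final_priors = priors
    trace.final_estimates = estimates
    return trace


def reference_fit(
    patient: PatientRecord,
    spec: ErrorModelSpec,
    prior: BayesPrior | None,
    constants: LiteratureConstants = DEFAULT_CONSTANTS,
    options: FitOptions | None = None,
    init: FitParameters | None = None,
    t_end: float = DEFAULT_T_END_MIN,
    tia_window: tuple[float, float] | None = None,
) -> tuple[FitResult, dict[str, TIAResult]]:
    """All-data fit and the resulting reference therapy TIA per region."""
    options = options or FitOptions()
    ms = patient.measurements
    phases = set(ms.table["phase"])
    if phases != {"diagnostic", "therapeutic"}:
        raise ValueError("reference fit requires both diagnostic and therapeutic records")
    ctx = PatientModelContext(patient.physiology, constants, patient.dosing, options.rtol, options.atol)
    result = fit_map(ms, spec, prior, init or FitParameters.default(), ctx, options)
    tias = _therapy_tias(patient, result.estimates, constants, t_end, tia_window)
    return result, tias


def _therapy_tias(patient, params, constants, t_end, window):
    if window is None:
        infusion = patient.dosing.event_for_nuclide("lu177").start_min
        window = (infusion, t_end)
    model = build_model(patient.physiology, constants, params)
    traj = simulate(model, patient.dosing, t_end=t_end, dense=True, rtol=1e-7, atol=1e-10)
    return {r: tia(traj, r, window, nuclide="lu177") for r in TIA_REGIONS}


@dataclass
class PredictionResult:
    patient_id: str
    method: str
    fit_result: FitResult
    tia: dict[str, TIAResult]
    b_used: dict[str, float]
    window: tuple[float, float]

    def tia_values(self) -> dict[str, float]:
        return {r: t.tia_mbq_min for r, t in self.tia.items()}


def predict_therapy(
    patient: PatientRecord,
    method: str,
    prior: BayesPrior,
    b_median: dict[str, float],
    constants: LiteratureConstants = DEFAULT_CONSTANTS,
    options: FitOptions | None = None,
    data: MeasurementSet | None = None,
    patient_specific_bd: bool = True,
    bd_rounds: int = 2,
    t_end: float = DEFAULT_T_END_MIN,
    tia_window: tuple[float, float] | None = None,
) -> PredictionResult:
    """Predict the therapeutic TAC/TIA from diagnostic data and the prior.

    Only diagnostic records may reach the fit.  When ``data`` is passed
    explicitly it must be diagnostic-only (a therapeutic record raises
    :class:`ContaminationError`); by default the patient's own diagnostic
    subset is used, so the result is invariant to any modification of the
    therapeutic records.
    """
    if method not in METHOD_FAMILY:
        raise ValueError(f"unknown method {method!r}")
    options = options or FitOptions()
    if data is not None:
        if (data.table["phase"] == "therapeutic").any():
            raise ContaminationError("therapeutic records passed to a prediction fit")
        diag = data
    else:
        diag = patient.measurements.subset(phase="diagnostic")
    if len(diag) == 0:
        raise ValueError("no diagnostic records available for prediction")

    family = METHOD_FAMILY[method]
    partition = METHOD_PARTITION[method]
    b = {c: b_median[c] for c in PARTITION_CLASSES[partition]}
    ctx = PatientModelContext(patient.physiology, constants, patient.dosing, options.rtol, options.atol)
    init = FitParameters.from_dict(prior.mean)

    result = fit_map(diag, ErrorModelSpec(family, partition, 0.0, dict(b)), prior, init, ctx, options)
    if method == "III" and patient_specific_bd:
        # self-consistent patient-specific diagnostic b (cohort medians keep
        # the therapeutic classes, which enter prediction only via the prior)
        for _ in range(bd_rounds):
            pb = _class_b("III", diag, result.residuals["f"].to_numpy(), "D")
            b.update(pb)
            result = fit_map(diag, ErrorModelSpec(family, partition, 0.0, dict(b)), prior, result.estimates, ctx, options)

    tias = _therapy_tias(patient, result.estimates, constants, t_end, tia_window)
    if tia_window is None:
        infusion = patient.dosing.event_for_nuclide("lu177").start_min
        tia_window = (infusion, t_end)
    return PredictionResult(
        patient_id=patient.patient_id,
        method=method,
        fit_result=result,
        tia=tias,
        b_used=dict(b),
        window=tia_window,
    )


@dataclass
class PipelineReport:
    method: str
    b_trace: BTrace
    reference: dict[str, tuple[FitResult, dict[str, TIAResult]]]
    predictions: dict[str, PredictionResult]
    rpe_by_region: dict[str, list[float]]
    evaluation: "object"  # pandas DataFrame
    all_converged: bool = True


def run_cohort_pipeline(
    cohort: Cohort,
    method: str = "III",
    max_iter: int | None = None,
    tol: float = 0.005,
    options: FitOptions | None = None,
    t_end: float = DEFAULT_T_END_MIN,
) -> PipelineReport:
    """End-to-end run: b loop, reference fits, predictions, evaluation table."""
    options = options or FitOptions()
    trace = iterate_b(cohort, method, max_iter=max_iter, tol=tol, options=options)
    spec = ErrorModelSpec(METHOD_FAMILY[method], METHOD_PARTITION[method], 0.0, dict(trace.final_medians))

    reference: dict[str, tuple[FitResult, dict[str, TIAResult]]] = {}
    predictions: dict[str, PredictionResult] = {}
    rpe_by_region: dict[str, list[float]] = {r: [] for r in TIA_REGIONS}
    all_converged = True
    for p in cohort.patients:
        pid = p.patient_id
        prior = trace.final_priors[pid]
        ref_res, ref_tia = reference_fit(
            p, spec, prior, cohort.constants, options, init=trace.final_estimates[pid], t_end=t_end
        )
        pred = predict_therapy(p, method, prior, trace.final_medians, cohort.constants, options, t_end=t_end)
        all_converged = all_converged and ref_res.converged and pred.fit_result.converged
        reference[pid] = (ref_res, ref_tia)
        predictions[pid] = pred
        for r in TIA_REGIONS:
            rpe_by_region[r].append(rpe(pred.tia[r].tia_mbq_min, ref_tia[r].tia_mbq_min))

    return PipelineReport(
        method=method,
        b_trace=trace,
        reference=reference,
        predictions=predictions,
        rpe_by_region=rpe_by_region,
        evaluation=evaluation_table(rpe_by_region),
        all_converged=all_converged,
    )
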