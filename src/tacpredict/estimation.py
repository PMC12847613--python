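"""MAP estimation of the ten model parameters from time-activity data.

The objective is the extended-least-squares form of the Gaussian negative
log-likelihood (times two),

    OF(p) = sum_i [ (y_i - f_i(p))^2 / sigma_i^2 + ln sigma_i^2 ]
          + sum_j (ln p_j - ln mu_j)^2 / s*_j^2 ,

where the prior penalty acts on log-parameters (all ten are positive scale
quantities) with the log-standard deviation ``s* = sqrt(ln(1 + cv^2))``
induced by the prior mean/sd.  The ``ln sigma^2`` term is what makes the
closed-form proportional-b estimators stationary points of OF, so it is kept
in the minimised objective for every error-model family.

Minimisation runs in log-parameter space with a damped Gauss-Newton
(Levenberg-Marquardt) iteration; the model sensitivities are obtained by
finite differences of the simulated activities.  Parameter uncertainties
(CV, correlation matrix) come from the Gauss-Newton curvature at the
optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import LiteratureConstants
from .errors import ErrorModelSpec
from .measurements import MeasurementSet
from .parameters import FitParameters, PARAMETER_NAMES, PARAMETER_RANGES
from .pbpk import build_model, simulate
from .physiology import PatientPhysiology, DosingSchedule

PHASE_NUCLIDE = {"diagnostic": "ga68", "therapeutic": "lu177"}

#: cv below which a prior is treated as a delta function (parameter pinned)
PIN_CV = 1e-9


class FitInputError(ValueError):
    pass


@dataclass
class BayesPrior:
    """Population prior: mean/sd per fit parameter, with provenance."""

    mean: dict[str, float]
    sd: dict[str, float]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.mean) != set(PARAMETER_NAMES) or set(self.sd) != set(PARAMETER_NAMES):
            raise ValueError("prior must cover exactly the 10 fit parameters")
        for n in PARAMETER_NAMES:
            if self.mean[n] <= 0:
                raise ValueError(f"prior mean for {n!r} must be positive")
            if self.sd[n] < 0:
                raise ValueError(f"prior sd for {n!r} must be non-negative")

    def log_sd(self, name: str) -> float:
        cv = self.sd[name] / self.mean[name]
        return math.sqrt(math.log1p(cv * cv))


@dataclass
class FitOptions:
    """Optimizer and solver settings for one fit."""

    rtol: float = 1e-6
    atol: float = 1e-9
    max_iter: int = 40
    ftol: float = 1e-6
    xtol: float = 1e-4
    fd_step: float = 0.02  # log-space finite-difference step
    n_starts: int = 1
    seed: int = 0
    max_reject: int = 7
    #: log-space search box: population range widened by this factor on both
    #: sides; keeps flat likelihood directions from drifting to absurd scales
    bound_factor: float = 100.0
    #: number of consecutive accepted steps for which the finite-difference
    #: Jacobian is carried forward with Broyden rank-1 updates before a full
    #: recompute (0 disables reuse)
    jac_reuse: int = 2


@dataclass
class FitResult:
    estimates: FitParameters
    objective_value: float
    cv_percent: dict[str, float]
    correlation: np.ndarray  # 10 x 10, PARAMETER_NAMES order
    aic: float
    converged: bool
    residuals: pd.DataFrame  # columns y, f, sigma (+ record labels)
    trace: list[float] = field(default_factory=list)
    n_simulations: int = 0
    n_free_parameters: int = 10

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "objective_value": self.objective_value,
            "cv_percent": self.cv_percent,
            "correlation": self.correlation.tolist(),
            "aic": self.aic,
            "converged": self.converged,
            "n_simulations": self.n_simulations,
        }


class PatientModelContext:
    """Maps a parameter vector to model activities at measurement records."""

    def __init__(
        self,
        physiology: PatientPhysiology,
        constants: LiteratureConstants,
        dosing: DosingSchedule,
        rtol: float = 1e-6,
        atol: float = 1e-9,
    ):
        self.physiology = physiology
        self.constants = constants
        self.dosing = dosing
        self.rtol = rtol
        self.atol = atol
        self.n_simulations = 0
        self._cache: dict[bytes, np.ndarray] = {}
        self._data_key: tuple | None = None

    def _record_layout(self, data: MeasurementSet):
        times = data.times
        grid = np.unique(times)
        regions = data.table["region"].to_numpy()
        nuclides = data.table["phase"].map(PHASE_NUCLIDE).to_numpy()
        t_idx = np.searchsorted(grid, times)
        return grid, regions, nuclides, t_idx

    def predict(self, params: np.ndarray | FitParameters, data: MeasurementSet) -> np.ndarray:
        """Model activity f(t_i | p) for every record of ``data``."""
        if isinstance(params, FitParameters):
            params = params.to_array()
        key = (tuple(np.round(data.times, 9)), tuple(data.table["region"]))
        if key != self._data_key:
            self._data_key = key
            self._layout = self._record_layout(data)
            self._cache.clear()
        ck = np.asarray(params, float).tobytes()
        if ck in self._cache:
            return self._cache[ck]
        grid, regions, nuclides, t_idx = self._layout
        model = build_model(self.physiology, self.constants, FitParameters.from_array(params))
        traj = simulate(
            model,
            self.dosing,
            t_end=float(grid[-1]),
            grid=grid,
            rtol=self.rtol,
            atol=self.atol,
            check_balance=False,
        )
        self.n_simulations += 1
        f = np.empty(len(data))
        series: dict[tuple[str, str], np.ndarray] = {}
        for i, (reg, nuc) in enumerate(zip(regions, nuclides)):
            if (reg, nuc) not in series:
                series[(reg, nuc)] = traj.activity_series(reg, nuc)
            f[i] = series[(reg, nuc)][t_idx[i]]
        f = np.maximum(f, 0.0)
        self._cache[ck] = f
        return f


def _prior_terms(prior: BayesPrior | None):
    if prior is None:
        return None, None, np.zeros(len(PARAMETER_NAMES), dtype=bool)
    log_mu = np.array([math.log(prior.mean[n]) for n in PARAMETER_NAMES])
    log_sd = np.array([prior.log_sd(n) for n in PARAMETER_NAMES])
    pinned = log_sd < PIN_CV
    return log_mu, log_sd, pinned


def objective(
    params: FitParameters | np.ndarray,
    data: MeasurementSet,
    spec: ErrorModelSpec,
    prior: BayesPrior | None,
    ctx: PatientModelContext,
) -> float:
    """The extended-least-squares MAP objective (see module docstring)."""
    p = params.to_array() if isinstance(params, FitParameters) else np.asarray(params, float)
    if len(data):
        f = ctx.predict(p, data)
        y = data.values
        labels = data.class_labels(spec.partition)
        sigma = np.array([spec.sigma(lbl, yi, fi) for lbl, yi, fi in zip(labels, y, f)])
        if np.any(sigma <= 0):
            raise FitInputError("non-positive sigma encountered; check b constants and data")
        value = float(np.sum((y - f) ** 2 / sigma**2 + np.log(sigma**2)))
    else:
        value = 0.0
    log_mu, log_sd, pinned = _prior_terms(prior)
    if log_mu is not None:
        z = np.log(p)
        free = ~pinned
        value += float(np.sum((z[free] - log_mu[free]) ** 2 / log_sd[free] ** 2))
    return value


def _sigma_and_dsigma(spec: ErrorModelSpec, labels, y, f):
    b = np.array([spec.b_for(lbl) for lbl in labels])
    if spec.family == "data_based":
        sigma = spec.a + b * y
        dsig_df = np.zeros_like(f)
    else:
        sigma = spec.a + b * f
        dsig_df = b
    return sigma, dsig_df


def fit_map(
    data: MeasurementSet,
    spec: ErrorModelSpec,
    prior: BayesPrior | None,
    init: FitParameters,
    ctx: PatientModelContext,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the ten parameters by damped Gauss-Newton on the MAP objective.

    Parameters are optimised on the log scale (positivity by construction).
    With fewer records than free parameters a prior is mandatory.
    """
    options = options or FitOptions()
    if len(data) == 0:
        raise FitInputError("empty measurement set")
    log_mu, log_sd, pinned = _prior_terms(prior)
    n_free = int(np.sum(~pinned))
    if len(data) < n_free and prior is None:
        raise FitInputError(
            f"{len(data)} records cannot determine {n_free} parameters without a prior"
        )
    ctx.rtol, ctx.atol = options.rtol, options.atol

    starts = [init.to_array()]
    if options.n_starts > 1:
        rng = np.random.default_rng(options.seed)
        lo = np.array([PARAMETER_RANGES[n][0] for n in PARAMETER_NAMES])
        hi = np.array([PARAMETER_RANGES[n][1] for n in PARAMETER_NAMES])
        for _ in range(options.n_starts - 1):
            starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    if n_free == 0:
        # every parameter pinned by a delta prior: nothing to optimise
        z = np.array([math.log(prior.mean[n]) for n in PARAMETER_NAMES])
        f = ctx.predict(np.exp(z), data)
        of = objective(np.exp(z), data, spec, prior, ctx)
        out0 = {"z": z, "of": of, "f": f, "J": np.zeros((len(data), len(PARAMETER_NAMES))), "trace": [of], "converged": True}
        best = (of, out0)
    else:
        best = None
    for p0 in starts if n_free else []:
        outcome = _fit_single(p0, data, spec, prior, ctx, options, log_mu, log_sd, pinned)
        if best is None or outcome["of"] < best[0]:
            best = (outcome["of"], outcome)
    out = best[1]

    # curvature-based uncertainties at the optimum
    z = out["z"]
    J = out["J"]  # d f / d z, shape (N, 10); pinned columns zero
    y = data.values
    f = out["f"]
    labels = data.class_labels(spec.partition)
    sigma, _ = _sigma_and_dsigma(spec, labels, y, f)
    H = J.T @ (J / sigma[:, None] ** 2)
    if log_mu is not None:
        H = H + np.diag(np.where(pinned, 0.0, 1.0 / np.maximum(log_sd, PIN_CV) ** 2))
    free = ~pinned
    cov = np.zeros((len(PARAMETER_NAMES), len(PARAMETER_NAMES)))
    try:
        cov[np.ix_(free, free)] = np.linalg.inv(H[np.ix_(free, free)])
    except np.linalg.LinAlgError:
        cov[np.ix_(free, free)] = np.linalg.pinv(H[np.ix_(free, free)])
    sd_z = np.sqrt(np.maximum(np.diag(cov), 0.0))
    cv = {n: 100.0 * sd_z[j] for j, n in enumerate(PARAMETER_NAMES)}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd_z, sd_z)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)

    residuals = data.table.copy()
    residuals["y"] = y
    residuals["f"] = f
    residuals["sigma"] = sigma

    estimates = FitParameters.from_array(np.exp(z))
    return FitResult(
        estimates=estimates,
        objective_value=out["of"],
        cv_percent=cv,
        correlation=corr,
        aic=2.0 * n_free + out["of"],
        converged=out["converged"],
        residuals=residuals,
        trace=out["trace"],
        n_simulations=ctx.n_simulations,
        n_free_parameters=n_free,
    )


def _fit_single(p0, data, spec, prior, ctx, options, log_mu, log_sd, pinned):
    y = data.values
    labels = data.class_labels(spec.partition)
    n_par = len(PARAMETER_NAMES)
    z = np.log(np.asarray(p0, float))
    if log_mu is not None:
        z[pinned] = log_mu[pinned]
    free = np.flatnonzero(~pinned)
    z_lo = np.array([math.log(PARAMETER_RANGES[n][0] / options.bound_factor) for n in PARAMETER_NAMES])
    z_hi = np.array([math.log(PARAMETER_RANGES[n][1] * options.bound_factor) for n in PARAMETER_NAMES])

    def of_value(zv):
        f = ctx.predict(np.exp(zv), data)
        sigma, _ = _sigma_and_dsigma(spec, labels, y, f)
        if np.any(sigma <= 0):
            return np.inf, f, sigma
        val = float(np.sum((y - f) ** 2 / sigma**2 + np.log(sigma**2)))
        if log_mu is not None:
            fr = ~pinned
            val += float(np.sum((zv[fr] - log_mu[fr]) ** 2 / log_sd[fr] ** 2))
        return val, f, sigma

    of0, f0, sigma0 = of_value(z)
    trace = [of0]
    lam = 1e-3
    converged = False
    J = np.zeros((len(y), n_par))
    jac_age = -1  # -1: no Jacobian yet

    for _ in range(options.max_iter):
        if jac_age < 0 or jac_age >= options.jac_reuse:
            # full finite-difference sensitivities in log space
            for j in free:
                zp = z.copy()
                zp[j] += options.fd_step
                fp = ctx.predict(np.exp(zp), data)
                J[:, j] = (fp - f0) / options.fd_step
            jac_age = 0
        sigma, dsig = _sigma_and_dsigma(spec, labels, y, f0)
        e = y - f0
        # dOF/df: residual term plus the ln-sigma and sigma(f) contributions
        w = -2.0 * e / sigma**2 + dsig * (-2.0 * e**2 / sigma**3 + 2.0 / sigma)
        g = J.T @ w
        H = 2.0 * J.T @ (J / sigma[:, None] ** 2)
        if log_mu is not None:
            fr = ~pinned
            g = g + np.where(fr, 2.0 * (z - log_mu) / np.maximum(log_sd, PIN_CV) ** 2, 0.0)
            H = H + np.diag(np.where(fr, 2.0 / np.maximum(log_sd, PIN_CV) ** 2, 0.0))
        g[pinned] = 0.0

        accepted = False
        for _reject in range(options.max_reject):
            Hd = H[np.ix_(free, free)] + lam * np.diag(np.maximum(np.diag(H[np.ix_(free, free)]), 1e-12))
            try:
                step_free = np.linalg.solve(Hd, -g[free])
            except np.linalg.LinAlgError:
                step_free = np.linalg.lstsq(Hd, -g[free], rcond=None)[0]
            step = np.zeros(n_par)
            step[free] = np.clip(step_free, -2.0, 2.0)
            z_new = np.clip(z + step, z_lo, z_hi)
            if log_mu is not None:
                z_new[pinned] = log_mu[pinned]
            step = z_new - z
            of_new, f_new, _ = of_value(z_new)
            if of_new < of0:
                accepted = True
                lam = max(lam / 3.0, 1e-8)
                rel_drop = (of0 - of_new) / max(1.0, abs(of0))
                dz = z_new - z
                denom = float(dz @ dz)
                if denom > 0:
                    # Broyden rank-1 secant update keeps J useful between
                    # full finite-difference recomputes
                    J += np.outer(f_new - f0 - J @ dz, dz) / denom
                    jac_age += 1
                z, of0, f0 = z_new, of_new, f_new
                trace.append(of0)
                if rel_drop < options.ftol or np.max(np.abs(step)) < options.xtol:
                    converged = True
                break
            lam *= 10.0
            jac_age = options.jac_reuse  # stale Jacobian may be the culprit
        if not accepted:
            converged = trace[-1] == min(trace)  # stalled at the best point found
            break
        if converged:
            break

    J[:, pinned] = 0.0
    return {"z": z, "of": of0, "f": f0, "J": J, "trace": trace, "converged": converged}


def covariance_from_curvature(hessian_of: np.ndarray) -> np.ndarray:
    """Parameter covariance implied by the curvature of OF (= 2 * NLL)."""
    return 2.0 * np.linalg.inv(hessian_of)


@dataclass
class GoodnessReport:
    cv_flags: list[str]
    correlation_flags: list[tuple[str, str, float]]
    aic: float

    @property
    def acceptable(self) -> bool:
        return not self.cv_flags and not self.correlation_flags


def goodness_of_fit(result: FitResult, cv_limit: float = 50.0, corr_limit: float = 0.8) -> GoodnessReport:
    """Flag parameters with CV >= 50% and correlation elements outside
    (-0.8, 0.8); report AIC for model comparison."""
    cv_flags = [n for n, v in result.cv_percent.items() if v >= cv_limit]
    corr_flags = []
    for i, ni in enumerate(PARAMETER_NAMES):
        for j in range(i + 1, len(PARAMETER_NAMES)):
            c = result.correlation[i, j]
            if abs(c) >= corr_limit:
                corr_flags.append((ni, PARAMETER_NAMES[j], float(c)))
    return GoodnessReport(cv_flags=cv_flags, correlation_flags=corr_flags, aic=result.aic)
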