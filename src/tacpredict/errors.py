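"""Residual-error models and their closed-form maximum-likelihood estimators.

Three measurement-uncertainty descriptions are supported:

* combined:      sigma_i = a + b * f(t_i | p)
* model-based:   sigma_i = b * f(t_i | p)        (a = 0)
* data-based:    sigma_i = b * y_i

For the proportional models the ML estimate of ``b`` under a Gaussian
likelihood (including the ``ln sigma`` normalisation term) has the closed
form  b = sqrt( (1/N) sum (y_i - f_i)^2 / w_i^2 )  with ``w = f`` for the
model-based and ``w = y`` for the data-based family: it is the stationary
point of the negative log-likelihood in ``b``.

The proportionality constant may be split by phase (diagnostic vs
therapeutic; ``two_b``) or additionally by tissue class (organ vs tumour;
``four_b``); residuals are pooled across regions within a class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FAMILIES = ("model_based", "data_based", "combined")
PARTITIONS = ("two_b", "four_b")

PARTITION_CLASSES = {
    "two_b": ("D", "T"),
    "four_b": ("D_organ", "D_tumour", "T_organ", "T_tumour"),
}


class SingularWeightError(ValueError):
    """A proportional weight is zero where the estimator needs to divide by it."""

    def __init__(self, which: str, indices):
        self.indices = list(indices)
        super().__init__(f"zero {which} value(s) at indices {self.indices}; estimator undefined")


class PartitionError(KeyError):
    pass


@dataclass
class ErrorModelSpec:
    """Residual-error model family, class partition, and constants."""

    family: str
    partition: str
    a: float = 0.0
    b: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.partition not in PARTITIONS:
            raise ValueError(f"unknown partition {self.partition!r}")
        if self.a < 0:
            raise ValueError("additive constant a must be >= 0")
        expected = set(PARTITION_CLASSES[self.partition])
        if self.b and set(self.b) != expected:
            raise ValueError(f"b keys {sorted(self.b)} do not match partition classes {sorted(expected)}")

    @classmethod
    def uniform(cls, family: str, partition: str, b: float, a: float = 0.0) -> "ErrorModelSpec":
        return cls(family, partition, a, {c: b for c in PARTITION_CLASSES[partition]})

    def b_for(self, label: str) -> float:
        try:
            return self.b[label]
        except KeyError:
            raise PartitionError(f"no b constant for class {label!r} in partition {self.partition!r}") from None

    def sigma(self, label: str, y: float, f: float) -> float:
        if self.family == "data_based":
            return self.a + self.b_for(label) * y
        return self.a + self.b_for(label) * f

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"family": self.family, "partition": self.partition, "a": self.a, "b": self.b}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ErrorModelSpec":
        return cls(**json.loads(Path(path).read_text()))


def combined_sigma(a: float, b: float, f: float) -> float:
    """sigma = a + b * f  (constant plus proportional uncertainty)."""
    if a < 0 or b < 0 or f < 0:
        raise ValueError("combined_sigma requires non-negative a, b and f")
    return a + b * f


def estimate_b_model_based(y, f, *, on_zero: str = "error") -> float:
    """Closed-form ML estimate of b with sigma proportional to the model value."""
    return _estimate_b(np.asarray(y, float), np.asarray(f, float), "f", on_zero)


def estimate_b_data_based(y, f, *, on_zero: str = "error") -> float:
    """Closed-form ML estimate of b with sigma proportional to the measurement."""
    return _estimate_b(np.asarray(y, float), np.asarray(f, float), "y", on_zero)


def _estimate_b(y: np.ndarray, f: np.ndarray, weight: str, on_zero: str) -> float:
    if y.shape != f.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and f must be equal-length non-empty 1-D arrays")
    w = f if weight == "f" else y
    zero = w == 0.0
    if zero.any():
        if on_zero == "exclude":
            import warnings

            warnings.warn(
                f"excluding {int(zero.sum())} record(s) with zero weight from b estimation",
                stacklevel=3,
            )
            y, f, w = y[~zero], f[~zero], w[~zero]
            if y.size == 0:
                raise SingularWeightError(weight, np.flatnonzero(zero))
        else:
            raise SingularWeightError(weight, np.flatnonzero(zero))
    return float(np.sqrt(np.mean(((y - f) / w) ** 2)))


def variance(spec: ErrorModelSpec, label: str, y: float, f: float) -> float:
    """Per-record variance sigma^2 under the given error-model spec."""
    return spec.sigma(label, y, f) ** 2


def estimate_combined(y, f) -> tuple[float, float]:
    """Joint ML fit of the combined model sigma = a + b*f (a >= 0).

    Used for the initial screening step: on purely proportional data the
    fitted ``a`` collapses to (numerically) zero and the proportional model
    is adopted.
    """
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    f = np.asarray(f, float)
    if np.any(f <= 0):
        raise SingularWeightError("f", np.flatnonzero(f <= 0))

    def nll(theta):
        a, b = theta
        s = a + b * f
        if np.any(s <= 0):
            return np.inf
        return float(np.sum(np.log(s) + (y - f) ** 2 / (2.0 * s**2)))

    b0 = max(estimate_b_model_based(y, f), 1e-6)
    res = minimize(nll, x0=[1e-3 * b0 * float(np.mean(f)), b0],
                   bounds=[(0.0, None), (1e-12, None)], method="L-BFGS-B")
    a, b = res.x
    return float(a), float(b)


def proportional_nll(b: float, y: np.ndarray, f: np.ndarray, weight: str = "f") -> float:
    """Gaussian negative log-likelihood profile in b (up to a constant).

    Used as the brute-force cross-check of the closed-form estimators.
    """
    w = f if weight == "f" else y
    s = b * w
    return float(np.sum(np.log(s) + (y - f) ** 2 / (2.0 * s**2)))
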