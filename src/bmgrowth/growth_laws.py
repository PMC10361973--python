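"""Closed-form tumor growth laws.

The central model is the power-law ODE ``dV/dt = alpha * V**beta`` (the
maintenance term is fixed at zero throughout this package), whose closed
form is

    V(t) = [V0**(1-beta) + (1-beta) * alpha * (t - t0)] ** (1/(1-beta))

with the exponential limit ``V0 * exp(alpha * (t - t0))`` at beta = 1.
For beta > 1 the solution blows up in finite time; evaluation at or past
the blow-up time is a :class:`~bmgrowth.errors.DomainError`.

Four textbook benchmark curves (exponential, cubic, Gompertz, logistic)
are also provided; they serve as forward models for the robustness
analyses in :mod:`bmgrowth.sensitivity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "BETA_ONE_TOL",
    "VonBertalanffyParams",
    "CanonicalCurveSpec",
    "vb_volume",
    "canonical_volume",
    "default_curve_specs",
]

#: Width of the removable singularity at beta = 1: below this distance the
#: exponential closed form is used instead of the power-law form.
BETA_ONE_TOL = 1e-6


@dataclass(frozen=True)
class VonBertalanffyParams:
    """Parameters of the growth law ``dV/dt = alpha * V**beta - b * V``.

    Parameters
    ----------
    V0 : float
        Volume (cm^3) at the reference time ``t0``. Must be positive.
    t0 : float
        Reference time (days).
    alpha : float
        Energy-intake coefficient (cm^(3(1-beta)) / day). Must be positive.
    beta : float
        Dimensionless growth exponent. ``beta = 1`` is exponential growth,
        ``beta > 1`` superexponential (finite-time blow-up), ``beta < 1``
        subexponential.
    b : float
        Maintenance coefficient (1/day). Fixed at 0 in this package.
    """

    V0: float
    t0: float
    alpha: float
    beta: float
    b: float = 0.0

    def __post_init__(self) -> None:
        if not self.V0 > 0:
            raise ValidationError(f"V0 must be positive, got {self.V0}")
        if not self.alpha > 0:
            raise ValidationError(f"alpha must be positive, got {self.alpha}")
        if self.b != 0.0:
            raise ValidationError("maintenance coefficient b is fixed at 0")
        if not math.isfinite(self.beta):
            raise ValidationError("beta must be finite")

    @property
    def blow_up_time(self) -> float:
        """Finite blow-up time for beta > 1, ``inf`` otherwise."""
        if self.beta > 1.0 + BETA_ONE_TOL:
            return self.t0 + self.V0 ** (1.0 - self.beta) / (
                (self.beta - 1.0) * self.alpha
            )
        return math.inf


def vb_volume(params: VonBertalanffyParams, t):
    """Evaluate the closed-form volume V(t) for ``dV/dt = alpha V**beta``.

    Accepts a scalar time or an array of times (days). Times must satisfy
    ``t >= t0`` and, for beta > 1, lie strictly before the blow-up time.

    Returns the volume(s) in the same shape as ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < params.t0):
        raise DomainError(f"t must be >= t0 = {params.t0}")
    dt = t_arr - params.t0
    one_minus_beta = 1.0 - params.beta
    if abs(one_minus_beta) < BETA_ONE_TOL:
        out = params.V0 * np.exp(params.alpha * dt)
    else:
        base = params.V0**one_minus_beta + one_minus_beta * params.alpha * dt
        if np.any(base <= 0):
            raise DomainError(
                f"evaluation at or past the blow-up time t* = {params.blow_up_time}"
            )
        out = base ** (1.0 / one_minus_beta)
    return out if out.ndim else float(out)


_CURVE_KINDS = ("exponential", "cubic", "gompertz", "logistic")

# Required parameter names per curve kind.
_CURVE_PARAMS = {
    "exponential": ("V0", "r"),
    "cubic": ("a", "s"),
    "gompertz": ("A", "c", "d"),
    "logistic": ("A", "m", "r"),
}


@dataclass(frozen=True)
class CanonicalCurveSpec:
    """A benchmark growth curve with its parameters and evaluation window.

    Functional forms (all strictly increasing for positive parameters):

    - ``exponential``: V(t) = V0 * exp(r t)
    - ``cubic``:       V(t) = a * (t + s)**3, valid for t + s > 0
    - ``gompertz``:    V(t) = A * exp(-c * exp(-d t))
    - ``logistic``:    V(t) = A / (1 + m * exp(-r t))
    """

    kind: str
    parameters: Mapping[str, float] = field(default_factory=dict)
    t_range: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.kind not in _CURVE_KINDS:
            raise ValidationError(
                f"unknown curve kind {self.kind!r}; expected one of {_CURVE_KINDS}"
            )
        missing = set(_CURVE_PARAMS[self.kind]) - set(self.parameters)
        if missing:
            raise ValidationError(f"{self.kind} curve missing parameters {missing}")
        if any(v <= 0 for v in self.parameters.values()):
            raise ValidationError("all curve parameters must be positive")
        lo, hi = self.t_range
        if not lo < hi:
            raise ValidationError(f"invalid t_range {self.t_range}")
        if self.kind == "cubic" and lo + self.parameters["s"] <= 0:
            raise ValidationError("cubic curve requires t + s > 0 on t_range")


def canonical_volume(spec: CanonicalCurveSpec, t):
    """Evaluate a canonical curve at time(s) ``t`` within its ``t_range``."""
    t_arr = np.asarray(t, dtype=float)
    lo, hi = spec.t_range
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise DomainError(f"t outside t_range {spec.t_range}")
    p = spec.parameters
    if spec.kind == "exponential":
        out = p["V0"] * np.exp(p["r"] * t_arr)
    elif spec.kind == "cubic":
        out = p["a"] * (t_arr + p["s"]) ** 3
    elif spec.kind == "gompertz":
        out = p["A"] * np.exp(-p["c"] * np.exp(-p["d"] * t_arr))
    else:  # logistic
        out = p["A"] / (1.0 + p["m"] * np.exp(-p["r"] * t_arr))
    return out if out.ndim else float(out)


def default_curve_specs(t_range: tuple[float, float] = (1.0, 180.0)) -> dict[str, CanonicalCurveSpec]:
    """Default parameterizations for the four benchmark curves.

    Chosen so every curve is strictly increasing and spans a few decades of
    volume over the default 180-day window (the values themselves are
    arbitrary and documented as such).
    """
    return {
        "exponential": CanonicalCurveSpec("exponential", {"V0": 0.05, "r": 0.03}, t_range),
        "cubic": CanonicalCurveSpec("cubic", {"a": 2e-6, "s": 1.0}, t_range),
        "gompertz": CanonicalCurveSpec("gompertz", {"A": 20.0, "c": 6.0, "d": 0.02}, t_range),
        "logistic": CanonicalCurveSpec("logistic", {"A": 15.0, "m": 300.0, "r": 0.05}, t_range),
    }
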