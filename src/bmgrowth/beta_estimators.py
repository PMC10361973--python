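"""Growth-exponent (beta) estimation.

Three estimators are provided, matching the three data regimes:

- :func:`solve_three_point_beta` — given exactly three (time, volume)
  measurements, beta is the root of the implicit equation

      (1 - (V1/V0)**(1-beta)) / (1 - (V2/V0)**(1-beta)) = (t1-t0)/(t2-t0)

  located by a sign-change scan over a bracket followed by Brent's method.

- :func:`fit_multipoint_beta` — for series with more than three points,
  the ODE is discretized: ln(dV/dt) is linear in ln V with slope beta, so
  beta comes from an ordinary least-squares fit of
  ln((Vi - Vi-1)/(ti - ti-1)) against ln(Vi). Late time points (where
  volumes saturate against a physical ceiling) are filtered out, and any
  volume decrease excludes the series.

- :func:`sweep_group_beta` — a grid sweep that finds the single exponent
  best fitting a whole group of three-point records: for each candidate
  beta', the best-fitting triple (V0', V1', V2') on a volume grid is found
  per record (V2' follows in closed form from the implicit equation), the
  per-record minimal relative errors are summed, and the argmin over the
  beta grid is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    AmbiguousRootError,
    ExclusionError,
    NoFitError,
    NoRootError,
    ValidationError,
)
from .growth_laws import BETA_ONE_TOL

__all__ = [
    "VolumeTimeSeries",
    "ThreePointRecord",
    "BetaEstimate",
    "GroupSweepResult",
    "solve_three_point_beta",
    "fit_multipoint_beta",
    "best_fit_volumes_for_beta",
    "sweep_group_beta",
]

GROUP_LABELS = ("untreated", "CT", "RT", "RT+CT", "simulated", "mouse", "other")


@dataclass(frozen=True)
class VolumeTimeSeries:
    """One lesion's longitudinal volume measurements."""

    lesion_id: str
    group: str
    times: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        volumes = tuple(float(v) for v in self.volumes)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "volumes", volumes)
        if self.group not in GROUP_LABELS:
            raise ValidationError(
                f"group {self.group!r} not in controlled vocabulary {GROUP_LABELS}"
            )
        if len(times) != len(volumes):
            raise ValidationError("times and volumes must have equal length")
        if len(times) < 2:
            raise ValidationError("a series needs at least 2 measurements")
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValidationError(f"times not strictly increasing for {self.lesion_id}")
        if any(v <= 0 for v in volumes):
            raise ValidationError(f"non-positive volume in {self.lesion_id}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ThreePointRecord:
    """Three strictly growing measurements (t0,V0), (t1,V1), (t2,V2)."""

    t0: float
    t1: float
    t2: float
    V0: float
    V1: float
    V2: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1 < self.t2):
            raise ValidationError("times must satisfy t0 < t1 < t2")
        if not (0 < self.V0 < self.V1 < self.V2):
            raise ValidationError("volumes must satisfy 0 < V0 < V1 < V2")

    @property
    def tau(self) -> float:
        """Time ratio (t1 - t0) / (t2 - t0), strictly in (0, 1)."""
        return (self.t1 - self.t0) / (self.t2 - self.t0)

    @classmethod
    def from_series(cls, series: VolumeTimeSeries, start: int = 0) -> "ThreePointRecord":
        """Build a record from the first three strictly increasing points."""
        t = series.times[start : start + 3]
        v = series.volumes[start : start + 3]
        if len(t) < 3:
            raise ValidationError(f"series {series.lesion_id} has fewer than 3 points")
        return cls(t0=t[0], t1=t[1], t2=t[2], V0=v[0], V1=v[1], V2=v[2])


@dataclass(frozen=True)
class BetaEstimate:
    """An estimated growth exponent plus provenance."""

    beta: float
    method: str  # three_point | multipoint_regression | group_sweep
    residual: float
    bracket: tuple[float, float] | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValidationError("residual must be non-negative")


def _ratio_minus_tau(beta: float, ln_r1: float, ln_r2: float, tau: float) -> float:
    """Stable evaluation of R(beta) - tau.

    R(beta) = (1 - exp(a)) / (1 - exp(b)) with a = (1-beta) ln r1,
    b = (1-beta) ln r2 and 0 < ln r1 < ln r2. At beta = 1 the limit is
    ln r1 / ln r2. For large positive a, b the direct form overflows and
    the factored form exp(a-b) * (1 - exp(-a)) / (1 - exp(-b)) is used.
    """
    u = 1.0 - beta
    a = u * ln_r1
    b = u * ln_r2
    if abs(u) * ln_r2 < 1e-12:
        r = ln_r1 / ln_r2
    elif b < 500.0:
        r = math.expm1(a) / math.expm1(b)
    else:
        r = math.exp(a - b) * (-math.expm1(-a)) / (-math.expm1(-b))
    return r - tau


def solve_three_point_beta(
    record: ThreePointRecord,
    bracket: tuple[float, float] = (-5.0, 10.0),
    scan_step: float = 0.01,
    xtol: float = 1e-10,
) -> BetaEstimate:
    """Solve the implicit three-point equation for the growth exponent.

    The defining function g(beta) = R(beta) - tau is scanned for sign
    changes over ``bracket`` at resolution ``scan_step``; each sign-change
    subinterval is refined with Brent's method. R is strictly monotone in
    beta for any valid record so exactly one root is expected; if several
    sign changes are found all roots are reported via
    :class:`AmbiguousRootError`.
    """
    ln_r1 = math.log(record.V1 / record.V0)
    ln_r2 = math.log(record.V2 / record.V0)
    tau = record.tau

    def g(beta: float) -> float:
        return _ratio_minus_tau(beta, ln_r1, ln_r2, tau)

    lo, hi = bracket
    n = max(2, int(math.ceil((hi - lo) / scan_step)) + 1)
    grid = np.linspace(lo, hi, n)
    vals = np.array([g(b) for b in grid])

    roots: list[float] = []
    exact = grid[vals == 0.0]
    roots.extend(float(b) for b in exact)
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        roots.append(float(brentq(g, grid[i], grid[i + 1], xtol=xtol)))

    if not roots:
        raise NoRootError(
            f"no sign change of g(beta) in bracket {bracket} (tau={tau:.4f})"
        )
    if len(roots) > 1:
        raise AmbiguousRootError(roots)
    beta = roots[0]
    return BetaEstimate(
        beta=beta, method="three_point", residual=abs(g(beta)), bracket=bracket
    )


def fit_multipoint_beta(
    series: VolumeTimeSeries,
    max_time: float | None = 21.0,
) -> BetaEstimate:
    """Estimate beta as the slope of ln(dV/dt) vs ln(V) over a series.

    ``max_time`` drops measurements taken after that day before fitting
    (the default of 21 removes late points where measured volumes press
    against the physical ceiling); pass ``None`` to disable the filter.

    Raises :class:`ExclusionError` if any successive volume difference is
    non-positive — series with volume decreases are excluded outright.
    """
    t = np.asarray(series.times)
    v = np.asarray(series.volumes)
    if max_time is not None:
        keep = t <= max_time
        t, v = t[keep], v[keep]
    if len(t) < 3:
        raise ValidationError(
            f"series {series.lesion_id}: fewer than 3 points after filtering"
        )
    dv = np.diff(v)
    if np.any(dv <= 0):
        raise ExclusionError(
            f"series {series.lesion_id} excluded: volume decrease detected"
        )
    dt = np.diff(t)
    x = np.log(v[1:])
    y = np.log(dv / dt)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return BetaEstimate(
        beta=float(slope),
        method="multipoint_regression",
        residual=rmse,
        alpha=float(np.exp(intercept)),
    )


def _predict_v2(
    v0: np.ndarray, v1: np.ndarray, beta: float, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form V2' from the implicit equation for candidate (V0', V1').

    Returns (V2', feasible mask). Candidates where the base of the power
    is non-positive (or V0' is non-positive) are infeasible.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        pos = v0 > 0
        ratio = np.where(pos, v1 / np.where(pos, v0, 1.0), np.nan)
        if abs(1.0 - beta) < BETA_ONE_TOL:
            v2 = v0 * ratio ** (1.0 / tau)
            feasible = pos & (ratio > 0)
        else:
            u = 1.0 - beta
            base = 1.0 - (1.0 - ratio**u) / tau
            feasible = pos & (ratio > 0) & (base > 0)
            v2 = v0 * np.where(feasible, base, 1.0) ** (1.0 / u)
        feasible &= np.isfinite(v2)
    return v2, feasible


def best_fit_volumes_for_beta(
    record: ThreePointRecord,
    beta: float,
    n_v0: int = 500,
    n_v1: int = 500,
) -> tuple[float, float, float, float]:
    """Best-fitting volume triple for a fixed exponent.

    Sweeps V0' over (0, V1] and V1' over [V0, V2] on uniform grids; V2'
    follows in closed form from the implicit three-point equation. Returns
    the candidate minimizing the summed relative error

        |V0'-V0|/V0 + |V1'-V1|/V1 + |V2'-V2|/V2

    as ``(V0', V1', V2', relative_error)``.
    """
    if not math.isfinite(beta):
        raise ValidationError("beta must be finite")
    tau = record.tau
    # open at 0: a zero candidate volume is never feasible anyway
    v0_grid = np.linspace(0.0, record.V1, n_v0 + 1)[1:]
    v1_grid = np.linspace(record.V0, record.V2, n_v1)
    V0c, V1c = np.meshgrid(v0_grid, v1_grid, indexing="ij")
    V2c, feasible = _predict_v2(V0c, V1c, beta, tau)
    if not np.any(feasible):
        raise NoFitError(f"no feasible (V0', V1') candidate for beta={beta}")
    err = (
        np.abs(V0c - record.V0) / record.V0
        + np.abs(V1c - record.V1) / record.V1
        + np.abs(V2c - record.V2) / record.V2
    )
    err = np.where(feasible, err, np.inf)
    i, j = np.unravel_index(np.argmin(err), err.shape)
    return float(V0c[i, j]), float(V1c[i, j]), float(V2c[i, j]), float(err[i, j])


@dataclass(frozen=True)
class GroupSweepResult:
    """Outcome of a group-level exponent sweep."""

    beta_grid: np.ndarray
    cumulative_error: np.ndarray
    beta_star: float
    per_lesion_errors: np.ndarray = field(repr=False)  # (n_records, n_beta)

    def __post_init__(self) -> None:
        i = int(np.argmin(self.cumulative_error))
        if not math.isclose(float(self.beta_grid[i]), self.beta_star):
            raise ValidationError("beta_star must be the grid argmin")


def sweep_group_beta(
    records: Sequence[ThreePointRecord],
    beta_range: tuple[float, float] = (0.0, 3.0),
    n_beta: int = 300,
    n_v0: int = 500,
    n_v1: int = 500,
) -> GroupSweepResult:
    """Find the single exponent best fitting a group of records.

    For each beta' on the grid, the minimal relative error of every record
    (via :func:`best_fit_volumes_for_beta`) is summed; beta* is the grid
    argmin, with ties broken toward the smaller beta'. Records that admit
    no feasible candidate at some beta' contribute an infinite error there.

    Note: at the full default resolution (300 x 500 x 500) this evaluates
    ~75M candidates per record; expect minutes per group. Tests and the
    CLI expose reduced grids.
    """
    if not records:
        raise ValidationError("need at least one record")
    beta_grid = np.linspace(beta_range[0], beta_range[1], n_beta)
    per_lesion = np.empty((len(records), n_beta))
    for k, rec in enumerate(records):
        for j, b in enumerate(beta_grid):
            try:
                *_, e = best_fit_volumes_for_beta(rec, float(b), n_v0=n_v0, n_v1=n_v1)
            except NoFitError:
                e = np.inf
            per_lesion[k, j] = e
    cumulative = per_lesion.sum(axis=0)
    # argmin returns the first (= smallest beta') index on ties
    beta_star = float(beta_grid[int(np.argmin(cumulative))])
    return GroupSweepResult(
        beta_grid=beta_grid,
        cumulative_error=cumulative,
        beta_star=beta_star,
        per_lesion_errors=per_lesion,
    )
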