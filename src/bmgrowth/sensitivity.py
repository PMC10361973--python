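"""Robustness checks for the three-point exponent estimate.

Two procedures:

- :func:`perturbation_screen` — per-record screen: each of the three
  volumes is multiplied by an independent factor uniform in
  [1-e, 1+e] (default e = 0.05), the exponent is re-solved, and the
  record passes if the mean of the perturbed exponents is within a
  threshold (default 0.5) of the unperturbed one.

- :func:`curve_family_beta_distribution` — draws random time triplets
  from a benchmark growth curve (exponential, cubic, Gompertz, logistic),
  solves for the exponent on clean and on noisy volumes (default +/-20%
  multiplicative noise), and returns both samples. Exponential and cubic
  curves give point-mass distributions (1 and 2/3); saturating curves
  give a spread below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beta_estimators import ThreePointRecord, solve_three_point_beta
from .errors import (
    AmbiguousRootError,
    NoRootError,
    ScreenUndefinedError,
    ValidationError,
)
from .growth_laws import CanonicalCurveSpec, canonical_volume

__all__ = [
    "PerturbationScreenResult",
    "CurveFamilyBetaSample",
    "perturbation_screen",
    "curve_family_beta_distribution",
]


@dataclass(frozen=True)
class PerturbationScreenResult:
    beta_original: float
    beta_perturbed: tuple[float, ...]
    beta_star_av: float
    passed: bool
    n_reps: int
    n_failed: int  # replicates lost to broken monotonicity or failed solves


def perturbation_screen(
    record: ThreePointRecord,
    n_reps: int = 200,
    max_rel_err: float = 0.05,
    threshold: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> PerturbationScreenResult:
    """Screen one record for sensitivity to small volume errors.

    Replicates whose perturbed volumes are no longer strictly increasing,
    or for which the solver finds no (or an ambiguous) root, are counted
    as failures and excluded from the mean. Raises
    :class:`ScreenUndefinedError` if every replicate fails.
    """
    if not 0 <= max_rel_err < 1:
        raise ValidationError("max_rel_err must be in [0, 1)")
    rng = np.random.default_rng(seed)
    beta_original = solve_three_point_beta(record).beta
    betas: list[float] = []
    n_failed = 0
    for _ in range(n_reps):
        f = rng.uniform(1.0 - max_rel_err, 1.0 + max_rel_err, size=3)
        v0, v1, v2 = record.V0 * f[0], record.V1 * f[1], record.V2 * f[2]
        if not (0 < v0 < v1 < v2):
            n_failed += 1
            continue
        try:
            est = solve_three_point_beta(
                ThreePointRecord(record.t0, record.t1, record.t2, v0, v1, v2)
            )
        except (NoRootError, AmbiguousRootError):
            n_failed += 1
            continue
        betas.append(est.beta)
    if not betas:
        raise ScreenUndefinedError("all perturbation replicates failed")
    mean = float(np.mean(betas))
    return PerturbationScreenResult(
        beta_original=beta_original,
        beta_perturbed=tuple(betas),
        beta_star_av=mean,
        passed=abs(mean - beta_original) < threshold,
        n_reps=n_reps,
        n_failed=n_failed,
    )


@dataclass(frozen=True)
class CurveFamilyBetaSample:
    kind: str
    betas_clean: tuple[float, ...]
    betas_noisy: tuple[float, ...]
    n_triplets: int
    n_failed_clean: int
    n_failed_noisy: int


def curve_family_beta_distribution(
    spec: CanonicalCurveSpec,
    n_triplets: int = 100,
    noise_level: float = 0.2,
    seed: int | np.random.Generator | None = None,
    n_grid: int = 256,
) -> CurveFamilyBetaSample:
    """Distribution of three-point exponents along a benchmark curve.

    Triplet times are drawn uniformly without replacement from an
    ``n_grid``-point discretization of the curve's time window (so any two
    chosen times are at least one grid step apart, avoiding degenerate
    time ratios). For each triplet the exponent is solved twice: on the
    exact curve values and on values perturbed by independent
    multiplicative uniform noise of amplitude ``noise_level``.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.linspace(spec.t_range[0], spec.t_range[1], n_grid)
    v_grid = canonical_volume(spec, t_grid)
    if np.any(np.diff(v_grid) <= 0):
        raise ValidationError(
            f"{spec.kind} curve is not strictly increasing on t_range {spec.t_range}"
        )

    clean: list[float] = []
    noisy: list[float] = []
    fail_clean = 0
    fail_noisy = 0
    for _ in range(n_triplets):
        idx = np.sort(rng.choice(n_grid, size=3, replace=False))
        t0, t1, t2 = t_grid[idx]
        v = v_grid[idx]
        try:
            clean.append(
                solve_three_point_beta(
                    ThreePointRecord(t0, t1, t2, v[0], v[1], v[2])
                ).beta
            )
        except (NoRootError, AmbiguousRootError):
            fail_clean += 1
        f = rng.uniform(1.0 - noise_level, 1.0 + noise_level, size=3)
        vn = v * f
        if not (0 < vn[0] < vn[1] < vn[2]):
            fail_noisy += 1
            continue
        try:
            noisy.append(
                solve_three_point_beta(
                    ThreePointRecord(t0, t1, t2, vn[0], vn[1], vn[2])
                ).beta
            )
        except (NoRootError, AmbiguousRootError):
            fail_noisy += 1
    return CurveFamilyBetaSample(
        kind=spec.kind,
        betas_clean=tuple(clean),
        betas_noisy=tuple(noisy),
        n_triplets=n_triplets,
        n_failed_clean=fail_clean,
        n_failed_noisy=fail_noisy,
    )
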