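"""Synthetic cohorts with known ground truth.

The clinical and animal volume datasets this package analyzes are not
public, so these generators produce stand-ins with the same statistical
structure: per-group distributions of the growth exponent, power-law
trajectories evaluated at realistic scan intervals, multiplicative
segmentation-like noise, and (for the animal-style series) a late-time
volume ceiling plus an optional injected decrease to exercise the
exclusion rules. Ground-truth parameters are always returned alongside so
parameter recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta_estimators import VolumeTimeSeries
from .errors import ValidationError
from .growth_laws import VonBertalanffyParams, vb_volume

__all__ = [
    "TruncatedNormal",
    "GroupSpec",
    "SyntheticCohortSpec",
    "SyntheticMouseSpec",
    "generate_cohort",
    "generate_mouse_series",
    "default_cohort_spec",
]

#: days per month used when converting follow-up intervals
DAYS_PER_MONTH = 30.44


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) redrawn until inside [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValidationError("lo must be < hi")

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(10_000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise ValidationError("truncated-normal acceptance region too small")


@dataclass(frozen=True)
class GroupSpec:
    """Distributions for one cohort group."""

    label: str
    n_lesions: int
    beta: TruncatedNormal
    alpha: TruncatedNormal
    V0: TruncatedNormal

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValidationError("n_lesions must be >= 1")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Whole-cohort generation settings.

    Inter-scan gaps are lognormal with the configured medians (days);
    volume noise is multiplicative uniform in [1 - noise_level,
    1 + noise_level]. Lesions violating the strict-growth inclusion
    criterion after noise are discarded and redrawn (the discard count is
    reported).
    """

    groups: tuple[GroupSpec, ...]
    gap_medians: tuple[float, float] = (3.04 * DAYS_PER_MONTH, 2.64 * DAYS_PER_MONTH)
    gap_log_sd: float = 0.3
    noise_level: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("at least one group required")
        if not 0 <= self.noise_level <= 0.5:
            raise ValidationError("noise_level must be in [0, 0.5]")
        if any(m <= 0 for m in self.gap_medians):
            raise ValidationError("gap medians must be positive")


def default_cohort_spec(
    n_per_group: int = 30, noise_level: float = 0.05, seed: int | None = None
) -> SyntheticCohortSpec:
    """Demo spec: an untreated-like group (exponents near 1.5) and a
    treated-like group (exponents near 0.65). Purely synthetic defaults —
    not a reproduction of any clinical table."""
    return SyntheticCohortSpec(
        groups=(
            GroupSpec(
                "untreated", n_per_group,
                beta=TruncatedNormal(1.5, 0.2, 0.8, 2.2),
                alpha=TruncatedNormal(0.01, 0.003, 0.003, 0.02),
                V0=TruncatedNormal(0.5, 0.3, 0.05, 2.0),
            ),
            GroupSpec(
                "RT", n_per_group,
                beta=TruncatedNormal(0.65, 0.2, 0.1, 1.3),
                alpha=TruncatedNormal(0.01, 0.003, 0.003, 0.02),
                V0=TruncatedNormal(0.5, 0.3, 0.05, 2.0),
            ),
        ),
        noise_level=noise_level,
        seed=seed,
    )


@dataclass(frozen=True)
class CohortSample:
    """Generated series plus ground truth and generation diagnostics."""

    series: tuple[VolumeTimeSeries, ...]
    ground_truth: pd.DataFrame = field(repr=False)
    n_discarded: int = 0


def generate_cohort(
    spec: SyntheticCohortSpec, seed: int | np.random.Generator | None = None
) -> CohortSample:
    """Generate three-scan lesions per group, discarding non-growing draws.

    Each lesion draws (V0, alpha, beta) from its group distributions and
    two inter-scan gaps, evaluates the closed-form growth law at the three
    scan times, and applies multiplicative noise. A draw is rejected (and
    redrawn, up to 1000 attempts) if the exponent would blow up inside the
    scan window or the noisy volumes are not strictly increasing.
    """
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series: list[VolumeTimeSeries] = []
    truth_rows = []
    n_discarded = 0
    counter = 0
    for grp in spec.groups:
        for _ in range(grp.n_lesions):
            for _attempt in range(1000):
                beta = grp.beta.draw(rng)
                alpha = grp.alpha.draw(rng)
                v0 = grp.V0.draw(rng)
                gaps = [
                    m * np.exp(spec.gap_log_sd * rng.standard_normal())
                    for m in spec.gap_medians
                ]
                times = (0.0, gaps[0], gaps[0] + gaps[1])
                params = VonBertalanffyParams(V0=v0, t0=0.0, alpha=alpha, beta=beta)
                if params.blow_up_time <= times[2]:
                    n_discarded += 1
                    continue
                clean = vb_volume(params, np.array(times))
                noisy = clean * rng.uniform(
                    1.0 - spec.noise_level, 1.0 + spec.noise_level, size=3
                )
                if not (0 < noisy[0] < noisy[1] < noisy[2]):
                    n_discarded += 1
                    continue
                lesion_id = f"{grp.label}-{counter:04d}"
                counter += 1
                series.append(
                    VolumeTimeSeries(
                        lesion_id=lesion_id,
                        group=grp.label,
                        times=times,
                        volumes=tuple(noisy),
                    )
                )
                truth_rows.append(
                    {
                        "lesion_id": lesion_id,
                        "group": grp.label,
                        "true_beta": beta,
                        "true_alpha": alpha,
                        "true_V0": v0,
                    }
                )
                break
            else:
                raise ValidationError(
                    f"group {grp.label}: could not draw a growing lesion in "
                    "1000 attempts; beta/alpha ranges cause blow-up or the "
                    "noise level destroys growth"
                )
    return CohortSample(
        series=tuple(series),
        ground_truth=pd.DataFrame(truth_rows),
        n_discarded=n_discarded,
    )


@dataclass(frozen=True)
class SyntheticMouseSpec:
    """Animal-style series: fixed measurement days, late-day saturation."""

    n_mice: int = 24
    measurement_days: tuple[float, ...] = (7.0, 14.0, 18.0, 21.0, 25.0, 28.0)
    beta: TruncatedNormal = TruncatedNormal(1.44, 0.15, 1.0, 1.9)
    alpha: TruncatedNormal = TruncatedNormal(0.5, 0.1, 0.3, 0.7)
    V0: TruncatedNormal = TruncatedNormal(0.02, 0.005, 0.005, 0.05)
    noise_level: float = 0.0
    ceiling_volume: float | None = None  # cap applied to days > ceiling_after
    ceiling_after: float = 21.0
    decrease_fraction: float = 0.0  # fraction of mice with an injected dip
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValidationError("n_mice must be >= 1")
        days = self.measurement_days
        if any(d1 <= d0 for d0, d1 in zip(days, days[1:])):
            raise ValidationError("measurement days must be strictly increasing")
        if not 0 <= self.decrease_fraction <= 1:
            raise ValidationError("decrease_fraction must be in [0, 1]")


@dataclass(frozen=True)
class MouseSample:
    series: tuple[VolumeTimeSeries, ...]
    ground_truth: pd.DataFrame = field(repr=False)


def generate_mouse_series(
    spec: SyntheticMouseSpec, seed: int | np.random.Generator | None = None
) -> MouseSample:
    """Generate animal-style growth series at fixed measurement days.

    Volumes follow the power-law closed form; if ``ceiling_volume`` is
    set, measurements after ``ceiling_after`` days are capped at it
    (space-limitation saturation). A ``decrease_fraction`` of mice get
    their last pre-ceiling measurement deflated below its predecessor to
    exercise the decreasing-series exclusion rule; they are flagged in the
    ground truth as ``injected_decrease``.
    """
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    days = np.asarray(spec.measurement_days)
    series: list[VolumeTimeSeries] = []
    rows = []
    n_decrease = int(round(spec.decrease_fraction * spec.n_mice))
    for m in range(spec.n_mice):
        for _attempt in range(1000):
            beta = spec.beta.draw(rng)
            alpha = spec.alpha.draw(rng)
            v0 = spec.V0.draw(rng)
            params = VonBertalanffyParams(V0=v0, t0=days[0], alpha=alpha, beta=beta)
            if params.blow_up_time <= days[-1]:
                continue
            v = np.asarray(vb_volume(params, days), dtype=float)
            if spec.ceiling_volume is not None:
                late = days > spec.ceiling_after
                v[late] = np.minimum(v[late], spec.ceiling_volume)
            if spec.noise_level > 0:
                v = v * rng.uniform(
                    1.0 - spec.noise_level, 1.0 + spec.noise_level, size=len(v)
                )
            injected = m < n_decrease
            if injected:
                # deflate the last measurement at or before the ceiling cutoff
                k = int(np.nonzero(days <= spec.ceiling_after)[0][-1])
                v[k] = 0.8 * v[k - 1]
            if np.any(v <= 0):
                continue
            series.append(
                VolumeTimeSeries(
                    lesion_id=f"mouse-{m:03d}",
                    group="mouse",
                    times=tuple(days),
                    volumes=tuple(v),
                )
            )
            rows.append(
                {
                    "lesion_id": f"mouse-{m:03d}",
                    "true_beta": beta,
                    "true_alpha": alpha,
                    "true_V0": v0,
                    "injected_decrease": injected,
                }
            )
            break
        else:
            raise ValidationError("could not generate a valid mouse series")
    return MouseSample(series=tuple(series), ground_truth=pd.DataFrame(rows))
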