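"""Cohort I/O, group statistics and analysis orchestration.

The CSV schema is ``patient_id,lesion_id,group,time_days,volume_cm3``
(comma-separated, UTF-8, dot decimal, header required). Rows may arrive
in any order; they are grouped by lesion and sorted by time.

``run_cohort_analysis`` reproduces the study workflow on a parsed cohort:
a per-lesion growth exponent from the first three measurements, an
optional perturbation screen that drops sensitive lesions, a
Kolmogorov-Smirnov normality report, a Kruskal-Wallis omnibus comparison
across groups with Dunn/Holm post-hoc pairs, and a per-group exponent
sweep.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .beta_estimators import (
    GROUP_LABELS,
    GroupSweepResult,
    ThreePointRecord,
    VolumeTimeSeries,
    solve_three_point_beta,
    sweep_group_beta,
)
from .errors import (
    AmbiguousRootError,
    NoRootError,
    ScreenUndefinedError,
    ValidationError,
)
from .sensitivity import perturbation_screen

__all__ = [
    "COHORT_COLUMNS",
    "CohortTable",
    "read_cohort_csv",
    "write_cohort_csv",
    "dunn_posthoc",
    "CohortAnalysisConfig",
    "CohortAnalysisResult",
    "run_cohort_analysis",
]

COHORT_COLUMNS = ("patient_id", "lesion_id", "group", "time_days", "volume_cm3")


@dataclass(frozen=True)
class CohortTable:
    """Validated long-format cohort table."""

    frame: pd.DataFrame = field(repr=False)

    def series(self) -> tuple[VolumeTimeSeries, ...]:
        out = []
        for lesion_id, sub in self.frame.groupby("lesion_id", sort=True):
            sub = sub.sort_values("time_days")
            out.append(
                VolumeTimeSeries(
                    lesion_id=str(lesion_id),
                    group=str(sub["group"].iloc[0]),
                    times=tuple(sub["time_days"]),
                    volumes=tuple(sub["volume_cm3"]),
                )
            )
        return tuple(out)

    def __len__(self) -> int:
        return len(self.frame)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {sorted(missing)}")
    df = df.loc[:, list(COHORT_COLUMNS)].copy()
    problems = []
    for col in ("time_days", "volume_cm3"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: non-numeric {col} {df.at[i, col]!r}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["time_days", "volume_cm3"]].isna().any().any():
        rows = df.index[df[["time_days", "volume_cm3"]].isna().any(axis=1)]
        problems.extend(f"line {i + 2}: missing value" for i in rows)
    for grp in df["group"].unique():
        if grp not in GROUP_LABELS:
            problems.append(f"unknown group label {grp!r}")
    if not problems:
        for lesion_id, sub in df.groupby("lesion_id"):
            sub = sub.sort_values("time_days")
            t = sub["time_days"].to_numpy()
            v = sub["volume_cm3"].to_numpy()
            if np.any(np.diff(t) <= 0):
                problems.append(f"lesion {lesion_id}: duplicate or non-increasing times")
            if np.any(v <= 0):
                problems.append(f"lesion {lesion_id}: non-positive volume")
            elif np.any(np.diff(v) <= 0):
                # the cohort schema carries only growing lesions (the
                # study's inclusion criterion); decreases are a parse error
                problems.append(f"lesion {lesion_id}: decreasing volume")
            if sub["group"].nunique() > 1:
                problems.append(f"lesion {lesion_id}: inconsistent group labels")
    if problems:
        raise ValidationError("cohort CSV invalid:\n  " + "\n  ".join(problems))
    return df


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Parse and validate a cohort CSV; errors name the offending lesions."""
    df = pd.read_csv(path)
    return CohortTable(frame=_validate_frame(df))


def write_cohort_csv(
    series: tuple[VolumeTimeSeries, ...] | list[VolumeTimeSeries],
    path: str | Path,
    patient_ids: dict[str, str] | None = None,
) -> None:
    """Write series to the cohort CSV schema (patient_id defaults to the
    lesion_id, making write/read a round trip)."""
    rows = []
    for s in series:
        pid = (patient_ids or {}).get(s.lesion_id, s.lesion_id)
        for t, v in zip(s.times, s.volumes):
            rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": s.lesion_id,
                    "group": s.group,
                    "time_days": t,
                    "volume_cm3": v,
                }
            )
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(path, index=False)


def dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z-tests with Holm adjustment.

    Uses pooled mid-ranks with the standard tie correction
    sum(t^3 - t) / (12 (N - 1)).
    """
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    n = {g: len(samples[g]) for g in labels}
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = float(np.mean(ranks[start : start + n[g]]))
        start += n[g]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1))
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_value": p})
    df = pd.DataFrame(rows)
    # Holm step-down adjustment
    order = np.argsort(df["p_value"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * df["p_value"].iloc[idx])
        adj[idx] = min(running, 1.0)
    df["p_adjusted"] = adj
    return df


@dataclass(frozen=True)
class CohortAnalysisConfig:
    """Knobs for :func:`run_cohort_analysis`."""

    apply_perturbation_screen: bool = False
    screen_reps: int = 200
    screen_max_rel_err: float = 0.05
    screen_threshold: float = 0.5
    run_group_sweep: bool = True
    sweep_n_beta: int = 61
    sweep_n_v0: int = 60
    sweep_n_v1: int = 60
    sweep_beta_range: tuple[float, float] = (0.0, 3.0)
    alpha_level: float = 0.05
    seed: int | None = None


@dataclass(frozen=True)
class CohortAnalysisResult:
    betas: pd.DataFrame = field(repr=False)  # lesion_id, group, beta, method, residual
    group_summary: pd.DataFrame = field(repr=False)
    normality: pd.DataFrame = field(repr=False)
    kruskal_statistic: float | None
    kruskal_pvalue: float | None
    pairwise: pd.DataFrame | None = field(repr=False, default=None)
    sweeps: dict[str, GroupSweepResult] = field(default_factory=dict, repr=False)
    warnings: tuple[str, ...] = ()

    def write_bundle(self, outdir: str | Path) -> None:
        """Write betas.csv, groups.csv, pairwise.csv and sweep_<group>.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.betas.to_csv(outdir / "betas.csv", index=False)
        summary = self.group_summary.copy()
        summary["kruskal_statistic"] = self.kruskal_statistic
        summary["kruskal_pvalue"] = self.kruskal_pvalue
        summary.to_csv(outdir / "groups.csv", index=False)
        self.normality.to_csv(outdir / "normality.csv", index=False)
        if self.pairwise is not None:
            self.pairwise.to_csv(outdir / "pairwise.csv", index=False)
        for group, sweep in self.sweeps.items():
            safe = group.replace("+", "_")
            pd.DataFrame(
                {"beta_grid": sweep.beta_grid, "cumulative_error": sweep.cumulative_error}
            ).to_csv(outdir / f"sweep_{safe}.csv", index=False)
        if self.warnings:
            (outdir / "run.log").write_text("\n".join(self.warnings) + "\n")


def run_cohort_analysis(
    table: CohortTable | tuple[VolumeTimeSeries, ...],
    config: CohortAnalysisConfig | None = None,
) -> CohortAnalysisResult:
    """Per-lesion exponents, group statistics and per-group sweeps.

    The exponent of each lesion comes from its first three measurements
    via the three-point solver; lesions whose first three volumes are not
    strictly increasing (or where no root is found) are excluded with a
    logged warning, as are groups with fewer than 2 estimable lesions when
    it comes to the omnibus comparison.
    """
    config = config or CohortAnalysisConfig()
    series = table.series() if isinstance(table, CohortTable) else tuple(table)
    notes: list[str] = []
    rows = []
    records: dict[str, ThreePointRecord] = {}
    rng = np.random.default_rng(config.seed)
    for s in series:
        try:
            rec = ThreePointRecord.from_series(s)
            est = solve_three_point_beta(rec)
        except (ValidationError, NoRootError, AmbiguousRootError) as exc:
            notes.append(f"lesion {s.lesion_id} excluded: {exc}")
            continue
        if config.apply_perturbation_screen:
            try:
                screen = perturbation_screen(
                    rec,
                    n_reps=config.screen_reps,
                    max_rel_err=config.screen_max_rel_err,
                    threshold=config.screen_threshold,
                    seed=rng,
                )
            except ScreenUndefinedError:
                notes.append(f"lesion {s.lesion_id} excluded: screen undefined")
                continue
            if not screen.passed:
                notes.append(f"lesion {s.lesion_id} excluded: failed perturbation screen")
                continue
        records[s.lesion_id] = rec
        rows.append(
            {
                "lesion_id": s.lesion_id,
                "group": s.group,
                "beta": est.beta,
                "method": est.method,
                "residual": est.residual,
            }
        )
    betas = pd.DataFrame(rows, columns=["lesion_id", "group", "beta", "method", "residual"])

    summary_rows = []
    norm_rows = []
    group_values: dict[str, np.ndarray] = {}
    for group, sub in betas.groupby("group"):
        vals = sub["beta"].to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
        summary_rows.append(
            {"group": group, "n": len(vals), "median_beta": med, "q1": q1, "q3": q3}
        )
        if len(vals) >= 3 and np.std(vals) > 0:
            ks = sps.kstest((vals - np.mean(vals)) / np.std(vals, ddof=1), "norm")
            norm_rows.append(
                {"group": group, "ks_statistic": ks.statistic, "ks_pvalue": ks.pvalue}
            )
        if len(vals) >= 2:
            group_values[group] = vals
        else:
            notes.append(f"group {group} excluded from comparison: fewer than 2 lesions")

    kruskal_stat = kruskal_p = None
    pairwise = None
    if len(group_values) >= 2:
        kruskal_stat, kruskal_p = sps.kruskal(*group_values.values())
        kruskal_stat, kruskal_p = float(kruskal_stat), float(kruskal_p)
        if kruskal_p < config.alpha_level and len(group_values) >= 2:
            pairwise = dunn_posthoc(group_values)
    else:
        notes.append("omnibus comparison skipped: fewer than 2 comparable groups")

    sweeps: dict[str, GroupSweepResult] = {}
    if config.run_group_sweep:
        for group in betas["group"].unique():
            grp_records = [
                records[lid] for lid in betas.loc[betas["group"] == group, "lesion_id"]
            ]
            if grp_records:
                sweeps[group] = sweep_group_beta(
                    grp_records,
                    beta_range=config.sweep_beta_range,
                    n_beta=config.sweep_n_beta,
                    n_v0=config.sweep_n_v0,
                    n_v1=config.sweep_n_v1,
                )

    return CohortAnalysisResult(
        betas=betas,
        group_summary=pd.DataFrame(summary_rows),
        normality=pd.DataFrame(norm_rows, columns=["group", "ks_statistic", "ks_pvalue"]),
        kruskal_statistic=kruskal_stat,
        kruskal_pvalue=kruskal_p,
        pairwise=pairwise,
        sweeps=sweeps,
        warnings=tuple(notes),
    )
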