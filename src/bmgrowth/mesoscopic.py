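"""Stochastic discrete mesoscopic simulator of clonal tumor growth.

The tumor lives on a 3D voxel lattice. Each voxel holds up to K cells
belonging to one or two clonal populations (population 0 is the baseline
clone, population 1 the "aggressive" clone carrying multiplicative
advantages in division and migration). Per time step and per voxel, the
number of cells of a population succeeding at a process is a single
binomial draw:

- division:  B(N, v_div * r_div * dt * (1 - N_tot/K))
- death:     B(N, r_death * dt * N_tot/K)
- migration: B(N - deaths, v_mig * D * dt / dx**2), migrants split
  uniformly over the 6 face-adjacent neighbors.

Boundaries are no-flux: migrants that would leave the lattice stay put.
Destination voxels never exceed K; migrants that do not fit remain in
their source voxel. All draws for one step are computed from the pre-step
state and applied synchronously via staging buffers. Cells never switch
population.

Treatment operators either wipe out one population or thin both to a
target size and composition; the growth exponent of a simulated
trajectory is extracted with the same three-point solver used for
clinical series, sampling one random recorded time from each third of
the simulated (or post-treatment) time span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .beta_estimators import BetaEstimate, ThreePointRecord, solve_three_point_beta
from .errors import (
    AmbiguousRootError,
    ConfigurationError,
    NoRootError,
    SamplingError,
    TreatmentError,
    ValidationError,
)

__all__ = [
    "ClonalTraits",
    "SimConfig",
    "LatticeState",
    "TreatmentSpec",
    "SimulationTrajectory",
    "binomial_process_update",
    "step",
    "simulate",
    "apply_treatment",
    "beta_from_trajectory",
    "advantage_sweep",
    "AdvantageSweepResult",
]

#: step length of 4 hours, in days
DEFAULT_DT = 4.0 / 24.0


@dataclass(frozen=True)
class ClonalTraits:
    """Per-population process rates and advantage coefficients.

    Rates are per day; the migration coefficient is in mm^2/day. The
    advantage coefficients multiply the division rate and the migration
    coefficient respectively and must be >= 1.
    """

    division_rate: float = 0.36
    death_rate: float = 0.144
    migration_coefficient: float = 2.88
    v_div: float = 1.0
    v_mig: float = 1.0

    def __post_init__(self) -> None:
        for name in ("division_rate", "death_rate", "migration_coefficient"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.v_div < 1 or self.v_mig < 1:
            raise ValidationError("advantage coefficients must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Lattice, time-stepping and start/stop configuration."""

    lattice_size: int = 80
    voxel_size: float = 1.0  # mm
    K: int = 200_000
    dt: float = DEFAULT_DT  # days
    initial_cells: int = 10
    initial_aggressive_fraction: float = 0.0
    limit_volume: float = 10.0  # cm^3
    record_every: float = 1.0  # days
    max_steps: int = 12_000
    seed: int | None = None
    # if True, the per-step migration probability carries a crowding factor
    # N_tot/K (cells escape dense voxels); if False it is density-free.
    # The crowding form produces front-limited ball growth, which is what
    # gives homogeneous tumors their ~2/3 exponent.
    migration_crowding: bool = True
    # minimum initial cell number used when the aggressive fraction is too
    # small to be representable with `initial_cells` cells
    small_fraction_floor: int = 1000

    def __post_init__(self) -> None:
        if self.lattice_size < 3:
            raise ValidationError("lattice_size must be >= 3")
        if self.K < 1:
            raise ValidationError("K must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")
        if self.initial_cells < 1:
            raise ValidationError("initial_cells must be >= 1")
        if not 0 <= self.initial_aggressive_fraction <= 1:
            raise ValidationError("initial_aggressive_fraction must be in [0, 1]")

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.voxel_size**3) / 1000.0


def validate_probabilities(traits: ClonalTraits, config: SimConfig) -> None:
    """Check that every per-step probability lies in [0, 1].

    Raises :class:`ConfigurationError` otherwise (e.g. a migration
    advantage large enough that v_mig * D * dt / dx^2 > 1).
    """
    p_div = traits.v_div * traits.division_rate * config.dt
    p_death = traits.death_rate * config.dt
    p_mig = traits.v_mig * traits.migration_coefficient * config.dt / config.voxel_size**2
    for name, p in (("division", p_div), ("death", p_death), ("migration", p_mig)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(
                f"per-step {name} probability {p:.3f} outside [0, 1]; "
                "reduce dt or the advantage coefficient"
            )


@dataclass
class LatticeState:
    """Cell counts per population on the voxel lattice.

    ``counts`` has shape (n_populations, L, L, L) with integer dtype.
    """

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.counts.ndim != 4:
            raise ValidationError("counts must have shape (n_pops, L, L, L)")
        if np.any(self.counts < 0):
            raise ValidationError("cell counts must be non-negative")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    def population_totals(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2, 3))

    def total_cells(self) -> int:
        return int(self.counts.sum())

    def occupancy(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class TreatmentSpec:
    """When and how treatment is applied.

    ``trigger_volume`` (cm^3) or ``trigger_time`` (days): whichever is set
    fires first. Scenarios:

    - ``deplete_aggressive``: population 1 removed entirely.
    - ``deplete_less_aggressive``: population 0 removed entirely.
    - ``balanced``: total cells thinned to ``survival_fraction`` of the
      pre-treatment total, with the surviving pool composed so the
      aggressive proportion equals ``post_aggressive_fraction``
      (binomial thinning per voxel).
    """

    scenario: str
    trigger_volume: float | None = 1.0
    trigger_time: float | None = None
    survival_fraction: float = 0.1
    post_aggressive_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.scenario not in ("deplete_aggressive", "deplete_less_aggressive", "balanced"):
            raise ValidationError(f"unknown treatment scenario {self.scenario!r}")
        if not 0 <= self.survival_fraction <= 1:
            raise ValidationError("survival_fraction must be in [0, 1]")
        if not 0 <= self.post_aggressive_fraction <= 1:
            raise ValidationError("post_aggressive_fraction must be in [0, 1]")
        if self.trigger_volume is None and self.trigger_time is None:
            raise ValidationError("treatment needs a volume or time trigger")


@dataclass(frozen=True)
class SimulationTrajectory:
    """Recorded time series from one simulation run."""

    times: np.ndarray  # days
    total_volume: np.ndarray  # cm^3
    population_counts: np.ndarray  # (n_times, n_pops)
    treatment_time: float | None = None
    stagnated: bool = False

    def aggressive_fraction(self) -> np.ndarray:
        tot = self.population_counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.population_counts[:, -1] / tot, 0.0)


def binomial_process_update(
    N: int | np.ndarray, p: float, rng: np.random.Generator
) -> int | np.ndarray:
    """Number of successes among N cells each succeeding with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"probability {p} outside [0, 1]")
    return rng.binomial(N, p)


def _active_box(occ: np.ndarray, margin: int = 1) -> tuple[slice, slice, slice]:
    """Bounding box of occupied voxels, expanded by ``margin`` and clipped."""
    nz = np.nonzero(occ)
    slices = []
    for axis in range(3):
        lo = max(int(nz[axis].min()) - margin, 0)
        hi = min(int(nz[axis].max()) + margin + 1, occ.shape[axis])
        slices.append(slice(lo, hi))
    return tuple(slices)


def step(
    state: LatticeState,
    traits: Sequence[ClonalTraits],
    config: SimConfig,
    rng: np.random.Generator,
    check: bool = False,
) -> LatticeState:
    """Advance the lattice by one time step of length ``config.dt``.

    Division, death and migration are sampled per voxel and population
    from the pre-step state and applied synchronously. Division is capped
    so no voxel exceeds K; migrants that would overfill their destination
    stay in their source voxel (cell number is conserved exactly by
    migration). Returns a new state; the input state is not modified.

    With ``check=True`` the capacity invariant is asserted on the result.
    """
    if len(traits) != state.n_populations:
        raise ValidationError("one ClonalTraits per population required")
    K = config.K
    dt = config.dt
    counts = state.counts
    if state.total_cells() == 0:
        return LatticeState(counts=counts.copy(), time=state.time + dt)

    box = _active_box(state.occupancy())
    sub = counts[(slice(None), *box)]  # (n_pops, bx, by, bz) view
    new_counts = counts.copy()
    n_pops = state.n_populations

    occ = sub.sum(axis=0)
    frac = occ / K

    # -- division and death, drawn from the pre-step state --------------
    births = np.zeros_like(sub)
    deaths = np.zeros_like(sub)
    for i, tr in enumerate(traits):
        p_div = tr.v_div * tr.division_rate * dt
        p_death = tr.death_rate * dt
        births[i] = rng.binomial(sub[i], np.clip(p_div * (1.0 - frac), 0.0, 1.0))
        deaths[i] = rng.binomial(sub[i], np.clip(p_death * frac, 0.0, 1.0))

    # cap total births so voxel totals never exceed K; populations are
    # served in index order (only binds within rounding of capacity)
    survivors = sub - deaths
    free = K - survivors.sum(axis=0)
    capped_births = np.zeros_like(births)
    for i in range(n_pops):
        take = np.minimum(births[i], free)
        capped_births[i] = take
        free = free - take
    staged = survivors + capped_births  # per pop, before migration

    # -- migration -------------------------------------------------------
    # emigrants drawn from survivors; uniformly split over 6 directions
    dirs = [(0, -1), (0, 1), (1, -1), (1, 1), (2, -1), (2, 1)]
    emig = np.zeros((n_pops, 6) + sub.shape[1:], dtype=sub.dtype)
    any_migration = False
    for i, tr in enumerate(traits):
        p_mig = tr.v_mig * tr.migration_coefficient * dt / config.voxel_size**2
        if p_mig == 0.0:
            continue
        if p_mig > 1.0:
            raise ConfigurationError(f"migration probability {p_mig:.3f} > 1")
        if config.migration_crowding:
            movers = rng.binomial(survivors[i], p_mig * frac)
        else:
            movers = rng.binomial(survivors[i], p_mig)
        total_movers = int(movers.sum())
        if total_movers == 0:
            continue
        any_migration = True
        split = rng.multinomial(movers.ravel(), np.full(6, 1.0 / 6.0))
        emig[i] = split.T.reshape((6,) + sub.shape[1:])

    if not any_migration:
        new_counts[(slice(None), *box)] = staged
        out = LatticeState(counts=new_counts, time=state.time + dt)
        if check:
            _assert_capacity(out, K)
        return out

    # global-boundary reflection: migrants pointing off the lattice never
    # leave (zeroed here, so they simply stay in `staged`). The box has a
    # 1-voxel interior margin except where it touches the lattice
    # boundary, so every other migrant lands inside the box.
    L = config.lattice_size
    for d, (axis, sign) in enumerate(dirs):
        edge_global = box[axis].start == 0 if sign < 0 else box[axis].stop == L
        if edge_global:
            sl = [slice(None)] * 3
            sl[axis] = 0 if sign < 0 else -1
            emig[(slice(None), d, *sl)] = 0

    # remove departing cells from their sources
    for i in range(n_pops):
        staged[i] -= emig[i].sum(axis=0)

    outstanding = emig.sum(axis=(0, 1))  # cells still in flight, per source
    T = staged.sum(axis=0)  # running per-voxel totals of settled cells

    def _shift(arr: np.ndarray, axis: int, sign: int) -> np.ndarray:
        """Move arr one voxel along axis (within the box, zero-filled)."""
        out = np.zeros_like(arr)
        if sign > 0:
            out[tuple(slice(1, None) if a == axis else slice(None) for a in range(3))] = arr[
                tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))
            ]
        else:
            out[tuple(slice(None, -1) if a == axis else slice(None) for a in range(3))] = arr[
                tuple(slice(1, None) if a == axis else slice(None) for a in range(3))
            ]
        return out

    for d, (axis, sign) in enumerate(dirs):
        for i in range(n_pops):
            e = emig[i, d]
            if not e.any():
                continue
            arrivals = _shift(e, axis, sign)
            # accept up to the space not reserved for the destination's own
            # in-flight emigrants (guarantees the capacity bound even if
            # they all bounce back)
            room = np.maximum(K - T - outstanding, 0)
            accepted = np.minimum(arrivals, room)
            bounced = arrivals - accepted
            staged[i] += accepted
            T = T + accepted
            back = _shift(bounced, axis, -sign)
            staged[i] += back
            T = T + back
            outstanding = outstanding - e  # this component now settled

    new_counts[(slice(None), *box)] = staged
    out = LatticeState(counts=new_counts, time=state.time + dt)
    if check:
        _assert_capacity(out, K)
    return out


def _assert_capacity(state: LatticeState, K: int) -> None:
    occ = state.occupancy()
    if int(occ.max(initial=0)) > K:
        raise AssertionError(f"capacity exceeded: max occupancy {int(occ.max())} > K={K}")


def initial_state(config: SimConfig, n_populations: int = 2) -> LatticeState:
    """All initial cells in the central voxel, split by the aggressive fraction.

    If the configured fraction is positive but not representable with
    ``initial_cells`` cells (e.g. 1% of 10), the initial cell number is
    raised to ``small_fraction_floor`` so the stated proportion holds.
    """
    n = config.initial_cells
    f = config.initial_aggressive_fraction
    if n_populations == 1:
        n_agg = 0
    else:
        n_agg = int(round(f * n))
        if f > 0 and n_agg == 0:
            n = config.small_fraction_floor
            n_agg = max(1, int(round(f * n)))
    L = config.lattice_size
    counts = np.zeros((n_populations, L, L, L), dtype=np.int64)
    c = L // 2
    counts[0, c, c, c] = n - n_agg
    if n_populations > 1:
        counts[1, c, c, c] = n_agg
    return LatticeState(counts=counts, time=0.0)


def apply_treatment(
    state: LatticeState, spec: TreatmentSpec, rng: np.random.Generator
) -> LatticeState:
    """Apply a treatment scenario, returning a new state at the same time."""
    counts = state.counts.copy()
    if spec.scenario == "deplete_aggressive":
        counts[1] = 0
    elif spec.scenario == "deplete_less_aggressive":
        counts[0] = 0
    else:  # balanced
        totals = counts.sum(axis=(1, 2, 3))
        total = int(totals.sum())
        if total == 0:
            raise TreatmentError("no cells to treat")
        target_total = spec.survival_fraction * total
        target_agg = spec.post_aggressive_fraction * target_total
        target_less = target_total - target_agg
        targets = (target_less, target_agg)
        for i in (0, 1):
            if targets[i] > 0 and totals[i] == 0:
                raise TreatmentError(
                    f"population {i} absent but a positive post-treatment share requested"
                )
            if totals[i] > 0:
                p = targets[i] / totals[i]
                if p > 1.0 + 1e-12:
                    raise TreatmentError(
                        f"population {i}: requested survivors exceed current cells"
                    )
                counts[i] = rng.binomial(state.counts[i], min(p, 1.0))
    return LatticeState(counts=counts, time=state.time)


def simulate(
    config: SimConfig,
    traits: Sequence[ClonalTraits],
    treatment: TreatmentSpec | None = None,
    seed: int | np.random.Generator | None = None,
    check: bool = False,
) -> SimulationTrajectory:
    """Run a full simulation until the limit volume, extinction, or the
    step budget.

    The trajectory is recorded every ``config.record_every`` days
    (including t=0 and the final step). If the budget is exhausted before
    the limit volume is reached a stagnation warning is emitted and the
    partial trajectory is returned with ``stagnated=True``.
    """
    for tr in traits:
        validate_probabilities(tr, config)
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed if seed is not None else config.seed)
    state = initial_state(config, n_populations=len(traits))

    record_steps = max(1, int(round(config.record_every / config.dt)))
    times = [state.time]
    volumes = [state.total_cells() / config.K * config.voxel_volume_cm3]
    pops = [state.population_totals().copy()]
    treatment_time: float | None = None
    treated = treatment is None  # nothing pending if no treatment given
    stagnated = True

    for n in range(1, config.max_steps + 1):
        state = step(state, traits, config, rng, check=check)
        total = state.total_cells()
        vol = total / config.K * config.voxel_volume_cm3

        if not treated:
            fire = (
                treatment.trigger_time is not None and state.time >= treatment.trigger_time
            ) or (
                treatment.trigger_volume is not None and vol >= treatment.trigger_volume
            )
            if fire:
                state = apply_treatment(state, treatment, rng)
                treated = True
                treatment_time = state.time
                total = state.total_cells()
                vol = total / config.K * config.voxel_volume_cm3

        done = vol >= config.limit_volume or total == 0
        if n % record_steps == 0 or done or treatment_time == state.time:
            times.append(state.time)
            volumes.append(vol)
            pops.append(state.population_totals().copy())
        if done:
            stagnated = False
            break

    if stagnated:
        warnings.warn(
            "step budget exhausted before reaching the limit volume; "
            "returning partial trajectory",
            RuntimeWarning,
            stacklevel=2,
        )
    return SimulationTrajectory(
        times=np.array(times),
        total_volume=np.array(volumes),
        population_counts=np.array(pops),
        treatment_time=treatment_time,
        stagnated=stagnated,
    )


def beta_from_trajectory(
    traj: SimulationTrajectory,
    rng: int | np.random.Generator | None = None,
    start_time: float | None = None,
    max_retries: int = 200,
) -> BetaEstimate:
    """Growth exponent from a trajectory via random three-point sampling.

    One recorded time is drawn uniformly from each third of the time span
    [start, end] (``start_time`` defaults to the treatment time if the
    trajectory was treated, else the first recorded time); the resulting
    record is passed to the three-point solver. Draws are retried while
    the sampled volumes are not strictly increasing.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if start_time is None:
        start_time = traj.treatment_time if traj.treatment_time is not None else traj.times[0]
    mask = traj.times >= start_time
    t = traj.times[mask]
    v = traj.total_volume[mask]
    if len(t) < 3:
        raise SamplingError("trajectory has fewer than 3 recorded points in range")
    t_start, t_end = t[0], t[-1]
    edges = np.linspace(t_start, t_end, 4)
    thirds = [
        np.nonzero((t >= edges[k]) & (t <= edges[k + 1]))[0] for k in range(3)
    ]
    if any(len(ix) == 0 for ix in thirds):
        raise SamplingError("a third of the time span contains no recorded point")
    for _ in range(max_retries):
        i0, i1, i2 = (int(rng.choice(ix)) for ix in thirds)
        if not (t[i0] < t[i1] < t[i2] and 0 < v[i0] < v[i1] < v[i2]):
            continue
        try:
            return solve_three_point_beta(
                ThreePointRecord(t[i0], t[i1], t[i2], v[i0], v[i1], v[i2])
            )
        except (NoRootError, AmbiguousRootError):
            continue
    raise SamplingError("retry budget exhausted sampling a monotone growing triple")


@dataclass(frozen=True)
class AdvantageSweepResult:
    """Replicate-mean growth exponents over an advantage-coefficient grid."""

    v_div_grid: np.ndarray
    v_mig_grid: np.ndarray
    mean_beta: np.ndarray  # (len(v_div_grid), len(v_mig_grid))
    argmax: tuple[float, float]  # (v_div, v_mig) of the largest mean beta


def advantage_sweep(
    v_div_grid: Sequence[float],
    v_mig_grid: Sequence[float],
    initial_aggressive_fraction: float = 0.1,
    replicates: int = 5,
    config: SimConfig | None = None,
    base_traits: ClonalTraits | None = None,
    seed: int | None = None,
) -> AdvantageSweepResult:
    """Mean growth exponent for each (v_div, v_mig) advantage combination.

    Each grid point runs ``replicates`` independent simulations (distinct
    seeds spawned from ``seed``) of a two-population tumor with the given
    initial aggressive fraction, extracts beta from each trajectory, and
    stores the mean.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    config = config or SimConfig()
    base = base_traits or ClonalTraits()
    config = replace(config, initial_aggressive_fraction=initial_aggressive_fraction)
    ss = np.random.SeedSequence(seed)
    vd = np.asarray(v_div_grid, dtype=float)
    vm = np.asarray(v_mig_grid, dtype=float)
    mean_beta = np.empty((len(vd), len(vm)))
    for i, v_div in enumerate(vd):
        for j, v_mig in enumerate(vm):
            aggressive = replace(base, v_div=float(v_div), v_mig=float(v_mig))
            betas = []
            for child in ss.spawn(replicates):
                rng = np.random.default_rng(child)
                traj = simulate(config, [base, aggressive], seed=rng)
                betas.append(beta_from_trajectory(traj, rng=rng).beta)
            mean_beta[i, j] = float(np.mean(betas))
    i, j = np.unravel_index(int(np.argmax(mean_beta)), mean_beta.shape)
    return AdvantageSweepResult(
        v_div_grid=vd, v_mig_grid=vm, mean_beta=mean_beta,
        argmax=(float(vd[i]), float(vm[j])),
    )
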