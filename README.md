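# bmgrowth

Growth-exponent analysis and stochastic clonal-competition simulation for
longitudinal tumor-volume data.

The package implements, end to end:

- **Growth laws** (`bmgrowth.growth_laws`): the power-law ODE
  `dV/dt = alpha * V**beta` (maintenance term fixed at 0) in closed form,
  with the exponential limit at `beta = 1` and finite-time blow-up handling
  for `beta > 1`; plus four textbook benchmark curves (exponential, cubic,
  Gompertz, logistic).
- **Exponent estimators** (`bmgrowth.beta_estimators`):
  - a three-point implicit solver — `beta` is the root of
    `(1-(V1/V0)^(1-b))/(1-(V2/V0)^(1-b)) = (t1-t0)/(t2-t0)`, located by a
    sign-change scan plus Brent refinement;
  - a multi-point discretized log-linear fit (`ln(dV/dt)` vs `ln V`),
    with a late-time-point filter and a decreasing-series exclusion rule;
  - a group-level grid sweep that finds the single exponent minimizing the
    summed relative volume error over all lesions in a group.
- **Sensitivity analyses** (`bmgrowth.sensitivity`): a ±5% per-volume
  perturbation screen (200 replicates, consistency threshold 0.5) and
  exponent distributions over random triplets of the benchmark curves with
  ±20% noise.
- **Mesoscopic simulator** (`bmgrowth.mesoscopic`): a 3D voxel lattice
  (default 80³ voxels, carrying capacity 2·10⁵ cells/voxel, 4-hour steps)
  with two clonal populations updated by per-voxel binomial draws of
  division, death and migration; treatment operators (depletion of either
  clone, balanced binomial thinning); exponent extraction from simulated
  trajectories; advantage-coefficient sweeps.
- **Synthetic data** (`bmgrowth.synthetic`): cohort and animal-style series
  generators with known ground truth, realistic inter-scan intervals,
  multiplicative volume noise, late-day saturation ceilings, and injected
  decreases to exercise the exclusion rules.
- **Pipeline + CLI** (`bmgrowth.pipeline`, `bmgrowth.cli`): cohort CSV I/O
  (`patient_id,lesion_id,group,time_days,volume_cm3`), per-lesion exponents,
  Kolmogorov–Smirnov normality report, Kruskal–Wallis omnibus comparison
  with Dunn/Holm post-hoc pairs, and per-group sweeps.

## Test

```sh
python -m pytest -q tests/
```

Note: three tests in `tests/test_acceptance.py::TestCriterion5InSilicoBetas`
are **expected to fail**. They compare replicate-mean simulated exponents
against externally printed values that are not reproducible with the
process-probability forms adopted here (the source defers those forms to an
upstream model without restating them). They are left red deliberately
rather than loosened; `notes/` (outside the package) documents the analysis.

## CLI

```sh
bmgrowth synth --n-per-group 30 --seed 0 --out cohort.csv   # + ground truth sidecar
bmgrowth estimate cohort.csv --out results/                 # betas + group stats
bmgrowth sweep cohort.csv --n-beta 60 --n-volumes 100       # group exponent sweep
bmgrowth sensitivity cohort.csv --out screen.csv            # perturbation screen
bmgrowth simulate --v-div 1.8 --v-mig 1.925 --seed 1        # lattice simulation
bmgrowth advantage-sweep --v-div-grid 1.25,1.8 --v-mig-grid 1.05,2.0
```

The full sweep grid (300 beta × 500 × 500 volume candidates per lesion,
~75M evaluations) takes minutes per group; `--n-beta/--n-volumes` reduce it.

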