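# Methods

## 1. Model

Two populations — resident hunter-gatherers (`HG`) and incoming farmers
(`F`) — interact as competing species with an assimilation channel:

```
dHG/dt = γ_hg · HG · (1 − HG/K_hg) − δ_hg · HG · F
dF/dt  = γ'_f · F · (1 − F/K_f) + η · I_hg − δ_f · HG · F
I_hg   = δ_hg · HG · F
```

Each population grows logistically toward its own carrying capacity.
Cross-population contact removes hunter-gatherers at rate `δ_hg·HG·F`
(the loss flux `I_hg`), of which a fraction `η` is absorbed into the
farming population (assimilation/acculturation); contact likewise removes
farmers at rate `δ_f·HG·F`. Farmer growth combines an intrinsic rate and
a migration contribution, `γ'_f = γ_f + μ`; the two are not separately
identifiable from aggregate density trajectories and are reported both
individually and as their sum.

Assumptions: spatially aggregated (no diffusion), deterministic densities,
constant rates over the study window, and assimilated individuals behaving
demographically as farmers from the moment of conversion.

### Equilibria and invasion analysis

The system has up to four fixed points: extinction `(0,0)`, HG-only
`(K_hg, 0)`, farmer-only `(0, K_f)`, and, when the nullclines cross in the
positive quadrant, an interior coexistence point obtained from the 2×2
linear nullcline system. Linearizing at the boundary equilibria gives the
invasion eigenvalues

```
λ_hg = γ_hg − δ_hg · K_f          (rare HG invading farmers at K_f)
λ_f  = γ'_f + (η·δ_hg − δ_f) · K_hg   (rare farmers invading HG at K_hg)
```

Mutual-invasibility signs classify the regime: farmers only, HG only,
coexistence (both invade), or initial-condition dependence (neither
invades). `equilibria.invasion_thresholds` returns the closed-form critical
rates implied by setting each eigenvalue to zero; these are the exact
boundaries that the grid explorations and the acceptance script recover.

## 2. Parameters

| name | meaning | units | prior / default |
|---|---|---|---|
| `gamma_hg` | HG intrinsic growth rate | 1/y | U(0.001, 0.022) |
| `gamma_f` | farmer intrinsic growth rate | 1/y | U(0.015, 0.035) |
| `mu` | farmer migration contribution | 1/y | U(0, 0.035) |
| `delta_hg` | HG interspecific mortality | 1/(y·density) | U(0, 0.04) |
| `delta_f` | farmer interspecific mortality | 1/(y·density) | U(0, 0.04) |
| `eta` | assimilation fraction of the HG loss flux | — | U(0, 0.3) |
| `rho` | initial farmer/HG density ratio | — | U(0.1, 0.4) |
| `hg0` | initial HG density (units of `K_hg`) | density | U(0.8, 1.2) |
| `k_hg` | HG carrying capacity | density | 1.0 (density unit) |
| `k_f` | farmer carrying capacity | density | 1.5·`hg0` in inference; 1.5 in exploration |

Densities are expressed in units of the HG carrying capacity, which fixes
`K_hg = 1` without loss of generality. In inference `K_f` is tied to the
observed peak-SPD ratio of the two date groups (`kf_ratio`), reflecting
that farming economies support higher population densities on the same
land; the exploration grids fix `K_f = 1.5`.

Scenario exploration uses two grids (50×50 cells by default, nine
(η, ρ) scenario combinations with η ∈ {0, 0.1, 0.2}, ρ ∈ {0.1, 0.2, 0.4},
1,500-year horizon):

- **Experiment 1** sweeps both interspecific mortalities over [0, 0.04] at
  fixed growth rates `γ_hg = 0.015`, `γ'_f = 0.02`.
- **Experiment 2** sweeps `γ_hg ∈ [0.001, 0.022]` and
  `γ'_f ∈ [0.015, 0.07]` at fixed `δ_hg = δ_f = 0.01`.

Three event times are recorded per cell: farmer overtake (first year
`F > HG`, scanning from year 1), farmer arrival at carrying capacity
(`F ≥ 0.99·K_f`), and HG quasi-extinction (`HG < 0.01·K_hg`). The 1%
tolerances make the asymptotic events well-defined in finite time.

## 3. Radiocarbon observation model

A calibration curve maps calendar years (cal BP, annual grid) to
conventional radiocarbon ages (CRA) with a curve error. A date
`(cra, sd)` calibrates to the normalized density

```
p(t) ∝ Normal(cra; c14(t), sd² + σ_curve(t)²)
```

on the annual calendar grid. The summed probability distribution (SPD) of
a set of dates is the per-year sum of their calibrated densities (either
raw, or normalized per date).

Case construction from a labelled date table applies, in order:

1. drop dates with `sd > 120` y;
2. calibrate and take the median calibrated date of each sample; the
   analysis window starts 100 y before the earliest farming median and
   ends at the peak of the provisional farmer SPD (overridable);
3. drop dates with ≤ 50% of their calibrated mass inside the window
   (strictly more than half must fall inside);
4. thin chronological clusters: within each label, dates are grouped into
   20-year bins of their calibrated medians and one representative kept
   per bin, which damps site-intensity artefacts in the SPD.

## 4. Inference (ABC-SMC)

The forward simulator integrates a candidate parameter vector over the
window, samples date counts proportional to the simulated densities,
assigns HG/farmer labels binomially from the relative densities at each
sampled year, attaches measurement errors resampled from the observed
error pool, perturbs the implied CRA accordingly, and rebuilds the two
SPDs exactly as for the observed data. The distance is the sum of the two
Euclidean norms between simulated and observed per-label SPD vectors.

The sampler is a sequential ABC:

- **Stage 0**: rejection — simulate `n_sims` prior draws, keep the best
  `keep` by distance.
- **Stages 1…S**: set the tolerance to the 25th percentile of the current
  particles' distances, then propose from the particles with a uniform
  kernel `U(x − 20%·x, x + 20%·x)` (with an absolute jitter floor of
  `1e-4` of each prior's width so particles at zero can still move),
  redrawing proposals that leave the prior support (clipping after 100
  redraws), until `keep` acceptances. Particles are unweighted; the final
  posterior pools `starts` independent replicate runs and keeps the
  overall best `keep` particles.

The full budget is 15,000 simulations / 500 kept / 6 stages / 100 starts;
the reduced desk-scale budget (`ABCBudget.reduced()`) is 1,500 / 100 / 3 /
5. Tolerances are non-increasing across stages by construction, which the
test suite asserts per start.

Posterior summaries report per-parameter median, mean, and 95% highest
posterior density intervals (shortest interval, computed with `arviz`),
posterior event-time distributions, the posterior probability of HG
quasi-extinction within the window, and posterior-predictive 95% SPD bands.

## 5. Synthetic generator: scope

`synthetic.generate_dataset` and the tactical recovery suite exercise the
full pipeline on data whose truth is known. The generator emulates:

- model-driven sampling intensity (dates drawn proportional to simulated
  densities),
- binomial cultural labelling from relative densities,
- calibration-curve information loss (calendar years are passed through
  the curve to CRAs and back, including curve error and lab error),
- lab-error heterogeneity (per-date errors from a scalar, callable, or
  resampled pool).

It does **not** emulate: spatial structure or site-level clustering beyond
what bin-thinning removes, taphonomic loss as a function of age, reservoir
effects or offsets between materials, or inter-lab systematic biases. The
bundled curves (`identity_curve`, `wiggly_curve`) are synthetic test
artefacts, not measured calibration curves; real analyses should load a
published curve via `load_calcurve`.

The tactical design crosses sample sizes, window lengths and window
offsets, with replicate synthetic datasets per cell, and reports bias,
RMSE, and 95%-HPDI coverage per parameter per cell. Cells in which no
replicate yields a fittable case (e.g. too few dates to form both-label
SPDs) are reported with `n_replicates = 0` and NaN scores rather than
dropped.

## 6. Numerical choices

- **Default integrator**: adaptive RK45 (`scipy.integrate.solve_ivp`,
  `rtol 1e-10`, `atol 1e-16`) with annual output. The absolute tolerance is
  kept far below `rtol` times the extinction floor because relative error
  control is what matters in exponential decay: absolute per-step errors
  committed once a population is small persist as large relative errors in
  its tail. A fixed-step RK4 with a
  user-chosen step (`integrate_fixed`) provides an independent oracle; the
  test suite requires agreement at `rtol 1e-5` against a 100×-finer step
  across parameter sets spanning the prior supports.
- **Throughput integrator**: grid exploration and ABC simulation use a
  batched fixed-step RK4 with an annual step (`integrate_batch`),
  numba-jitted when numba is available, with a pure-numpy fallback that
  matches the jitted path to machine precision. The annual step is accurate
  to well below the event-time resolution (events are reported in whole
  years) at these rates (|rates| ≤ 0.07/y).
- **State clamping**: derivatives clamp negative states to zero and
  trajectories are clipped at an extinction floor of `1e-12`, preventing
  sign-flip blow-ups of the logistic terms near extinction.
- **Calibration at scale**: per-date densities are evaluated only on the
  calendar slice where the curve can place the date (bracketed at ±8
  combined standard deviations using running min/max envelopes of the
  curve's CRA axis), then renormalized — exact to normalization, since the
  excluded tail mass is below double-precision relevance.
- **Density memoization**: inside ABC, simulated CRAs are rounded to
  integer years and their calibrated densities cached keyed on
  `(integer CRA, sd)`; the 1-year rounding is far below measurement error
  (≥ several decades) and makes the cache effective across proposals.
- **Seeding**: all stochastic fan-out (replicates, starts) derives child
  generators from `numpy.random.SeedSequence.spawn`, so runs are
  reproducible from a single master seed and independent across children.
- **Problem sizes**: grid resolution 50, horizon 1,500 y, SPD chunk size
  256, and the reduced ABC budget are package defaults chosen to keep a
  desk-scale analysis in minutes on one CPU; all are overridable.

## 7. Limitations

- The model is deterministic and spatially aggregated; it cannot represent
  wave-of-advance geography, demographic stochasticity at low densities,
  or time-varying contact rates.
- `γ_f` and `μ` are only weakly identified individually (their sum drives
  the dynamics); interpret `gamma_f_total`.
- SPDs are a lossy summary: posterior uncertainty from the reduced budget
  is wide, and interval coverage rather than point accuracy is the
  realistic target at archaeological sample sizes (see the tactical suite).
- The event-time grids and critical thresholds are exact properties of the
  model, not empirical claims about any particular region; fitting real
  regional date tables requires the full ABC budget and a measured
  calibration curve.
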