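# demicdyn

Demographic competition between hunter-gatherer and migrant farming
populations, modelled as a generalized Lotka–Volterra system, with

- analytic classification of the competition outcomes (who can invade whom,
  and when coexistence is possible),
- scenario exploration of *event times* — how long until farmers outnumber
  foragers, reach carrying capacity, or drive foragers below an extinction
  threshold — across grids of interaction rates,
- a forward simulator that turns model trajectories into synthetic
  radiocarbon date samples and summed probability distributions (SPDs), and
- likelihood-free (ABC-SMC) inference that fits the interaction rates to
  labelled radiocarbon date tables.

## The scientific problem

When farming spreads into a region occupied by hunter-gatherers, the
archaeological record (typically radiocarbon-dated material attributable to
one population or the other) shows farmers growing while foragers decline.
The model treats the two populations as competing species:

```
dHG/dt = γ_hg · HG · (1 − HG/K_hg) − δ_hg · HG · F
dF/dt  = γ'_f · F · (1 − F/K_f) + η · δ_hg · HG · F − δ_f · HG · F
```

- `HG`, `F`: hunter-gatherer and farmer population densities,
- `γ_hg`: intrinsic HG growth rate; `γ'_f = γ_f + μ` combines intrinsic
  farmer growth and in-migration,
- `δ_hg`, `δ_f`: interspecific mortality/conversion rates,
- `η`: assimilation — the fraction of the HG loss flux `δ_hg·HG·F`
  absorbed into the farming population,
- `K_hg`, `K_f`: carrying capacities.

Linearizing at the single-population equilibria gives exact invasion
thresholds, so the long-run outcome (farmers only, foragers only,
coexistence, or dependence on initial conditions) is known analytically and
the simulator can be checked against it.

## Worked example

Simulate one parameter set and classify its regime:

```python
import numpy as np
from demicdyn import (ParameterSet, InitialConditions, integrate,
                      classify_regime, invasion_thresholds)

p = ParameterSet.from_total(gamma_hg=0.015, gamma_f_total=0.02,
                            delta_hg=0.02, delta_f=0.01, eta=0.1)
init = InitialConditions.from_rho(rho=0.2, hg0=1.0, k_hg=1.0, k_f=1.5)
traj = integrate(p, init, horizon=1500)

overtake = traj.t[np.argmax(traj.f > traj.hg)]
print(overtake)                      # 124  (first year farmers outnumber HG)
print(round(traj.hg[-1], 4), round(traj.f[-1], 4))
                                    # 0.0 1.5  (HG extinct, F at capacity)
print(classify_regime(p, 1.0, 1.5)) # Regime(label='F_only', degenerate=False)
print(invasion_thresholds(p, 1.0, 1.5))  # (0.03, 0.022)
```

Fit the model to a synthetic labelled date table (reduced ABC budget,
1,500 simulations / 100 kept / 3 stages / 5 starts — a few tens of seconds):

```python
from demicdyn import ABCBudget, CaseConfig, build_case, multi_start, summarize
from demicdyn.synthetic import generate_dataset, identity_curve

curve = identity_curve(5000, 9500, 8.0)
theta = ParameterSet(gamma_hg=0.0115, gamma_f=0.025, mu=0.0175,
                     delta_hg=0.02, delta_f=0.02, eta=0.15)
rng = np.random.default_rng(7)
dates, truth = generate_dataset(theta, 0.25, 150, 700, curve, rng)

case = build_case(dates, curve, CaseConfig(), rng)
print(case.n_dates, case.window)    # 26 (7651.0, 7112.0)

particles, history = multi_start(case, seed=7, budget=ABCBudget.reduced())
out = summarize(particles, case, np.random.default_rng(7), n_predictive=100)
print(out.params.round(4))
```

which prints (the true `gamma_hg = 0.0115`, `gamma_f_total = 0.0425`,
`eta = 0.15` and `rho = 0.25` all fall inside their 95% HPDIs):

```
               median    mean  hpdi_lo  hpdi_hi
parameter
gamma_hg       0.0098  0.0104   0.0010   0.0198
gamma_f        0.0206  0.0220   0.0151   0.0333
mu             0.0109  0.0128   0.0001   0.0300
delta_hg       0.0148  0.0158   0.0056   0.0323
delta_f        0.0245  0.0242   0.0099   0.0394
eta            0.0928  0.1160   0.0025   0.2691
rho            0.1706  0.1950   0.1037   0.3512
hg0            0.9551  0.9724   0.8081   1.1833
gamma_f_total  0.0343  0.0348   0.0200   0.0521
```

with `out.extinction_fraction == 0.53` and a posterior median farmer
overtake time of 135 years.

The same workflows are available on the command line:

```bash
demicdyn simulate --params params.yaml --horizon 1500 --out run/traj.csv
demicdyn explore  --experiment 2 --eta 0 --rho 0.1 --out grid.csv
demicdyn fit      --dates dates.csv --curve intcal.14c --seed 1 --out fitdir/
demicdyn tactical --seed 2 --sizes 25,100 --out tactdir/
```

Each stochastic command writes a `manifest.json` (seed, configuration,
SHA-256 input checksums) next to its outputs.

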