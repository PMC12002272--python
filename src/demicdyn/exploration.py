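"""Event detection on trajectories and the theoretical scenario-grid experiments.

Three demographic events are tracked on every trajectory:

1. *overtake* — the first year in which farmers outnumber hunter-gatherers
   (the first time step with F/HG > 1);
2. *farmer carrying capacity* — the first year in which the farming
   population reaches its ceiling (within a small tolerance);
3. *HG disappearance* — the first year in which the hunter-gatherer
   population falls below a small fraction of its carrying capacity.

Two grid experiments probe the parameter space over a 1,500-year horizon
under nine (eta, rho) scenarios (eta in {0, 0.1, 0.2}, rho in {0.1, 0.2,
0.4}): experiment 1 varies the two interspecific mortalities with growth
rates fixed (gamma_hg = 0.015, gamma_f' = 0.02); experiment 2 varies the two
growth rates (gamma_hg in [0.001, 0.022], gamma_f' in [0.015, 0.07]) with
both mortalities fixed at 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ParameterSet, Trajectory, integrate_batch
from .equilibria import classify_regime

__all__ = ["EventTimes", "ScenarioGrid", "detect_events", "run_experiment",
           "ETA_SCENARIOS", "RHO_SCENARIOS", "DEFAULT_HORIZON"]

#: the nine scenario values for assimilation and initial population ratio
ETA_SCENARIOS = (0.0, 0.1, 0.2)
RHO_SCENARIOS = (0.1, 0.2, 0.4)
DEFAULT_HORIZON = 1500

#: farmers count as "at carrying capacity" at >= (1 - TOL_K) * K_f
TOL_K = 0.01
#: hunter-gatherers count as "disappeared" below TOL_EXTINCT * K_hg
TOL_EXTINCT = 0.01


@dataclass(frozen=True)
class EventTimes:
    """Times (years since interaction start) of the three key events.

    Each field is ``None`` when the event does not occur within the horizon
    (censored, never reported as horizon + 1).
    """

    t_overtake: int | None
    t_farmer_k: int | None
    t_hg_extinct: int | None


def _first_true(mask: np.ndarray) -> int | None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    return max(int(idx[0]), 1)  # events are reported from time step 1


def detect_events(traj: Trajectory, k_f: float, k_hg: float = 1.0,
                  tol_k: float = TOL_K, tol_extinct: float = TOL_EXTINCT) -> EventTimes:
    """Locate the three demographic events on an annual trajectory."""
    return EventTimes(
        t_overtake=_first_true(traj.f > traj.hg),
        t_farmer_k=_first_true(traj.f >= (1.0 - tol_k) * k_f),
        t_hg_extinct=_first_true(traj.hg < tol_extinct * k_hg),
    )


@dataclass(frozen=True)
class ScenarioGrid:
    """Grid specification for one theoretical experiment.

    ``experiment=1`` sweeps the interspecific mortalities (delta_hg,
    delta_f); ``experiment=2`` sweeps the growth rates (gamma_hg,
    gamma_f_total). Defaults follow the published exploration: K_hg = 1,
    K_f = 1.5, 1,500-year horizon, and the nine (eta, rho) scenarios.
    """

    experiment: int = 2
    etas: tuple = ETA_SCENARIOS
    rhos: tuple = RHO_SCENARIOS
    resolution: int = 50
    horizon: int = DEFAULT_HORIZON
    k_hg: float = 1.0
    k_f: float = 1.5
    # experiment 1: fixed growth rates, mortality axes over the prior support
    gamma_hg_fixed: float = 0.015
    gamma_f_total_fixed: float = 0.02
    delta_range: tuple = (0.0, 0.04)
    # experiment 2: fixed mortalities, growth-rate axes
    delta_fixed: float = 0.01
    gamma_hg_range: tuple = (0.001, 0.022)
    gamma_f_total_range: tuple = (0.015, 0.07)
    tol_k: float = TOL_K
    tol_extinct: float = TOL_EXTINCT

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.resolution < 2:
            raise ValueError("grid resolution must be >= 2 per axis")

    def axes(self) -> tuple[str, np.ndarray, str, np.ndarray]:
        if self.experiment == 1:
            v = np.linspace(*self.delta_range, self.resolution)
            return "delta_hg", v, "delta_f", v.copy()
        g1 = np.linspace(*self.gamma_hg_range, self.resolution)
        g2 = np.linspace(*self.gamma_f_total_range, self.resolution)
        return "gamma_hg", g1, "gamma_f_total", g2


def run_experiment(grid: ScenarioGrid, etas=None, rhos=None) -> pd.DataFrame:
    """Run one scenario-grid experiment; one row per grid cell per scenario.

    Returns a tidy DataFrame with columns ``eta, rho, <p1>, <p2>,
    t_overtake, t_farmer_K, t_hg_extinct, regime`` (event times are NaN when
    censored at the horizon). Deterministic; the sweep is batched through
    the vectorised integrator.
    """
    name1, vals1, name2, vals2 = grid.axes()
    p1, p2 = (a.ravel() for a in np.meshgrid(vals1, vals2, indexing="ij"))
    n = p1.size
    if grid.experiment == 1:
        gamma_hg = np.full(n, grid.gamma_hg_fixed)
        gamma_ft = np.full(n, grid.gamma_f_total_fixed)
        delta_hg, delta_f = p1, p2
    else:
        gamma_hg, gamma_ft = p1, p2
        delta_hg = np.full(n, grid.delta_fixed)
        delta_f = np.full(n, grid.delta_fixed)

    frames = []
    for eta in (grid.etas if etas is None else np.atleast_1d(etas)):
        # regimes do not depend on rho; classify once per eta
        regimes = [
            classify_regime(
                ParameterSet.from_total(g1, g2, d1, d2, eta), grid.k_hg, grid.k_f
            ).label
            for g1, g2, d1, d2 in zip(gamma_hg, gamma_ft, delta_hg, delta_f)
        ]
        for rho in (grid.rhos if rhos is None else np.atleast_1d(rhos)):
            hg0 = grid.k_hg
            hg, f = integrate_batch(gamma_hg, gamma_ft, delta_hg, delta_f, eta,
                                    hg0, rho * hg0, grid.k_hg, grid.k_f, grid.horizon)
            t_over = _first_true_batch(f > hg)
            t_k = _first_true_batch(f >= (1.0 - grid.tol_k) * grid.k_f)
            t_ext = _first_true_batch(hg < grid.tol_extinct * grid.k_hg)
            frames.append(pd.DataFrame({
                "eta": eta, "rho": rho, name1: p1, name2: p2,
                "t_overtake": t_over, "t_farmer_K": t_k, "t_hg_extinct": t_ext,
                "regime": regimes,
            }))
    return pd.concat(frames, ignore_index=True)


def _first_true_batch(mask: np.ndarray) -> np.ndarray:
    """Row-wise first-True index (from step 1; NaN when never true)."""
    any_true = mask.any(axis=1)
    first = np.maximum(mask.argmax(axis=1).astype(float), 1.0)
    first[~any_true] = np.nan
    return first
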