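"""Analytic fixed points, linear stability and equilibrium-regime classification.

Four long-run outcomes are possible: only hunter-gatherers survive, only
farmers survive, stable coexistence, or survival of a single population
determined by the initial conditions (bistability). With assimilation folded
into the farmer equation the classification reduces to mutual invasibility:

* hunter-gatherers invade the farmer-only state ``(0, K_f)`` iff
  ``gamma_hg > delta_hg * K_f``;
* farmers invade the HG-only state ``(K_hg, 0)`` iff
  ``gamma_f_total + (eta * delta_hg - delta_f) * K_hg > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import InitialConditions, ParameterSet, rhs

__all__ = [
    "Equilibrium",
    "Regime",
    "fixed_points",
    "classify_regime",
    "invasion_thresholds",
    "invasion_eigenvalues",
]

#: eigenvalue real parts within this of zero are treated as degenerate
STABILITY_TOL = 1e-10


@dataclass(frozen=True)
class Equilibrium:
    hg_star: float
    f_star: float
    stability: str  # "stable" | "unstable" | "saddle"
    eigenvalues: tuple


@dataclass(frozen=True)
class Regime:
    """Long-run outcome label for a parameter set.

    ``degenerate`` flags parameters lying exactly on a regime boundary (an
    invasion eigenvalue numerically zero); the less restrictive regime is
    then reported.
    """

    label: str  # "HG_only" | "F_only" | "coexistence" | "initial_condition_dependent"
    degenerate: bool = False


def _jacobian(hg: float, f: float, p: ParameterSet, k_hg: float, k_f: float) -> np.ndarray:
    a = p.eta * p.delta_hg - p.delta_f
    return np.array([
        [p.gamma_hg * (1.0 - 2.0 * hg / k_hg) - p.delta_hg * f, -p.delta_hg * hg],
        [a * f, p.gamma_f_total * (1.0 - 2.0 * f / k_f) + a * hg],
    ])


def _stability(hg, f, p, k_hg, k_f) -> Equilibrium:
    eig = np.linalg.eigvals(_jacobian(hg, f, p, k_hg, k_f))
    re = np.real(eig)
    if np.all(re < -STABILITY_TOL):
        s = "stable"
    elif np.all(re > STABILITY_TOL):
        s = "unstable"
    else:
        s = "saddle"
    return Equilibrium(hg_star=hg, f_star=f, stability=s, eigenvalues=tuple(eig))


def fixed_points(params: ParameterSet, k_hg: float, k_f: float) -> list[Equilibrium]:
    """All non-negative fixed points of the system with their stability.

    Always returns the origin and the two single-population logistic
    equilibria; an interior coexistence point is appended when the two
    nullclines intersect at positive densities. With assimilation folded in
    the nullclines are straight lines, so the interior root is the solution
    of a 2x2 linear system.
    """
    if k_hg <= 0 or k_f <= 0:
        raise ValueError("carrying capacities must be positive")
    pts = [
        _stability(0.0, 0.0, params, k_hg, k_f),
        _stability(k_hg, 0.0, params, k_hg, k_f),
        _stability(0.0, k_f, params, k_hg, k_f),
    ]
    # nullclines: gamma_hg - (gamma_hg/K_hg) HG - delta_hg F = 0
    #             gamma_f' + (eta delta_hg - delta_f) HG - (gamma_f'/K_f) F = 0
    a = np.array([
        [params.gamma_hg / k_hg, params.delta_hg],
        [params.eta * params.delta_hg - params.delta_f, -params.gamma_f_total / k_f],
    ])
    b = np.array([params.gamma_hg, -params.gamma_f_total])
    if abs(np.linalg.det(a)) > 1e-14:
        hg_star, f_star = np.linalg.solve(a, b)
        if hg_star > STABILITY_TOL and f_star > STABILITY_TOL:
            pts.append(_stability(float(hg_star), float(f_star), params, k_hg, k_f))
    return pts


def invasion_eigenvalues(params: ParameterSet, k_hg: float, k_f: float) -> tuple[float, float]:
    """Per-capita growth of each population when rare at the other's equilibrium.

    Returns ``(lambda_hg, lambda_f)``: the growth rate of hunter-gatherers
    introduced at the farmer-only state ``(0, K_f)`` and of farmers
    introduced at the HG-only state ``(K_hg, 0)``. A positive value means
    the rare population can invade.
    """
    lam_hg = params.gamma_hg - params.delta_hg * k_f
    lam_f = params.gamma_f_total + (params.eta * params.delta_hg - params.delta_f) * k_hg
    return lam_hg, lam_f


def classify_regime(params: ParameterSet, k_hg: float, k_f: float) -> Regime:
    """Classify the long-run outcome by mutual invasibility.

    Both populations invade when rare -> stable coexistence; neither ->
    bistability (outcome set by initial conditions); exactly one -> that
    population alone survives. Parameters sitting numerically on a boundary
    are flagged degenerate and resolved toward the less restrictive regime
    (invasion counted as succeeding).
    """
    if k_hg <= 0 or k_f <= 0:
        raise ValueError("carrying capacities must be positive")
    lam_hg, lam_f = invasion_eigenvalues(params, k_hg, k_f)
    degenerate = abs(lam_hg) <= STABILITY_TOL or abs(lam_f) <= STABILITY_TOL
    hg_invades = lam_hg >= -STABILITY_TOL if degenerate else lam_hg > 0
    f_invades = lam_f >= -STABILITY_TOL if degenerate else lam_f > 0
    if hg_invades and f_invades:
        label = "coexistence"
    elif hg_invades:
        label = "HG_only"
    elif f_invades:
        label = "F_only"
    else:
        label = "initial_condition_dependent"
    return Regime(label=label, degenerate=degenerate)


def invasion_thresholds(params: ParameterSet, k_hg: float, k_f: float) -> tuple[float, float]:
    """Critical rates at which the two invasion eigenvalues change sign.

    Returns ``(critical_gamma_hg, critical_delta_f)``:

    * ``critical_gamma_hg = delta_hg * K_f`` — the HG growth rate below
      which hunter-gatherers cannot invade the farmer-only state;
    * ``critical_delta_f = (gamma_f_total + eta * delta_hg * K_hg) / K_hg``
      — the farmer interspecific mortality above which farmers cannot
      invade the HG-only state (``gamma_f_total / K_hg`` when eta = 0).
    """
    crit_gamma_hg = params.delta_hg * k_f
    crit_delta_f = (params.gamma_f_total + params.eta * params.delta_hg * k_hg) / k_hg
    return crit_gamma_hg, crit_delta_f


def regime_grid(params: ParameterSet, k_hg: float, k_f: float,
                axis1: str, values1, axis2: str, values2):
    """Regime label over a 2-D parameter grid, as a tidy DataFrame.

    ``axis1``/``axis2`` name ParameterSet fields (``gamma_f`` is interpreted
    as total farmer growth). Intended for phase-diagram export.
    """
    import pandas as pd

    rows = []
    base = params.to_dict()
    for v1 in values1:
        for v2 in values2:
            d = dict(base)
            d[axis1] = float(v1)
            d[axis2] = float(v2)
            p = ParameterSet.from_dict(d)
            rows.append({axis1: float(v1), axis2: float(v2),
                         "regime": classify_regime(p, k_hg, k_f).label})
    return pd.DataFrame(rows)
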