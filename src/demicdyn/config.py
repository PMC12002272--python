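"""Shared defaults, configuration I/O and seed management.

All study-level constants live here as named defaults: the uniform priors,
the ABC budget (15,000 rejection simulations, 500 particles, 6 SMC stages,
100 randomized starts), the 120-year laboratory-error cutoff, the 20-year
thinning bins, the 100-year lead before the earliest farming date, and the
1,500-year exploration horizon.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

__all__ = ["Priors", "ABCBudget", "CaseConfig", "child_rngs", "load_config", "dump_config"]

PARAM_NAMES = ("gamma_hg", "gamma_f", "mu", "delta_hg", "delta_f", "eta")
SAMPLED_NAMES = PARAM_NAMES + ("rho", "hg0")


@dataclass(frozen=True)
class Priors:
    """Independent uniform priors for the model rates and initial state.

    The six rate priors follow the archaeological/ethnographic ranges used
    for late hunter-gatherers and early farmers; ``rho`` (initial
    farmer-to-forager ratio) and ``hg0`` (initial HG density in K_hg units)
    are package defaults, exposed for override.
    """

    gamma_hg: tuple = (0.001, 0.022)
    gamma_f: tuple = (0.015, 0.035)
    mu: tuple = (0.0, 0.035)
    delta_hg: tuple = (0.0, 0.04)
    delta_f: tuple = (0.0, 0.04)
    eta: tuple = (0.0, 0.3)
    rho: tuple = (0.1, 0.4)
    hg0: tuple = (0.8, 1.2)

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def width(self, name: str) -> float:
        lo, hi = self.bounds(name)
        return hi - lo

    def sample(self, rng: np.random.Generator, n: int):
        import pandas as pd

        return pd.DataFrame({
            name: rng.uniform(*self.bounds(name), size=n) for name in SAMPLED_NAMES
        })

    def contains(self, name: str, values) -> np.ndarray:
        lo, hi = self.bounds(name)
        v = np.asarray(values)
        return (v >= lo) & (v <= hi)

    def midpoint(self) -> dict:
        return {name: 0.5 * sum(self.bounds(name)) for name in SAMPLED_NAMES}


@dataclass(frozen=True)
class ABCBudget:
    """Computational budget of the rejection + SMC pipeline."""

    n_sims: int = 15_000
    keep: int = 500
    stages: int = 6
    starts: int = 100
    max_attempts_per_stage: int = 200_000
    batch: int = 64  # candidates simulated per vectorised chunk

    def __post_init__(self) -> None:
        if self.n_sims < self.keep:
            raise ValueError("n_sims must be >= keep")
        if min(self.keep, self.stages, self.starts) < 1:
            raise ValueError("keep, stages and starts must be >= 1")

    @classmethod
    def reduced(cls) -> "ABCBudget":
        """Desk-scale budget for testing and tactical simulation."""
        return cls(n_sims=1500, keep=100, stages=3, starts=5)


@dataclass(frozen=True)
class CaseConfig:
    """Observed-case construction settings.

    ``lead`` years are prepended before the earliest farming date to allow
    for archaeologically invisible early farmers; ``end_bp`` (calBP)
    truncates the window where the farming SPD suggests carrying capacity —
    located automatically at the farming-SPD maximum when left unset.
    """

    sd_cutoff: float = 120.0
    bin_width: float = 20.0
    lead: float = 100.0
    end_bp: float | None = None
    normalize: str = "per_date"


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a master seed out into ``n`` independent substreams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(obj, path) -> None:
    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
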