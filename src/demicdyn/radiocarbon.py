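"""Radiocarbon calibration, summed probability distributions, and the
model-driven synthetic date sampler.

A radiocarbon determination is a conventional radiocarbon age (CRA, in 14C
years BP) with a Gaussian 1-sigma laboratory error. Calibration inverts the
calibration curve probabilistically: on an annual calendar grid the
calibrated density is

    p(t) ~ N(cra; c14_age(t), sd^2 + curve_sigma(t)^2)

normalised to unit mass over the curve support. A summed probability
distribution (SPD) is the per-year sum of calibrated densities over a set of
dates, used here as a relative population-size proxy for each of the two
labelled populations (``hg`` and ``farmer``).

Calendar convention: internal time is calendar years BP (present = AD 1950);
the interaction clock ``t`` (years since the start of interaction) maps onto
the BP axis as ``cal_bp = start_bp - t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalCurve", "RadiocarbonDate", "SPD",
    "load_calcurve", "load_dates",
    "calibrate", "calibrate_many", "median_calibrated",
    "mass_in_window", "window_filter", "sd_filter", "bin_thin",
    "build_spd", "sample_dates_from_model",
]

#: laboratory errors above this (years) disqualify a date
SD_CUTOFF = 120.0
#: chronological thinning bin width (calendar years)
BIN_WIDTH = 20.0


@dataclass(frozen=True)
class CalCurve:
    """Calibration curve interpolated to an annual calendar grid.

    ``cal_bp`` is strictly increasing (annual); ``c14_age`` gives the
    expected conventional radiocarbon age at each calendar year and
    ``sigma`` its 1-sigma curve error.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.cal_bp) == len(self.c14_age) == len(self.sigma)):
            raise ValueError("curve columns must have equal length")
        if len(self.cal_bp) < 2 or np.any(np.diff(self.cal_bp) <= 0):
            raise ValueError("cal_bp grid must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("curve errors must be positive")

    @classmethod
    def from_anchors(cls, cal_bp, c14_age, sigma) -> "CalCurve":
        """Linearly interpolate anchor rows to a 1-year calBP grid."""
        cal_bp = np.asarray(cal_bp, dtype=float)
        c14_age = np.asarray(c14_age, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        order = np.argsort(cal_bp)
        cal_bp, c14_age, sigma = cal_bp[order], c14_age[order], sigma[order]
        if np.any(np.diff(cal_bp) <= 0):
            raise ValueError("calBP anchors must be distinct")
        grid = np.arange(np.ceil(cal_bp[0]), np.floor(cal_bp[-1]) + 1)
        return cls(cal_bp=grid,
                   c14_age=np.interp(grid, cal_bp, c14_age),
                   sigma=np.interp(grid, cal_bp, sigma))

    def index_of(self, cal_bp_years) -> np.ndarray:
        """Grid indices of (integer) calBP years; errors if outside the grid."""
        idx = np.asarray(np.rint(cal_bp_years - self.cal_bp[0]), dtype=int)
        if np.any(idx < 0) or np.any(idx >= len(self.cal_bp)):
            raise ValueError("calendar year outside calibration-curve span")
        return idx


@dataclass(frozen=True)
class RadiocarbonDate:
    """A labelled 14C determination: lab id, CRA (14C yr BP), 1-sigma error."""

    lab_id: str
    cra: float
    sd: float
    label: str  # "hg" | "farmer"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be > 0, got {self.sd}")
        if self.label not in ("hg", "farmer"):
            raise ValueError(f"label must be 'hg' or 'farmer', got {self.label!r}")


@dataclass(frozen=True)
class SPD:
    """Summed probability density over a calendar window.

    ``cal_bp`` descends from the window start (older) to its end (younger),
    so index i corresponds to i years after the window opens. ``mode``
    records the normalisation: ``per_date`` (each calibrated density sums
    to 1 before summation, total mass <= n_dates) or ``unit`` (the summed
    curve rescaled to total mass 1).
    """

    cal_bp: np.ndarray
    density: np.ndarray
    n_dates: int
    mode: str = "per_date"

    def __post_init__(self) -> None:
        if len(self.cal_bp) != len(self.density):
            raise ValueError("grid/density length mismatch")
        if np.any(self.density < 0):
            raise ValueError("SPD density must be non-negative")

    @property
    def window(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cal_bp": self.cal_bp, "density": self.density})


# ---------------------------------------------------------------------------
# file formats

def load_calcurve(path) -> CalCurve:
    """Read a calibration curve in the standard ``.14c`` layout.

    Comment lines start with ``#``; data rows are comma- or
    whitespace-separated with at least three columns (calBP, 14C age BP,
    1-sigma curve error); extra columns are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"malformed curve row: {line!r}")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise ValueError(f"malformed curve row: {line!r}") from exc
    if len(rows) < 2:
        raise ValueError("calibration curve needs at least two anchor rows")
    arr = np.asarray(rows)
    return CalCurve.from_anchors(arr[:, 0], arr[:, 1], arr[:, 2])


def load_dates(path) -> pd.DataFrame:
    """Read a labelled date table: CSV with columns lab_id, cra, sd, label."""
    df = pd.read_csv(path)
    missing = {"lab_id", "cra", "sd", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"date table missing columns: {sorted(missing)}")
    bad = ~df["label"].isin(["hg", "farmer"])
    if bad.any():
        raise ValueError(f"unknown population labels: {sorted(df.loc[bad, 'label'].unique())}")
    return df


# ---------------------------------------------------------------------------
# calibration

def calibrate_many(cras, sds, curve: CalCurve) -> np.ndarray:
    """Calibrated densities for many dates at once, shape (n_dates, n_grid).

    Each row is normalised to sum to 1 over the curve support.
    """
    cras = np.atleast_1d(np.asarray(cras, dtype=float))
    sds = np.atleast_1d(np.asarray(sds, dtype=float))
    var = sds[:, None] ** 2 + curve.sigma[None, :] ** 2
    z = (cras[:, None] - curve.c14_age[None, :]) ** 2 / var
    dens = np.exp(-0.5 * z) / np.sqrt(var)
    total = dens.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("date has no probability mass on the curve span")
    return dens / total


def calibrate(date: RadiocarbonDate, curve: CalCurve) -> np.ndarray:
    """Calibrated density of one date on the curve's annual calBP grid.

    Raises if the CRA lies outside the radiocarbon span of the curve.
    """
    lo = curve.c14_age.min() - 3.0 * date.sd
    hi = curve.c14_age.max() + 3.0 * date.sd
    if not (lo <= date.cra <= hi):
        raise ValueError(
            f"date {date.lab_id}: CRA {date.cra} outside curve span [{lo:.0f}, {hi:.0f}]")
    return calibrate_many([date.cra], [date.sd], curve)[0]


def median_calibrated(density: np.ndarray, curve: CalCurve) -> float:
    """Weighted median calendar year (calBP) of a calibrated density."""
    cdf = np.cumsum(density)
    cdf = cdf / cdf[-1]
    return float(curve.cal_bp[np.searchsorted(cdf, 0.5)])


def _window_mask(curve: CalCurve, window) -> np.ndarray:
    start_bp, end_bp = window
    if start_bp < end_bp:
        raise ValueError("window start must be older (larger calBP) than its end")
    return (curve.cal_bp <= start_bp) & (curve.cal_bp >= end_bp)


def mass_in_window(density: np.ndarray, curve: CalCurve, window) -> float:
    """Probability mass of a calibrated density inside [start_bp, end_bp]."""
    return float(density[_window_mask(curve, window)].sum())


# ---------------------------------------------------------------------------
# filtering and thinning

def sd_filter(dates: pd.DataFrame, cutoff: float = SD_CUTOFF) -> pd.DataFrame:
    """Drop dates with laboratory errors above the cutoff (120 y default)."""
    return dates[dates["sd"] <= cutoff].reset_index(drop=True)


def window_filter(dates: pd.DataFrame, densities: np.ndarray, curve: CalCurve,
                  window) -> tuple[pd.DataFrame, np.ndarray]:
    """Keep dates with strictly more than half their mass inside the window."""
    mask = _window_mask(curve, window)
    masses = densities[:, mask].sum(axis=1)
    keep = masses > 0.5
    return dates[keep].reset_index(drop=True), densities[keep]


def bin_thin(dates: pd.DataFrame, medians, rng: np.random.Generator,
             bin_width: float = BIN_WIDTH) -> pd.DataFrame:
    """Random chronological thinning: one date per occupied 20-year bin.

    Dates are partitioned into consecutive calendar bins (closed-start,
    half-open-end on the BP axis) by their median calibrated year, and one
    date per occupied bin is retained uniformly at random. Deterministic
    given the generator state. Bins are keyed purely on chronology because
    the input schema carries no site identifier.
    """
    medians = np.asarray(medians, dtype=float)
    if len(medians) != len(dates):
        raise ValueError("one median calibrated year per date required")
    bins = np.floor(medians / bin_width).astype(int)
    keep = []
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        keep.append(members[rng.integers(len(members))])
    keep = np.sort(np.asarray(keep))
    return dates.iloc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# SPDs

def build_spd(dates: pd.DataFrame, curve: CalCurve, window,
              normalize: str = "per_date") -> SPD:
    """Sum the windowed calibrated densities of a date set.

    ``normalize='per_date'`` sums per-date unit-mass densities (the default,
    so the SPD total equals the within-window mass of the set);
    ``'unit'`` rescales the summed curve to total mass 1.
    """
    if len(dates) == 0:
        raise ValueError("cannot build an SPD from an empty date list")
    if normalize not in ("per_date", "unit"):
        raise ValueError(f"unknown normalisation mode {normalize!r}")
    dens = calibrate_many(dates["cra"].to_numpy(), dates["sd"].to_numpy(), curve)
    mask = _window_mask(curve, window)
    total = dens[:, mask].sum(axis=0)
    if normalize == "unit":
        s = total.sum()
        if s > 0:
            total = total / s
    # descending calBP: index i = i years after the window opens
    return SPD(cal_bp=curve.cal_bp[mask][::-1].copy(), density=total[::-1].copy(),
               n_dates=len(dates), mode=normalize)


# ---------------------------------------------------------------------------
# forward sampler

def sample_dates_from_model(traj, n: int, curve: CalCurve, start_bp: float,
                            error_model, rng: np.random.Generator,
                            id_prefix: str = "SIM") -> pd.DataFrame:
    """Draw labelled radiocarbon dates from a model trajectory.

    Emulates the archaeological sampling and dating process: (i) calendar
    years are drawn from the discretised total density HG(t) + F(t); (ii)
    each is labelled ``farmer`` binomially with probability
    F(t)/(HG(t)+F(t)); (iii) each calendar year is *uncalibrated* — a CRA is
    drawn from ``N(c14_age(t), sd^2 + curve_sigma(t)^2)`` with ``sd`` from
    the error model — so that recalibrating downstream reproduces the
    information loss of real dates.

    ``error_model`` may be a scalar sd, an array pool to resample with
    replacement, or a callable ``(rng, n) -> sd array``. The trajectory's
    clock maps to the calendar as ``cal_bp = start_bp - t``.
    """
    if n < 1:
        raise ValueError("need n >= 1 dates")
    total = traj.hg + traj.f
    mass = total.sum()
    if mass <= 0:
        raise ValueError("trajectory has zero total density; cannot sample dates")
    t_idx = rng.choice(len(total), size=n, p=total / mass)
    p_farmer = np.zeros(n)
    nz = total[t_idx] > 0
    p_farmer[nz] = traj.f[t_idx][nz] / total[t_idx][nz]
    labels = np.where(rng.random(n) < p_farmer, "farmer", "hg")

    if callable(error_model):
        sds = np.asarray(error_model(rng, n), dtype=float)
    elif np.ndim(error_model) == 0:
        sds = np.full(n, float(error_model))
    else:
        pool = np.asarray(error_model, dtype=float)
        sds = pool[rng.integers(len(pool), size=n)]
    if np.any(sds <= 0):
        raise ValueError("error model produced non-positive sd")

    cal_years = start_bp - traj.t[t_idx]
    gi = curve.index_of(cal_years)
    cras = rng.normal(curve.c14_age[gi], np.sqrt(sds**2 + curve.sigma[gi]**2))
    return pd.DataFrame({
        "lab_id": [f"{id_prefix}-{i:05d}" for i in range(n)],
        "cra": cras, "sd": sds, "label": labels,
    })
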