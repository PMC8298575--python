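"""Age-depth chronology ensembles for sediment cores.

Dated horizons (calibrated ages with Gaussian errors) are turned into an
ensemble of strictly monotone age-depth realizations by a
perturb-project-interpolate sampler:

1. perturb each dated horizon's age with Gaussian noise at its 1-sigma error,
2. project the perturbed ages back onto the monotone cone with isotonic
   regression (pool-adjacent-violators) along depth,
3. piecewise-linearly interpolate each realization onto a common depth grid.

This is a deliberately simple surrogate for full Bayesian accumulation
modelling (BACON-style): downstream analyses consume only the
depth-dependent dating uncertainty, which this sampler reproduces, not the
accumulation-rate prior structure, which it does not attempt to match.

All ages are in calibrated years before 2000 (cal yrs b2k) and increase
with depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

__all__ = [
    "DatedHorizon",
    "AgeEnsemble",
    "apply_reservoir_offset",
    "sample_age_models",
    "accumulation_rates",
    "load_dates_csv",
    "write_agemodel_csv",
]

# Minimum strict age increment (yr) imposed after isotonic projection so that
# every realization is strictly, not just weakly, increasing.
_STRICT_EPS = 1e-9


@dataclass(frozen=True)
class DatedHorizon:
    """One dated depth in a core.

    Parameters
    ----------
    depth : float
        Depth below surface, cm (non-negative).
    age : float
        Calibrated age, cal yrs b2k.
    age_sigma : float
        1-sigma age uncertainty in years. If the source quotes its errors at
        a k-sigma convention, divide by k before constructing (the CSV
        loader does this), and record k in ``sigma_convention``.
    sigma_convention : float
        Multiplier k such that the originally stated uncertainty equals
        k * age_sigma. Metadata only; sampling always uses ``age_sigma``.
    """

    depth: float
    age: float
    age_sigma: float
    sigma_convention: float = 1.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")
        if self.age_sigma < 0:
            raise ValueError(f"age_sigma must be non-negative, got {self.age_sigma}")
        if self.sigma_convention <= 0:
            raise ValueError("sigma_convention must be positive")

    @property
    def stated_error(self) -> float:
        """The uncertainty as originally stated (k-sigma)."""
        return self.age_sigma * self.sigma_convention


@dataclass
class AgeEnsemble:
    """Monotone age-depth realizations on a common depth grid.

    ``draws`` has shape (n_draws, n_depths); every row is strictly
    increasing along depth. ``median_ages``, ``p5`` and ``p95`` are the
    per-depth 50th, 5th and 95th percentiles across draws.
    """

    depth_grid: np.ndarray
    draws: np.ndarray
    median_ages: np.ndarray = field(init=False)
    p5: np.ndarray = field(init=False)
    p95: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != self.depth_grid.size:
            raise ValueError("draws must be (n_draws, n_depths)")
        if not np.all(np.diff(self.draws, axis=1) > 0):
            raise ValueError("every age draw must be strictly increasing with depth")
        self.p5, self.median_ages, self.p95 = np.percentile(
            self.draws, [5.0, 50.0, 95.0], axis=0
        )

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def ages_at(self, depths: np.ndarray) -> np.ndarray:
        """Interpolate every draw onto arbitrary depths (shape n_draws x len(depths))."""
        depths = np.asarray(depths, dtype=float)
        lo, hi = self.depth_grid[0], self.depth_grid[-1]
        if np.any(depths < lo - 1e-12) or np.any(depths > hi + 1e-12):
            raise ValueError(
                f"requested depths outside ensemble span [{lo}, {hi}] cm"
            )
        out = np.empty((self.n_draws, depths.size))
        for i in range(self.n_draws):
            out[i] = np.interp(depths, self.depth_grid, self.draws[i])
        return out


def apply_reservoir_offset(
    age: float, age_sigma: float, delta_r: float = 140.0, delta_r_sigma: float = 60.0
) -> tuple[float, float]:
    """Apply a marine reservoir correction to a calibrated age.

    The offset is subtracted from the age and its uncertainty combined in
    quadrature with the age's own. Default offset 140 +/- 60 yr (regional
    value for deep sites under the West Greenland Current).

    >>> apply_reservoir_offset(1000, 50, 140, 60)
    (860.0, 78.10249675906654)
    """
    if age_sigma < 0 or delta_r_sigma < 0:
        raise ValueError("sigmas must be non-negative")
    return float(age - delta_r), math.hypot(age_sigma, delta_r_sigma)


def _validate_horizons(horizons: Sequence[DatedHorizon]) -> None:
    if len(horizons) < 2:
        raise ValueError("need at least 2 dated horizons")
    depths = [h.depth for h in horizons]
    if not all(b > a for a, b in zip(depths, depths[1:])):
        raise ValueError("horizon depths must be strictly increasing")


def sample_age_models(
    horizons: Sequence[DatedHorizon],
    n_draws: int,
    depth_grid: np.ndarray,
    seed: int | np.random.Generator = 0,
    extrapolate: bool = False,
) -> AgeEnsemble:
    """Draw an ensemble of monotone age-depth models.

    Each draw perturbs every horizon age by independent Gaussian noise at
    its 1-sigma error, restores monotonicity with an isotonic projection
    (least-squares pool-adjacent-violators along depth), and linearly
    interpolates onto ``depth_grid``.

    Parameters
    ----------
    extrapolate : bool
        If False (default) grid points outside the dated span are refused;
        if True, the end segments' rates are extended.
    """
    _validate_horizons(horizons)
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    depth_grid = np.asarray(depth_grid, dtype=float)
    depths = np.array([h.depth for h in horizons])
    ages = np.array([h.age for h in horizons])
    sigmas = np.array([h.age_sigma for h in horizons])
    if not extrapolate and (
        depth_grid.min() < depths[0] - 1e-12 or depth_grid.max() > depths[-1] + 1e-12
    ):
        raise ValueError(
            "depth_grid extends beyond dated span; pass extrapolate=True to allow"
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perturbed = ages + rng.standard_normal((n_draws, depths.size)) * sigmas
    draws = np.empty((n_draws, depth_grid.size))
    # strictness offsets, scaled to the record so they never matter numerically
    eps = _STRICT_EPS * max(1.0, ages[-1] - ages[0]) * np.arange(depths.size)
    for i in range(n_draws):
        mono = isotonic_regression(perturbed[i]).x + eps
        if extrapolate:
            draws[i] = _interp_extrap(depth_grid, depths, mono)
        else:
            draws[i] = np.interp(depth_grid, depths, mono)
    return AgeEnsemble(depth_grid=depth_grid, draws=draws)


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with constant-rate (linear) extension beyond the end points."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        r = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + r * (x[lo] - xp[0])
    if hi.any():
        r = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + r * (x[hi] - xp[-1])
    return y


def accumulation_rates(ensemble: AgeEnsemble) -> pd.DataFrame:
    """Median sedimentation rate per depth-grid interval.

    Returns a frame with interval midpoints (cm), the median-age-model rate
    (cm/yr) and the per-draw 5th/95th percentile rates. Intervals over which
    the median age does not increase are rejected.
    """
    d_depth = np.diff(ensemble.depth_grid)
    d_age = np.diff(ensemble.median_ages)
    if np.any(d_age <= 0):
        raise ValueError("median age must increase over every interval")
    rate_draws = d_depth / np.diff(ensemble.draws, axis=1)
    lo, hi = np.percentile(rate_draws, [5.0, 95.0], axis=0)
    return pd.DataFrame(
        {
            "depth_mid_cm": 0.5 * (ensemble.depth_grid[:-1] + ensemble.depth_grid[1:]),
            "rate_cm_yr": d_depth / d_age,
            "rate_p5": lo,
            "rate_p95": hi,
        }
    )


def load_dates_csv(path: str | Path) -> list[DatedHorizon]:
    """Read a dated-horizon table: depth_cm, age_b2k, age_err, sigma_convention.

    ``age_err`` is the uncertainty as stated at the file's sigma convention;
    it is converted to 1-sigma on load.
    """
    df = pd.read_csv(path, comment="#")
    required = {"depth_cm", "age_b2k", "age_err", "sigma_convention"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dates CSV missing columns: {sorted(missing)}")
    return [
        DatedHorizon(
            depth=row.depth_cm,
            age=row.age_b2k,
            age_sigma=row.age_err / row.sigma_convention,
            sigma_convention=row.sigma_convention,
        )
        for row in df.itertuples()
    ]


def write_agemodel_csv(ensemble: AgeEnsemble, path: str | Path) -> None:
    pd.DataFrame(
        {
            "depth_cm": ensemble.depth_grid,
            "age_median": ensemble.median_ages,
            "age_p5": ensemble.p5,
            "age_p95": ensemble.p95,
        }
    ).to_csv(path, index=False, float_format="%.6g")
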