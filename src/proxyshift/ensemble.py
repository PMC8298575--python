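"""Monte Carlo uncertainty propagation and PCA synthesis of proxy records.

Each proxy measurement is uncertain in two ways: its value (analytical
error) and its position in time (dating error). Both are propagated by
simulation: draw i pairs the i-th age-model realization with an independent
measurement-noise realization, and the perturbed (age, value) path is
interpolated onto a common time grid. The resulting draw cloud is
summarised per grid time as a frequency density, a median ("most likely")
series, and a 5th-95th percentile 90% confidence envelope.

The median series of several proxies are then synthesised by principal
component analysis of their correlation matrix (each series z-scored over
time), and the per-proxy Monte Carlo envelopes are propagated onto PC1 as
loading-weighted fractional mean uncertainties — a declared convention,
isolated in :func:`fractional_mean_uncertainty` /
:func:`propagate_pc_envelope` so alternatives can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chronology import AgeEnsemble
from .proxies import ProxySeries

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleSummary",
    "PCSynthesis",
    "simulate_ensemble",
    "envelope_coverage",
    "pca_median",
    "fractional_mean_uncertainty",
    "propagate_pc_envelope",
    "default_time_grid",
    "write_ensemble_csv",
    "write_pca_csv",
    "write_density_csv",
]


@dataclass
class EnsembleSummary:
    """Per-time-grid summary of one proxy's Monte Carlo draw cloud.

    ``draws`` is the (n_draws, n_times) matrix of interpolated draw values;
    ``density`` is a (n_value_bins, n_times) frequency histogram whose
    columns each sum to n_draws. Grid times not covered by every draw's age
    span are rejected at construction, so all summaries are defined
    everywhere on ``time_grid``.
    """

    name: str
    time_grid: np.ndarray
    draws: np.ndarray
    value_bin_edges: np.ndarray = field(init=False)
    density: np.ndarray = field(init=False)
    median: np.ndarray = field(init=False)
    p5: np.ndarray = field(init=False)
    p95: np.ndarray = field(init=False)
    n_value_bins: int = 50

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != self.time_grid.size:
            raise ValueError("draws must be (n_draws, n_times)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws must be finite on the covered grid")
        self.p5, self.median, self.p95 = np.percentile(
            self.draws, [5.0, 50.0, 95.0], axis=0
        )
        lo, hi = self.draws.min(), self.draws.max()
        if hi == lo:
            hi = lo + 1.0
        self.value_bin_edges = np.linspace(lo, hi, self.n_value_bins + 1)
        self.density = np.stack(
            [
                np.histogram(self.draws[:, j], bins=self.value_bin_edges)[0]
                for j in range(self.time_grid.size)
            ],
            axis=1,
        )

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


@dataclass
class PCSynthesis:
    """PCA of median proxy series with a propagated PC1 uncertainty envelope.

    ``loadings`` is (n_proxies, n_components) with orthonormal columns;
    ``pc1_lo``/``pc1_hi`` bound PC1 magnitude (Y-envelope) and
    ``x_halfwidth`` is the dating half-width in years (X-envelope), both
    filled by :func:`propagate_pc_envelope`.
    """

    proxy_names: list[str]
    loadings: np.ndarray
    var_explained: np.ndarray
    time_grid: np.ndarray
    scores: np.ndarray  # (n_times, n_components)
    sign_convention: str
    pc1_lo: np.ndarray | None = None
    pc1_hi: np.ndarray | None = None
    x_halfwidth: np.ndarray | None = None

    @property
    def pc1_series(self) -> np.ndarray:
        return self.scores[:, 0]


def default_time_grid(
    series: list[ProxySeries], ages: AgeEnsemble, step: float = 20.0
) -> np.ndarray:
    """A common time grid: `step`-year spacing over the overlap of all series'
    median age spans, clipped slightly inward so dating jitter rarely pushes a
    draw's span off the grid edge."""
    lo = -np.inf
    hi = np.inf
    for s in series:
        a = np.interp(s.depth, ages.depth_grid, ages.median_ages)
        lo, hi = max(lo, a.min()), min(hi, a.max())
    pad = 2.0 * step
    return np.arange(lo + pad, hi - pad + 1e-9, step)


def simulate_ensemble(
    series: ProxySeries,
    ages: AgeEnsemble,
    n_draws: int,
    time_grid: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> EnsembleSummary:
    """Propagate measurement and dating uncertainty into one proxy series.

    Draw i uses the i-th age-model realization (one-to-one pairing) and an
    independent value perturbation (relative: v*(1+eps); absolute: v+eps,
    eps ~ N(0, sigma)). Each perturbed (age, value) path is linearly
    interpolated onto ``time_grid``; grid times outside any draw's age span
    are rejected with a log message so every summary column holds exactly
    n_draws values.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100 for stable percentiles")
    if n_draws > ages.n_draws:
        raise ValueError(
            f"age ensemble has {ages.n_draws} draws but {n_draws} were requested"
        )
    time_grid = np.asarray(time_grid, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    age_draws = ages.ages_at(series.depth)[:n_draws]
    unc = series.meas_unc
    eps = rng.standard_normal((n_draws, len(series))) * unc.magnitude
    if unc.mode == "relative":
        value_draws = series.value * (1.0 + eps)
    else:
        value_draws = series.value + eps

    out = np.empty((n_draws, time_grid.size))
    for i in range(n_draws):
        out[i] = np.interp(
            time_grid, age_draws[i], value_draws[i], left=np.nan, right=np.nan
        )
    covered = np.all(np.isfinite(out), axis=0)
    if not covered.all():
        logger.info(
            "simulate_ensemble(%s): rejecting %d/%d grid times outside some draw's span",
            series.name,
            int((~covered).sum()),
            time_grid.size,
        )
    if not covered.any():
        raise ValueError("time_grid entirely outside the simulated age spans")
    return EnsembleSummary(
        name=series.name, time_grid=time_grid[covered], draws=out[:, covered]
    )


def envelope_coverage(summary: EnsembleSummary) -> float:
    """Mean over grid times of the fraction of draw values inside [p5, p95].

    By construction of the percentile envelope this is 0.90 up to ties and
    the percentile interpolation convention.
    """
    inside = (summary.draws >= summary.p5) & (summary.draws <= summary.p95)
    return float(inside.mean())


def _common_grid(summaries: list[EnsembleSummary]) -> np.ndarray:
    grid = summaries[0].time_grid
    for s in summaries[1:]:
        grid = np.intersect1d(grid, s.time_grid)
    if grid.size < 3:
        raise ValueError("summaries share fewer than 3 common grid times")
    return grid


def _median_matrix(summaries: list[EnsembleSummary], grid: np.ndarray) -> np.ndarray:
    cols = []
    for s in summaries:
        idx = np.searchsorted(s.time_grid, grid)
        cols.append(s.median[idx])
    return np.column_stack(cols)


def pca_median(
    summaries: list[EnsembleSummary], orient_proxy: str | None = None
) -> PCSynthesis:
    """PCA of the median time series of several proxies.

    Each median series is z-scored over the common time grid and the
    correlation matrix eigendecomposed; components are ordered by
    decreasing eigenvalue. The PC1 sign is fixed so that ``orient_proxy``
    (default: the first summary) loads positively; higher components are
    oriented so their largest-magnitude loading is positive.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 proxy summaries")
    names = [s.name for s in summaries]
    orient_proxy = orient_proxy or names[0]
    if orient_proxy not in names:
        raise ValueError(f"orientation proxy {orient_proxy!r} not among {names}")
    grid = _common_grid(summaries)
    m = _median_matrix(summaries, grid)
    sd = m.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        bad = [n for n, z in zip(names, zero_var) if z]
        raise ValueError(f"zero-variance median series: {bad}")
    z = (m - m.mean(axis=0)) / sd
    corr = (z.T @ z) / (grid.size - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign conventions
    oi = names.index(orient_proxy)
    if evecs[oi, 0] < 0:
        evecs[:, 0] *= -1.0
    for j in range(1, evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] *= -1.0
    return PCSynthesis(
        proxy_names=names,
        loadings=evecs,
        var_explained=evals / evals.sum(),
        time_grid=grid,
        scores=z @ evecs,
        sign_convention=f"PC1 loading of {orient_proxy!r} positive",
    )


def fractional_mean_uncertainty(summary: EnsembleSummary) -> float:
    """One proxy's envelope width as a fraction of its typical magnitude.

    f = mean over time of (p95 - p5) / (2 |median|), with an absolute
    fallback (the series' mean |median|) in the denominator wherever the
    median is negligible, so near-zero crossings do not blow up the
    fraction.
    """
    scale = np.mean(np.abs(summary.median))
    if scale == 0:
        raise ValueError(f"summary {summary.name!r} has an all-zero median")
    denom = np.abs(summary.median)
    denom = np.where(denom < 1e-6 * scale, scale, denom)
    return float(np.mean((summary.p95 - summary.p5) / (2.0 * denom)))


def propagate_pc_envelope(
    synthesis: PCSynthesis,
    summaries: list[EnsembleSummary],
    ages: AgeEnsemble | None = None,
) -> PCSynthesis:
    """Bound PC1 by the proxies' fractional mean uncertainties.

    The Y-envelope half-width at each time is |PC1| scaled by the
    loading-weighted mean of the per-proxy fractions:
    h(t) = |PC1(t)| * sum_i |l_i| f_i / sum_i |l_i|. If an age ensemble is
    supplied, the X-envelope (dating half-width in years, mapped from depth
    to the time grid through the median age model) is filled too.
    """
    if [s.name for s in summaries] != synthesis.proxy_names:
        raise ValueError("summaries must match the synthesis' proxies, in order")
    if not summaries:
        raise ValueError("no summaries given")
    f = np.array([fractional_mean_uncertainty(s) for s in summaries])
    w = np.abs(synthesis.loadings[:, 0])
    frac = float((w * f).sum() / w.sum())
    half = np.abs(synthesis.pc1_series) * frac
    x_half = None
    if ages is not None:
        x_half = np.interp(
            synthesis.time_grid, ages.median_ages, (ages.p95 - ages.p5) / 2.0
        )
    return replace(
        synthesis,
        pc1_lo=synthesis.pc1_series - half,
        pc1_hi=synthesis.pc1_series + half,
        x_halfwidth=x_half,
    )


# ---------------------------------------------------------------------------
# CSV output


def write_ensemble_csv(summary: EnsembleSummary, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_b2k": summary.time_grid,
            "median": summary.median,
            "p5": summary.p5,
            "p95": summary.p95,
        }
    ).to_csv(path, index=False, float_format="%.8g")


def write_density_csv(summary: EnsembleSummary, path: str | Path) -> None:
    """Long-form 2D frequency histogram: time_bin, value_bin (centre), count."""
    centres = 0.5 * (summary.value_bin_edges[:-1] + summary.value_bin_edges[1:])
    t, v = np.meshgrid(summary.time_grid, centres)
    pd.DataFrame(
        {
            "time_bin": t.ravel(),
            "value_bin": v.ravel(),
            "count": summary.density.ravel().astype(int),
        }
    ).to_csv(path, index=False, float_format="%.8g")


def write_pca_csv(synthesis: PCSynthesis, path: str | Path) -> None:
    """Loadings/variance block (comment lines) then the PC time-series block."""
    with open(path, "w") as fh:
        fh.write("# sign convention: " + synthesis.sign_convention + "\n")
        fh.write(
            "# var_explained: "
            + ", ".join(f"{v:.6g}" for v in synthesis.var_explained)
            + "\n"
        )
        for name, row in zip(synthesis.proxy_names, synthesis.loadings):
            fh.write(f"# loading {name}: " + ", ".join(f"{v:.6g}" for v in row) + "\n")
        cols = {"time_b2k": synthesis.time_grid, "pc1": synthesis.pc1_series}
        if synthesis.pc1_lo is not None:
            cols["pc1_lo"] = synthesis.pc1_lo
            cols["pc1_hi"] = synthesis.pc1_hi
        if synthesis.x_halfwidth is not None:
            cols["time_halfwidth_yr"] = synthesis.x_halfwidth
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.8g")
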