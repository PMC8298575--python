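"""Derived proxy quantities from raw sediment-core measurement tables.

Covers the standard derived series of a combined marine/lake multi-proxy
study: fluxes from concentrations and mass accumulation rates,
TOC-normalised biomarker concentrations, the cholesterol /
(cholesterol + beta-sitosterol) seabird-influence index and its flux-weighted
"fractional sterol", XRF Cd:Ti count ratios with depth binning, diatom
relative abundances, and a variance-weighted diatom assemblage index built
from assemblage PCA scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementUncertainty",
    "ProxySeries",
    "AssemblageTable",
    "compute_flux",
    "toc_normalise",
    "sterol_index",
    "fractional_sterol",
    "cd_ti_ratio",
    "relative_abundance",
    "assemblage_pc_scores",
    "diatom_index",
    "load_proxies_csv",
    "write_derived_csv",
]

#: Minimum valve count below which an assemblage sample is not considered
#: quantitative (standard counting convention).
MIN_VALVE_COUNT = 400


@dataclass(frozen=True)
class MeasurementUncertainty:
    """Per-measurement uncertainty model.

    mode="relative": magnitude is a 1-sigma fraction of the value (in [0, 1]).
    mode="absolute": magnitude is a 1-sigma error in the series' own units.
    """

    mode: Literal["relative", "absolute"]
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown uncertainty mode {self.mode!r}")
        if self.mode == "relative" and not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("relative magnitude must be in [0, 1]")
        if self.magnitude < 0:
            raise ValueError("uncertainty magnitude must be non-negative")


@dataclass(frozen=True)
class ProxySeries:
    """A depth-indexed measurement series with units and uncertainty model."""

    name: str
    depth: np.ndarray
    value: np.ndarray
    units: str
    meas_unc: MeasurementUncertainty

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.depth.shape != self.value.shape or self.depth.ndim != 1:
            raise ValueError("depth and value must be equal-length 1D arrays")
        if not np.all(np.diff(self.depth) > 0):
            raise ValueError(f"series {self.name!r}: depths must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError(f"series {self.name!r}: values must be finite")

    def __len__(self) -> int:
        return self.depth.size


@dataclass(frozen=True)
class AssemblageTable:
    """Per-depth diatom valve counts by taxon."""

    depth: np.ndarray
    counts: pd.DataFrame  # rows align with depth, one integer column per taxon

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth", np.asarray(self.depth, dtype=float))
        if len(self.counts) != self.depth.size:
            raise ValueError("counts rows must match depth length")
        vals = self.counts.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)


def _check_aligned(a: ProxySeries, b: ProxySeries) -> None:
    if not np.array_equal(a.depth, b.depth):
        raise ValueError(f"depth grids of {a.name!r} and {b.name!r} do not match")


def compute_flux(concentration: ProxySeries, mar: ProxySeries) -> ProxySeries:
    """Flux = concentration (per g) x mass accumulation rate (g cm-2 yr-1)."""
    _check_aligned(concentration, mar)
    if np.any(mar.value <= 0):
        raise ValueError("mass accumulation rates must be positive")
    unit = concentration.units.replace(" g-1", "").replace("g-1", "").strip()
    return replace(
        concentration,
        name=f"{concentration.name}_flux",
        value=concentration.value * mar.value,
        units=f"{unit} cm-2 yr-1".strip(),
    )


def toc_normalise(biomarker: ProxySeries, toc: ProxySeries) -> ProxySeries:
    """Normalise a biomarker concentration by total organic carbon.

    toc is in % weight; samples with toc <= 0 are dropped with a warning.
    """
    _check_aligned(biomarker, toc)
    ok = toc.value > 0
    if not ok.all():
        logger.warning(
            "toc_normalise(%s): dropping %d sample(s) with TOC <= 0",
            biomarker.name,
            int((~ok).sum()),
        )
    if not ok.any():
        raise ValueError("no samples with positive TOC")
    return replace(
        biomarker,
        name=f"{biomarker.name}_toc",
        depth=biomarker.depth[ok],
        value=biomarker.value[ok] / (toc.value[ok] / 100.0),
        units=f"{biomarker.units} (g TOC)-1",
    )


def sterol_index(cholesterol, beta_sitosterol):
    """Cholesterol / (cholesterol + beta-sitosterol) seabird-influence index.

    Marine zooplankton (seabird diet) are cholesterol-rich and essentially
    beta-sitosterol free, while terrestrial/freshwater producers are the
    reverse, so the index approaches 1 under strong seabird (guano) input
    and 0 under purely catchment input. Scale-invariant: only the
    concentration ratio matters. Accepts scalars or aligned arrays; samples
    with both sterols zero are undefined and rejected.
    """
    c = np.asarray(cholesterol, dtype=float)
    b = np.asarray(beta_sitosterol, dtype=float)
    if np.any(c < 0) or np.any(b < 0):
        raise ValueError("sterol concentrations must be non-negative")
    total = c + b
    if np.any(total == 0):
        raise ValueError("sterol index undefined where both sterols are zero")
    out = c / total
    return float(out) if out.ndim == 0 else out


def fractional_sterol(sterol_flux, index):
    """Sterol flux x sterol index: a single composite seabird-input series.

    Collapsing flux and index into their product avoids the sterols entering
    a later PCA as two correlated variables.
    """
    f = np.asarray(sterol_flux, dtype=float)
    r = np.asarray(index, dtype=float)
    if np.any(f < 0):
        raise ValueError("sterol flux must be non-negative")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("sterol index must lie in [0, 1]")
    out = f * r
    return float(out) if out.ndim == 0 else out


def cd_ti_ratio(
    cd: ProxySeries, ti: ProxySeries, bin_mm: float = 1.0
) -> ProxySeries:
    """Cd:Ti XRF count ratio with counts summed into depth bins first.

    Scanning-XRF count rates for trace elements are noisy at native step
    size, so counts are summed into bins of at least ``bin_mm`` before the
    ratio is formed (Ti normalises for detrital catchment input). Bins whose
    Ti total is zero are dropped with a warning.
    """
    _check_aligned(cd, ti)
    if np.any(cd.value < 0) or np.any(ti.value < 0):
        raise ValueError("XRF counts must be non-negative")
    if bin_mm <= 0:
        raise ValueError("bin_mm must be positive")
    bin_cm = bin_mm / 10.0
    edges = np.arange(cd.depth[0], cd.depth[-1] + bin_cm, bin_cm)
    idx = np.clip(np.digitize(cd.depth, edges) - 1, 0, edges.size - 2)
    mids, ratios = [], []
    for k in np.unique(idx):
        sel = idx == k
        ti_sum = ti.value[sel].sum()
        if ti_sum == 0:
            logger.warning("cd_ti_ratio: dropping bin at %.3f cm (zero Ti)", edges[k])
            continue
        mids.append(cd.depth[sel].mean())
        ratios.append(cd.value[sel].sum() / ti_sum)
    return ProxySeries(
        name="cd_ti",
        depth=np.array(mids),
        value=np.array(ratios),
        units="ratio",
        meas_unc=MeasurementUncertainty("relative", 0.02),
    )


def relative_abundance(table: AssemblageTable, min_count: int = MIN_VALVE_COUNT) -> pd.DataFrame:
    """Per-sample relative abundances (%) from assemblage counts.

    Rows sum to 100. Samples below ``min_count`` total valves are kept but
    flagged with a warning; zero-total samples are rejected.
    """
    totals = table.totals
    if np.any(totals == 0):
        raise ValueError("assemblage sample(s) with zero total count")
    low = totals < min_count
    if low.any():
        logger.warning(
            "relative_abundance: %d sample(s) below the %d-valve minimum",
            int(low.sum()),
            min_count,
        )
    pct = table.counts.div(totals, axis=0) * 100.0
    pct.insert(0, "depth_cm", table.depth)
    return pct


def assemblage_pc_scores(
    table: AssemblageTable, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores of square-root transformed, standardised relative abundances.

    The square root (Hellinger-style) transform is applied to proportions to
    damp dominant taxa; each taxon column is then centred and scaled to unit
    variance, and the correlation-matrix eigendecomposition gives scores and
    variance fractions. Returns (scores [n_samples x n_components],
    var_explained fractions over all components truncated to n_components).
    Constant taxa are dropped.
    """
    prop = relative_abundance(table).drop(columns="depth_cm").to_numpy() / 100.0
    x = np.sqrt(prop)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    corr = np.corrcoef(x, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    scores = x @ evecs[:, :n_components]
    # fix signs so each score series correlates positively with the mean trend
    for j in range(scores.shape[1]):
        if evecs[:, j].sum() < 0:
            scores[:, j] *= -1.0
    return scores, evals / evals.sum()


def diatom_index(
    pc_scores: np.ndarray, var_explained: tuple[float, float] = (0.34, 0.27)
) -> np.ndarray:
    """Variance-weighted sum of the first two assemblage PC score series.

    index = (v1*PC1 + v2*PC2) / (v1 + v2), compressing two ordination axes
    into one series so the assemblage contributes a single variable to the
    record-level PCA. Default weights are the variance fractions of the
    study system (34% and 27%).
    """
    scores = np.asarray(pc_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("pc_scores must be (n_samples, >=2)")
    v1, v2 = var_explained
    if v1 < 0 or v2 < 0 or v1 + v2 <= 0:
        raise ValueError("variance fractions must be non-negative, not both zero")
    return (v1 * scores[:, 0] + v2 * scores[:, 1]) / (v1 + v2)


def load_proxies_csv(
    path: str | Path, uncertainties: dict[str, MeasurementUncertainty] | None = None
) -> list[ProxySeries]:
    """Read a wide proxy table: depth_cm plus one column per measurement.

    An optional second header line ``#units: name=unit, ...`` carries units.
    ``uncertainties`` maps column name to its measurement-uncertainty model;
    columns without one default to exact (absolute 0).
    """
    units: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#units:"):
                for part in line[len("#units:"):].strip().split(","):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        units[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    if "depth_cm" not in df.columns:
        raise ValueError("proxies CSV must have a depth_cm column")
    uncertainties = uncertainties or {}
    out = []
    for col in df.columns:
        if col == "depth_cm":
            continue
        out.append(
            ProxySeries(
                name=col,
                depth=df["depth_cm"].to_numpy(),
                value=df[col].to_numpy(),
                units=units.get(col, ""),
                meas_unc=uncertainties.get(col, MeasurementUncertainty("absolute", 0.0)),
            )
        )
    return out


def write_derived_csv(series: list[ProxySeries], path: str | Path) -> None:
    """Write aligned derived series as depth_cm + one column each."""
    base = series[0].depth
    for s in series[1:]:
        if not np.array_equal(s.depth, base):
            raise ValueError("all series must share one depth grid to be written together")
    df = pd.DataFrame({"depth_cm": base, **{s.name: s.value for s in series}})
    with open(path, "w") as fh:
        fh.write("#units: " + ", ".join(f"{s.name}={s.units}" for s in series) + "\n")
        df.to_csv(fh, index=False, float_format="%.8g")
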