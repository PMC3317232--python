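"""SMPS-style number size-distribution processing and series summaries.

A scanning mobility particle sizer (DMA + CPC) reports, every few minutes,
number concentrations on a log-spaced grid of electrical-mobility
diameters (44 channels here, spanning either 5–350 nm or 10–1100 nm).
This module derives the standard summaries: total concentration C_tot,
number-weighted geometric mean diameter d_GM, sub-cutoff number fractions
x(<cut), the dN/dln d density, and spherical surface-area partitions, plus
the lognormal GM/GSD statistics, Pearson correlations and diurnal profiles
used to tabulate such series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nuclide_chain import InvalidInputError

__all__ = [
    "SizeGrid",
    "SizeDistribution",
    "SummaryStats",
    "make_grid",
    "summarize",
    "surface_partition",
    "gm_gsd",
    "correlate",
    "diurnal_profile",
    "read_smps_csv",
    "write_smps_csv",
]

N_CHANNELS = 44

#: nominal DMA ranges, nm
GRID_RANGES = {"medium": (5.0, 350.0), "long": (10.0, 1100.0)}


class UndefinedSummaryError(ValueError):
    """Raised when a summary is undefined (empty spectrum, empty cut side)."""


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced diameter grid of an SMPS unit.

    ``diameters`` are channel-centre diameters in nm, strictly increasing.
    Bin edges sit at geometric midpoints between adjacent centres and are
    extrapolated log-uniformly at the ends, giving the Δln d needed for
    dN/dln d.
    """

    diameters: np.ndarray
    descriptor: str = "custom"

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise InvalidInputError("diameters must be 1-D, positive, strictly increasing")
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return len(self.diameters)

    @property
    def log_edges(self) -> np.ndarray:
        ln = np.log(self.diameters)
        mid = (ln[:-1] + ln[1:]) / 2.0
        first = ln[0] - (mid[0] - ln[0])
        last = ln[-1] + (ln[-1] - mid[-1])
        return np.concatenate([[first], mid, [last]])

    @property
    def dlnd(self) -> np.ndarray:
        return np.diff(self.log_edges)


def make_grid(descriptor: str = "medium", n_channels: int = N_CHANNELS) -> SizeGrid:
    """Log-uniform 44-channel grid over the named DMA range."""
    if descriptor not in GRID_RANGES:
        raise InvalidInputError(f"unknown grid descriptor {descriptor!r}")
    lo, hi = GRID_RANGES[descriptor]
    d = np.geomspace(lo, hi, n_channels)
    return SizeGrid(diameters=d, descriptor=descriptor)


@dataclass(frozen=True)
class SizeDistribution:
    """One spectrum: per-channel number concentrations (cm⁻³) on a grid."""

    timestamp: pd.Timestamp
    grid: SizeGrid
    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=float)
        if n.shape != self.grid.diameters.shape:
            raise InvalidInputError("concentration vector does not match grid")
        if np.any(n < 0):
            raise InvalidInputError("concentrations must be >= 0")
        object.__setattr__(self, "n", n)


@dataclass(frozen=True)
class SpectrumSummary:
    c_tot: float                     # cm⁻³
    d_gm: float                      # nm, number-weighted geometric mean
    x_below: dict[float, float]      # cut nm -> number fraction below cut
    dndlnd: np.ndarray               # cm⁻³ per unit ln d


def summarize(dist: SizeDistribution, cuts: Sequence[float] = (10.0, 20.0)) -> SpectrumSummary:
    """Total concentration, d_GM, sub-cutoff fractions and dN/dln d.

    d_GM = exp(Σ nᵢ ln dᵢ / Σ nᵢ) over raw channel counts; a channel lies
    below a cut iff its centre diameter is strictly smaller than the cut.
    """
    n, d = dist.n, dist.grid.diameters
    c_tot = float(n.sum())
    if c_tot == 0:
        raise UndefinedSummaryError("all-zero spectrum has no summary")
    d_gm = float(np.exp(np.sum(n * np.log(d)) / c_tot))
    x_below = {float(c): float(n[d < c].sum() / c_tot) for c in cuts}
    return SpectrumSummary(c_tot=c_tot, d_gm=d_gm, x_below=x_below,
                           dndlnd=n / dist.grid.dlnd)


def total_surface(dist: SizeDistribution) -> float:
    """Total spherical surface-area concentration Σ nᵢ π dᵢ², nm² cm⁻³."""
    return float(np.sum(dist.n * np.pi * dist.grid.diameters ** 2))


def surface_partition(dist: SizeDistribution, cut: float) -> tuple[float, float]:
    """Number and surface ratios across a diameter cut.

    Returns ``(N_ratio, S_ratio)`` with N_ratio = C(<cut)/C(>cut) and
    S_ratio = S(<cut)/S(>cut), surfaces taken as spherical (π d² per
    particle). Both sides of the cut must hold nonzero concentration.
    """
    n, d = dist.n, dist.grid.diameters
    below, above = d < cut, d >= cut
    n_lo, n_hi = n[below].sum(), n[above].sum()
    if n_lo == 0 or n_hi == 0:
        raise UndefinedSummaryError(f"no particles on one side of the {cut} nm cut")
    s_lo = float(np.sum(n[below] * np.pi * d[below] ** 2))
    s_hi = float(np.sum(n[above] * np.pi * d[above] ** 2))
    return float(n_lo / n_hi), s_lo / s_hi


@dataclass(frozen=True)
class SummaryStats:
    """Min/max plus geometric mean/GSD (and arithmetic mean/SD) of a series."""

    minimum: float
    maximum: float
    gm: float
    gsd: float
    mean: float
    sd: float
    n_used: int
    n_dropped: int  # non-positive values excluded from the log statistics


def gm_gsd(series: Sequence[float]) -> SummaryStats:
    """Lognormal summary of a positive-valued series.

    GM = exp(mean(ln x)), GSD = exp(sd(ln x), ddof=1). Zeros and negatives
    are dropped (their count is reported), never imputed. The arithmetic
    mean/SD are computed on the same retained values.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise InvalidInputError("empty series")
    keep = x > 0
    n_dropped = int((~keep).sum())
    x = x[keep]
    if x.size == 0:
        raise InvalidInputError("no positive values in series")
    ln = np.log(x)
    gsd = float(np.exp(np.std(ln, ddof=1))) if x.size > 1 else 1.0
    return SummaryStats(
        minimum=float(x.min()),
        maximum=float(x.max()),
        gm=float(np.exp(ln.mean())),
        gsd=gsd,
        mean=float(x.mean()),
        sd=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        n_used=int(x.size),
        n_dropped=n_dropped,
    )


def correlate(series_a: pd.Series, series_b: pd.Series, bin_width: str = "30min") -> float:
    """Pearson correlation of two time series after binning onto a shared grid.

    Both series are averaged into half-hour bins (label = interval start),
    inner-joined on bin, and correlated. At least three paired bins with
    nonzero variance on both sides are required.
    """
    a = series_a.resample(bin_width).mean().dropna()
    b = series_b.resample(bin_width).mean().dropna()
    joined = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise UndefinedSummaryError("fewer than 3 paired points after alignment")
    va, vb = joined.iloc[:, 0], joined.iloc[:, 1]
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedSummaryError("zero variance; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def diurnal_profile(series: pd.Series, geometric: bool = False) -> pd.Series:
    """Hour-of-day aggregate (24 values) of a datetime-indexed series.

    Requires at least 24 h of coverage. ``geometric=True`` aggregates with
    the geometric mean (positive values only), else the arithmetic mean.
    """
    if series.index.max() - series.index.min() < pd.Timedelta(hours=24):
        raise InvalidInputError("series must span at least 24 h")
    grouped = series.groupby(series.index.hour)
    if geometric:
        prof = grouped.apply(lambda x: float(np.exp(np.log(x[x > 0]).mean())))
    else:
        prof = grouped.mean()
    return prof.reindex(range(24))


def two_hour_spectra(frames: pd.DataFrame) -> pd.DataFrame:
    """Average channel spectra into two-hour bins (index = bin start)."""
    return frames.resample("2h").mean().dropna(how="all")


# -- CSV dialect -------------------------------------------------------------
# Header row: "timestamp" followed by channel diameters in nm; one record
# per row, ISO-8601 timestamp + 44 concentrations in cm⁻³.

def write_smps_csv(path, grid: SizeGrid, records: pd.DataFrame) -> None:
    out = records.copy()
    out.columns = [f"{d:.4f}" for d in grid.diameters]
    out.index.name = "timestamp"
    out.to_csv(path, float_format="%.6g")


def read_smps_csv(path) -> tuple[SizeGrid, pd.DataFrame]:
    df = pd.read_csv(path, index_col=0, parse_dates=True)
    diameters = np.array([float(c) for c in df.columns])
    grid = SizeGrid(diameters=diameters)
    df.columns = diameters
    return grid, df
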