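"""Dynamic Habitat Indices (DHIs) from periodic FPAR stacks.

The three DHIs summarise a vegetation-productivity time series per pixel:

* cumulative DHI — the sum of FPAR over the annual composite (total
  productivity, unitless sum of 0–1 fractions);
* minimum DHI — the lowest composite FPAR of the year (productivity floor);
* variation DHI — the coefficient of variation (sample SD / mean) of the
  composite series (seasonality).

The composite series is the median of FPAR across years for each
within-year period, optionally aggregating 8-day periods into 16-day ones
first. Missing observations (winter darkness, snow) are NaN throughout;
pixels missing in every year for a period stay missing in the composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FparStack",
    "CompositeSeries",
    "DhiRaster",
    "composite_fpar",
    "cumulative_dhi",
    "minimum_dhi",
    "variation_dhi",
    "compute_dhi",
    "default_winter_periods",
    "load_fpar_directory",
]


@dataclass
class FparStack:
    """FPAR observations shaped (years, periods, rows, cols); NaN = missing."""

    values: np.ndarray
    period_length_days: int = 8
    year_labels: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("FparStack.values must be 4-D (year, period, row, col)")
        if self.values.size == 0:
            raise ValueError("empty FPAR stack")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("FPAR values must lie in [0, 1]")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]

    @property
    def periods_per_year(self) -> int:
        return self.values.shape[1]


@dataclass
class CompositeSeries:
    """Cross-year median FPAR, shaped (periods, rows, cols)."""

    values: np.ndarray
    period_length_days: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("CompositeSeries.values must be 3-D")

    @property
    def n_periods(self) -> int:
        return self.values.shape[0]


@dataclass
class DhiRaster:
    """Per-pixel DHI bands; NaN marks undefined pixels."""

    cumulative: np.ndarray
    minimum: np.ndarray
    variation: np.ndarray
    band_names: tuple[str, ...] = field(default=("cumulative", "minimum", "variation"))

    def stack(self) -> np.ndarray:
        return np.stack([self.cumulative, self.minimum, self.variation])


def load_fpar_directory(path, period_length_days: int = 8) -> FparStack:
    """Read per-year multi-band TIFFs named ``fpar_<year>.tif`` into a stack."""
    from pathlib import Path

    from .rasters import read_raster

    files = sorted(Path(path).glob("fpar_*.tif"))
    if not files:
        raise ValueError(f"no fpar_*.tif files under {path}")
    years, arrays = [], []
    for f in files:
        years.append(int(f.stem.split("_")[1]))
        arr, _ = read_raster(f)
        arrays.append(np.asarray(arr, dtype=float))
    return FparStack(np.stack(arrays), period_length_days=period_length_days,
                     year_labels=years)


def composite_fpar(stack: FparStack, target_period_days: int | None = None) -> CompositeSeries:
    """Median-composite an FPAR stack across years.

    When ``target_period_days`` is a multiple of the stack's period length
    (e.g. 16 vs 8 days), consecutive within-year periods are pooled with the
    years before taking the median, yielding one composite layer per target
    period. A cell-period with no finite value in any year stays NaN.
    """
    if target_period_days is None:
        target_period_days = stack.period_length_days
    if target_period_days % stack.period_length_days != 0:
        raise ValueError(
            f"target period ({target_period_days} d) must be a multiple of the "
            f"stack period ({stack.period_length_days} d)"
        )
    factor = target_period_days // stack.period_length_days
    ny, npd, h, w = stack.values.shape
    if npd % factor != 0:
        raise ValueError(f"{npd} periods per year not divisible by aggregation factor {factor}")
    pooled = (
        stack.values.reshape(ny, npd // factor, factor, h, w)
        .transpose(1, 0, 2, 3, 4)
        .reshape(npd // factor, ny * factor, h, w)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        comp = np.nanmedian(pooled, axis=1)
    return CompositeSeries(comp, target_period_days)


def cumulative_dhi(series: CompositeSeries) -> np.ndarray:
    """Sum of available composite FPAR per pixel; all-missing pixels → NaN.

    Missing periods are omitted from the sum without rescaling (the
    gap-omitted convention); see the methods note for the alternatives.
    """
    if series.n_periods == 0:
        raise ValueError("empty composite series")
    v = series.values
    out = np.nansum(v, axis=0)
    out[np.all(np.isnan(v), axis=0)] = np.nan
    return out


def default_winter_periods(n_periods: int) -> np.ndarray:
    """Period indices treated as boreal winter: the first and last eighth of
    the year (the annual insolation minimum for a mid-year growing peak)."""
    k = max(1, int(np.ceil(n_periods / 8)))
    return np.concatenate([np.arange(k), np.arange(n_periods - k, n_periods)])


def minimum_dhi(
    series: CompositeSeries,
    darkness_fill: bool = True,
    winter_periods: np.ndarray | None = None,
) -> np.ndarray:
    """Lowest available composite FPAR per pixel.

    With ``darkness_fill`` (default), a pixel missing any winter period is
    set to 0: high-latitude winter gaps reflect darkness or snow over bare
    or dormant vegetation, so the annual productivity floor is zero there.
    """
    if series.n_periods == 0:
        raise ValueError("empty composite series")
    v = series.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmin(v, axis=0)
    out[np.all(np.isnan(v), axis=0)] = np.nan
    if darkness_fill:
        if winter_periods is None:
            winter_periods = default_winter_periods(series.n_periods)
        winter_gap = np.any(np.isnan(v[np.asarray(winter_periods, dtype=int)]), axis=0)
        out[winter_gap & ~np.all(np.isnan(v), axis=0)] = 0.0
    return out


def variation_dhi(series: CompositeSeries, ddof: int = 1) -> np.ndarray:
    """Coefficient of variation (SD / mean) of the composite series.

    Uses the sample SD (``ddof=1``) over available periods. Pixels with a
    non-positive mean or fewer than two available periods are NaN.
    """
    if series.n_periods == 0:
        raise ValueError("empty composite series")
    v = series.values
    n_avail = np.sum(np.isfinite(v), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(v, axis=0)
        sd = np.nanstd(v, axis=0, ddof=ddof)
    out = np.full(mean.shape, np.nan)
    ok = (n_avail >= max(2, ddof + 1)) & (mean > 0)
    out[ok] = sd[ok] / mean[ok]
    return out


def compute_dhi(
    stack: FparStack,
    target_period_days: int | None = 16,
    darkness_fill: bool = True,
    winter_periods: np.ndarray | None = None,
    ddof: int = 1,
) -> DhiRaster:
    """Composite the stack and compute all three DHI bands."""
    series = composite_fpar(stack, target_period_days)
    return DhiRaster(
        cumulative=cumulative_dhi(series),
        minimum=minimum_dhi(series, darkness_fill=darkness_fill, winter_periods=winter_periods),
        variation=variation_dhi(series, ddof=ddof),
    )
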