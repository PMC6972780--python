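"""Regional abundance → interpolated counts, densities and CV diagnostics.

Winter-track-count programmes report one population total per region per
year, with occasional gaps. Gaps are filled by linear interpolation in time
(boundary gaps take the nearest observed value), counts are converted to
densities by dividing by suitable-habitat area, averaged over a period, and
natural-log-transformed for regression. The coefficient of variation of
density among regions tracks survey-data quality over time.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "interpolate_missing",
    "density",
    "density_by_year",
    "cv_across_regions",
    "decade_periods",
    "decline_fraction",
]


def _check_table(table: pd.DataFrame) -> None:
    required = {"region_id", "year", "count"}
    if not required <= set(table.columns):
        raise ValueError(f"abundance table needs columns {sorted(required)}")
    if table.duplicated(["region_id", "year"]).any():
        raise ValueError("duplicate (region_id, year) rows")


def interpolate_missing(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing counts per region by linear interpolation over years.

    Interior gaps interpolate between the nearest observed years; boundary
    gaps extend the nearest observed value (the series cannot be
    extrapolated). Every region must have at least two observed years.
    """
    _check_table(table)
    wide = table.pivot(index="region_id", columns="year", values="count").sort_index(axis=1)
    n_obs = wide.notna().sum(axis=1)
    bad = n_obs[n_obs < 2]
    if len(bad):
        raise ValueError(f"regions with <2 observed years: {list(bad.index)}")
    filled = wide.apply(
        lambda row: row.interpolate(method="index").ffill().bfill(), axis=1
    )
    out = filled.stack().rename("count").reset_index()
    return out.sort_values(["region_id", "year"]).reset_index(drop=True)


def density(
    table: pd.DataFrame,
    areas: pd.DataFrame,
    period: Iterable[int],
    label: str | None = None,
) -> pd.DataFrame:
    """Mean density (individuals/km²) per region over ``period`` years.

    Density is the mean over years of count / habitat area (the mean of
    yearly densities, not pooled counts over pooled area-years). Regions
    with zero or missing habitat area are excluded with a warning.
    log_density is the natural log.
    """
    _check_table(table)
    years = sorted(set(period))
    if not years:
        raise ValueError("empty period")
    if label is None:
        label = f"{years[0]}-{years[-1]}"
    merged = table[table["year"].isin(years)].merge(areas, on="region_id", how="left")
    if merged["count"].isna().any():
        raise ValueError("missing counts in period; interpolate first")
    bad = merged.loc[~(merged["habitat_km2"] > 0), "region_id"].unique()
    if len(bad):
        log.warning("excluding regions with zero/absent habitat area: %s", sorted(bad))
        merged = merged[~merged["region_id"].isin(bad)]
    merged = merged.assign(d=merged["count"] / merged["habitat_km2"])
    out = merged.groupby("region_id", as_index=False)["d"].mean()
    out = out.rename(columns={"d": "density"})
    out.insert(1, "period_label", label)
    with np.errstate(divide="ignore"):
        out["log_density"] = np.where(out["density"] > 0, np.log(out["density"]), np.nan)
    return out


def density_by_year(table: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Yearly density per region (count / habitat area), for CV diagnostics."""
    _check_table(table)
    merged = table.merge(areas, on="region_id", how="left")
    merged = merged[merged["habitat_km2"] > 0]
    merged["density"] = merged["count"] / merged["habitat_km2"]
    return merged[["region_id", "year", "density"]]


def cv_across_regions(yearly: pd.DataFrame, grouping: str = "year") -> pd.DataFrame:
    """Coefficient of variation (sample SD / mean) of density among regions.

    ``grouping='year'`` gives the annual CV; ``grouping='decade'`` reports
    the median of the annual CVs within each decade, the summary used to
    compare survey quality across decades.
    """
    if not {"region_id", "year", "density"} <= set(yearly.columns):
        raise ValueError("need columns region_id, year, density")
    if yearly["region_id"].nunique() < 2:
        raise ValueError("CV across regions needs at least two regions")

    def _cv(x: pd.Series) -> float:
        m = x.mean()
        if m == 0:
            raise ValueError("mean density is zero; CV undefined")
        return x.std(ddof=1) / m

    per_year = yearly.groupby("year")["density"].apply(_cv).rename("cv").reset_index()
    if grouping == "year":
        return per_year
    if grouping == "decade":
        periods = decade_periods(sorted(yearly["year"].unique()))
        rows = []
        for lab, years in periods.items():
            sub = per_year[per_year["year"].isin(years)]
            rows.append((lab, float(sub["cv"].median())))
        return pd.DataFrame(rows, columns=["period_label", "median_cv"])
    raise ValueError(f"unknown grouping {grouping!r}")


def decade_periods(years: Sequence[int]) -> dict[str, list[int]]:
    """Split the study years into three contiguous, near-equal blocks.

    For the canonical 1981–2010 span this yields 1981–1990, 1991–2000 and
    2001–2010 inclusive.
    """
    years = sorted(years)
    n = len(years)
    if n < 3:
        raise ValueError("need at least three years to form decades")
    cuts = [0, round(n / 3), round(2 * n / 3), n]
    out: dict[str, list[int]] = {}
    for a, b in zip(cuts[:-1], cuts[1:]):
        block = years[a:b]
        out[f"{block[0]}-{block[-1]}"] = list(block)
    return out


def decline_fraction(totals: pd.Series) -> tuple[int, int, float]:
    """Peak-to-trough decline of a population trajectory.

    Returns (peak_year, trough_year, fraction) where the trough is the
    minimum after the peak and fraction = (peak − trough) / peak.
    """
    totals = totals.sort_index()
    peak_year = int(totals.idxmax())
    after = totals.loc[peak_year:]
    trough_year = int(after.idxmin())
    peak, trough = float(totals.loc[peak_year]), float(after.min())
    if peak <= 0:
        raise ValueError("non-positive peak")
    return peak_year, trough_year, (peak - trough) / peak
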