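"""Zonal covariate extraction and design-table assembly.

Raster covariates (DHI bands, BIOCLIM variables, elevation, human
footprint) are averaged over suitable habitat within each region; tabular
covariates (road density, rural population) join on region id. The
assembled table is one row per region, ready for regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["RegionMap", "zonal_mean", "road_density", "assemble_design"]


@dataclass
class RegionMap:
    """Integer region labels (1..n; 0 = background) plus centroids in degrees."""

    values: np.ndarray
    centroids: pd.DataFrame  # region_id, lon, lat

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        ids = self.region_ids
        if not set(self.centroids["region_id"]) >= set(ids):
            raise ValueError("centroid table missing regions present in the map")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.values)
        return ids[ids > 0]


def zonal_mean(
    raster: np.ndarray,
    regions: RegionMap,
    mask: np.ndarray | None = None,
    name: str = "mean",
) -> pd.DataFrame:
    """Mean of raster cells per region, optionally restricted to a mask.

    NaN cells are excluded. A region with no contributing cells gets NaN
    and a warning — downstream joins will then fail loudly rather than
    silently propagate a fabricated value.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.shape != regions.values.shape:
        raise ValueError("raster grid does not match region map grid")
    keep = np.isfinite(raster)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != raster.shape:
            raise ValueError("mask grid does not match raster grid")
        keep &= mask
    rows = []
    for rid in regions.region_ids:
        sel = keep & (regions.values == rid)
        if sel.any():
            rows.append((int(rid), float(raster[sel].mean())))
        else:
            log.warning("region %d has no cells contributing to zonal mean", rid)
            rows.append((int(rid), np.nan))
    return pd.DataFrame(rows, columns=["region_id", name])


def road_density(road_length_km: pd.DataFrame, region_area_km2: pd.DataFrame) -> pd.DataFrame:
    """Road length divided by whole-region area (km/km²) per region."""
    merged = road_length_km.merge(region_area_km2, on="region_id", how="inner")
    if (merged["region_area_km2"] <= 0).any():
        bad = merged.loc[merged["region_area_km2"] <= 0, "region_id"].tolist()
        raise ValueError(f"non-positive region area for regions {bad}")
    merged["road_density"] = merged["road_length_km"] / merged["region_area_km2"]
    return merged[["region_id", "road_density"]]


def assemble_design(*tables: pd.DataFrame, names: list[str] | None = None) -> pd.DataFrame:
    """Inner-join per-region tables on region_id, failing loudly on mismatch.

    Every table must cover exactly the union of region ids; any region
    absent from any source is named in the error.
    """
    if not tables:
        raise ValueError("no tables to assemble")
    if names is None:
        names = [f"table_{i}" for i in range(len(tables))]
    all_ids: set[int] = set()
    for t in tables:
        if "region_id" not in t.columns:
            raise ValueError("every table needs a region_id column")
        all_ids |= set(t["region_id"])
    problems = []
    for name, t in zip(names, tables):
        missing = sorted(all_ids - set(t["region_id"]))
        if missing:
            problems.append(f"{name} missing regions {missing}")
    if problems:
        raise ValueError("region mismatch: " + "; ".join(problems))
    out = tables[0]
    for t in tables[1:]:
        overlap = (set(out.columns) & set(t.columns)) - {"region_id"}
        if overlap:
            raise ValueError(f"duplicate columns across tables: {sorted(overlap)}")
        out = out.merge(t, on="region_id", how="inner")
    return out.sort_values("region_id").reset_index(drop=True)
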