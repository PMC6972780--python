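"""Stable land cover and suitable-habitat masking.

A pixel's land cover is "stable" when a single class holds in strictly more
than half of the observed years; otherwise the pixel is excluded (nodata).
Suitable habitat is the intersection of a suitable stable class with the
species range mask; habitat area is tallied per region on an equal-area
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LandCoverStack",
    "StableLandCoverMap",
    "HabitatMask",
    "SUITABLE_CLASSES",
    "stable_landcover",
    "habitat_mask",
    "habitat_area_by_region",
    "majority_resample",
]

#: Land-cover classes treated as suitable moose habitat: evergreen needleleaf
#: (1), evergreen broadleaf (2), deciduous needleleaf (3), deciduous
#: broadleaf (4), mixed forest (5), open shrubland (7), woody savanna (8)
#: and permanent wetland (11).
SUITABLE_CLASSES = frozenset({1, 2, 3, 4, 5, 7, 8, 11})

NODATA = -1


@dataclass
class LandCoverStack:
    """Annual integer class rasters shaped (years, rows, cols)."""

    values: np.ndarray
    class_codebook: dict[int, str]
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("LandCoverStack.values must be 3-D (year, row, col)")
        if self.values.shape[0] == 0:
            raise ValueError("empty land-cover stack")
        observed = set(np.unique(self.values)) - {self.nodata}
        unknown = observed - set(self.class_codebook)
        if unknown:
            raise ValueError(f"classes {sorted(unknown)} missing from codebook")


@dataclass
class StableLandCoverMap:
    values: np.ndarray
    class_codebook: dict[int, str]
    nodata: int = NODATA


@dataclass
class HabitatMask:
    values: np.ndarray  # boolean (rows, cols)
    cell_area_km2: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def stable_landcover(stack: LandCoverStack) -> StableLandCoverMap:
    """Per-pixel modal class when its count strictly exceeds half the years.

    The strict majority makes ties impossible; pixels without such a class
    (including any whose count equals exactly half) become nodata. All
    years, nodata included, count in the denominator.
    """
    v = stack.values
    n_years = v.shape[0]
    out = np.full(v.shape[1:], stack.nodata, dtype=v.dtype)
    best = np.zeros(v.shape[1:], dtype=int)
    for cls in stack.class_codebook:
        count = np.sum(v == cls, axis=0)
        take = count > best
        out[take] = cls
        best[take] = count[take]
    out[best * 2 <= n_years] = stack.nodata
    return StableLandCoverMap(out, dict(stack.class_codebook), stack.nodata)


def habitat_mask(
    stable: StableLandCoverMap,
    suitable: frozenset[int] | set[int] = SUITABLE_CLASSES,
    range_mask: np.ndarray | None = None,
    cell_area_km2: float = 1.0,
) -> HabitatMask:
    """Suitable stable class AND inside the species range."""
    missing = set(suitable) - set(stable.class_codebook)
    if missing:
        raise ValueError(f"suitable classes {sorted(missing)} absent from codebook")
    mask = np.isin(stable.values, list(suitable))
    if range_mask is not None:
        range_mask = np.asarray(range_mask, dtype=bool)
        if range_mask.shape != mask.shape:
            raise ValueError("range mask grid does not match stable land cover grid")
        mask &= range_mask
    return HabitatMask(mask, cell_area_km2)


def habitat_area_by_region(mask: HabitatMask, region_values: np.ndarray) -> pd.DataFrame:
    """Suitable-habitat area (km²) per region; every region present, possibly 0."""
    regions = np.asarray(region_values)
    if regions.shape != mask.values.shape:
        raise ValueError("region map grid does not match habitat mask grid")
    ids = np.unique(regions)
    ids = ids[ids > 0]
    rows = []
    for rid in ids:
        cells = int(np.sum(mask.values & (regions == rid)))
        rows.append((int(rid), cells * mask.cell_area_km2))
    return pd.DataFrame(rows, columns=["region_id", "habitat_km2"])


def majority_resample(values: np.ndarray, factor: int, nodata: int = NODATA) -> np.ndarray:
    """Aggregate an integer raster by ``factor`` using the block mode.

    Provided for mismatched input resolutions (e.g. 500 m land cover onto a
    1 km analysis grid). Ties break toward the smallest class code.
    """
    v = np.asarray(values)
    h, w = v.shape
    if h % factor or w % factor:
        raise ValueError("grid not divisible by resampling factor")
    blocks = v.reshape(h // factor, factor, w // factor, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(h // factor, w // factor, factor * factor)
    out = np.full((h // factor, w // factor), nodata, dtype=v.dtype)
    classes = np.unique(v)
    classes = classes[classes != nodata]
    best = np.zeros(out.shape, dtype=int)
    for cls in classes:  # ascending, so ties keep the first (smallest) code
        count = np.sum(blocks == cls, axis=2)
        take = count > best
        out[take] = cls
        best[take] = count[take]
    return out
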