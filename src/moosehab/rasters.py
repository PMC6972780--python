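"""Minimal raster I/O: single- or multi-band TIFF with a JSON metadata tag.

Synthetic grids are declared equal-area (1 km² cells by default), so no
projection machinery is needed; metadata carries the nodata marker and band
names so files round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile


def write_raster(
    path: str | Path,
    data: np.ndarray,
    nodata: float | int | None = None,
    band_names: list[str] | None = None,
) -> Path:
    """Write a (rows, cols) or (bands, rows, cols) array as TIFF.

    Float arrays keep NaN as-is; ``nodata`` is recorded in metadata for
    integer rasters (where NaN cannot be stored).
    """
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ValueError(f"raster must be 2-D or 3-D, got shape {data.shape}")
    meta = {"nodata": nodata, "band_names": band_names}
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, data, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_raster`; returns (array, metadata)."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta: dict = {"nodata": None, "band_names": None}
        if desc is not None:
            try:
                meta.update(json.loads(desc.value))
            except (json.JSONDecodeError, TypeError):
                pass
    return data, meta
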