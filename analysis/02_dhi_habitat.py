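"""Compute the Dynamic Habitat Indices and the suitable-habitat map.

Median-composites the FPAR stack into 16-day layers, derives the three DHI
bands, builds the stable land-cover map (strict majority over years) and
tallies suitable-habitat area per region.
"""

import argparse
from pathlib import Path

import numpy as np

from moosehab import rasters
from moosehab.dhi import compute_dhi
from moosehab.habitat import habitat_area_by_region, habitat_mask, stable_landcover
from moosehab.scenario import ScenarioConfig, generate_scenario


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = ScenarioConfig(seed=args.seed)
    bundle = generate_scenario(cfg)

    dhi = compute_dhi(bundle.fpar, target_period_days=16)
    rasters.write_raster(args.out / "dhi.tif", dhi.stack().astype(np.float32),
                         band_names=list(dhi.band_names))
    stable = stable_landcover(bundle.landcover)
    hmask = habitat_mask(stable, set(cfg.suitable_classes), bundle.range_mask)
    areas = habitat_area_by_region(hmask, bundle.regions.values)
    args.out.mkdir(parents=True, exist_ok=True)
    areas.to_csv(args.out / "habitat_areas.csv", index=False)

    stable_frac = float(np.mean(stable.values != stable.nodata))
    print(f"cumulative DHI: median {np.nanmedian(dhi.cumulative):.1f} "
          f"(north-south gradient from winter darkness and short seasons)")
    print(f"minimum DHI zero-filled where winter periods are dark: "
          f"{float(np.mean(dhi.minimum == 0)):.0%} of pixels")
    print(f"stable land cover resolved for {stable_frac:.0%} of pixels; "
          f"suitable habitat covers {float(hmask.values.mean()):.0%} of the grid")
    print(f"habitat area per region: min {areas['habitat_km2'].min():.0f}, "
          f"median {areas['habitat_km2'].median():.0f} km2")


if __name__ == "__main__":
    main()
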