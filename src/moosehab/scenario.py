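"""Synthetic study scenario: rasters and tables with known ground truth.

Emulates the full input bundle of a regional moose-habitat analysis — a
multi-year 8-day FPAR stack with high-latitude winter gaps, annual
land-cover rasters, a Voronoi region map (62 regions by default, the
administrative units of the real survey), BIOCLIM-style climate rasters,
elevation and human footprint, and a 30-year winter-track-count abundance
table with a small fraction of missing cells.

The generative model for abundance: per-region habitat-masked zonal means
of the chosen covariates are z-scored across regions, the log of each
region's baseline density is β₀ + Σ βⱼ·zⱼ + ε with ε ~ N(0, σ²), a fixed
national trajectory multiplier (growth to a peak ~1991, collapse to ~2002,
partial recovery — normalised to mean 1 so period averages recover the
baseline) scales the density by year, and counts are density × habitat
area, rounded (Poisson optional). σ = 0 is a noiseless diagnostic mode:
counts are exact real-valued expectations so that identifiability checks
(exact R² = 1, exact support recovery) are well-posed.

All randomness flows from ``ScenarioConfig.seed``; identical configs give
bit-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from . import rasters
from .dhi import FparStack, compute_dhi, default_winter_periods
from .habitat import SUITABLE_CLASSES, HabitatMask, LandCoverStack, StableLandCoverMap
from .habitat import habitat_area_by_region, habitat_mask, stable_landcover
from .zonal import RegionMap, zonal_mean

__all__ = ["ScenarioConfig", "ScenarioTruth", "ScenarioBundle", "generate_scenario", "degrade_abundance"]

#: Grid ↔ geographic mapping (degrees): row 0 is the northern edge.
LON_RANGE = (30.0, 100.0)
LAT_RANGE = (70.0, 50.0)

CLASS_NAMES = {
    1: "evergreen needleleaf forest",
    2: "evergreen broadleaf forest",
    3: "deciduous needleleaf forest",
    4: "deciduous broadleaf forest",
    5: "mixed forest",
    7: "open shrubland",
    8: "woody savanna",
    10: "grassland",
    11: "permanent wetland",
    13: "urban",
    16: "barren",
}

BIO_NAMES = [f"bio{i}" for i in range(1, 20)]


@dataclass
class ScenarioConfig:
    """Study conditions of the synthetic scenario (defaults follow the
    real study design: 62 regions, 12 FPAR years × 46 8-day periods,
    30 abundance years, 0.3% missing abundance cells)."""

    grid_height: int = 80
    grid_width: int = 80
    n_regions: int = 62
    n_years_fpar: int = 12
    periods_per_year: int = 46
    n_years_abundance: int = 30
    first_abundance_year: int = 1981
    first_fpar_year: int = 2003
    landcover_classes: tuple[int, ...] = (1, 2, 3, 4, 5, 7, 8, 10, 11, 13, 16)
    suitable_classes: tuple[int, ...] = tuple(sorted(SUITABLE_CLASSES))
    n_years_landcover: int = 10
    beta: tuple[float, ...] = (2.0, 0.5, -0.3)
    covariate_names: tuple[str, ...] = ("dhi_cum", "bio1")
    sigma: float = 0.1
    missing_abundance_fraction: float = 0.003
    darkness_latitude_fraction: float = 0.25
    landcover_change_prob: float = 0.08
    fpar_noise_sd: float = 0.03
    count_model: str = "round"  # "round" | "poisson"
    cell_area_km2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not set(self.suitable_classes) <= set(self.landcover_classes):
            raise ValueError("suitable_classes must be a subset of landcover_classes")
        for name in ("grid_height", "grid_width", "n_regions", "n_years_fpar",
                     "periods_per_year", "n_years_abundance", "n_years_landcover"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_regions > self.grid_height * self.grid_width:
            raise ValueError("more regions than grid cells")
        if not 0 <= self.missing_abundance_fraction < 1:
            raise ValueError("missing_abundance_fraction must be in [0, 1)")
        if len(self.beta) != len(self.covariate_names) + 1:
            raise ValueError("beta must have one intercept plus one slope per covariate")
        if self.count_model not in ("round", "poisson"):
            raise ValueError("count_model must be 'round' or 'poisson'")

    @property
    def abundance_years(self) -> list[int]:
        return list(range(self.first_abundance_year,
                          self.first_abundance_year + self.n_years_abundance))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        for f_ in dataclasses.fields(cls):
            if f_.name in d and isinstance(d[f_.name], list):
                d[f_.name] = tuple(d[f_.name])
        return cls(**d)


@dataclass
class ScenarioTruth:
    """Generating coefficients and transforms for parameter recovery."""

    beta: tuple[float, ...]
    sigma: float
    covariate_names: tuple[str, ...]
    covariate_means: dict[str, float]
    covariate_sds: dict[str, float]
    region_centroids: pd.DataFrame
    year_multipliers: pd.Series

    def standardize(self, table: pd.DataFrame) -> pd.DataFrame:
        """Z-score the generating covariates with the generator's scaling,
        producing columns ``z_<name>`` comparable to the true beta."""
        out = table.copy()
        for name in self.covariate_names:
            out[f"z_{name}"] = (out[name] - self.covariate_means[name]) / self.covariate_sds[name]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "beta": list(self.beta),
            "sigma": self.sigma,
            "covariate_names": list(self.covariate_names),
            "covariate_means": self.covariate_means,
            "covariate_sds": self.covariate_sds,
            "region_centroids": self.region_centroids.to_dict(orient="list"),
            "year_multipliers": {int(k): float(v) for k, v in self.year_multipliers.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ScenarioBundle:
    config: ScenarioConfig
    fpar: FparStack
    landcover: LandCoverStack
    regions: RegionMap
    range_mask: np.ndarray
    covariates: dict[str, np.ndarray]
    abundance: pd.DataFrame
    roads: pd.DataFrame
    rural_population: pd.DataFrame
    truth: ScenarioTruth
    # internal products the generator derived (recomputable from the above)
    stable: StableLandCoverMap = field(repr=False, default=None)
    habitat: HabitatMask = field(repr=False, default=None)
    habitat_areas: pd.DataFrame = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        self.truth.to_json(out / "truth.json")
        for i, year in enumerate(self.fpar.year_labels):
            rasters.write_raster(out / f"fpar_{year}.tif", self.fpar.values[i].astype(np.float32))
        rasters.write_raster(out / "landcover.tif", self.landcover.values.astype(np.int16),
                             nodata=self.landcover.nodata)
        rasters.write_raster(out / "regions.tif", self.regions.values.astype(np.int16), nodata=0)
        rasters.write_raster(out / "range_mask.tif", self.range_mask.astype(np.uint8))
        for name, arr in self.covariates.items():
            rasters.write_raster(out / f"cov_{name}.tif", arr.astype(np.float32))
        self.regions.centroids.to_csv(out / "centroids.csv", index=False)
        self.abundance.to_csv(out / "abundance.csv", index=False)
        self.roads.to_csv(out / "roads.csv", index=False)
        self.rural_population.to_csv(out / "rural_population.csv", index=False)
        return out


def _smooth_field(rng: np.random.Generator, h: int, w: int, scale: float) -> np.ndarray:
    """Standardised Gaussian random field with correlation length ``scale``."""
    f = gaussian_filter(rng.standard_normal((h, w)), sigma=scale, mode="reflect")
    return (f - f.mean()) / f.std()


def _region_map(rng: np.random.Generator, cfg: ScenarioConfig) -> RegionMap:
    """Contiguous regions: Voronoi cells of a jittered rectangular lattice."""
    h, w, n = cfg.grid_height, cfg.grid_width, cfg.n_regions
    nr = max(1, int(round(np.sqrt(n * h / w))))
    nc = int(np.ceil(n / nr))
    while nr * nc < n:
        nc += 1
    tiles = [(i, j) for i in range(nr) for j in range(nc)]
    keep = rng.permutation(len(tiles))[:n]
    seeds = []
    for k in sorted(keep):
        i, j = tiles[k]
        y = (i + 0.5) * h / nr + rng.uniform(-0.3, 0.3) * h / nr
        x = (j + 0.5) * w / nc + rng.uniform(-0.3, 0.3) * w / nc
        seeds.append((min(h - 1e-6, max(0.0, y)), min(w - 1e-6, max(0.0, x))))
    seeds_arr = np.array(seeds)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - seeds_arr[:, 0]) ** 2 + (xx[..., None] - seeds_arr[:, 1]) ** 2
    values = np.argmin(d2, axis=-1).astype(np.int32) + 1
    rows = []
    for rid in range(1, n + 1):
        sel = values == rid
        r_mean, c_mean = yy[sel].mean(), xx[sel].mean()
        lon = LON_RANGE[0] + (c_mean + 0.5) / w * (LON_RANGE[1] - LON_RANGE[0])
        lat = LAT_RANGE[0] + (r_mean + 0.5) / h * (LAT_RANGE[1] - LAT_RANGE[0])
        rows.append((rid, float(lon), float(lat)))
    centroids = pd.DataFrame(rows, columns=["region_id", "lon", "lat"])
    return RegionMap(values, centroids)


def _climate_rasters(rng: np.random.Generator, cfg: ScenarioConfig,
                     veg: np.ndarray) -> dict[str, np.ndarray]:
    """BIOCLIM-style covariates, elevation and human footprint.

    Temperature variables share a latitudinal gradient (warmer south) so
    they are realistically inter-correlated; precipitation variables are
    independent smooth fields. Units are plain °C / mm / index points.
    """
    h, w = cfg.grid_height, cfg.grid_width
    south = (np.arange(h)[:, None] + 0.5) / h * np.ones((1, w))  # 0 north → 1 south
    cov: dict[str, np.ndarray] = {}
    t_base = -8.0 + 14.0 * south + 2.5 * _smooth_field(rng, h, w, 6)
    cov["bio1"] = t_base
    cov["bio4"] = 900.0 - 250.0 * south + 120.0 * _smooth_field(rng, h, w, 6)
    cov["bio5"] = t_base + 22.0 + 1.5 * _smooth_field(rng, h, w, 6)
    cov["bio6"] = t_base - 24.0 + 1.5 * _smooth_field(rng, h, w, 6)
    cov["bio7"] = cov["bio5"] - cov["bio6"]
    for name in ("bio2", "bio3", "bio8", "bio9", "bio10", "bio11"):
        cov[name] = t_base + 3.0 * _smooth_field(rng, h, w, 6)
    p_base = 550.0 + 180.0 * _smooth_field(rng, h, w, 8)
    cov["bio12"] = p_base
    for name in ("bio13", "bio14", "bio15", "bio16", "bio17", "bio18", "bio19"):
        cov[name] = np.clip(0.2 * p_base + 60.0 * _smooth_field(rng, h, w, 8), 0, None)
    cov["elevation"] = np.abs(120.0 + 260.0 * _smooth_field(rng, h, w, 10))
    cov["human_footprint"] = np.clip(
        12.0 + 9.0 * south + 4.0 * _smooth_field(rng, h, w, 5) + 0.15 * veg, 0, 50
    )
    return cov


def _fpar_stack(rng: np.random.Generator, cfg: ScenarioConfig, veg: np.ndarray) -> FparStack:
    h, w, pp = cfg.grid_height, cfg.grid_width, cfg.periods_per_year
    south = (np.arange(h)[:, None] + 0.5) / h * np.ones((1, w))
    mean = np.clip(0.30 + 0.30 * south + 0.08 * veg, 0.05, 0.90)
    amp = 0.85 * np.minimum(mean, 1 - mean) * (0.7 + 0.1 * np.tanh(veg))
    season = -np.cos(2 * np.pi * (np.arange(pp) + 0.5) / pp)  # trough at year edges
    values = mean[None, None] + amp[None, None] * season[None, :, None, None]
    values = values + rng.normal(0.0, cfg.fpar_noise_sd,
                                 size=(cfg.n_years_fpar, pp, h, w))
    values = np.clip(values, 0.0, 1.0)
    dark_rows = int(round(h * cfg.darkness_latitude_fraction))
    if dark_rows > 0:
        winter = default_winter_periods(pp)
        values[:, winter[:, None], np.arange(dark_rows)[None, :], :] = np.nan
    years = list(range(cfg.first_fpar_year, cfg.first_fpar_year + cfg.n_years_fpar))
    return FparStack(values, period_length_days=8, year_labels=years)


def _landcover_stack(rng: np.random.Generator, cfg: ScenarioConfig,
                     veg: np.ndarray) -> LandCoverStack:
    h, w = cfg.grid_height, cfg.grid_width
    # order class bands along the vegetation gradient with unsuitable classes
    # interleaved mid-distribution, so vegetation extremes stay suitable and
    # every region keeps some habitat
    suit = [c for c in cfg.landcover_classes if c in set(cfg.suitable_classes)]
    unsuit = [c for c in cfg.landcover_classes if c not in set(cfg.suitable_classes)]
    classes = list(suit) if suit else list(cfg.landcover_classes)
    if suit:
        for i, c in enumerate(unsuit):
            pos = int((i + 1) * len(classes) / (len(unsuit) + 1))
            classes.insert(max(1, min(pos, len(classes) - 1)), c)
    weights = np.array([5.0 if c in set(cfg.suitable_classes) else 1.0 for c in classes])
    cum = np.cumsum(weights / weights.sum())
    # patchy banding: jitter before ranking so class bands interleave locally
    noisy = veg + 0.35 * rng.standard_normal(veg.shape)
    ranks = noisy.flatten().argsort().argsort() / (h * w)  # uniform on [0, 1)
    base = np.array(classes)[np.searchsorted(cum, ranks, side="right").clip(0, len(classes) - 1)]
    base = base.reshape(h, w)
    stack = np.repeat(base[None], cfg.n_years_landcover, axis=0).astype(np.int16)
    flips = rng.random(stack.shape) < cfg.landcover_change_prob
    stack[flips] = rng.choice(classes, size=int(flips.sum()))
    codebook = {c: CLASS_NAMES.get(c, f"class {c}") for c in classes}
    return LandCoverStack(stack, codebook)


def _year_multipliers(cfg: ScenarioConfig) -> pd.Series:
    """National trajectory: growth to a peak, post-1991-style collapse,
    partial recovery; normalised to mean exactly 1 over the study years."""
    years = np.array(cfg.abundance_years, dtype=float)
    frac = (years - years[0]) / max(1.0, years[-1] - years[0])
    m = np.interp(frac, [0.0, 0.345, 0.72, 1.0], [0.75, 1.30, 0.75, 0.93])
    m = m / m.mean()
    return pd.Series(m, index=cfg.abundance_years)


def degrade_abundance(table: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Flag exactly round(fraction × cells) counts as missing (NaN).

    No region ever drops below two observed years, so interpolation stays
    well-posed. Deterministic given ``seed``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    out = table.copy().reset_index(drop=True)
    k = int(np.rint(fraction * len(out)))
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(out))
    remaining = dict(out.groupby("region_id")["count"].apply(lambda s: int(s.notna().sum())))
    chosen: list[int] = []
    for idx in order:
        if len(chosen) == k:
            break
        rid = out.at[idx, "region_id"]
        if pd.isna(out.at[idx, "count"]) or remaining[rid] <= 2:
            continue
        chosen.append(idx)
        remaining[rid] -= 1
    if len(chosen) < k:
        raise ValueError("cannot remove that many cells without emptying a region")
    out.loc[chosen, "count"] = np.nan
    return out


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate the full input bundle for one scenario (see module docs)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    regions = _region_map(rng, cfg)
    veg = _smooth_field(rng, cfg.grid_height, cfg.grid_width, 7)
    covariates = _climate_rasters(rng, cfg, veg)
    fpar = _fpar_stack(rng, cfg, veg)
    landcover = _landcover_stack(rng, cfg, veg)
    range_mask = np.ones((cfg.grid_height, cfg.grid_width), dtype=bool)

    # derive the pipeline products the abundance model conditions on
    dhi = compute_dhi(fpar, target_period_days=16)
    stable = stable_landcover(landcover)
    hmask = habitat_mask(stable, set(cfg.suitable_classes), range_mask, cfg.cell_area_km2)
    areas = habitat_area_by_region(hmask, regions.values)
    if (areas["habitat_km2"] <= 0).any():
        bad = areas.loc[areas["habitat_km2"] <= 0, "region_id"].tolist()
        raise RuntimeError(f"regions without suitable habitat: {bad}; enlarge the grid")

    raster_bank = {"dhi_cum": dhi.cumulative, "dhi_min": dhi.minimum,
                   "dhi_var": dhi.variation, **covariates}
    cov_table = areas[["region_id"]].copy()
    for name in cfg.covariate_names:
        if name not in raster_bank:
            raise ValueError(f"unknown generating covariate {name!r}")
        cov_table = cov_table.merge(
            zonal_mean(raster_bank[name], regions, hmask.values, name=name), on="region_id"
        )
    means = {n: float(cov_table[n].mean()) for n in cfg.covariate_names}
    sds = {n: float(cov_table[n].std(ddof=1)) for n in cfg.covariate_names}
    Z = np.column_stack(
        [(cov_table[n] - means[n]) / sds[n] for n in cfg.covariate_names]
    ) if cfg.covariate_names else np.empty((len(cov_table), 0))
    eps = rng.normal(0.0, cfg.sigma, size=len(cov_table)) if cfg.sigma > 0 else np.zeros(len(cov_table))
    log_d = cfg.beta[0] + Z @ np.asarray(cfg.beta[1:]) + eps
    base_density = np.exp(log_d)

    multipliers = _year_multipliers(cfg)
    area_vec = areas.set_index("region_id").loc[cov_table["region_id"], "habitat_km2"].to_numpy()
    rows = []
    for i, rid in enumerate(cov_table["region_id"]):
        expected = base_density[i] * multipliers.to_numpy() * area_vec[i]
        if cfg.sigma == 0:
            counts = expected  # noiseless diagnostic mode: exact expectations
        elif cfg.count_model == "poisson":
            counts = rng.poisson(expected).astype(float)
        else:
            counts = np.rint(expected)
        for year, c in zip(cfg.abundance_years, counts):
            rows.append((int(rid), int(year), float(c)))
    abundance = pd.DataFrame(rows, columns=["region_id", "year", "count"])
    if cfg.missing_abundance_fraction > 0:
        abundance = degrade_abundance(abundance, cfg.missing_abundance_fraction,
                                      seed=int(rng.integers(2**31)))

    region_area = pd.DataFrame({
        "region_id": regions.region_ids.astype(int),
        "region_area_km2": [float(np.sum(regions.values == r) * cfg.cell_area_km2)
                            for r in regions.region_ids],
    })
    hf_region = zonal_mean(covariates["human_footprint"], regions, None, name="hf")
    hf_z = (hf_region["hf"] - hf_region["hf"].mean()) / hf_region["hf"].std(ddof=1)
    roads = region_area.copy()
    roads["road_length_km"] = roads["region_area_km2"] * np.clip(
        0.15 + 0.05 * hf_z.to_numpy() + rng.uniform(-0.03, 0.03, len(roads)), 0.01, None
    )
    roads = roads[["region_id", "road_length_km", "region_area_km2"]]

    from .density import decade_periods  # avoid cycle at import time

    decade_labels = list(decade_periods(cfg.abundance_years))
    pop_base = np.exp(rng.normal(0.0, 0.4, len(region_area))) * (
        region_area["region_area_km2"].to_numpy() * (3.0 + 2.0 * np.clip(hf_z, -1, None))
    )
    rural_rows = []
    for lab in decade_labels[1:]:  # no data for the first decade, as surveyed
        scale = 1.0 if lab == decade_labels[1] else rng.uniform(0.85, 1.0)
        for rid, base in zip(region_area["region_id"], pop_base):
            rural_rows.append((int(rid), lab, float(base * scale)))
    rural = pd.DataFrame(rural_rows, columns=["region_id", "period_label", "rural_population"])

    truth = ScenarioTruth(
        beta=tuple(cfg.beta),
        sigma=cfg.sigma,
        covariate_names=tuple(cfg.covariate_names),
        covariate_means=means,
        covariate_sds=sds,
        region_centroids=regions.centroids.copy(),
        year_multipliers=multipliers,
    )
    return ScenarioBundle(
        config=cfg, fpar=fpar, landcover=landcover, regions=regions,
        range_mask=range_mask, covariates=covariates, abundance=abundance,
        roads=roads, rural_population=rural, truth=truth,
        stable=stable, habitat=hmask, habitat_areas=areas,
    )
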