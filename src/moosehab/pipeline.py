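"""End-to-end pipeline: simulate → DHI → habitat → density → covariates →
screening → best subsets + VIF refinement → decade comparison → diagnostics.

Each stage is a pure function of the scenario bundle and the configuration;
``run_pipeline`` chains them, writes every tabular artifact as CSV under the
run directory and records a manifest (stage list, config, seed, SHA-256 of
each artifact) so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import rasters
from .decades import compare_decades
from .density import (cv_across_regions, decade_periods, density, density_by_year,
                      interpolate_missing)
from .dhi import compute_dhi
from .regression import (ModelSpec, best_subsets, fit_ols, predict_residuals,
                         residual_semivariogram, screen_collinearity, vif)
from .scenario import BIO_NAMES, ScenarioBundle, ScenarioConfig, generate_scenario
from .zonal import assemble_design, road_density, zonal_mean

log = logging.getLogger(__name__)

STAGES = ["simulate", "dhi", "habitat", "density", "covariates",
          "screen", "fit", "decades", "diagnostics"]

FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    target_period_days: int = 16
    vif_limit: float = 10.0
    cluster_threshold: float = 0.5  # squared-Spearman similarity cut
    max_model_size: int = 4

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d["scenario"].items():
            if isinstance(v, tuple):
                d["scenario"][k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        scenario = d.pop("scenario", {})
        for k, v in list(scenario.items()):
            if isinstance(v, list):
                scenario[k] = tuple(v)
        return cls(scenario=ScenarioConfig(**scenario), **d)


def extract_design(bundle: ScenarioBundle, target_period_days: int = 16) -> dict:
    """Run the observation side of the pipeline on a bundle.

    Returns a dict with the DHI raster, habitat products, density tables
    (full period + decades), the assembled covariate table, and the yearly
    density view — everything downstream model selection needs.
    """
    from .habitat import habitat_area_by_region, habitat_mask, stable_landcover

    cfg = bundle.config
    dhi = compute_dhi(bundle.fpar, target_period_days=target_period_days)
    stable = stable_landcover(bundle.landcover)
    hmask = habitat_mask(stable, set(cfg.suitable_classes), bundle.range_mask,
                         cfg.cell_area_km2)
    areas = habitat_area_by_region(hmask, bundle.regions.values)

    filled = interpolate_missing(bundle.abundance)
    periods = decade_periods(cfg.abundance_years)
    full_label = f"{cfg.abundance_years[0]}-{cfg.abundance_years[-1]}"
    dens_full = density(filled, areas, cfg.abundance_years, label=full_label)
    dens_decades = {lab: density(filled, areas, yrs, label=lab)
                    for lab, yrs in periods.items()}
    yearly = density_by_year(filled, areas)

    raster_bank = {"dhi_cum": dhi.cumulative, "dhi_min": dhi.minimum,
                   "dhi_var": dhi.variation, **bundle.covariates}
    zonal_tables = [zonal_mean(arr, bundle.regions, hmask.values, name=name)
                    for name, arr in raster_bank.items()]
    roads = road_density(bundle.roads[["region_id", "road_length_km"]],
                         bundle.roads[["region_id", "region_area_km2"]])
    base = assemble_design(
        *zonal_tables, roads,
        names=[*raster_bank.keys(), "road_density"],
    )
    design = assemble_design(base, dens_full[["region_id", "density", "log_density"]],
                             names=["covariates", "density"])

    decade_designs = {}
    for lab in periods:
        t = assemble_design(base, dens_decades[lab][["region_id", "density", "log_density"]],
                            names=["covariates", "density"])
        rural = bundle.rural_population
        sub = rural[rural["period_label"] == lab]
        if len(sub):
            t = t.merge(sub[["region_id", "rural_population"]], on="region_id", how="left")
        decade_designs[lab] = t

    return {
        "dhi": dhi, "stable": stable, "habitat_mask": hmask, "areas": areas,
        "abundance_filled": filled, "density_full": dens_full,
        "density_decades": dens_decades, "yearly_density": yearly,
        "design": design, "decade_designs": decade_designs,
        "decade_labels": list(periods),
    }


def candidate_predictors(design: pd.DataFrame) -> list[str]:
    cands = ["dhi_cum", "dhi_min", "dhi_var", *BIO_NAMES,
             "elevation", "human_footprint", "road_density"]
    return [c for c in cands if c in design.columns]


def refine_by_vif(design: pd.DataFrame, spec: ModelSpec, limit: float = 10.0
                  ) -> tuple[ModelSpec, list[str]]:
    """Drop predictors until all VIF < limit (highest VIF first; among ties
    the last-listed predictor goes). Returns the refined spec and the drops."""
    preds = list(spec.predictors)
    dropped: list[str] = []
    while len(preds) >= 2:
        v = vif(design, preds)
        worst = float(np.nanmax(v.to_numpy()))
        if worst < limit:
            break
        offenders = [p for p in preds if v[p] == worst or (np.isinf(worst) and np.isinf(v[p]))]
        victim = offenders[-1]
        log.info("VIF refinement: dropping %s (VIF=%.3g >= %g)", victim, worst, limit)
        preds.remove(victim)
        dropped.append(victim)
    return ModelSpec(spec.response, tuple(preds)), dropped


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 bundle: ScenarioBundle | None = None) -> dict:
    """Execute every stage, write artifacts + manifest, return all products."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []

    if bundle is None:
        bundle = generate_scenario(config.scenario)
    bundle.write(out / "inputs")
    completed.append("simulate")

    products = extract_design(bundle, target_period_days=config.target_period_days)
    dhi = products["dhi"]
    rasters.write_raster(out / "dhi.tif", dhi.stack().astype(np.float32),
                         band_names=list(dhi.band_names))
    completed.append("dhi")

    rasters.write_raster(out / "stable_landcover.tif",
                         products["stable"].values.astype(np.int16),
                         nodata=products["stable"].nodata)
    rasters.write_raster(out / "habitat_mask.tif",
                         products["habitat_mask"].values.astype(np.uint8))
    _write_csv(products["areas"], out / "habitat_areas.csv")
    completed.append("habitat")

    _write_csv(products["abundance_filled"], out / "abundance_interpolated.csv")
    dens_all = pd.concat([products["density_full"], *products["density_decades"].values()],
                         ignore_index=True)
    _write_csv(dens_all, out / "densities.csv")
    _write_csv(cv_across_regions(products["yearly_density"], "year"), out / "cv_by_year.csv")
    _write_csv(cv_across_regions(products["yearly_density"], "decade"), out / "cv_by_decade.csv")
    completed.append("density")

    design = products["design"]
    _write_csv(design, out / "covariates.csv")
    completed.append("covariates")

    cands = candidate_predictors(design)
    bio_cols = [c for c in cands if c.startswith("bio")]
    report = screen_collinearity(design, cands, cluster_columns=bio_cols,
                                 threshold=config.cluster_threshold)
    report.pearson.to_csv(out / "pearson.csv", float_format=FLOAT_FMT)
    _write_csv(pd.DataFrame({"retained": report.retained}), out / "retained.csv")
    completed.append("screen")

    search = best_subsets(design, "log_density", report.retained,
                          max_size=config.max_model_size)
    _write_csv(search.to_frame(), out / "model_ranking.csv")
    top_spec = search.best.spec
    if top_spec.predictors and len(top_spec.predictors) >= 2:
        vif_table = vif(design, list(top_spec.predictors))
        vif_table.rename_axis("predictor").reset_index().to_csv(
            out / "vif.csv", index=False, float_format=FLOAT_FMT)
    refined_spec, dropped = refine_by_vif(design, top_spec, config.vif_limit)
    final_fit = fit_ols(design, refined_spec)
    (out / "parsimonious_model.json").write_text(json.dumps({
        "formula": refined_spec.formula(),
        "dropped_by_vif": dropped,
        "coefficients": {k: float(v) for k, v in final_fit.params.items()},
        "r2_adj": final_fit.r2_adj, "rmse": final_fit.rmse, "bic": final_fit.bic,
    }, indent=1))
    completed.append("fit")

    comparison = compare_decades(products["decade_designs"], refined_spec)
    decade_rows = [(lab, " + ".join(refined_spec.predictors), f.r2_adj, f.rmse)
                   for lab, f in comparison.fits.items()]
    _write_csv(pd.DataFrame(decade_rows, columns=["period_label", "predictors", "r2_adj", "rmse"]),
               out / "decade_fits.csv")
    _write_csv(comparison.tests, out / "decade_tests.csv")
    completed.append("decades")

    resid = predict_residuals(final_fit, design)
    _write_csv(resid, out / "residuals.csv")
    coords = bundle.regions.centroids.set_index("region_id").loc[
        resid["region_id"], ["lon", "lat"]].to_numpy()
    sv = residual_semivariogram(resid["residual"].to_numpy(), coords,
                                n_bins=10, metric="greatcircle")
    _write_csv(pd.DataFrame({"distance_km": sv.bin_mid, "semivariance": sv.semivariance,
                             "pairs": sv.pair_counts}), out / "semivariogram.csv")
    completed.append("diagnostics")

    artifacts = sorted(p for p in out.rglob("*.csv"))
    manifest = {
        "stages": completed,
        "seed": config.scenario.seed,
        "config": yaml.safe_load(_config_yaml(config)),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {"bundle": bundle, **products, "screen": report, "search": search,
            "final_spec": refined_spec, "final_fit": final_fit,
            "comparison": comparison, "semivariogram": sv, "manifest": manifest,
            "out_dir": out}


def _config_yaml(config: PipelineConfig) -> str:
    d = dataclasses.asdict(config)
    for k, v in d["scenario"].items():
        if isinstance(v, tuple):
            d["scenario"][k] = list(v)
    return yaml.safe_dump(d, sort_keys=False)
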