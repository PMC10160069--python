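"""End-to-end orchestration: simulate/ingest -> normalize -> krige ->
zone detection -> fluxes -> carbonate reconstruction -> nutrient
decomposition -> production and compensation.

Stages log to stderr with stage-scoped prefixes and timings; the JSON run
report is fully deterministic for a fixed config and seed (timings stay in
the log, never in the report). Every number in the report traces to a
config entry (see ``buscarb.config.CITATIONS``) or to an input artifact.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from contextlib import contextmanager
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from buscarb import carbonate, flux, geo, gridding, io, nutrients, synthetic, zones
from buscarb.config import RunConfig

logger = logging.getLogger("buscarb")

SEASONS = ("annual", "spring_summer", "autumn_winter")
GRID_VARS = ("pco2", "sst", "sss", "wind10")


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("[%s] start", name)
    try:
        yield
    except Exception as exc:
        logger.error("[%s] FAILED: %s", name, exc)
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    logger.info("[%s] done in %.1f s", name, time.perf_counter() - t0)


def _survey_config(cfg: RunConfig) -> synthetic.SurveyConfig:
    overrides = dict(cfg.get("synthetic", "survey", default={}) or {})
    overrides.setdefault("coastline", tuple(map(tuple, cfg["coastline"])))
    overrides.setdefault("seed", cfg.seed)
    if "lat_range" in overrides:
        overrides["lat_range"] = tuple(overrides["lat_range"])
    return synthetic.SurveyConfig(**overrides)


def _profile_config(cfg: RunConfig) -> synthetic.ProfileConfig:
    overrides = dict(cfg.get("synthetic", "profiles", default={}) or {})
    overrides.setdefault("seed", cfg.seed + 1)
    return synthetic.ProfileConfig(**overrides)


def stage_simulate(cfg: RunConfig, outdir: Path):
    """Generate (or, when paths are configured, ingest) the input records."""
    with _stage("simulate"):
        underway_path = cfg.get("inputs", "underway")
        bottles_path = cfg.get("inputs", "bottles")
        if underway_path:
            underway = io.read_underway(underway_path)
            coast = np.asarray(cfg["coastline"], dtype=float)
            underway["dist_coast_km"] = geo.dist_to_coast_km(
                underway["lon"].to_numpy(), underway["lat"].to_numpy(), coast
            )
        else:
            underway = synthetic.generate_underway_survey(_survey_config(cfg))
            io.write_underway(underway, outdir / "underway.tsv")
        if bottles_path:
            bottles = io.read_bottles(bottles_path)
        else:
            bottles = synthetic.generate_ctd_profiles(_profile_config(cfg))
            io.write_bottles(bottles, outdir / "bottles.tsv")
        logger.info("[simulate] %d underway records, %d bottles", len(underway), len(bottles))
    return underway, bottles


def stage_normalize(cfg: RunConfig, underway: pd.DataFrame) -> pd.DataFrame:
    """Normalize pCO2 records to the reference year via the secular trend."""
    with _stage("normalize"):
        year_ref = int(cfg["reference_year"])
        years = pd.to_datetime(underway["time"]).dt.year.to_numpy()
        underway = underway.copy()
        underway["pco2"] = gridding.normalize_pco2(underway["pco2"].to_numpy(), years, year_ref)
        underway["season"] = synthetic.season_of_month(
            pd.to_datetime(underway["time"]).dt.month.to_numpy()
        )
    return underway


def _season_frame(underway: pd.DataFrame, season: str) -> pd.DataFrame:
    if season == "annual":
        return underway
    return underway[underway["season"] == season]


def stage_grid(cfg: RunConfig, underway: pd.DataFrame, outdir: Path) -> dict:
    """Kriged grids of pCO2, SST, SSS and wind for annual + both seasons."""
    g = cfg["grid"]
    spec = gridding.GridSpec.around(
        underway["lon"].to_numpy(), underway["lat"].to_numpy(), g["resolution_deg"]
    )
    grids: dict[str, dict] = {}
    for season in SEASONS:
        records = _season_frame(underway, season)
        grids[season] = {}
        with _stage(f"grid:{season}"):
            for var in GRID_VARS:
                emp = gridding.empirical_variogram(
                    records["lon"].to_numpy(),
                    records["lat"].to_numpy(),
                    records[var].to_numpy(),
                    n_lags=g["variogram_n_lags"],
                    max_lag_deg=g["variogram_max_lag_deg"],
                    seed=cfg.seed,
                )
                model = gridding.fit_variogram(emp)
                result = gridding.krige_grid(
                    records,
                    model,
                    spec,
                    value_col=var,
                    max_dist_deg=g["max_dist_deg"],
                    min_neighbors=g["min_neighbors"],
                    max_neighbors=g["max_neighbors"],
                )
                grids[season][var] = result
                logger.info(
                    "[grid:%s] %s: %s model, range %.3f deg, %d cells predicted",
                    season, var, model.family, model.range_deg, result.n_predicted,
                )
        ds = xr.merge(
            [grids[season][v].to_dataset(name=v).drop_vars("n_obs") for v in GRID_VARS]
            + [grids[season]["pco2"].to_dataset(name="pco2")[["n_obs"]]]
        )
        io.write_grid(ds, outdir / f"grid_{season}.nc")
    return grids


def stage_zone(cfg: RunConfig, underway: pd.DataFrame, outdir: Path) -> dict:
    """Offshore boundary and area per subsystem from cross-shelf s.d."""
    out = {}
    z = cfg["zone"]
    with _stage("zone"):
        for region, bounds in cfg["regions"].items():
            sel = underway[
                (underway["lat"] >= bounds["lat_min"]) & (underway["lat"] < bounds["lat_max"])
            ]
            profile = zones.cross_shelf_profile(sel, bin_km=z["bin_km"])
            res = zones.detect_offshore_boundary(profile, sd_threshold=z["sd_threshold_uatm"])
            zone = zones.UpwellingZone(
                region, bounds["lat_min"], bounds["lat_max"], res.boundary_km,
                z["sd_threshold_uatm"],
            )
            profile.to_csv(outdir / f"profile_{region}.csv", index=False)
            out[region] = {"zone": zone, "converged": res.converged, "profile": profile}
            logger.info(
                "[zone] %s boundary %.0f km, area %.0f km2 (converged=%s)",
                region, zone.boundary_km, zone.area_km2, res.converged,
            )
    with open(outdir / "zones.json", "w") as fh:
        json.dump(
            {r: dict(v["zone"].to_dict(), converged=v["converged"]) for r, v in out.items()},
            fh, indent=2, sort_keys=True,
        )
    return out


def _zone_cell_stats(cfg: RunConfig, grids_season: dict, zone: zones.UpwellingZone):
    """Zone-mean kriged inputs + Eq.-1 uncertainty of the zone-mean pCO2."""
    result = grids_season["pco2"]
    lon2d, lat2d = np.meshgrid(result.lon, result.lat)
    coast = np.asarray(cfg["coastline"], dtype=float)
    dist = geo.dist_to_coast_km(lon2d.ravel(), lat2d.ravel(), coast).reshape(lon2d.shape)
    mask = zone.contains(lat2d, dist) & np.isfinite(result.prediction)
    if not mask.any():
        raise ValueError(f"no predicted cells inside zone {zone.name}")
    means = {}
    for var, res in grids_season.items():
        vals = res.prediction[mask]
        means[var] = float(np.nanmean(vals))
    sigma = result.sigma[mask]
    n = int(mask.sum())
    n_eff = gridding.effective_n(
        lon2d[mask], lat2d[mask], result.model.autocorrelation_range_deg()
    )
    fallback = n_eff < 0.05 * n
    se = gridding.aggregate_se(sigma, n if fallback else n_eff)
    return means, {"n_cells": n, "n_eff": n_eff, "se_uatm": se, "neff_fallback": fallback}


def stage_flux(cfg: RunConfig, grids: dict, zone_info: dict, outdir: Path) -> dict:
    """Region-average fluxes per subsystem, season, k-parameterization."""
    out = {}
    pco2_at = float(cfg["pco2_atm_uatm"])
    rows = []
    with _stage("flux"):
        for region, info in zone_info.items():
            zone = info["zone"]
            out[region] = {}
            for season in SEASONS:
                means, unc = _zone_cell_stats(cfg, grids[season], zone)
                out[region][season] = {"inputs": dict(means, pco2_at_uatm=pco2_at, **unc)}
                for param in cfg["flux"]["k_params"]:
                    est = flux.flux_from_region_means(
                        means["pco2"], pco2_at, means["sst"], means["sss"], means["wind10"],
                        zone, param=param, season=season, pco2_se=unc["se_uatm"],
                    )
                    out[region][season][param] = est
                    rows.append(
                        {
                            "subsystem": region,
                            "season": season,
                            "param": param,
                            "mean_flux_molm2yr": est.mean_flux_molm2yr,
                            "total_tgc_yr": est.total_tgc_yr,
                            "se_total_tgc_yr": est.se_total_tgc_yr,
                        }
                    )
                logger.info(
                    "[flux] %s %s: %.2f Tg C/yr (%s)",
                    region, season,
                    out[region][season][cfg["flux"]["baseline_param"]].total_tgc_yr,
                    cfg["flux"]["baseline_param"],
                )
            annual = [out[region]["annual"][p] for p in cfg["flux"]["k_params"]]
            lo, hi, spread = flux.parameterization_spread(annual)
            out[region]["spread"] = {"min_abs": lo, "max_abs": hi, "percent": spread}
    pd.DataFrame(rows).to_csv(outdir / "flux_summary.csv", index=False)
    return out


def stage_carbonate(cfg: RunConfig, grids: dict, bottles: pd.DataFrame, zone_info: dict) -> dict:
    """TA-S relation, source-water validation, non-thermal pCO2 fields."""
    out = {}
    with _stage("carbonate"):
        surface = bottles[bottles["depth_m"] <= cfg["carbonate"]["surface_bottle_max_depth_m"]]
        reg = carbonate.fit_ta_salinity(
            surface["sal"].to_numpy(), surface["ta_umolkg"].to_numpy()
        )
        out["ta_salinity"] = {
            "slope": reg.slope, "intercept": reg.intercept, "r2": reg.r2, "n": reg.n,
        }
        for region, sw_cfg in cfg["source_water"].items():
            sw = carbonate.SourceWater(**sw_cfg)
            zone = zone_info[region]["zone"]
            annual = grids["annual"]
            means, _ = _zone_cell_stats(cfg, annual, zone)
            src, src_se = carbonate.source_water_pco2(sw)
            post, post_se = carbonate.post_consumption_pco2(
                sw, means["sst"], means["sss"], ta_per_no3=cfg["carbonate"]["ta_per_no3"]
            )
            lon2d, lat2d = np.meshgrid(annual["pco2"].lon, annual["pco2"].lat)
            coast = np.asarray(cfg["coastline"], dtype=float)
            dist = geo.dist_to_coast_km(lon2d.ravel(), lat2d.ravel(), coast).reshape(lon2d.shape)
            mask = zone.contains(lat2d, dist)
            nonthermal, n_failed = carbonate.nonthermal_pco2_grid(
                np.where(mask, annual["pco2"].prediction, np.nan),
                annual["sst"].prediction,
                annual["sss"].prediction,
                reg, sw.temp, sw.sal,
            )
            out[region] = {
                "source_water_pco2_uatm": [src, src_se],
                "post_consumption_pco2_uatm": [post, post_se],
                "nonthermal_mean_uatm": float(np.nanmean(nonthermal)),
                "measured_mean_uatm": means["pco2"],
                "n_nonthermal_cells": int(np.isfinite(nonthermal).sum()),
                "n_solver_failures": n_failed,
                "inputs": {"source_water": sw_cfg, "sst": means["sst"], "sss": means["sss"]},
            }
            logger.info(
                "[carbonate] %s: source %.0f, post-consumption %.0f, nonthermal mean %.0f uatm",
                region, src, post, out[region]["nonthermal_mean_uatm"],
            )
    return out


def stage_nutrients(cfg: RunConfig, bottles: pd.DataFrame) -> dict:
    """AOU, water-mass labels, preformed/regenerated split, recovery stats."""
    with _stage("nutrients"):
        aou = nutrients.compute_aou(
            bottles["temp_c"].to_numpy(), bottles["sal"].to_numpy(), bottles["o2_umolkg"].to_numpy()
        )
        labels = nutrients.classify_water_mass(
            bottles["temp_c"].to_numpy(), bottles["sal"].to_numpy()
        )
        dec = nutrients.decompose_nutrients(
            bottles["no3_umolkg"].to_numpy(), bottles["po4_umolkg"].to_numpy(), aou
        )
        frac, frac_se = nutrients.preformed_fraction(dec.n_pref, bottles["no3_umolkg"].to_numpy())
        n_pref_mean = float(np.mean(dec.n_pref))
        n_pref_se = float(np.std(dec.n_pref, ddof=1) / np.sqrt(dec.n_pref.size))
        counts = pd.Series(labels).value_counts().to_dict()
        logger.info(
            "[nutrients] n_pref %.2f +- %.2f umol/kg, preformed fraction %.1f%%",
            n_pref_mean, n_pref_se, 100 * frac,
        )
        return {
            "n_bottles": int(len(bottles)),
            "mass_counts": {k: int(v) for k, v in counts.items()},
            "n_pref_umol_kg": [n_pref_mean, n_pref_se],
            "preformed_fraction": [frac, frac_se],
            "n_negative_preformed": dec.n_negative,
        }


def stage_production(cfg: RunConfig) -> dict:
    """Worked-example production arithmetic from the configured inputs."""
    with _stage("production"):
        p = cfg["production"]
        out = {}
        total_lo = total_hi = 0.0
        for region in cfg["regions"]:
            n_pref, n_pref_se = p["n_pref_umol_kg"][region]
            est = nutrients.new_production_from_npref(
                n_pref, p["upwelling_sv"][region], n_pref_se,
                subsystem=region, kg_per_sv=p["kg_per_sv"],
                redfield_c_n=p["redfield_c_n"],
            )
            frac, frac_se = p["preformed_fraction"][region]
            np_lo, np_hi = p["published_np_tgc_yr"][region]
            est_lo = nutrients.new_production_from_fraction(np_lo, frac, frac_se, region)
            est_hi = nutrients.new_production_from_fraction(np_hi, frac, frac_se, region)
            out[region] = {
                "bottom_up": asdict(est),
                "fraction_low": asdict(est_lo),
                "fraction_high": asdict(est_hi),
            }
            total_lo += est.rate_tgc_yr
            total_hi += est_hi.rate_tgc_yr
        so = p["southern_ocean_outgassing_tgc_yr"]
        out["total_np_pref_tgc_yr"] = [total_lo, total_hi]
        out["compensation_percent"] = [
            nutrients.compensation_percent(total_lo, so),
            nutrients.compensation_percent(total_hi, so),
        ]
        logger.info(
            "[production] total %.1f-%.1f Tg C/yr, compensation %.0f-%.0f%%",
            total_lo, total_hi, *out["compensation_percent"],
        )
    return out


def _flux_report(flux_out: dict) -> dict:
    rep = {}
    for region, seasons in flux_out.items():
        rep[region] = {}
        for season, block in seasons.items():
            if season == "spread":
                rep[region]["spread"] = block
                continue
            rep[region][season] = {
                k: (asdict(v) if isinstance(v, flux.FluxEstimate) else v)
                for k, v in block.items()
            }
    return rep


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    underway, bottles = stage_simulate(cfg, outdir)
    underway = stage_normalize(cfg, underway)
    grids = stage_grid(cfg, underway, outdir)
    zone_info = stage_zone(cfg, underway, outdir)
    flux_out = stage_flux(cfg, grids, zone_info, outdir)
    carb_out = stage_carbonate(cfg, grids, bottles, zone_info)
    nut_out = stage_nutrients(cfg, bottles)
    prod_out = stage_production(cfg)

    grid_report = {
        season: {
            var: {
                "family": res.model.family,
                "range_deg": res.model.range_deg,
                "nugget": res.model.nugget,
                "partial_sill": res.model.partial_sill,
                "n_predicted": res.n_predicted,
                "n_negative_var": res.n_negative_var,
            }
            for var, res in per_var.items()
        }
        for season, per_var in grids.items()
    }
    report = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "config": cfg.values,
        "stages": {
            "simulate": {
                "n_underway": int(len(underway)),
                "n_bottles": int(len(bottles)),
                "n_clipped_negative": int(bottles.attrs.get("n_clipped_negative", 0)),
            },
            "grid": grid_report,
            "zone": {
                r: dict(v["zone"].to_dict(), converged=v["converged"])
                for r, v in zone_info.items()
            },
            "flux": _flux_report(flux_out),
            "carbonate": carb_out,
            "nutrients": nut_out,
            "production": prod_out,
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
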