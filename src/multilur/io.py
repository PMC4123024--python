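"""File formats, configuration and the one-command pipeline.

All tables are UTF-8 comma-separated CSV with a header row and '.' decimals;
coordinates and buffer radii are meters throughout. Rasters are plain-text
ESRI ASCII grids (6-line header: ncols, nrows, xllcorner, yllcorner,
cellsize, nodata_value). Models and reports are JSON at full decimal
precision, so write -> read round-trips are exact. Every pipeline run writes
a manifest with SHA-256 hashes of its outputs; a re-run with the same
configuration and seed reproduces the hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import builder, evaluation, synthetic, temporal, transfer
from .builder import LURModel, StepwiseOptions
from .campaign import simulate_campaign
from .dataset import LURDataset
from .errors import ConfigurationError, DataError
from .types import (
    LandUseRaster,
    PredictorTable,
    ReferenceSeries,
    ROAD_COLUMNS,
    SITE_COLUMNS,
    TrueModel,
    VariableDef,
    validate_site_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# tables


def read_site_table(path) -> pd.DataFrame:
    sites = pd.read_csv(path)
    try:
        return validate_site_table(sites)
    except DataError as e:
        raise DataError(f"{path}: {e}") from None


def write_site_table(sites: pd.DataFrame, path) -> None:
    sites[SITE_COLUMNS].to_csv(path, index=False)


def read_roads(path) -> pd.DataFrame:
    roads = pd.read_csv(path)
    missing = [c for c in ROAD_COLUMNS if c not in roads.columns]
    if missing:
        raise DataError(f"{path}: road table missing columns {missing}")
    return roads


def write_roads(roads: pd.DataFrame, path) -> None:
    cols = ROAD_COLUMNS + (["area_code"] if "area_code" in roads.columns else [])
    roads[cols].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    m = pd.read_csv(path)
    missing = [c for c in ("site_id", "period", "value") if c not in m.columns]
    if missing:
        raise DataError(f"{path}: measurements missing columns {missing}")
    return m


def write_measurements(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False)


def read_reference(path) -> dict[str, ReferenceSeries]:
    ref = pd.read_csv(path)
    missing = [c for c in ("area_code", "period", "value") if c not in ref.columns]
    if missing:
        raise DataError(f"{path}: reference table missing columns {missing}")
    out = {}
    for area, grp in ref.groupby("area_code", sort=True):
        out[area] = ReferenceSeries(area_code=area,
                                    values=dict(zip(grp["period"], grp["value"])))
    return out


def write_reference(references: dict[str, ReferenceSeries], path) -> None:
    rows = [
        (area, period, value)
        for area, series in sorted(references.items())
        for period, value in series.values.items()
    ]
    pd.DataFrame(rows, columns=["area_code", "period", "value"]).to_csv(path, index=False)


def read_annual(path) -> pd.Series:
    a = pd.read_csv(path)
    missing = [c for c in ("site_id", "annual_value") if c not in a.columns]
    if missing:
        raise DataError(f"{path}: annual table missing columns {missing}")
    return pd.Series(a["annual_value"].to_numpy(),
                     index=pd.Index(a["site_id"], name="site_id"))


def write_annual(annual: pd.Series, path) -> None:
    pd.DataFrame({"site_id": annual.index, "annual_value": annual.to_numpy()}).to_csv(
        path, index=False
    )


def read_predictors(path, variables: list[VariableDef]) -> PredictorTable:
    data = pd.read_csv(path).set_index("site_id")
    return PredictorTable(data=data, variables=variables)


def write_predictors(table: PredictorTable, path) -> None:
    table.data[table.names].to_csv(path, index=True)


# ---------------------------------------------------------------------------
# rasters (plain-text ESRI ASCII grid)


def read_raster(path) -> LandUseRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        grid = np.loadtxt(fh, dtype=int)
    return LandUseRaster(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        grid=grid.reshape(int(header["nrows"]), int(header["ncols"])),
        nodata=int(header["nodata_value"]),
    )


def write_raster(raster: LandUseRaster, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x0!r}\n")
        fh.write(f"yllcorner {raster.y0!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"nodata_value {raster.nodata}\n")
        np.savetxt(fh, raster.grid, fmt="%d")


# ---------------------------------------------------------------------------
# JSON artifacts


def read_variables(path) -> list[VariableDef]:
    with open(path) as fh:
        return [VariableDef.from_dict(d) for d in json.load(fh)]


def write_variables(variables: list[VariableDef], path) -> None:
    with open(path, "w") as fh:
        json.dump([v.to_dict() for v in variables], fh, indent=1)


def read_model(path) -> LURModel:
    with open(path) as fh:
        return LURModel.from_dict(json.load(fh))


def write_model(model: LURModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def read_truth(path) -> TrueModel:
    with open(path) as fh:
        return TrueModel.from_dict(json.load(fh))


def write_truth(true_model: TrueModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(true_model.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# pipeline


_PRESETS = {
    "default": synthetic.StudyConfig,
    "no2_like": synthetic.no2_like_config,
    "pm25_like": synthetic.pm25_like_config,
}


def study_config_from_dict(block: dict, seed: int | None = None) -> synthetic.StudyConfig:
    block = dict(block)
    preset = block.pop("preset", "default")
    if preset not in _PRESETS:
        raise ConfigurationError(f"unknown simulate preset {preset!r}")
    if seed is not None:
        block["seed"] = seed
    if "site_type_mix" in block:
        block["site_type_mix"] = tuple(block["site_type_mix"])
    return _PRESETS[preset](**block)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study, conc, true_model, out: Path) -> list[Path]:
    """Write all simulated artifacts (sites/roads/rasters/samples/truth)."""
    paths = []

    def _w(name, fn):
        p = out / name
        fn(p)
        paths.append(p)

    _w("sites.csv", lambda p: write_site_table(study.sites, p))
    _w("roads.csv", lambda p: write_roads(study.roads, p))
    _w("measurements.csv", lambda p: write_measurements(conc.seasonal, p))
    _w("reference.csv", lambda p: write_reference(conc.references, p))
    _w("truth.json", lambda p: write_truth(true_model, p))
    for area, raster in study.rasters.items():
        _w(f"raster_{area}.txt", lambda p, r=raster: write_raster(r, p))
    return paths


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run the full pipeline and write every stage's outputs plus a manifest.

    ``config`` holds either a ``simulate`` block (synthetic campaign) or
    ``inputs`` paths (sites/roads/rasters/measurements/reference), plus
    optional ``variables`` (path or inline list of dicts), ``options`` and an
    ``evaluation`` plan. Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    counts: dict = {}

    if ("simulate" in config) == ("inputs" in config):
        raise ConfigurationError("config must contain exactly one of 'simulate' or 'inputs'")

    varspec = config.get("variables")
    if isinstance(varspec, str):
        variables = read_variables(varspec)
    elif varspec is not None:
        variables = [VariableDef.from_dict(d) for d in varspec]
    else:
        variables = synthetic.default_variables()

    opts = StepwiseOptions(**config.get("options", {}))
    plan = config.get("evaluation", {})
    used_seed = seed if seed is not None else config.get("seed")

    if "simulate" in config:
        if used_seed is None:
            raise ConfigurationError("a seed is required for simulation")
        sim_config = study_config_from_dict(config["simulate"], seed=used_seed)
        truth_kind = config.get("true_model", "no2")
        tm = (TrueModel.from_dict(truth_kind) if isinstance(truth_kind, dict)
              else synthetic.default_true_model(truth_kind))
        camp = simulate_campaign(sim_config, variables, tm,
                                 n_decoys=int(config.get("n_decoys", 0)))
        written += write_study(camp.study, camp.concentrations, camp.true_model, out)
        dataset, table = camp.dataset, camp.table
        annual = camp.annual
    else:
        paths = config["inputs"]
        sites = read_site_table(paths["sites"])
        roads = read_roads(paths["roads"])
        rasters = None
        if "rasters" in paths:
            rasters = {area: read_raster(p) for area, p in paths["rasters"].items()}
        measurements = read_measurements(paths["measurements"])
        references = read_reference(paths["reference"])
        from . import buffers

        gis_vars = [v for v in variables if v.category != "regional_background"]
        table = buffers.extract_predictors(sites, roads, gis_vars, rasters)
        annual = temporal.adjust_campaign(measurements, references, sites)
        dataset = LURDataset(sites=sites, predictors=table, annual=annual,
                             background=synthetic.regional_background_def())

    p = out / "predictors.csv"
    write_predictors(table, p)
    written.append(p)
    p = out / "annual.csv"
    write_annual(annual, p)
    written.append(p)

    ptable, y = dataset.design()
    model = builder.supervised_stepwise(ptable, y, opts,
                                        provenance={"seed": used_seed, "excluded_areas": []})
    p = out / "model.json"
    write_model(model, p)
    written.append(p)
    counts["sites"] = len(dataset.sites)
    counts["model_terms"] = len(model.terms)

    reports = {}
    intra = evaluation.model_intra_r2(model, dataset)
    reports["model_intra"] = intra.to_dict()

    frac = plan.get("holdout_fraction")
    if frac:
        split = evaluation.stratified_holdout_split(dataset.sites, frac, seed=used_seed or 0)
        hv = evaluation.holdout_validate(dataset, split, opts)
        reports["holdout"] = hv.to_dict()
        counts["holdout_truncated_cells"] = hv.truncated_cells
    if plan.get("loaocv"):
        cv = evaluation.loaocv(dataset, opts)
        reports["loaocv"] = cv.to_dict()
        counts["loaocv_refits"] = len(cv.models)
    p = out / "evaluation.json"
    with open(p, "w") as fh:
        json.dump(reports, fh, indent=1)
    written.append(p)

    if plan.get("transfer"):
        tr = transfer.transfer_excluding_each_area(dataset, opts)
        p = out / "transfer_report.json"
        with open(p, "w") as fh:
            json.dump(tr.to_dict(), fh, indent=1)
        written.append(p)
        p = out / "transfer_report.csv"
        tr.per_area.to_csv(p, index=False)
        written.append(p)
        counts["transfer_refits"] = len(tr.models)

    for region in plan.get("regions", []):
        sub = dataset.region_subset(region)
        rtable, ry = sub.design()
        rmodel = builder.supervised_stepwise(
            rtable, ry, opts, provenance={"seed": used_seed, "region": region})
        p = out / f"model_{region}.json"
        write_model(rmodel, p)
        written.append(p)

    manifest = {
        "seed": used_seed,
        "counts": counts,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %d files in %s", len(written) + 1, out)
    return manifest
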