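"""Synthetic multi-area monitoring campaigns with known ground truth.

Generates "worlds" with the statistical and geographic structure that
multi-area land-use-regression modelling assumes:

* 2+ study areas allocated to four European-style regions, each area a
  radial "city": a few high-intensity arterial roads through the center and
  many low-intensity local roads, with lognormal traffic intensities;
* 20+ monitoring sites per area split across street, urban-background and
  regional-background types, with the type geography enforced (street sites
  within a configured distance of a qualifying high-intensity road,
  regional-background sites far from any major road);
* a land-use raster per area (residential core, natural/green periphery);
* annual concentrations from a known linear model: area background +
  buffer-variable contributions + Gaussian site noise, and three seasonal
  2-week samples per site sharing the area reference site's sinusoidal
  seasonal deviation plus independent sampling noise.

Between-area versus within-area variance structure is configurable:
``between_within_sd_ratio`` calibrates the spread of area background effects
against the realized within-area signal (PM2.5-like: between-dominated;
NO2-like: within-dominated), and ``within_r2_target`` calibrates the site
noise against the local signal.

All randomness flows from ``StudyConfig.seed`` through named substreams, so
identical configs give byte-identical studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import buffers
from .errors import ConfigurationError, DataError
from .types import (
    LandUseRaster,
    PredictorTable,
    ReferenceSeries,
    TrueModel,
    VariableDef,
)

REGIONS = ("north", "west", "central", "south")

#: land-use raster class codes
CLASS_OTHER, CLASS_RESIDENTIAL, CLASS_NATURAL_GREEN = 0, 1, 2

#: reference-series period labels: 12 synthetic "months"
REF_PERIODS = [f"m{k:02d}" for k in range(12)]

#: the three 2-week campaign samples: cold, intermediate and warm season
SAMPLE_PERIODS = {"cold": "m00", "intermediate": "m03", "warm": "m06"}

_STREAMS = {"areas": 0, "roads": 1, "sites": 2, "raster": 3, "concentrations": 4, "tabular": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class StudyConfig:
    """Configuration of a synthetic multi-area monitoring campaign.

    The defaults describe a European-scale campaign: 20 areas of 20 sites in
    four regions, lognormal between-area backgrounds, sinusoidal seasonal
    structure and independent site noise.
    """

    n_areas: int = 20
    sites_per_area: int = 20
    site_type_mix: tuple[float, float, float] = (0.45, 0.35, 0.20)
    region_assignment: dict[str, str] | None = None
    background_mean: float = 14.0  # µg/m³
    background_sd: float = 4.0  # µg/m³ between-area SD (when ratio not set)
    background_distribution: str = "lognormal"  # or "normal"
    between_within_sd_ratio: float | None = None
    noise_sd: float = 2.0  # µg/m³ site noise (ignored when within_r2_target set)
    within_r2_target: float | None = None
    seasonal_amplitude: float = 4.0  # µg/m³ typical area seasonal swing
    season_noise_sd: float = 1.0  # µg/m³ per-sample noise
    street_max_road_distance: float = 50.0  # m
    street_min_intensity: float = 10000.0  # vehicles/day
    background_min_major_distance: float = 1000.0  # m
    seed: int = 0
    # city geometry
    city_radius: float = 2500.0
    arterial_length: float = 4000.0
    n_arterials: int = 6
    n_local_roads: int = 60
    raster_cell_size: float = 200.0
    raster_half_extent: float = 13000.0
    area_spacing: float = 30000.0

    def validate(self) -> "StudyConfig":
        if self.n_areas < 2:
            raise ConfigurationError("n_areas must be >= 2")
        if self.sites_per_area < 6:
            raise ConfigurationError("sites_per_area must be >= 6")
        mix = np.asarray(self.site_type_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or (mix > 1).any():
            raise ConfigurationError("site_type_mix must be 3 fractions in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError("site_type_mix must sum to 1")
        if self.background_distribution not in ("lognormal", "normal"):
            raise ConfigurationError("background_distribution must be lognormal or normal")
        if self.within_r2_target is not None and not 0 < self.within_r2_target < 1:
            raise ConfigurationError("within_r2_target must be in (0, 1)")
        return self

    def area_codes(self) -> list[str]:
        return [f"A{i:02d}" for i in range(self.n_areas)]

    def regions(self) -> dict[str, str]:
        if self.region_assignment is not None:
            return dict(self.region_assignment)
        return {a: REGIONS[i % 4] for i, a in enumerate(self.area_codes())}


@dataclass
class SyntheticStudy:
    """A fully generated world: areas, sites, roads, rasters, backgrounds."""

    config: StudyConfig
    sites: pd.DataFrame
    roads: pd.DataFrame
    rasters: dict[str, LandUseRaster]
    area_backgrounds: pd.Series  # area_code -> latent background level (µg/m³)
    area_background_u: pd.Series  # area_code -> standard-normal draw (for calibration)

    @property
    def area_codes(self) -> list[str]:
        return list(self.config.area_codes())


@dataclass
class ConcentrationData:
    """Generated observations: annual truth, seasonal samples, references."""

    annual_true: pd.Series  # site_id -> annual value (deterministic + site noise)
    deterministic: pd.Series  # site_id -> noise-free annual value
    seasonal: pd.DataFrame  # columns site_id, period, value
    references: dict[str, ReferenceSeries]
    area_effects: pd.Series  # realized area background level per area
    noise_sd: float  # site-noise SD actually used (after calibration)


# ---------------------------------------------------------------------------
# study generation


def _area_center(config: StudyConfig, i: int) -> tuple[float, float]:
    col, row = i % 5, i // 5
    half = config.area_spacing / 2.0
    return col * config.area_spacing + half, row * config.area_spacing + half


def _type_counts(config: StudyConfig) -> tuple[int, int, int]:
    n = config.sites_per_area
    f_st, f_ub, f_rb = config.site_type_mix
    # every area needs at least one regional background site
    n_rb = max(1, int(round(f_rb * n)))
    n_st = int(round(f_st * n))
    n_ub = n - n_st - n_rb
    if n_ub < 0:
        n_st += n_ub
        n_ub = 0
    if n_st < 0:
        raise ConfigurationError("site_type_mix incompatible with sites_per_area")
    return n_st, n_ub, n_rb


def _generate_area_roads(config: StudyConfig, area: str, cx: float, cy: float,
                         rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for j in range(config.n_arterials):
        angle = 2 * math.pi * j / config.n_arterials + rng.uniform(-0.1, 0.1)
        ex = cx + config.arterial_length * math.cos(angle)
        ey = cy + config.arterial_length * math.sin(angle)
        # arterials are guaranteed to qualify as high-intensity streets
        intensity = max(20000.0 * math.exp(rng.normal(0.0, 0.4)),
                        1.2 * config.street_min_intensity)
        rows.append((f"{area}_R{k:03d}", cx, cy, ex, ey, intensity, True, area))
        k += 1
    for _ in range(config.n_local_roads):
        r = config.city_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        mx, my = cx + r * math.cos(th), cy + r * math.sin(th)
        d = rng.uniform(0, 2 * math.pi)
        half = rng.uniform(100.0, 400.0)
        intensity = 800.0 * math.exp(rng.normal(0.0, 0.8))
        rows.append((
            f"{area}_R{k:03d}",
            mx - half * math.cos(d), my - half * math.sin(d),
            mx + half * math.cos(d), my + half * math.sin(d),
            intensity, False, area,
        ))
        k += 1
    return pd.DataFrame(
        rows, columns=["segment_id", "x1", "y1", "x2", "y2", "intensity", "is_major", "area_code"]
    )


def _min_major_distance(x: float, y: float, roads: pd.DataFrame) -> float:
    majors = roads.loc[roads["is_major"]]
    if len(majors) == 0:
        return math.inf
    d = buffers.point_segment_distance(
        x, y,
        majors["x1"].to_numpy(), majors["y1"].to_numpy(),
        majors["x2"].to_numpy(), majors["y2"].to_numpy(),
    )
    return float(np.min(np.atleast_1d(d)))


def _generate_area_sites(config: StudyConfig, area: str, region: str, cx: float, cy: float,
                         roads: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n_st, n_ub, n_rb = _type_counts(config)
    arterials = roads.loc[roads["is_major"] & (roads["intensity"] >= config.street_min_intensity)]
    if n_st > 0 and len(arterials) == 0:
        raise DataError(f"area {area}: no road qualifies for street-site placement")
    rows = []
    idx = 0

    for _ in range(n_st):
        seg = arterials.iloc[rng.integers(len(arterials))]
        t = rng.uniform(0.05, 0.95)
        bx = seg["x1"] + t * (seg["x2"] - seg["x1"])
        by = seg["y1"] + t * (seg["y2"] - seg["y1"])
        length = math.hypot(seg["x2"] - seg["x1"], seg["y2"] - seg["y1"])
        nx = -(seg["y2"] - seg["y1"]) / length
        ny = (seg["x2"] - seg["x1"]) / length
        offset = rng.uniform(5.0, 0.9 * config.street_max_road_distance) * rng.choice([-1, 1])
        rows.append((f"{area}_S{idx:03d}", area, region, "street", bx + offset * nx, by + offset * ny))
        idx += 1

    for _ in range(n_ub):
        x = y = None
        for _try in range(200):
            r = config.city_radius * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            x, y = cx + r * math.cos(th), cy + r * math.sin(th)
            if _min_major_distance(x, y, roads) >= 1.5 * config.street_max_road_distance:
                break
        rows.append((f"{area}_S{idx:03d}", area, region, "urban_background", x, y))
        idx += 1

    r_lo = max(config.arterial_length + config.background_min_major_distance + 200.0,
               config.city_radius + config.background_min_major_distance + 200.0)
    r_hi = max(r_lo + 500.0, config.raster_half_extent - 5000.0)
    for _ in range(n_rb):
        for _try in range(1000):
            r = rng.uniform(r_lo, r_hi)
            th = rng.uniform(0, 2 * math.pi)
            x, y = cx + r * math.cos(th), cy + r * math.sin(th)
            if _min_major_distance(x, y, roads) >= config.background_min_major_distance:
                break
        else:
            raise DataError(f"area {area}: could not place regional background site")
        rows.append((f"{area}_S{idx:03d}", area, region, "regional_background", x, y))
        idx += 1

    return pd.DataFrame(rows, columns=["site_id", "area_code", "region", "site_type", "x", "y"])


def _generate_area_raster(config: StudyConfig, cx: float, cy: float,
                          rng: np.random.Generator) -> LandUseRaster:
    cs = config.raster_cell_size
    half = config.raster_half_extent
    n = int(round(2 * half / cs))
    x0, y0 = cx - half, cy - half
    cols = x0 + (np.arange(n) + 0.5) * cs
    rows = y0 + (n - 1 - np.arange(n) + 0.5) * cs
    xs, ys = np.meshgrid(cols, rows)
    d = np.hypot(xs - cx, ys - cy)
    p_res = 0.8 * np.exp(-((d / 2000.0) ** 2))
    # green is a saturating radial trend (low urban core, uniformly green
    # countryside) plus patchy urban/peri-urban parks and forests, so green
    # varies within the city without tracking road density one-for-one
    p_green_raw = 0.15 + 0.6 * (1.0 - np.exp(-((d / 3000.0) ** 2)))
    for _ in range(10):
        r = 5000.0 * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        px, py = cx + r * math.cos(th), cy + r * math.sin(th)
        width = rng.uniform(800.0, 2500.0)
        p_green_raw = p_green_raw + 0.7 * np.exp(
            -(((xs - px) ** 2 + (ys - py) ** 2) / width ** 2)
        )
    p_green = (1.0 - p_res) * np.clip(p_green_raw, 0.0, 0.95)
    u = rng.uniform(size=(n, n))
    grid = np.full((n, n), CLASS_OTHER, dtype=int)
    grid[u < p_res + p_green] = CLASS_NATURAL_GREEN
    grid[u < p_res] = CLASS_RESIDENTIAL
    return LandUseRaster(x0=x0, y0=y0, cell_size=cs, grid=grid)


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full synthetic world for a monitoring campaign.

    Deterministic for a fixed (config, seed): identical calls produce
    byte-identical site, road and raster artifacts.
    """
    config.validate()
    rng_areas = _rng(config.seed, "areas")
    rng_roads = _rng(config.seed, "roads")
    rng_sites = _rng(config.seed, "sites")
    rng_raster = _rng(config.seed, "raster")

    codes = config.area_codes()
    regions = config.regions()

    # latent area backgrounds (used directly when no variance-ratio calibration)
    u = rng_areas.standard_normal(config.n_areas)
    m, s = config.background_mean, config.background_sd
    if config.background_distribution == "lognormal":
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        bg = np.exp(mu + math.sqrt(sigma2) * u)
    else:
        bg = m + s * u

    roads_parts, site_parts, rasters = [], [], {}
    for i, area in enumerate(codes):
        cx, cy = _area_center(config, i)
        roads = _generate_area_roads(config, area, cx, cy, rng_roads)
        roads_parts.append(roads)
        site_parts.append(_generate_area_sites(config, area, regions[area], cx, cy, roads, rng_sites))
        rasters[area] = _generate_area_raster(config, cx, cy, rng_raster)

    return SyntheticStudy(
        config=config,
        sites=pd.concat(site_parts, ignore_index=True),
        roads=pd.concat(roads_parts, ignore_index=True),
        rasters=rasters,
        area_backgrounds=pd.Series(bg, index=pd.Index(codes, name="area_code")),
        area_background_u=pd.Series(u, index=pd.Index(codes, name="area_code")),
    )


# ---------------------------------------------------------------------------
# predictor tables


def default_variables() -> list[VariableDef]:
    """The default candidate GIS variable set (buffer-structured, Table-style)."""
    return [
        VariableDef("traffic_load_50", "traffic_load", 50.0, None, "positive"),
        VariableDef("traffic_load_50_1000", "traffic_load", 1000.0, 50.0, "positive"),
        VariableDef("road_length_100", "road_length", 100.0, None, "positive"),
        VariableDef("road_length_1000", "road_length", 1000.0, None, "positive"),
        VariableDef("natural_green_5000", "land_use_area", 5000.0, None, "negative",
                    classes=(CLASS_NATURAL_GREEN,)),
        VariableDef("nearest_road_intensity", "nearest_road_intensity", None, None, "positive"),
    ]


def regional_background_def() -> VariableDef:
    """The forced regional-background predictor (area mean of background sites)."""
    return VariableDef("regional_background", "regional_background", None, None,
                       "positive", forced=True)


def decoy_variables(n: int) -> list[VariableDef]:
    """n inert tabular candidate variables (no true effect), for recovery tests."""
    return [
        VariableDef(f"decoy_{i:02d}", "other_local", None, None,
                    "positive" if i % 2 == 0 else "negative")
        for i in range(n)
    ]


def generate_predictor_table(
    study: SyntheticStudy,
    variables: list[VariableDef],
    mode: str = "geometry",
    marginals: dict[str, tuple[float, float]] | None = None,
    rank_corr: np.ndarray | None = None,
) -> PredictorTable:
    """Build the site-by-variable predictor table.

    ``geometry`` mode extracts every variable from the study's roads and
    rasters (regional_background-category variables are filled with the
    latent true area background). ``tabular`` mode draws lognormal marginals
    with a target Spearman rank-correlation matrix through a Gaussian copula;
    ``marginals`` maps variable name to (median, sigma-of-log).
    """
    if mode == "geometry":
        return buffers.extract_predictors(
            study.sites, study.roads, variables, study.rasters,
            area_backgrounds=study.area_backgrounds,
        )
    if mode != "tabular":
        raise ConfigurationError(f"unknown mode {mode!r}")

    rng = _rng(study.config.seed, "tabular")
    names = [v.name for v in variables]
    k = len(names)
    if rank_corr is None:
        pearson = np.eye(k)
    else:
        rank_corr = np.asarray(rank_corr, dtype=float)
        if rank_corr.shape != (k, k):
            raise ConfigurationError("rank_corr shape must match number of variables")
        # Gaussian-copula Pearson correlation reproducing the Spearman target
        pearson = 2.0 * np.sin(np.pi * rank_corr / 6.0)
        np.fill_diagonal(pearson, 1.0)
    try:
        chol = np.linalg.cholesky(pearson)
    except np.linalg.LinAlgError as e:
        raise ConfigurationError("correlation target is not positive definite") from e
    n = len(study.sites)
    z = rng.standard_normal((n, k)) @ chol.T
    cols = {}
    for j, name in enumerate(names):
        median, sigma = (marginals or {}).get(name, (1.0, 1.0))
        cols[name] = median * np.exp(sigma * z[:, j])
    data = pd.DataFrame(cols, index=pd.Index(study.sites["site_id"], name="site_id"))
    return PredictorTable(data=data, variables=list(variables))


# ---------------------------------------------------------------------------
# concentrations


def default_true_model(kind: str = "no2") -> TrueModel:
    """A plausible generating model on the default GIS variable set.

    Coefficient magnitudes are scaled to the generator's predictor scales so
    that each term contributes a concentration SD of roughly 1-2 µg/m³.
    """
    if kind == "no2":
        coef = {
            "traffic_load_50": 2.0e-06,
            "road_length_1000": 5.0e-04,
            "natural_green_5000": -1.0e-06,
            "nearest_road_intensity": 1.5e-04,
        }
        return TrueModel(intercept=8.0, coefficients=coef, background_weight=1.0)
    if kind == "pm25":
        coef = {
            "traffic_load_50": 8.0e-07,
            "traffic_load_50_1000": 3.0e-08,
            "road_length_100": 2.0e-03,
        }
        return TrueModel(intercept=1.0, coefficients=coef, background_weight=1.0)
    raise ConfigurationError(f"unknown kind {kind!r}")


def no2_like_config(**overrides) -> StudyConfig:
    """Within-area-dominated variance structure (traffic pollutant)."""
    base = dict(
        background_mean=16.0,
        between_within_sd_ratio=0.5,  # between-area variance 1/4 of within
        within_r2_target=0.65,
        seasonal_amplitude=5.0,
        season_noise_sd=1.5,
    )
    base.update(overrides)
    return StudyConfig(**base)


def pm25_like_config(**overrides) -> StudyConfig:
    """Between-area-dominated variance structure (regional pollutant)."""
    base = dict(
        background_mean=14.0,
        between_within_sd_ratio=math.sqrt(3.0),  # between-area variance 3x within
        within_r2_target=0.55,
        seasonal_amplitude=3.0,
        season_noise_sd=1.0,
    )
    base.update(overrides)
    return StudyConfig(**base)


def _check_signs(table: PredictorTable, true_model: TrueModel) -> None:
    for name, beta in true_model.coefficients.items():
        if name not in table.data.columns:
            raise ConfigurationError(f"true-model variable {name!r} not in predictor table")
        try:
            var = table.variable(name)
        except KeyError:
            continue
        if beta != 0 and np.sign(beta) != var.sign:
            raise ConfigurationError(
                f"true coefficient for {name} contradicts its declared direction"
            )


def generate_concentrations(
    study: SyntheticStudy, table: PredictorTable, true_model: TrueModel
) -> ConcentrationData:
    """Generate annual truths, seasonal samples and reference series.

    The deterministic annual value is intercept + background_weight * B_a +
    sum(beta * x). Each of the three seasonal samples adds the area's
    sinusoidal seasonal deviation (shared exactly with the area's reference
    series) plus independent sampling noise. The reference series spans 12
    periods of a full sinusoid cycle, so its seasonal deviations average to
    zero and the difference adjustment is exact in expectation.
    """
    config = study.config
    _check_signs(table, true_model)
    rng = _rng(config.seed, "concentrations")

    sites = study.sites
    site_ids = sites["site_id"].to_numpy()
    areas = sites["area_code"].to_numpy()
    codes = study.area_codes

    local = np.zeros(len(sites))
    for name, beta in true_model.coefficients.items():
        local += beta * table.data[name].reindex(site_ids).to_numpy(dtype=float)

    # pooled within-area SD of the local signal
    local_s = pd.Series(local, index=areas)
    within_var = local_s.groupby(level=0).var(ddof=1)
    s_w = float(np.sqrt(within_var.mean()))

    if config.within_r2_target is not None:
        if s_w == 0:
            raise ConfigurationError("within_r2_target requires non-degenerate local signal")
        t = config.within_r2_target
        noise_sd = s_w * math.sqrt((1.0 - t) / t)
    else:
        noise_sd = config.noise_sd

    bw = true_model.background_weight
    if config.between_within_sd_ratio is not None:
        if bw == 0:
            raise ConfigurationError("variance-ratio calibration requires background_weight != 0")
        s_tot = math.sqrt(s_w ** 2 + noise_sd ** 2)
        target_sd = config.between_within_sd_ratio * s_tot
        # the local signal's area means already contribute between-area
        # variance; the drawn area effects supply only the remainder, so the
        # total between-area variance of the signal matches the target
        m_a = local_s.groupby(level=0).mean().reindex(codes)
        vm = float(m_a.var(ddof=1))
        dev_sd = math.sqrt(max(target_sd ** 2 - vm, 0.0))
        u = study.area_background_u.reindex(codes)
        effects = config.background_mean + dev_sd * u / bw
    else:
        effects = study.area_backgrounds.reindex(codes)
    effects = pd.Series(effects.to_numpy(dtype=float), index=pd.Index(codes, name="area_code"))

    det = true_model.intercept + bw * effects.reindex(areas).to_numpy() + local
    annual = det + rng.normal(0.0, noise_sd, size=len(det)) if noise_sd > 0 else det.copy()

    # area seasonal structure: full-cycle sinusoid (sums to zero over 12 periods)
    months = np.arange(12)
    references: dict[str, ReferenceSeries] = {}
    delta = {}
    for area in codes:
        amp = config.seasonal_amplitude * (0.5 + rng.uniform())
        phase = rng.uniform(0.0, 12.0)
        d = amp * np.cos(2 * math.pi * (months - phase) / 12.0)
        delta[area] = dict(zip(REF_PERIODS, d))
        base = true_model.intercept + bw * float(effects[area])
        references[area] = ReferenceSeries(
            area_code=area, values={p: base + dv for p, dv in zip(REF_PERIODS, d)}
        )

    rows = []
    for sid, area, a_true in zip(site_ids, areas, annual):
        for _season, period in SAMPLE_PERIODS.items():
            eps = rng.normal(0.0, config.season_noise_sd) if config.season_noise_sd > 0 else 0.0
            rows.append((sid, period, a_true + delta[area][period] + eps))
    seasonal = pd.DataFrame(rows, columns=["site_id", "period", "value"])

    return ConcentrationData(
        annual_true=pd.Series(annual, index=pd.Index(site_ids, name="site_id")),
        deterministic=pd.Series(det, index=pd.Index(site_ids, name="site_id")),
        seasonal=seasonal,
        references=references,
        area_effects=effects,
        noise_sd=noise_sd,
    )
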