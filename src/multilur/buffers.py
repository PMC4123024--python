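"""Buffer-based GIS predictor extraction.

Computes the classic land-use-regression predictor variables around a
monitoring site from a road-segment table and a land-use raster:

* road length / major-road length in a circular buffer,
* traffic load (intensity-weighted road length) in a buffer or ring,
* traffic intensity on the nearest road,
* land-use class area in a buffer.

All geometry is exact planar geometry on a closed disc: the length of a
segment inside the disc comes from the quadratic parametrization of
``|P(t) - c|^2 = r^2`` with t clipped to [0, 1]. Ring (annulus) variables are
always computed as the difference of two disc values, which makes the
identity ``ring + inner disc = outer disc`` hold exactly.

Raster areas use a cell-center inclusion test (a cell counts if its center
lies in the closed disc), so the result equals ``count * cell_size**2`` and
approaches the true disc area as ``cell_size / radius -> 0``; the absolute
error is bounded by the area of the one-cell-wide ring straddling the circle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError
from .types import LandUseRaster, PredictorTable, VariableDef

logger = logging.getLogger(__name__)

__all__ = [
    "segment_length_in_disc",
    "point_segment_distance",
    "buffer_sum",
    "ring_sum",
    "nearest_road_intensity",
    "raster_class_area_in_disc",
    "extract_predictors",
]


def segment_length_in_disc(x1, y1, x2, y2, cx, cy, radius):
    """Length of the part of segment (x1,y1)-(x2,y2) inside the closed disc.

    Vectorized over segments: all of x1..y2 may be equal-length arrays.
    Zero-length segments are treated as points and contribute 0.
    """
    if not radius > 0:
        raise ValueError("radius must be > 0")
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    dx = x2 - x1
    dy = y2 - y1
    fx = x1 - cx
    fy = y1 - cy
    a = dx * dx + dy * dy  # |d|^2
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - radius * radius
    disc = b * b - 4.0 * a * c
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrt_disc = np.sqrt(np.maximum(disc, 0.0))
        t1 = (-b - sqrt_disc) / (2.0 * a)
        t2 = (-b + sqrt_disc) / (2.0 * a)
        frac = np.clip(t2, 0.0, 1.0) - np.clip(t1, 0.0, 1.0)
        length = np.where((a > 0.0) & (disc > 0.0), np.maximum(frac, 0.0) * np.sqrt(a), 0.0)
    if length.ndim == 0:
        return float(length)
    return length


def point_segment_distance(px, py, x1, y1, x2, y2):
    """Euclidean distance from point(s) to segment(s), vectorized."""
    x1 = np.asarray(x1, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    dx = x2 - x1
    dy = y2 - y1
    a = dx * dx + dy * dy
    fx = np.asarray(px, dtype=float) - x1
    fy = np.asarray(py, dtype=float) - y1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(a > 0.0, (fx * dx + fy * dy) / np.where(a > 0.0, a, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    ex = fx - t * dx
    ey = fy - t * dy
    d = np.sqrt(ex * ex + ey * ey)
    if d.ndim == 0:
        return float(d)
    return d


def _road_arrays(roads: pd.DataFrame, major_only: bool):
    r = roads
    if major_only:
        r = roads.loc[roads["is_major"].astype(bool)]
    return r


def buffer_sum(
    roads: pd.DataFrame,
    x: float,
    y: float,
    radius: float,
    weight: str = "unit",
    major_only: bool = False,
) -> float:
    """Sum of in-disc segment lengths, optionally intensity-weighted.

    ``weight="unit"`` yields road length (m); ``weight="intensity"`` yields
    traffic load (vehicles·m/day). An empty road set gives 0.
    """
    if weight not in ("unit", "intensity"):
        raise ValueError(f"unknown weight {weight!r}")
    r = _road_arrays(roads, major_only)
    if len(r) == 0:
        return 0.0
    lengths = segment_length_in_disc(
        r["x1"].to_numpy(), r["y1"].to_numpy(), r["x2"].to_numpy(), r["y2"].to_numpy(), x, y, radius
    )
    if weight == "intensity":
        lengths = lengths * r["intensity"].to_numpy(dtype=float)
    return float(np.sum(lengths))


def ring_sum(
    roads: pd.DataFrame,
    x: float,
    y: float,
    inner: float,
    outer: float,
    weight: str = "unit",
    major_only: bool = False,
) -> float:
    """Buffer sum in the annulus inner < d <= outer, as a disc difference."""
    if not outer > inner or not inner > 0:
        raise ValueError("ring requires outer > inner > 0")
    return buffer_sum(roads, x, y, outer, weight, major_only) - buffer_sum(
        roads, x, y, inner, weight, major_only
    )


def nearest_road_intensity(
    roads: pd.DataFrame, x: float, y: float, major_only: bool = False
) -> float:
    """Traffic intensity on the road segment nearest to (x, y).

    Ties in distance are broken by the smallest segment_id.
    """
    r = _road_arrays(roads, major_only)
    if len(r) == 0:
        raise DataError("nearest_road_intensity requires at least one road segment")
    d = point_segment_distance(
        x, y, r["x1"].to_numpy(), r["y1"].to_numpy(), r["x2"].to_numpy(), r["y2"].to_numpy()
    )
    d = np.atleast_1d(d)
    dmin = d.min()
    tied = np.flatnonzero(d == dmin)
    if len(tied) > 1:
        ids = r["segment_id"].to_numpy()[tied]
        pick = tied[np.argsort(ids)[0]]
    else:
        pick = tied[0]
    return float(r["intensity"].to_numpy(dtype=float)[pick])


def raster_class_area_in_disc(
    raster: LandUseRaster, cx: float, cy: float, radius: float, classes
) -> float:
    """Area (m²) of raster cells of the given classes with center in the disc."""
    if not radius > 0:
        raise ValueError("radius must be > 0")
    classes = set(classes)
    if not classes:
        return 0.0
    xs, ys = raster.cell_centers()
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    inside = d2 <= radius * radius
    if not inside.any():
        logger.warning(
            "buffer of radius %.0f m at (%.0f, %.0f) lies outside the raster extent",
            radius, cx, cy,
        )
        return 0.0
    match = np.isin(raster.grid, list(classes))
    return float(np.count_nonzero(inside & match)) * raster.cell_size ** 2


def _extract_one(var: VariableDef, x, y, roads, raster):
    if var.category in ("road_length", "major_road_length", "traffic_load"):
        weight = "intensity" if var.category == "traffic_load" else "unit"
        major = var.major_only or var.category == "major_road_length"
        if var.buffer_radius is None:
            raise DataError(f"{var.name}: buffer_radius required for {var.category}")
        if var.inner_radius is not None:
            return ring_sum(roads, x, y, var.inner_radius, var.buffer_radius, weight, major)
        return buffer_sum(roads, x, y, var.buffer_radius, weight, major)
    if var.category == "nearest_road_intensity":
        return nearest_road_intensity(roads, x, y, var.major_only)
    if var.category == "land_use_area":
        if raster is None:
            raise DataError(f"{var.name}: land_use_area requires a raster")
        if var.buffer_radius is None:
            raise DataError(f"{var.name}: buffer_radius required for land_use_area")
        return raster_class_area_in_disc(raster, x, y, var.buffer_radius, var.classes)
    raise DataError(f"cannot extract category {var.category!r} from geometry")


def extract_predictors(
    sites: pd.DataFrame,
    roads: pd.DataFrame,
    variables: list[VariableDef],
    rasters: dict[str, LandUseRaster] | LandUseRaster | None = None,
    area_backgrounds: pd.Series | None = None,
) -> PredictorTable:
    """Extract all geometry-based predictor variables for every site.

    ``rasters`` may be a single raster or an area_code -> raster mapping.
    If the road table has an ``area_code`` column, roads are restricted to
    the site's own area (areas are assumed geographically disjoint).
    Variables of category ``regional_background`` are filled from
    ``area_backgrounds`` (area_code -> level) when provided; the model
    building pipeline normally recomputes this column from measured annual
    averages instead.
    """
    by_area = "area_code" in roads.columns
    cols: dict[str, list] = {v.name: [] for v in variables}
    for _, site in sites.iterrows():
        r = roads.loc[roads["area_code"] == site["area_code"]] if by_area else roads
        if isinstance(rasters, dict):
            raster = rasters.get(site["area_code"])
        else:
            raster = rasters
        for var in variables:
            if var.category == "regional_background":
                if area_backgrounds is None:
                    raise DataError(
                        f"{var.name}: regional_background requires area_backgrounds"
                    )
                cols[var.name].append(float(area_backgrounds[site["area_code"]]))
            else:
                cols[var.name].append(_extract_one(var, site["x"], site["y"], r, raster))
    data = pd.DataFrame(cols, index=pd.Index(sites["site_id"], name="site_id"))
    return PredictorTable(data=data, variables=list(variables))
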