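"""Core domain types for multi-area land use regression.

The package works on plain pandas DataFrames for bulk tables (sites, roads,
predictors, measurements) and small dataclasses for structured records
(variable definitions, rasters, reference series, fitted models).

Coordinate convention: planar metric coordinates (a projected CRS); all
buffer radii and distances are in meters. Concentrations are in the
pollutant's native units (µg/m³ for NO2 and PM2.5, 1e-5/m for PM2.5
absorbance); the code is unit-agnostic beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

SITE_TYPES = ("street", "urban_background", "regional_background")

#: required columns of a site table
SITE_COLUMNS = ["site_id", "area_code", "region", "site_type", "x", "y"]

#: required columns of a road-segment table
ROAD_COLUMNS = ["segment_id", "x1", "y1", "x2", "y2", "intensity", "is_major"]

VARIABLE_CATEGORIES = (
    "traffic_load",
    "road_length",
    "major_road_length",
    "land_use_area",
    "nearest_road_intensity",
    "regional_background",
    "other_local",
)


@dataclass(frozen=True)
class VariableDef:
    """Definition of one candidate (or forced) predictor variable.

    Parameters
    ----------
    name
        Unique variable name; also the predictor-table column name.
    category
        What the variable measures (one of ``VARIABLE_CATEGORIES``).
    buffer_radius
        Outer buffer radius in meters, where applicable.
    inner_radius
        Inner radius for ring (annulus) variables; ``None`` for plain discs.
    direction
        A-priori direction of effect, ``"positive"`` or ``"negative"``.
        Candidates whose fitted coefficient contradicts it are never admitted.
    forced
        Forced variables enter the model unconditionally in the first step and
        are exempt from sign checks, p-value pruning and VIF removal.
    classes
        For ``land_use_area``: the raster class codes counted as this variable.
    """

    name: str
    category: str
    buffer_radius: Optional[float] = None
    inner_radius: Optional[float] = None
    direction: str = "positive"
    forced: bool = False
    classes: tuple = ()
    major_only: bool = False

    def __post_init__(self):
        if self.category not in VARIABLE_CATEGORIES:
            raise ConfigurationError(f"unknown variable category {self.category!r}")
        if self.direction not in ("positive", "negative"):
            raise ConfigurationError(f"direction must be positive/negative, got {self.direction!r}")
        if self.inner_radius is not None and self.buffer_radius is not None:
            if not self.buffer_radius > self.inner_radius:
                raise ConfigurationError(
                    f"{self.name}: buffer_radius must exceed inner_radius"
                )

    @property
    def sign(self) -> int:
        return 1 if self.direction == "positive" else -1

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "buffer_radius": self.buffer_radius,
            "inner_radius": self.inner_radius,
            "direction": self.direction,
            "forced": self.forced,
            "classes": list(self.classes),
            "major_only": self.major_only,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableDef":
        d = dict(d)
        d["classes"] = tuple(d.get("classes", ()))
        return cls(**d)


@dataclass
class LandUseRaster:
    """Rectangular land-use grid of integer class codes.

    ``grid[0, 0]`` is the north-west cell (ESRI ASCII grid row order);
    ``x0, y0`` are the coordinates of the lower-left corner of the grid.
    """

    x0: float
    y0: float
    cell_size: float
    grid: np.ndarray
    nodata: int = -9999

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise DataError("raster grid must be 2-dimensional")
        if not self.cell_size > 0:
            raise DataError("raster cell_size must be > 0")

    @property
    def nrows(self) -> int:
        return self.grid.shape[0]

    @property
    def ncols(self) -> int:
        return self.grid.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (nrows, ncols) with cell-center coordinates."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = self.x0 + (cols + 0.5) * self.cell_size
        ys = self.y0 + (self.nrows - 1 - rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class ReferenceSeries:
    """Continuous reference-site series for one study area.

    Maps measurement period labels to concentrations; the annual mean is the
    arithmetic mean over all periods.
    """

    area_code: str
    values: dict[str, float]

    def __post_init__(self):
        if len(self.values) == 0:
            raise DataError(f"reference series for {self.area_code} is empty")

    @property
    def annual_mean(self) -> float:
        return float(np.mean(list(self.values.values())))

    @property
    def periods(self) -> list[str]:
        return list(self.values.keys())


@dataclass
class PredictorTable:
    """Site-by-variable predictor matrix plus per-variable metadata.

    ``data`` is indexed by site_id with one column per variable, in the order
    the variables were defined.
    """

    data: pd.DataFrame
    variables: list[VariableDef]

    def __post_init__(self):
        missing = [v.name for v in self.variables if v.name not in self.data.columns]
        if missing:
            raise DataError(f"predictor table missing columns: {missing}")
        if self.data.isna().any().any():
            raise DataError("predictor table contains missing values")

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]


@dataclass
class TrueModel:
    """Ground-truth linear generating model for synthetic studies.

    The generated deterministic annual concentration at site *i* in area *a* is

        intercept + background_weight * B_a + sum_v coefficients[v] * x_iv

    with B_a the latent area background and independent Gaussian site noise
    on top. Exists so recovery tests can compare fitted against true terms.
    """

    intercept: float
    coefficients: dict[str, float]
    background_weight: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "background_weight": self.background_weight,
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueModel":
        return cls(**d)


def validate_site_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a site table against the package schema; returns it unchanged."""
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise DataError(f"site table missing columns: {missing}")
    dup = sites["site_id"][sites["site_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate site_id(s): {sorted(set(dup))}")
    bad = sites.loc[~sites["site_type"].isin(SITE_TYPES)]
    if len(bad):
        row = bad.index[0]
        raise DataError(
            f"unknown site_type {bad['site_type'].iloc[0]!r} at row {row}"
        )
    return sites
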