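"""The assembled modelling dataset: sites, predictors and annual averages.

``LURDataset`` bundles what the model-building and evaluation layers need:
the site table, the local (GIS/tabular) predictor table, the temporally
adjusted annual averages, and optionally the forced regional-background
variable definition. The regional background column is always computed from
the measured annual averages at each area's own regional-background sites
(never from the latent synthetic truth), so a model refit without an area
uses no observation from that area, while the excluded area's own background
value — the minimal measurement a "new" area must supply — remains available
for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import pandas as pd

from . import builder
from .errors import ConfigurationError, DataError
from .types import PredictorTable, VariableDef


@dataclass
class LURDataset:
    sites: pd.DataFrame  # site_id, area_code, region, site_type, x, y
    predictors: PredictorTable  # local candidate variables, indexed by site_id
    annual: pd.Series  # site_id -> adjusted annual average
    background: VariableDef | None = None  # forced background variable, if any

    def __post_init__(self):
        ids = set(self.sites["site_id"])
        if set(self.predictors.data.index) != ids:
            raise DataError("predictor table does not cover exactly the site table")
        if set(self.annual.index) != ids:
            raise DataError("annual observations do not cover exactly the site table")
        if self.background is not None and not self.background.forced:
            raise ConfigurationError("background variable must be forced")

    @property
    def areas(self) -> list[str]:
        return sorted(self.sites["area_code"].unique())

    @cached_property
    def background_column(self) -> pd.Series | None:
        """Per-site regional background (area mean of its background sites)."""
        if self.background is None:
            return None
        return builder.regional_background_variable(self.annual, self.sites)

    @cached_property
    def full_frame(self) -> pd.DataFrame:
        """All predictor columns (background first, when present), all sites."""
        frame = self.predictors.data
        if self.background is not None:
            frame = frame.copy()
            frame.insert(0, self.background.name, self.background_column)
        return frame

    @property
    def all_variables(self) -> list[VariableDef]:
        local = list(self.predictors.variables)
        return ([self.background] + local) if self.background is not None else local

    def design(self, site_ids=None) -> tuple[PredictorTable, pd.Series]:
        """(PredictorTable incl. background column, y) for the given sites."""
        if site_ids is None:
            site_ids = self.sites["site_id"]
        idx = pd.Index(site_ids)
        table = PredictorTable(data=self.full_frame.loc[idx], variables=self.all_variables)
        return table, self.annual.loc[idx]

    def subset_sites(self, site_ids) -> "LURDataset":
        idx = pd.Index(site_ids)
        return replace(
            self,
            sites=self.sites.loc[self.sites["site_id"].isin(idx)].reset_index(drop=True),
            predictors=PredictorTable(
                data=self.predictors.data.loc[idx], variables=self.predictors.variables
            ),
            annual=self.annual.loc[idx],
        )

    def exclude_areas(self, areas) -> "LURDataset":
        areas = set([areas] if isinstance(areas, str) else areas)
        keep = self.sites.loc[~self.sites["area_code"].isin(areas), "site_id"]
        return self.subset_sites(keep)

    def region_subset(self, region: str) -> "LURDataset":
        """Restrict to one region's areas (to build "regional" models)."""
        if region not in set(self.sites["region"]):
            raise ValueError(f"unknown region {region!r}")
        keep = self.sites.loc[self.sites["region"] == region, "site_id"]
        return self.subset_sites(keep)
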