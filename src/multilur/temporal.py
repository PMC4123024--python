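"""Temporal adjustment of campaign samples to annual averages.

Short monitoring campaigns measure each site in only three 2-week periods
(cold, warm, intermediate season). Because the periods differ between sites,
the raw mean of the three samples confounds spatial contrasts with seasonal
trends. The adjustment uses each area's continuous reference site: the
reference's deviation from its own annual mean in a period is subtracted
from the site sample taken in that period (difference method), and the
adjusted annual average is the mean of the adjusted samples:

    adjusted = mean_p [ sample_p - (ref_p - ref_annual_mean) ]

The subtraction removes the temporal component exactly whenever a site
shares the reference site's temporal deviations. A constant reference series
leaves the plain mean unchanged. The method uses signed differences: an
absolute-value "difference" cannot de-trend and is not offered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .types import ReferenceSeries

__all__ = ["reference_annual_mean", "adjust_annual_average", "adjust_campaign"]


def reference_annual_mean(series: ReferenceSeries) -> float:
    """Arithmetic mean of the reference series over all its periods."""
    if len(series.values) == 0:
        raise DataError("empty reference series")
    return series.annual_mean


def adjust_annual_average(site_samples: dict[str, float], ref: ReferenceSeries) -> float:
    """Temporally adjusted annual average of one site's campaign samples.

    ``site_samples`` maps period label -> measured concentration; every
    period must exist in the reference series. Fewer than 3 samples raises a
    warning (a partially failed campaign) but is computed on what remains.
    """
    if len(site_samples) == 0:
        raise DataError("site has no samples")
    if len(site_samples) < 3:
        warnings.warn(
            f"only {len(site_samples)} sample(s) available; adjusted annual is "
            "computed on the available periods",
            stacklevel=2,
        )
    ref_mean = reference_annual_mean(ref)
    adjusted = []
    for period, value in site_samples.items():
        if period not in ref.values:
            raise DataError(
                f"period {period!r} missing from reference series of area {ref.area_code}"
            )
        adjusted.append(value - (ref.values[period] - ref_mean))
    return float(np.mean(adjusted))


def adjust_campaign(
    measurements: pd.DataFrame,
    references: dict[str, ReferenceSeries],
    sites: pd.DataFrame,
) -> pd.Series:
    """Adjusted annual average for every site in a measurements table.

    ``measurements`` has columns site_id, period, value; ``sites`` maps
    site_id to area_code (to pick the area's reference series). Returns a
    Series indexed by site_id in the site-table order.
    """
    required = {"site_id", "period", "value"}
    if not required.issubset(measurements.columns):
        raise DataError(f"measurements table needs columns {sorted(required)}")
    area_of = dict(zip(sites["site_id"], sites["area_code"]))
    out = {}
    for sid, grp in measurements.groupby("site_id", sort=False):
        if sid not in area_of:
            raise DataError(f"measurement for unknown site {sid!r}")
        area = area_of[sid]
        if area not in references:
            raise DataError(f"no reference series for area {area!r}")
        samples = dict(zip(grp["period"], grp["value"]))
        out[sid] = adjust_annual_average(samples, references[area])
    missing = [s for s in sites["site_id"] if s not in out]
    if missing:
        raise DataError(f"no measurements for site(s): {missing[:5]}")
    return pd.Series([out[s] for s in sites["site_id"]],
                     index=pd.Index(sites["site_id"], name="site_id"))
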