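"""Model evaluation: within-area fit, cross-validation and hold-out validation.

Three complementary layers, mirroring how multi-area LUR models are judged:

* **Model_intra R²** — the combined model applied to each area's own
  training sites; the per-area squared Pearson correlation shows how much
  *within-area* variation the multi-area model explains, directly comparable
  with city-specific models.
* **Leave-one-area-out cross-validation (LOAOCV)** — refit the full
  supervised stepwise model M times, each time excluding one complete area,
  and predict the excluded area; pooled and per-area statistics reflect the
  between-area heterogeneity of model fit.
* **Hold-out validation (HV)** — fit on a training subset (for example a
  per-area stratified 75% sample) and predict the held-out sites, with
  predictor values truncated to the training range to prevent extrapolation.

Validation R² is the squared Pearson correlation between predictions and
observations (which is blind to calibration bias, so the MSE-based
1 - SSE/SST variant is also reported as a secondary diagnostic). Per-area
regression slopes regress predictions on observations, so a slope below 1
expresses compression of the predicted contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import builder
from .builder import LURModel, StepwiseOptions
from .dataset import LURDataset
from .errors import ConfigurationError, DataError

__all__ = [
    "pearson_r2",
    "rmse",
    "per_area_metrics",
    "model_intra_r2",
    "stratified_holdout_split",
    "holdout_validate",
    "loaocv",
    "EvaluationReport",
]

MIN_AREA_SITES = 3  # areas with fewer evaluable sites are reported as missing


def pearson_r2(pred, obs) -> float:
    """Squared Pearson correlation; NaN (missing) if either vector is constant."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("pred and obs must have equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        warnings.warn("constant vector: Pearson R² undefined, reported as missing")
        return float("nan")
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def rmse(pred, obs) -> float:
    """Root mean squared prediction error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) == 0:
        raise ValueError("need at least 1 pair")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _slope(pred, obs) -> float:
    """Least-squares slope of predictions regressed on observations."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    design = np.column_stack([np.ones(len(obs)), obs])
    coef, _, _, _ = np.linalg.lstsq(design, pred, rcond=None)
    return float(coef[1])


def _iqr(values) -> float:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q75, q25 = np.percentile(v, [75, 25])  # linear-interpolation quantiles
    return float(q75 - q25)


def _median(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.median(v[~np.isnan(v)]))


def per_area_metrics(pred: pd.Series, obs: pd.Series, areas: pd.Series) -> pd.DataFrame:
    """Per-area n, squared Pearson R² and regression slope.

    Areas with fewer than 3 evaluated sites are reported with missing
    metrics rather than silently dropped.
    """
    frame = pd.DataFrame({"pred": pred, "obs": obs, "area": np.asarray(areas)})
    rows = []
    for area, grp in frame.groupby("area", sort=True):
        if len(grp) < MIN_AREA_SITES:
            warnings.warn(f"area {area}: only {len(grp)} site(s); metrics reported missing")
            rows.append((area, len(grp), np.nan, np.nan, np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = pearson_r2(grp["pred"], grp["obs"])
        rows.append((area, len(grp), r2, _slope(grp["pred"], grp["obs"]),
                     rmse(grp["pred"], grp["obs"])))
    return pd.DataFrame(rows, columns=["area", "n", "r2", "slope", "rmse"])


@dataclass
class EvaluationReport:
    """Overall and per-area agreement between predictions and observations."""

    overall_r2: float  # squared Pearson correlation, pooled
    overall_rmse: float
    r2_mse: float  # secondary diagnostic: 1 - SSE/SST (calibration-sensitive)
    per_area: pd.DataFrame  # columns area, n, r2, slope
    median_r2: float
    iqr_r2: float
    median_slope: float
    iqr_slope: float
    truncated_cells: int = 0
    split: str = ""
    models: list = field(default_factory=list)  # refit models, where applicable

    def to_dict(self) -> dict:
        return {
            "overall_r2": self.overall_r2,
            "overall_rmse": self.overall_rmse,
            "r2_mse": self.r2_mse,
            "median_r2": self.median_r2,
            "iqr_r2": self.iqr_r2,
            "median_slope": self.median_slope,
            "iqr_slope": self.iqr_slope,
            "truncated_cells": self.truncated_cells,
            "split": self.split,
            "per_area": self.per_area.to_dict(orient="records"),
        }


def _report(pred: pd.Series, obs: pd.Series, areas, truncated: int, split: str,
            models: list | None = None) -> EvaluationReport:
    table = per_area_metrics(pred, obs, areas)
    sse = float(((np.asarray(pred) - np.asarray(obs)) ** 2).sum())
    sst = float(((np.asarray(obs) - np.mean(obs)) ** 2).sum())
    return EvaluationReport(
        overall_r2=pearson_r2(pred, obs),
        overall_rmse=rmse(pred, obs),
        r2_mse=1.0 - sse / sst if sst > 0 else float("nan"),
        per_area=table,
        median_r2=_median(table["r2"]),
        iqr_r2=_iqr(table["r2"]),
        median_slope=_median(table["slope"]),
        iqr_slope=_iqr(table["slope"]),
        truncated_cells=truncated,
        split=split,
        models=models or [],
    )


def model_intra_r2(model: LURModel, dataset: LURDataset) -> EvaluationReport:
    """Apply a combined model to each area's own sites; per-area R² summary."""
    frame = dataset.full_frame
    pred = builder.predict(model, frame, truncate=False)
    areas = dataset.sites.set_index("site_id")["area_code"].reindex(frame.index)
    return _report(pred, dataset.annual.reindex(frame.index), areas, 0, "model_intra")


def stratified_holdout_split(
    sites: pd.DataFrame, fraction: float, seed: int, stratum: str = "area_code"
) -> tuple[list[str], list[str]]:
    """Per-stratum random split: round(fraction * n) sites go to the test set.

    Deterministic for a fixed seed. A stratum with a single site stays
    entirely in training (with a warning).
    """
    if not 0 <= fraction < 1:
        raise ConfigurationError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, grp in sites.groupby(stratum, sort=True):
        ids = grp["site_id"].tolist()
        if len(ids) < 2:
            warnings.warn(f"stratum with {len(ids)} site(s) left entirely in training")
            train.extend(ids)
            continue
        k = int(round(fraction * len(ids)))
        chosen = set(rng.choice(len(ids), size=k, replace=False).tolist())
        for j, sid in enumerate(ids):
            (test if j in chosen else train).append(sid)
    return train, test


def designated_split(sites: pd.DataFrame, test_flag: pd.Series) -> tuple[list[str], list[str]]:
    """Designated training/test split from a boolean per-site flag (for
    designs where the test set is a fixed second monitoring network)."""
    flag = test_flag.reindex(sites["site_id"])
    if flag.isna().any():
        raise DataError("test flag missing for some sites")
    test = sites.loc[flag.to_numpy(), "site_id"].tolist()
    train = sites.loc[~flag.to_numpy(), "site_id"].tolist()
    return train, test


def holdout_validate(
    dataset: LURDataset,
    split: tuple[list[str], list[str]],
    options: StepwiseOptions | None = None,
    truncate: bool = True,
) -> EvaluationReport:
    """Fit on the training sites only; predict the held-out sites."""
    train_ids, test_ids = split
    if not train_ids or not test_ids:
        raise ConfigurationError("training and test sets must both be non-empty")
    if set(train_ids) & set(test_ids):
        raise ConfigurationError("training and test sets overlap")
    table, y = dataset.design(train_ids)
    model = builder.supervised_stepwise(table, y, options, provenance={"split": "holdout"})
    test_frame = dataset.full_frame.loc[pd.Index(test_ids)]
    pred, truncated = builder.predict(model, test_frame, truncate=truncate,
                                      return_truncated_count=True)
    areas = dataset.sites.set_index("site_id")["area_code"].reindex(test_frame.index)
    report = _report(pred, dataset.annual.loc[pd.Index(test_ids)], areas, truncated,
                     f"holdout({len(train_ids)} train / {len(test_ids)} test)",
                     models=[model])
    return report


def loaocv(
    dataset: LURDataset,
    options: StepwiseOptions | None = None,
    truncate: bool = True,
) -> EvaluationReport:
    """Leave-one-area-out cross-validation: M areas, M refits.

    Each refit excludes one complete area, predicts it (with truncation),
    and the left-out predictions are pooled for the overall statistics.
    """
    areas = dataset.areas
    if len(areas) < 2:
        raise ConfigurationError("LOAOCV requires at least 2 areas")
    preds, models = [], []
    truncated = 0
    for area in areas:
        training = dataset.exclude_areas(area)
        table, y = training.design()
        model = builder.supervised_stepwise(
            table, y, options, provenance={"excluded_areas": [area]}
        )
        models.append(model)
        out_ids = dataset.sites.loc[dataset.sites["area_code"] == area, "site_id"]
        frame = dataset.full_frame.loc[pd.Index(out_ids)]
        p, t = builder.predict(model, frame, truncate=truncate, return_truncated_count=True)
        truncated += t
        preds.append(p)
    pred = pd.concat(preds)
    obs = dataset.annual.reindex(pred.index)
    area_s = dataset.sites.set_index("site_id")["area_code"].reindex(pred.index)
    return _report(pred, obs, area_s, truncated, f"loaocv({len(areas)} areas)", models)
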