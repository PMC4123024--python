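"""Transferability of combined models to areas excluded from model building.

For each of the M study areas, the combined model is rebuilt from scratch on
the other M-1 areas and applied, with predictor truncation, to the sites of
the excluded area. The squared Pearson correlation between observations and
predictions in the excluded area (TRANS_intra R²) measures how well the
model transfers to a "new" area whose measurements never entered model
building. The excluded area's regional background value is computed from its
own regional-background sites: that is the minimal measurement a new area
must supply for the forced background term to be defined at all.

Per-area rows are summarized as median (IQR) of the refit model R², the full
model's within-area Model_intra R², TRANS_intra R² and RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import builder, evaluation
from .builder import LURModel, StepwiseOptions
from .dataset import LURDataset
from .errors import ConfigurationError

__all__ = ["TransferReport", "transfer_excluding_each_area", "region_subset"]


@dataclass
class TransferReport:
    """Area-exclusion transfer experiment results."""

    per_area: pd.DataFrame  # area, n, model_r2, trans_intra_r2, rmse, truncated
    summary: dict  # median/iqr of model R², Model_intra R², TRANS_intra R², RMSE
    models: list[LURModel] = field(default_factory=list)
    full_model: LURModel | None = None
    model_intra: evaluation.EvaluationReport | None = None

    def to_dict(self) -> dict:
        return {
            "per_area": self.per_area.to_dict(orient="records"),
            "summary": dict(self.summary),
        }


def _med_iqr(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    q75, q25 = np.percentile(v, [75, 25])
    return float(np.median(v)), float(q75 - q25)


def transfer_excluding_each_area(
    dataset: LURDataset,
    options: StepwiseOptions | None = None,
    truncate: bool = True,
) -> TransferReport:
    """Rebuild the combined model without each area and predict that area."""
    areas = dataset.areas
    if len(areas) < 3:
        raise ConfigurationError("transfer experiment requires at least 3 areas")

    # reference full model, for the Model_intra comparison column
    full_table, full_y = dataset.design()
    full_model = builder.supervised_stepwise(full_table, full_y, options,
                                             provenance={"excluded_areas": []})
    intra = evaluation.model_intra_r2(full_model, dataset)

    rows, models = [], []
    for area in areas:
        training = dataset.exclude_areas(area)
        table, y = training.design()
        model = builder.supervised_stepwise(
            table, y, options, provenance={"excluded_areas": [area]}
        )
        models.append(model)
        out_ids = dataset.sites.loc[dataset.sites["area_code"] == area, "site_id"]
        frame = dataset.full_frame.loc[pd.Index(out_ids)]
        pred, truncated = builder.predict(model, frame, truncate=truncate,
                                          return_truncated_count=True)
        obs = dataset.annual.loc[pred.index]
        if len(pred) >= evaluation.MIN_AREA_SITES and np.ptp(obs.to_numpy()) > 0:
            r2 = evaluation.pearson_r2(pred, obs)
        else:
            r2 = float("nan")
        rows.append((area, len(pred), model.r2, r2, evaluation.rmse(pred, obs), truncated))

    per_area = pd.DataFrame(
        rows, columns=["area", "n", "model_r2", "trans_intra_r2", "rmse", "truncated"]
    )
    med_m, iqr_m = _med_iqr(per_area["model_r2"])
    med_t, iqr_t = _med_iqr(per_area["trans_intra_r2"])
    med_r, iqr_r = _med_iqr(per_area["rmse"])
    summary = {
        "model_r2_median": med_m, "model_r2_iqr": iqr_m,
        "model_intra_r2_median": intra.median_r2, "model_intra_r2_iqr": intra.iqr_r2,
        "trans_intra_r2_median": med_t, "trans_intra_r2_iqr": iqr_t,
        "rmse_median": med_r, "rmse_iqr": iqr_r,
        "n_refits": len(models),
    }
    return TransferReport(per_area=per_area, summary=summary, models=models,
                          full_model=full_model, model_intra=intra)


def region_subset(dataset: LURDataset, region: str) -> LURDataset:
    """Restrict the dataset to one region's areas (regional models)."""
    return dataset.region_subset(region)
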