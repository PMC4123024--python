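"""End-to-end simulated campaigns: world -> predictors -> samples -> dataset.

Chains the synthetic generator, buffer extraction and temporal adjustment
into the ``LURDataset`` the model-building and evaluation layers consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic, temporal
from .dataset import LURDataset
from .synthetic import ConcentrationData, StudyConfig, SyntheticStudy
from .types import PredictorTable, TrueModel, VariableDef


@dataclass
class Campaign:
    """A complete simulated campaign with its assembled modelling dataset."""

    study: SyntheticStudy
    table: PredictorTable  # local candidate predictors (geometry + any decoys)
    concentrations: ConcentrationData
    annual: pd.Series  # temporally adjusted annual averages
    dataset: LURDataset
    true_model: TrueModel


def simulate_campaign(
    config: StudyConfig,
    variables: list[VariableDef] | None = None,
    true_model: TrueModel | None = None,
    n_decoys: int = 0,
) -> Campaign:
    """Simulate a full monitoring campaign and assemble its dataset.

    ``variables`` are the local candidate predictors offered to the model
    (default: the standard buffer set); ``n_decoys`` appends that many inert
    tabular candidates with no true effect. The forced regional-background
    variable is added to the dataset automatically and computed from the
    adjusted annual averages at each area's regional-background sites.
    """
    study = synthetic.generate_study(config)
    gis_vars = list(variables) if variables is not None else synthetic.default_variables()
    gis_vars = [v for v in gis_vars if v.category != "regional_background"]
    table = synthetic.generate_predictor_table(study, gis_vars, mode="geometry")

    if n_decoys:
        decoys = synthetic.decoy_variables(n_decoys)
        decoy_table = synthetic.generate_predictor_table(study, decoys, mode="tabular")
        data = pd.concat([table.data, decoy_table.data], axis=1)
        table = PredictorTable(data=data, variables=gis_vars + decoys)

    tm = true_model if true_model is not None else synthetic.default_true_model("no2")
    conc = synthetic.generate_concentrations(study, table, tm)
    annual = temporal.adjust_campaign(conc.seasonal, conc.references, study.sites)

    dataset = LURDataset(
        sites=study.sites,
        predictors=table,
        annual=annual,
        background=synthetic.regional_background_def(),
    )
    return Campaign(
        study=study, table=table, concentrations=conc, annual=annual,
        dataset=dataset, true_model=tm,
    )
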