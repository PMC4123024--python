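"""Supervised stepwise land-use-regression model building.

The selection procedure is the standardized multi-area LUR protocol:

1. Start from the forced variables (the regional background concentration,
   for combined multi-area models; none, for city-specific models).
2. Repeatedly offer every remaining candidate to the current model. A
   candidate is eligible only if its own fitted coefficient matches its
   a-priori direction of effect and it does not flip the required sign of
   any term already in the model. Admit the eligible candidate with the
   largest adjusted-R² gain, provided the gain is at least ``options.gain``
   (default 0.01, i.e. "at least 1%").
3. Stop when no eligible candidate clears the gain threshold.
4. Remove non-forced terms with p-value > ``options.alpha`` (default 0.1),
   iteratively, largest p first, refitting after each removal.
5. Enforce a maximum variance inflation factor (default: all VIF < 3),
   dropping the worst non-forced term and re-pruning until satisfied.

Ties on equal gains break lexicographically by variable name; constant or
rank-deficient candidates are silently ineligible. The final model records
the partial-R² path (cumulative R² refitting the surviving terms in entry
order), per-term p-values and VIFs, and the training min/max of every
predictor for truncation at prediction time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .types import PredictorTable, VariableDef

logger = logging.getLogger(__name__)

__all__ = [
    "StepwiseOptions",
    "FitResult",
    "LURTerm",
    "LURModel",
    "fit_ols",
    "adjusted_r2",
    "vif",
    "regional_background_variable",
    "supervised_stepwise",
    "prune_by_pvalue",
    "enforce_vif",
    "predict",
]


@dataclass(frozen=True)
class StepwiseOptions:
    """Tuning constants of the supervised stepwise procedure."""

    gain: float = 0.01  # minimum absolute adjusted-R² improvement to admit
    alpha: float = 0.1  # p-value threshold for the final pruning step
    vif_max: float = 3.0  # strict upper bound on any variance inflation factor

    def to_dict(self) -> dict:
        return {"gain": self.gain, "alpha": self.alpha, "vif_max": self.vif_max}


@dataclass
class FitResult:
    """Ordinary least squares fit with intercept."""

    intercept: float
    coef: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    adj_r2: float
    n: int
    residual_sd: float
    rank_deficient: bool = False


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R²: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_ols(y, X, names: list[str] | None = None) -> FitResult:
    """OLS with intercept on predictor columns X (n × k).

    Coefficient p-values are two-sided t-tests. A rank-deficient design is
    flagged (the stepwise loop treats such candidates as ineligible).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k + 1:
        raise DataError(f"need n > p + 1 observations (n={n}, p={k})")
    design = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise DataError("response variable is constant")
    r2 = 1.0 - sse / sst
    dof = n - k - 1
    sigma2 = sse / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.inf * np.sign(coef))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return FitResult(
        intercept=float(coef[0]),
        coef=dict(zip(names, coef[1:])),
        pvalues=dict(zip(names, p[1:])),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, k),
        n=n,
        residual_sd=float(np.sqrt(sigma2)),
        rank_deficient=rank < k + 1,
    )


def vif(X, names: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors: 1/(1 - R²_j) regressing column j on the rest.

    The auxiliary regressions include an intercept. A perfectly collinear
    column is reported as ``inf``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("vif requires at least 2 columns")
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    out = {}
    for j in range(k):
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, X[:, j], rcond=None)
        resid = X[:, j] - design @ coef
        sst = float(((X[:, j] - X[:, j].mean()) ** 2).sum())
        if sst == 0.0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - float(resid @ resid) / sst
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def regional_background_variable(annual: pd.Series, sites: pd.DataFrame) -> pd.Series:
    """Per-site regional background: mean annual value at the site's own
    area's regional-background sites. Constant within each area."""
    rb = sites.loc[sites["site_type"] == "regional_background", ["site_id", "area_code"]]
    merged = rb.assign(value=annual.reindex(rb["site_id"]).to_numpy())
    if merged["value"].isna().any():
        missing = merged.loc[merged["value"].isna(), "site_id"].tolist()
        raise DataError(f"regional background sites without observations: {missing[:5]}")
    means = merged.groupby("area_code")["value"].mean()
    lacking = sorted(set(sites["area_code"]) - set(means.index))
    if lacking:
        raise DataError(f"area(s) without regional background sites: {lacking}")
    return pd.Series(
        means.reindex(sites["area_code"]).to_numpy(),
        index=pd.Index(sites["site_id"], name="site_id"),
    )


# ---------------------------------------------------------------------------
# model representation


@dataclass
class LURTerm:
    name: str
    beta: float
    direction: str
    forced: bool
    p_value: float
    vif: float
    cum_r2: float  # model R² after this term entered (entry order)
    cum_adj_r2: float  # adjusted R² after this term entered
    train_min: float
    train_max: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class LURModel:
    """A fitted LUR model: ordered terms, diagnostics and training ranges."""

    terms: list[LURTerm]
    intercept: float
    r2: float
    adj_r2: float
    n: int
    residual_sd: float
    options: StepwiseOptions
    provenance: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def selection_path(self) -> list[str]:
        """Variable entry order of the greedy selection, before pruning."""
        return list(self.provenance.get("selection_path", self.names))

    def validate(self) -> None:
        """Assert the model-type invariants (signs, p-values, VIF, ranges)."""
        for t in self.terms:
            if not t.forced:
                want = 1 if t.direction == "positive" else -1
                if np.sign(t.beta) != want:
                    raise AssertionError(f"term {t.name} violates its direction constraint")
                if t.p_value > self.options.alpha:
                    raise AssertionError(f"term {t.name} has p={t.p_value:.3g} > alpha")
            if not t.train_min <= t.train_max:
                raise AssertionError(f"term {t.name} has an empty training range")
        if len(self.terms) >= 2:
            worst = max(t.vif for t in self.terms)
            if not worst < self.options.vif_max:
                raise AssertionError(f"max VIF {worst:.3g} >= {self.options.vif_max}")
        cum = [t.cum_r2 for t in self.terms]
        if any(b < a - 1e-10 for a, b in zip(cum, cum[1:])):
            raise AssertionError("partial-R² path is not non-decreasing")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "intercept": self.intercept,
            "r2": self.r2,
            "adj_r2": self.adj_r2,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "options": self.options.to_dict(),
            "terms": [t.to_dict() for t in self.terms],
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LURModel":
        if d.get("schema_version") != 1:
            raise DataError(f"unsupported model schema version {d.get('schema_version')!r}")
        if "terms" not in d:
            raise DataError("model file lacks a 'terms' field")
        for t in d["terms"]:
            if "train_min" not in t or "train_max" not in t:
                raise DataError(f"model term {t.get('name')!r} lacks training ranges")
        return cls(
            terms=[LURTerm(**t) for t in d["terms"]],
            intercept=d["intercept"],
            r2=d["r2"],
            adj_r2=d["adj_r2"],
            n=d["n"],
            residual_sd=d["residual_sd"],
            options=StepwiseOptions(**d["options"]),
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# the supervised stepwise algorithm


def _columns(table: PredictorTable, names: list[str]) -> np.ndarray:
    return table.data[names].to_numpy(dtype=float)


def _signs_ok(fit: FitResult, defs: dict[str, VariableDef]) -> bool:
    for name, beta in fit.coef.items():
        var = defs[name]
        if var.forced:
            continue
        if np.sign(beta) != var.sign:
            return False
    return True


def _select(table: PredictorTable, y: np.ndarray, options: StepwiseOptions) -> list[str]:
    """Greedy forward selection under sign constraints; returns entry order."""
    defs = {v.name: v for v in table.variables}
    forced = [v.name for v in table.variables if v.forced]
    candidates = [v.name for v in table.variables if not v.forced]
    if not forced and not candidates:
        raise ConfigurationError("no forced variables and no candidates")

    current = list(forced)
    if current:
        fit = fit_ols(y, _columns(table, current), current)
        cur_adj = fit.adj_r2
    else:
        cur_adj = 0.0

    remaining = set(candidates)
    while remaining:
        best_name, best_gain = None, -np.inf
        for name in sorted(remaining):
            col = table.data[name].to_numpy(dtype=float)
            if np.ptp(col) == 0.0:
                continue  # constant candidate: ineligible
            trial = current + [name]
            try:
                fit = fit_ols(y, _columns(table, trial), trial)
            except DataError:
                break  # not enough observations to grow further
            if fit.rank_deficient:
                logger.debug("candidate %s rank-deficient with current model", name)
                continue
            if not _signs_ok(fit, defs):
                continue
            gain = fit.adj_r2 - cur_adj
            if gain > best_gain:
                best_name, best_gain = name, gain
        if best_name is None or best_gain < options.gain:
            break
        current.append(best_name)
        remaining.discard(best_name)
        cur_adj += best_gain
    return current


def _prune_names(table: PredictorTable, y: np.ndarray, names: list[str],
                 alpha: float) -> list[str]:
    defs = {v.name: v for v in table.variables}
    names = list(names)
    while names:
        fit = fit_ols(y, _columns(table, names), names)
        removable = {n: fit.pvalues[n] for n in names if not defs[n].forced}
        if not removable:
            break
        worst = max(removable, key=lambda n: (removable[n], n))
        if removable[worst] <= alpha:
            break
        names.remove(worst)
    return names


def _enforce_vif_names(table: PredictorTable, y: np.ndarray, names: list[str],
                       options: StepwiseOptions) -> list[str]:
    defs = {v.name: v for v in table.variables}
    names = list(names)
    while len(names) >= 2:
        v = vif(_columns(table, names), names)
        worst_all = max(v.values())
        if worst_all < options.vif_max:
            break
        removable = {n: v[n] for n in names if not defs[n].forced}
        if not removable:
            raise DataError("only forced terms remain but they are collinear")
        drop = max(removable, key=lambda n: (removable[n], n))
        names.remove(drop)
        names = _prune_names(table, y, names, options.alpha)
    return names


def _finalize(table: PredictorTable, y: np.ndarray, names: list[str],
              options: StepwiseOptions, provenance: dict) -> LURModel:
    defs = {v.name: v for v in table.variables}
    n = len(y)
    if names:
        fit = fit_ols(y, _columns(table, names), names)
        vifs = (vif(_columns(table, names), names) if len(names) >= 2
                else {names[0]: 1.0})
        # partial-R² path: sequential refits over the final entry order
        path_r2, path_adj = [], []
        for k in range(1, len(names) + 1):
            sub = fit_ols(y, _columns(table, names[:k]), names[:k])
            path_r2.append(sub.r2)
            path_adj.append(sub.adj_r2)
        terms = []
        for j, name in enumerate(names):
            col = table.data[name].to_numpy(dtype=float)
            terms.append(LURTerm(
                name=name,
                beta=float(fit.coef[name]),
                direction=defs[name].direction,
                forced=defs[name].forced,
                p_value=float(fit.pvalues[name]),
                vif=float(vifs[name]),
                cum_r2=path_r2[j],
                cum_adj_r2=path_adj[j],
                train_min=float(col.min()),
                train_max=float(col.max()),
            ))
        model = LURModel(
            terms=terms, intercept=fit.intercept, r2=fit.r2, adj_r2=fit.adj_r2,
            n=n, residual_sd=fit.residual_sd, options=options, provenance=provenance,
        )
    else:
        model = LURModel(
            terms=[], intercept=float(np.mean(y)), r2=0.0, adj_r2=0.0, n=n,
            residual_sd=float(np.std(y, ddof=1)), options=options, provenance=provenance,
        )
    model.validate()
    return model


def supervised_stepwise(
    table: PredictorTable,
    y,
    options: StepwiseOptions | None = None,
    provenance: dict | None = None,
) -> LURModel:
    """Build a LUR model by supervised forward selection with sign constraints.

    ``y`` is aligned with ``table.data`` rows (a Series indexed like the
    table, or a plain array in row order). Forced variables (``forced=True``
    in their definitions) always enter first and are never removed.
    """
    opts = options or StepwiseOptions()
    if isinstance(y, pd.Series):
        y = y.reindex(table.data.index).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise DataError("response contains missing values")

    selected = _select(table, y, opts)
    pruned = _prune_names(table, y, selected, opts.alpha)
    final = _enforce_vif_names(table, y, pruned, opts)

    prov = dict(provenance or {})
    prov["selection_path"] = list(selected)
    prov["options"] = opts.to_dict()
    return _finalize(table, y, final, opts, prov)


def prune_by_pvalue(model: LURModel, table: PredictorTable, y,
                    alpha: float | None = None) -> LURModel:
    """Iteratively drop the non-forced term with the largest p-value > alpha."""
    if isinstance(y, pd.Series):
        y = y.reindex(table.data.index).to_numpy(dtype=float)
    a = model.options.alpha if alpha is None else alpha
    names = _prune_names(table, y, model.names, a)
    return _finalize(table, y, names, model.options, dict(model.provenance))


def enforce_vif(model: LURModel, table: PredictorTable, y,
                vif_max: float | None = None) -> LURModel:
    """Drop the worst non-forced term until every VIF is below the bound."""
    if isinstance(y, pd.Series):
        y = y.reindex(table.data.index).to_numpy(dtype=float)
    opts = model.options if vif_max is None else StepwiseOptions(
        gain=model.options.gain, alpha=model.options.alpha, vif_max=vif_max)
    names = _enforce_vif_names(table, y, model.names, opts)
    return _finalize(table, y, names, opts, dict(model.provenance))


def predict(model: LURModel, data: pd.DataFrame, truncate: bool = True,
            return_truncated_count: bool = False):
    """Linear prediction, clamping predictors to the training range first.

    ``data`` must contain a column for every model variable. With
    ``truncate`` (the default, as in out-of-sample validation), predictor
    values outside the model's stored training [min, max] are clamped before
    the linear combination; the number of clamped cells is logged.
    """
    missing = [t.name for t in model.terms if t.name not in data.columns]
    if missing:
        raise DataError(f"prediction data missing variable column(s): {missing}")
    yhat = np.full(len(data), model.intercept, dtype=float)
    truncated = 0
    for t in model.terms:
        col = data[t.name].to_numpy(dtype=float)
        if truncate:
            clipped = np.clip(col, t.train_min, t.train_max)
            truncated += int(np.count_nonzero(clipped != col))
            col = clipped
        yhat += t.beta * col
    if truncated:
        logger.info("truncated %d predictor cell(s) to the training range", truncated)
    result = pd.Series(yhat, index=data.index, name="prediction")
    if return_truncated_count:
        return result, truncated
    return result
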