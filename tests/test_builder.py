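"""The supervised stepwise builder and its statistical primitives."""

import numpy as np
import pandas as pd
import pytest

from _oracles import greedy_stepwise_oracle, ols_normal_equations

import multilur as ml
from multilur.builder import (
    LURModel,
    StepwiseOptions,
    adjusted_r2,
    enforce_vif,
    fit_ols,
    predict,
    prune_by_pvalue,
    regional_background_variable,
    supervised_stepwise,
    vif,
)
from multilur.errors import ConfigurationError, DataError
from multilur.types import PredictorTable, VariableDef


def make_table(data: pd.DataFrame, defs: list[VariableDef]) -> PredictorTable:
    return PredictorTable(data=data, variables=defs)


def candidate(name, direction="positive", forced=False):
    return VariableDef(name, "other_local", None, None, direction, forced=forced)


class TestFitOLS:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        fit = fit_ols(2 * x, x, ["x"])
        assert fit.coef["x"] == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.pvalues["x"] < 1e-12

    def test_orthogonal_response(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
        y = np.tile([1.0, -1.0], 10)  # uncorrelated with x by construction
        fit = fit_ols(y, x, ["x"])
        assert fit.coef["x"] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(0.0, abs=1e-10)

    def test_fixed_dataset_matches_normal_equations(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 2.0], [5.0, 7.0], [6.0, 1.0]])
        y = np.array([3.1, 4.2, 9.8, 7.9, 15.2, 10.1])
        fit = fit_ols(y, X, ["a", "b"])
        beta, r2, adj = ols_normal_equations(y, X)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.coef["a"] == pytest.approx(beta[1], rel=1e-10)
        assert fit.coef["b"] == pytest.approx(beta[2], rel=1e-10)
        assert fit.r2 == pytest.approx(r2, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(adj, rel=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=40)
        fit = fit_ols(y, X, ["a", "b", "c"])
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-9)
        np.testing.assert_allclose(list(fit.coef.values()), ref.params[1:], rtol=1e-9)
        np.testing.assert_allclose(list(fit.pvalues.values()), ref.pvalues[1:], rtol=1e-7)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.adj_r2 == pytest.approx(ref.rsquared_adj, rel=1e-10)

    def test_duplicate_column_flagged_rank_deficient(self, rng):
        x = rng.normal(size=30)
        fit = fit_ols(x * 3 + rng.normal(size=30), np.column_stack([x, x]))
        assert fit.rank_deficient

    def test_too_few_observations_rejected(self):
        with pytest.raises(DataError):
            fit_ols([1.0, 2.0], np.ones((2, 2)))


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 20, 3) == 1.0

    def test_textbook_value(self):
        assert adjusted_r2(0.5, 20, 3) == pytest.approx(0.40625, abs=1e-12)

    def test_random_triples_match_formula(self, rng):
        for _ in range(50):
            r2 = rng.uniform()
            n = int(rng.integers(10, 500))
            p = int(rng.integers(1, 8))
            assert adjusted_r2(r2, n, p) == pytest.approx(
                1 - (1 - r2) * (n - 1) / (n - p - 1), rel=1e-12)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 4, 3)


class TestVIF:
    def test_orthogonal_columns_give_one(self):
        X = np.column_stack([np.tile([1.0, -1.0], 10), np.repeat([1.0, -1.0], 10)])
        v = vif(X, ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=1e-10)
        assert v["b"] == pytest.approx(1.0, abs=1e-10)

    def test_correlation_08_closed_form(self):
        # exact sample correlation 0.8 by Gram-Schmidt construction
        rng = np.random.default_rng(0)
        a = rng.normal(size=200)
        z = rng.normal(size=200)
        a = (a - a.mean()) / a.std()
        z = z - z.mean()
        z -= (z @ a) / (a @ a) * a
        z /= z.std()
        b = 0.8 * a + np.sqrt(1 - 0.64) * z
        v = vif(np.column_stack([a, b]), ["a", "b"])
        assert v["a"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)
        assert v["b"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)

    def test_duplicated_column_reports_infinity(self, rng):
        x = rng.normal(size=30)
        v = vif(np.column_stack([x, x]), ["a", "b"])
        assert np.isinf(v["a"]) and np.isinf(v["b"])


class TestRegionalBackgroundVariable:
    def _sites(self):
        return pd.DataFrame({
            "site_id": ["s1", "s2", "s3", "t1", "t2", "t3"],
            "area_code": ["A", "A", "A", "B", "B", "B"],
            "region": ["north"] * 6,
            "site_type": ["street", "regional_background", "regional_background",
                          "street", "urban_background", "regional_background"],
            "x": 0.0, "y": 0.0,
        })

    def test_mean_of_background_sites_broadcast(self):
        sites = self._sites()
        annual = pd.Series([30.0, 10.0, 14.0, 25.0, 20.0, 12.0], index=sites["site_id"])
        col = regional_background_variable(annual, sites)
        assert (col.loc[["s1", "s2", "s3"]] == 12.0).all()
        assert (col.loc[["t1", "t2", "t3"]] == 12.0).all()

    def test_constant_within_every_area(self, small_campaign):
        col = regional_background_variable(small_campaign.annual, small_campaign.study.sites)
        areas = small_campaign.study.sites.set_index("site_id")["area_code"]
        assert (col.groupby(areas).nunique() == 1).all()
        # group-by oracle
        sites = small_campaign.study.sites
        rb = sites[sites["site_type"] == "regional_background"]
        for area, grp in rb.groupby("area_code"):
            expected = small_campaign.annual.loc[grp["site_id"]].mean()
            one_site = sites.loc[sites["area_code"] == area, "site_id"].iloc[0]
            assert col[one_site] == pytest.approx(expected, rel=1e-12)

    def test_area_without_background_sites_named_in_error(self):
        sites = self._sites()
        sites.loc[sites["area_code"] == "B", "site_type"] = "street"
        annual = pd.Series(np.arange(6.0), index=sites["site_id"])
        with pytest.raises(DataError, match="B"):
            regional_background_variable(annual, sites)


def _instance(seed, n=60, k=8):
    """A seeded stepwise instance: 1 forced + k candidates, 3 true effects."""
    rng = np.random.default_rng(seed)
    mix = np.eye(k + 1) + 0.3 * rng.normal(size=(k + 1, k + 1)) / np.sqrt(k + 1)
    X = np.exp(0.6 * rng.normal(size=(n, k + 1)) @ mix.T)
    names = ["forced_bg"] + [f"c{j}" for j in range(k)]
    data = pd.DataFrame(X, columns=names,
                        index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
    true_idx = rng.choice(k, size=3, replace=False)
    signs = rng.choice([-1.0, 1.0], size=3)
    y = 2.0 * X[:, 0] + rng.normal(0, 1.0, size=n)
    defs = [VariableDef("forced_bg", "regional_background", direction="positive", forced=True)]
    for j in range(k):
        where = np.where(true_idx == j)[0]
        if len(where):
            s = signs[where[0]]
            scale = 1.5 / X[:, j + 1].std()
            y = y + s * scale * X[:, j + 1]
            direction = "positive" if s > 0 else "negative"
        else:
            direction = "positive" if rng.uniform() < 0.5 else "negative"
        defs.append(VariableDef(f"c{j}", "other_local", direction=direction))
    return make_table(data, defs), y


class TestSupervisedStepwise:
    def test_no_eligible_gain_keeps_forced_only(self, rng):
        n = 400
        bg = rng.normal(10, 3, size=n)
        data = pd.DataFrame({
            "bg": bg,
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
            "n3": rng.normal(size=n),
        }, index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        defs = [candidate("bg", forced=True), candidate("n1"), candidate("n2"),
                candidate("n3", "negative")]
        y = 2.0 * bg + rng.normal(0, 1, size=n)  # candidates are pure noise
        model = supervised_stepwise(make_table(data, defs), y)
        assert model.names == ["bg"]

    def test_wrong_sign_candidate_never_admitted(self, rng):
        n = 100
        x = rng.normal(size=n)
        data = pd.DataFrame({"bg": rng.normal(10, 2, size=n), "x": x},
                            index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        defs = [candidate("bg", forced=True), candidate("x", "positive")]
        y = 2 * data["bg"].to_numpy() - 5.0 * x  # strong but negative effect
        model = supervised_stepwise(make_table(data, defs), y)
        assert "x" not in model.names

    def test_no_variables_at_all_rejected(self):
        data = pd.DataFrame(index=pd.Index(["a", "b", "c"], name="site_id"))
        with pytest.raises(ConfigurationError):
            supervised_stepwise(PredictorTable(data=data, variables=[]), np.ones(3))

    @pytest.mark.parametrize("seed", range(12))
    def test_selection_path_matches_greedy_oracle(self, seed):
        table, y = _instance(seed)
        model = supervised_stepwise(table, y)
        oracle = greedy_stepwise_oracle(table.data, table.variables, y)
        assert model.selection_path == oracle

    def test_partial_r2_path_non_decreasing(self, small_model):
        cum = [t.cum_r2 for t in small_model.terms]
        assert all(b >= a - 1e-12 for a, b in zip(cum, cum[1:]))
        assert small_model.terms[-1].cum_r2 == pytest.approx(small_model.r2, rel=1e-12)

    def test_emitted_model_satisfies_invariants(self, small_model):
        small_model.validate()
        assert small_model.terms[0].forced
        assert small_model.terms[0].name == "regional_background"

    def test_training_ranges_bracket_training_values(self, small_campaign, small_model):
        frame = small_campaign.dataset.full_frame
        for t in small_model.terms:
            assert t.train_min == frame[t.name].min()
            assert t.train_max == frame[t.name].max()

    def test_city_mode_without_forced_background(self, small_campaign):
        area = small_campaign.dataset.areas[0]
        ids = small_campaign.study.sites.loc[
            small_campaign.study.sites["area_code"] == area, "site_id"]
        sub = small_campaign.dataset.subset_sites(ids)
        sub.background = None
        table, y = sub.design()
        model = supervised_stepwise(table, y)
        assert all(not t.forced for t in model.terms)


class TestPruneByPvalue:
    def test_all_significant_model_unchanged(self, small_campaign, small_model):
        table, y = small_campaign.dataset.design()
        pruned = prune_by_pvalue(small_model, table, y)
        assert pruned.names == small_model.names

    def test_null_term_pvalue_exceeds_alpha_about_90_percent(self):
        # under the null, P(p > 0.1) = 0.9: the pruning step removes a pure
        # noise term in about 90% of campaigns
        over = 0
        n_trials = 400
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=500)
            noise_col = rng.normal(size=500)
            y = 2 * x + rng.normal(size=500)
            fit = fit_ols(y, np.column_stack([x, noise_col]), ["x", "noise"])
            over += fit.pvalues["noise"] > 0.1
        assert over / n_trials == pytest.approx(0.9, abs=0.05)

    def test_forced_terms_exempt_from_pruning(self, rng):
        n = 200
        data = pd.DataFrame({"bg": rng.normal(size=n), "x": rng.normal(size=n)},
                            index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        defs = [candidate("bg", forced=True), candidate("x")]
        y = rng.normal(size=n)  # neither variable matters
        model = supervised_stepwise(make_table(data, defs), y)
        assert "bg" in model.names  # forced survives p-value pruning


class TestEnforceVIF:
    def test_near_duplicate_traffic_variables_resolved(self, rng):
        n = 300
        base = np.exp(rng.normal(size=n))
        dup = base * (1 + 0.01 * rng.normal(size=n))  # VIF far above 3
        other = rng.normal(size=n)
        data = pd.DataFrame({"bg": rng.normal(10, 3, size=n), "t1": base,
                             "t2": dup, "o": other},
                            index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        defs = [candidate("bg", forced=True), candidate("t1"), candidate("t2"),
                candidate("o")]
        y = 2 * data["bg"] + 3 * base + 1.5 * other + rng.normal(size=n)
        model = supervised_stepwise(make_table(data, defs), y)
        assert not {"t1", "t2"} <= set(model.names)  # at most one survivor
        if len(model.terms) >= 2:
            assert max(t.vif for t in model.terms) < 3.0

    def test_single_term_model_trivially_passes(self, rng):
        n = 100
        data = pd.DataFrame({"bg": rng.normal(10, 3, size=n)},
                            index=pd.Index([f"s{i}" for i in range(n)], name="site_id"))
        y = 2 * data["bg"] + rng.normal(size=n)
        model = supervised_stepwise(make_table(data, [candidate("bg", forced=True)]), y)
        enforced = enforce_vif(model, make_table(data, [candidate("bg", forced=True)]), y)
        assert enforced.names == model.names


class TestPredict:
    def test_clamp_to_training_maximum(self, small_campaign, small_model):
        frame = small_campaign.dataset.full_frame.iloc[[0]].copy()
        name = small_model.terms[-1].name
        at_max = frame.copy()
        at_max[name] = small_model.terms[-1].train_max
        beyond = frame.copy()
        beyond[name] = small_model.terms[-1].train_max * 10 + 1
        assert predict(small_model, beyond).iloc[0] == pytest.approx(
            predict(small_model, at_max).iloc[0], rel=1e-12)

    def test_truncation_noop_inside_ranges(self, small_campaign, small_model):
        frame = small_campaign.dataset.full_frame
        a = predict(small_model, frame, truncate=True)
        b = predict(small_model, frame, truncate=False)
        pd.testing.assert_series_equal(a, b)

    def test_refit_identity_on_training_data(self, small_campaign, small_model):
        frame = small_campaign.dataset.full_frame
        pred = predict(small_model, frame)
        obs = small_campaign.annual.reindex(frame.index)
        assert ml.pearson_r2(pred, obs) == pytest.approx(small_model.r2, rel=1e-10)

    def test_missing_column_rejected(self, small_model):
        with pytest.raises(DataError):
            predict(small_model, pd.DataFrame({"nothing": [1.0]}))
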