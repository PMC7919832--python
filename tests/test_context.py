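"""Design construction, VIF, overdispersion, AIC, Wald, Holm, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.outliers_influence import variance_inflation_factor

from finclick.context import (EffectTest, aic_select, build_design,
                              default_predictor_groups, fit_context_model,
                              holm_adjust, overdispersion_ratio,
                              pairwise_contrasts, percent_change, vif,
                              wald_test)
from finclick.glmm import GlmmFit, fit_poisson_glmm


def annot_row(**overrides):
    base = dict(season="spring", time_of_day="morning", training="outside",
                grouping="together", enrichment="none", toys=0, humans=0,
                humans_and_toys=0, new_object=0, live_fish=0,
                unusual_event="none", visitors="none", n_individuals=5,
                date_id="d0", session_id="s0", minute_index=0)
    base.update(overrides)
    return base


def make_tables(rows):
    annot = pd.DataFrame(rows)
    counts = pd.DataFrame({"minute_index": annot.minute_index,
                           "click_count": 100})
    return counts, annot


class TestBuildDesign:
    def test_single_enrichment_indicator(self):
        counts, annot = make_tables([annot_row(enrichment="toys", toys=1)])
        _, _, X, _ = build_design(counts, annot)
        enr = X[[c for c in X.columns if c.startswith("enrichment[")]]
        assert enr.to_numpy().sum() == 1
        assert X["enrichment[toys]"].iloc[0] == 1

    def test_live_fish_rows_dropped(self):
        rows = [annot_row(minute_index=0),
                annot_row(minute_index=1, enrichment="live_fish", live_fish=1)]
        counts, annot = make_tables(rows)
        y, offset, X, groups = build_design(counts, annot)
        assert len(y) == 1

    def test_all_reference_row(self):
        counts, annot = make_tables([annot_row(n_individuals=4)])
        y, offset, X, _ = build_design(counts, annot)
        dummies = X.drop(columns=["intercept", "n_individuals"])
        assert not dummies.to_numpy().any()
        assert offset[0] == pytest.approx(np.log(4))

    def test_unknown_level_names_row(self):
        counts, annot = make_tables([annot_row(minute_index=42,
                                               season="monsoon")])
        with pytest.raises(ValueError, match="42"):
            build_design(counts, annot)


class TestVif:
    def test_orthogonal_columns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"intercept": 1.0,
                          "a": np.tile([1., -1.], 50),
                          "b": np.repeat([1., -1.], 50)})
        out = vif(X)
        assert np.allclose(out.vif, 1.0, atol=1e-9)
        assert not out.flagged.any()

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=60)
        X = pd.DataFrame({"intercept": 1.0, "a": a, "b": a.copy(),
                          "c": rng.normal(size=60)})
        out = vif(X).set_index("column")
        assert np.isinf(out.loc["a", "vif"]) and out.loc["a", "flagged"]
        assert np.isinf(out.loc["b", "vif"])

    def test_known_r2_three_quarters(self):
        # construct column with R^2 = 0.75 against the rest -> VIF = 4
        rng = np.random.default_rng(2)
        n = 20000
        z = rng.normal(size=n)
        e = rng.normal(size=n)
        target = np.sqrt(3.0) * z + e        # var = 4, explained 3 -> R2 .75
        X = pd.DataFrame({"intercept": 1.0, "z": z, "t": target})
        out = vif(X).set_index("column")
        assert out.loc["t", "vif"] == pytest.approx(4.0, rel=0.05)
        assert out.loc["t", "flagged"]

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(200, 4))
        M[:, 3] = 0.7 * M[:, 0] + 0.3 * rng.normal(size=200)
        X = pd.DataFrame(M, columns=list("abcd"))
        X.insert(0, "intercept", 1.0)
        ours = vif(X).vif.to_numpy()
        theirs = [variance_inflation_factor(X.to_numpy(), j)
                  for j in range(1, 5)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)

    def test_too_few_columns_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10), "a": np.arange(10.0)})
        with pytest.raises(ValueError):
            vif(X)


class TestOverdispersion:
    def test_well_specified_near_one(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.normal(size=n)
        mu = np.exp(3 + 0.3 * x)
        y = rng.poisson(mu)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        fit = fit_poisson_glmm(y, X)
        ratio, p = overdispersion_ratio(y, fit.fitted, fit.n_params)
        assert 0.9 <= ratio <= 1.1

    def test_lognormal_extra_variation_flagged(self):
        rng = np.random.default_rng(5)
        n = 3000
        mu = np.exp(3 + rng.normal(0, 0.6, n))
        y = rng.poisson(mu)
        X = pd.DataFrame({"intercept": np.ones(n)})
        fit = fit_poisson_glmm(y, X)
        ratio, p = overdispersion_ratio(y, fit.fitted, fit.n_params)
        assert ratio > 1.5
        assert p < 0.001

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError):
            overdispersion_ratio(np.array([1, 2]), np.array([1.0, 2.0]), 2)


def _fake_fit(aic, n_params, converged=True):
    s = pd.Series([0.0], index=["intercept"])
    return GlmmFit(coef=s, se=s, cov=pd.DataFrame([[1.0]], index=["intercept"],
                                                  columns=["intercept"]),
                   re_sd={}, loglik=-aic / 2, aic=aic, n_params=n_params,
                   converged=converged, n_obs=10, fitted=np.ones(10))


class TestAicSelect:
    def test_lowest_aic_wins(self):
        fits = [_fake_fit(100, 5), _fake_fit(90, 5), _fake_fit(95, 5)]
        assert aic_select(fits).aic == 90

    def test_tie_broken_toward_fewer_parameters(self):
        fits = [_fake_fit(90, 7), _fake_fit(90, 5)]
        assert aic_select(fits).n_params == 5

    def test_no_converged_fit_errors(self):
        with pytest.raises(ValueError):
            aic_select([_fake_fit(90, 5, converged=False)])

    def test_nested_simulation_prefers_true_model(self):
        rng = np.random.default_rng(6)
        n = 10_000
        x = rng.integers(0, 2, n).astype(float)
        y = rng.poisson(np.exp(3 + np.log(2) * x))
        X_full = pd.DataFrame({"intercept": 1.0, "x": x})
        X_null = pd.DataFrame({"intercept": np.ones(n)})
        full = fit_poisson_glmm(y, X_full)
        null = fit_poisson_glmm(y, X_null)
        assert aic_select([full, null]) is full


class TestWald:
    def test_single_coefficient_closed_form(self):
        s = pd.Series([2.0], index=["b"])
        fit = GlmmFit(coef=s, se=pd.Series([1.0], index=["b"]),
                      cov=pd.DataFrame([[1.0]], index=["b"], columns=["b"]),
                      re_sd={}, loglik=0, aic=0, n_params=1, converged=True,
                      n_obs=10, fitted=np.ones(10))
        (t,) = wald_test(fit, {"b": ["b"]})
        assert t.chi2 == pytest.approx(4.0)
        assert t.df == 1
        assert t.p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_coefficient(self):
        s = pd.Series([0.0], index=["b"])
        fit = GlmmFit(coef=s, se=pd.Series([1.0], index=["b"]),
                      cov=pd.DataFrame([[1.0]], index=["b"], columns=["b"]),
                      re_sd={}, loglik=0, aic=0, n_params=1, converged=True,
                      n_obs=10, fitted=np.ones(10))
        (t,) = wald_test(fit, {"b": ["b"]})
        assert t.chi2 == 0.0 and t.p == 1.0

    def test_multi_level_factor_df(self, small_counts):
        counts, annot = small_counts
        fit = fit_context_model(counts, annot,
                                random_effects=("date", "session"))
        groups = default_predictor_groups(fit.coef.to_frame().T)
        tests = {t.predictor: t for t in wald_test(fit, groups)}
        assert tests["season"].df == 3
        assert tests["visitors"].df == 2
        assert tests["grouping"].percent_change is not None


class TestHolm:
    def test_two_pvalues_by_hand(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_never_below_raw(self, ps):
        adj = holm_adjust(ps)
        order = np.argsort(ps, kind="stable")
        sorted_adj = [adj[i] for i in order]
        assert all(a <= b + 1e-15 for a, b in zip(sorted_adj, sorted_adj[1:]))
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        assert all(a <= 1.0 for a in adj)


class TestPercentChange:
    @pytest.mark.parametrize("beta,expected", [
        (np.log(2.36), 136.0), (0.0, 0.0), (np.log(4.12), 312.0),
        (np.log(0.65), -35.0)])
    def test_reference_values(self, beta, expected):
        assert percent_change(beta) == pytest.approx(expected, abs=0.01)

    @given(st.floats(-3, 3))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, beta):
        pc = percent_change(beta)
        assert np.log1p(pc / 100.0) == pytest.approx(beta, abs=1e-9)
        assert (pc >= 0) == (beta >= 0)


class TestPairwiseContrasts:
    def test_season_has_six_pairs(self, small_counts):
        counts, annot = small_counts
        ref = fit_context_model(counts, annot,
                                random_effects=("date", "session"))
        tests, warns = pairwise_contrasts(counts, annot, "season",
                                          random_effects=("date", "session"),
                                          reference_fit=ref)
        assert len(tests) == 6     # C(4, 2)
        for t in tests:
            assert t.p_adjusted is not None and t.p_adjusted >= t.p - 1e-12

    def test_two_level_factor_rejected(self, small_counts):
        counts, annot = small_counts
        with pytest.raises(ValueError):
            pairwise_contrasts(counts, annot, "grouping")
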