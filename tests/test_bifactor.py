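import numpy as np
import pandas as pd
import pytest

import nightvar as nv
from nightvar import bifactor
from nightvar.bifactor import (
    FREE,
    FactorModelSpec,
    aggregate_raters,
    bifactor_spec,
    correlated_spec,
    factor_scores,
    fit_factor_model,
    fit_indices,
    indices_from_chi2,
    model_df,
)
from nightvar.sleep_records import FACETS


class TestAggregateRaters:
    def _persons(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"person_id": [f"p{i}" for i in range(n)]})
        for f in FACETS:
            base = rng.standard_normal(n)
            df[f"{f}_cg"] = 10 * base + rng.standard_normal(n)
            df[f"{f}_yr"] = base + 0.1 * rng.standard_normal(n)
        return df

    def test_mean_of_rater_z_scores(self):
        df = self._persons()
        panel = aggregate_raters(df)
        zc = (df["ad_cg"] - df["ad_cg"].mean()) / df["ad_cg"].std(ddof=1)
        zy = (df["ad_yr"] - df["ad_yr"].mean()) / df["ad_yr"].std(ddof=1)
        agg = (zc + zy) / 2
        expect = (agg - agg.mean()) / agg.std(ddof=1)
        np.testing.assert_allclose(panel["ad"].values, expect.values, atol=1e-12)
        # re-standardized to mean 0, variance 1
        assert panel["ad"].mean() == pytest.approx(0.0, abs=1e-12)
        assert panel["ad"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_missing_rater_uses_available_one(self):
        df = self._persons()
        df.loc[:, "wd_yr"] = np.nan
        panel = aggregate_raters(df)
        zc = (df["wd_cg"] - df["wd_cg"].mean()) / df["wd_cg"].std(ddof=1)
        assert abs(np.corrcoef(panel["wd"], zc)[0, 1]) == pytest.approx(1.0)

    def test_identical_rater_columns_degenerate_agreement(self):
        df = self._persons()
        df["som_yr"] = df["som_cg"]
        panel = aggregate_raters(df)
        assert np.corrcoef(panel["som"], df["som_cg"])[0, 1] == pytest.approx(1.0)

    def test_empty_facet_raises_naming_it(self):
        df = self._persons()
        df["cd_cg"] = np.nan
        df["cd_yr"] = np.nan
        with pytest.raises(ValueError, match="cd"):
            aggregate_raters(df)


class TestModelDf:
    def test_standard_specification(self):
        assert model_df(bifactor_spec()) == 10

    def test_single_factor_model(self):
        spec = FactorModelSpec(
            indicators=FACETS, factors=("g",),
            loadings={(f, "g"): FREE for f in FACETS})
        assert model_df(spec) == 20  # 36 - 8 loadings - 8 residuals

    def test_saturated_covariance_model(self):
        # 8 loadings on one factor + 8 residuals + all 28 residual covs
        pairs = tuple((FACETS[i], FACETS[j]) for i in range(8)
                      for j in range(i + 1, 8))
        spec = FactorModelSpec(
            indicators=FACETS, factors=("g",),
            loadings={(f, "g"): 0.0 for f in FACETS},
            resid_cov=pairs)
        assert model_df(spec) == 0

    def test_overparameterized_raises(self):
        pairs = tuple((FACETS[i], FACETS[j]) for i in range(8)
                      for j in range(i + 1, 8))
        spec = FactorModelSpec(
            indicators=FACETS, factors=("g",),
            loadings={(f, "g"): FREE for f in FACETS},
            resid_cov=pairs)
        with pytest.raises(ValueError, match="over-parameterized"):
            model_df(spec)


class TestFitIndices:
    def test_exact_fit_limits(self):
        cfi, rmsea = indices_from_chi2(10.0, 10, 200.0, 28, 500)
        assert cfi == 1.0 and rmsea == 0.0

    def test_hand_computed_values(self):
        cfi, rmsea = indices_from_chi2(20.0, 10, 200.0, 28, 200)
        assert cfi == pytest.approx(0.9419, abs=1e-4)
        assert rmsea == pytest.approx(0.0707, abs=1e-4)

    def test_df_zero_contract(self):
        assert indices_from_chi2(0.0, 0, 50.0, 28, 100) == (1.0, 0.0)
        with pytest.raises(ZeroDivisionError):
            indices_from_chi2(5.0, 0, 50.0, 28, 100)

    def test_srmr_near_zero_when_model_true_and_n_large(self, cfa2000):
        _, fit = cfa2000
        assert fit_indices(fit)["srmr"] < 0.02


class TestFiml:
    def test_loglik_at_mle_dominates_generating_parameters(self, cohort2000):
        cfg, persons, _, _ = cohort2000
        panel = aggregate_raters(persons)
        fit = bifactor.fit_bifactor_s1(panel, seed=0)
        # generating Sigma from the configured standardized loadings
        Lam = np.zeros((8, 3))
        for i, f in enumerate(FACETS):
            Lam[i, 0] = cfg.lambda_general[f]
        for i, f in enumerate(FACETS):
            if f in ("ad", "wd", "som"):
                Lam[i, 1] = cfg.lambda_specific[f]
            elif f != "eri":
                Lam[i, 2] = cfg.lambda_specific[f]
        Theta = np.diag(1.0 - (Lam ** 2).sum(axis=1))
        Sigma0 = Lam @ Lam.T + Theta
        X = panel.to_numpy()
        patterns = bifactor._pattern_stats(X)
        ll_truth = bifactor._fiml_loglik(np.zeros(8), Sigma0, patterns)
        assert fit.loglik >= ll_truth

    def test_missing_data_fit_close_to_complete_fit(self, cohort2000):
        _, persons, _, _ = cohort2000
        panel = aggregate_raters(persons).iloc[:600].copy()
        full = bifactor.fit_bifactor_s1(panel, seed=0)
        holed = panel.copy()
        rng = np.random.default_rng(3)
        mask = rng.random(holed.shape) < 0.1  # 10% MCAR holes
        holed.values[mask] = np.nan
        fit = bifactor.fit_bifactor_s1(holed, seed=0)
        assert fit.converged
        d = (fit.loadings_table() - full.loadings_table()).abs().max().max()
        assert d < 0.1

    def test_deterministic_given_identical_starts(self, cohort_small):
        _, persons, _ = cohort_small
        panel = aggregate_raters(persons)
        f1 = bifactor.fit_bifactor_s1(panel, seed=4, n_starts=3)
        f2 = bifactor.fit_bifactor_s1(panel, seed=4, n_starts=3)
        np.testing.assert_array_equal(f1.Lambda, f2.Lambda)
        assert f1.loglik == f2.loglik


class TestFactorScores:
    def test_zero_indicators_give_zero_scores(self, cfa2000):
        panel, fit = cfa2000
        zero = pd.DataFrame([np.zeros(8) + fit.mu], columns=list(FACETS))
        s = factor_scores(fit, zero)
        np.testing.assert_allclose(s.values, 0.0, atol=1e-10)

    def test_scores_track_generating_factors(self, cohort2000, cfa2000):
        _, _, _, truth = cohort2000
        panel, fit = cfa2000
        s = factor_scores(fit, panel)
        r = np.corrcoef(s["g"], truth["g"])[0, 1]
        assert r > 0.8

    def test_reference_indicator_only_pattern(self, cfa2000):
        panel, fit = cfa2000
        row = pd.DataFrame([[np.nan] * 7 + [2.0]], columns=list(FACETS))
        s = factor_scores(fit, row)
        assert np.isfinite(s["g"].iloc[0]) and s["g"].iloc[0] > 0
        # specific factors shrink toward 0 given no informative indicator
        assert abs(s["s_int"].iloc[0]) < abs(s["g"].iloc[0])
        assert abs(s["s_ext"].iloc[0]) < abs(s["g"].iloc[0])

    def test_all_missing_person_retained_with_missing_scores(self, cfa2000):
        panel, fit = cfa2000
        rows = pd.DataFrame([[np.nan] * 8, [0.5] * 8], columns=list(FACETS))
        s = factor_scores(fit, rows)
        assert len(s) == 2
        assert s.iloc[0].isna().all() and s.iloc[1].notna().all()


def test_correlated_factor_model_fits(cohort_small):
    _, persons, _ = cohort_small
    panel = aggregate_raters(persons)
    fit = fit_factor_model(panel, correlated_spec(), seed=0)
    assert fit.converged
    # shared general signal induces a positive INT-EXT factor correlation
    assert fit.Phi[0, 1] > 0.2
    s = factor_scores(fit, panel)
    assert np.corrcoef(s.iloc[:, 0], s.iloc[:, 1])[0, 1] > 0.2
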