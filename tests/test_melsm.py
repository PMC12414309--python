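import numpy as np
import pandas as pd
import pytest

import nightvar as nv
from nightvar import bifactor, melsm, pipeline
from nightvar.melsm import (
    McmcConfig,
    MelsmPosterior,
    MelsmSpec,
    converge_and_double,
    credibility_intervals,
    fit_melsm,
    icc,
    psr,
    standardize_effects,
)


def _fit_inputs(n_persons=80, seed=5, **cfg_kw):
    cfg = nv.default_config(n_persons=n_persons, seed=seed, **cfg_kw)
    persons, nights = nv.generate_cohort(cfg)
    panel = bifactor.aggregate_raters(persons)
    fit = bifactor.fit_bifactor_s1(panel, seed=0)
    cov = pipeline.prepare_covariates(persons, bifactor.factor_scores(fit, panel))
    series = pipeline._filtered_series(nights, persons)
    return cfg, series, cov


class TestPsr:
    def test_identical_chains_at_most_one(self):
        assert psr(np.array([[1.0, 2, 3], [1.0, 2, 3]])) <= 1.0

    def test_constant_equal_chains_return_one(self):
        assert psr(np.array([[2.0, 2, 2], [2.0, 2, 2]])) == 1.0

    def test_monotone_in_mean_separation(self):
        close = psr(np.array([[1.0, 2, 3], [1.0, 2, 3]]))
        far = psr(np.array([[1.0, 2, 3], [101.0, 102, 103]]))
        assert far > close and far > 1.0

    def test_hand_computed_value(self):
        # W = 1, chain means (2, 3): B = 3 * 0.5; PSR = sqrt((2/3 + 1/2))
        val = psr(np.array([[1.0, 2, 3], [2.0, 3, 4]]))
        assert val == pytest.approx(np.sqrt(7.0 / 6.0), abs=1e-12)

    def test_long_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 10_000))
        assert psr(chains) == pytest.approx(1.0, abs=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            psr(np.array([[1.0, 2, 3]]))


def _dummy_posterior(values: np.ndarray, labels):
    """Posterior with fixed draws; enough structure for interval tests."""
    return MelsmPosterior(labels=list(labels), draws=values, data=None,
                          spec=MelsmSpec(), config=McmcConfig())


class TestCredibilityIntervals:
    def test_linear_interpolation_quantiles(self):
        draws = np.arange(1.0, 101.0).reshape(2, 50, 1)
        ci = credibility_intervals(_dummy_posterior(draws, ["x"]))
        assert ci.loc["x", "lower"] == pytest.approx(3.475)
        assert ci.loc["x", "upper"] == pytest.approx(97.525)

    def test_significance_flags(self):
        pos = np.abs(np.random.default_rng(0).standard_normal((2, 50, 1))) + 0.1
        sym = np.concatenate([np.linspace(-1, 1, 50)[None, :, None]] * 2)
        assert credibility_intervals(_dummy_posterior(pos, ["x"])).loc["x", "significant"]
        assert not credibility_intervals(
            _dummy_posterior(sym, ["x"])).loc["x", "significant"]

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            credibility_intervals(_dummy_posterior(np.ones((2, 10, 1)), ["x"]))


class TestStandardizedEffects:
    def _posterior(self, b, psi, n=400, seed=0):
        """One-outcome posterior with constant draws b and Psi diag psi."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        data = melsm.MelsmData(
            Y=np.zeros((n, 1, 1)), night=np.zeros((n, 1)),
            weekend=np.zeros((n, 1)),
            X=np.column_stack([np.ones(n), x]),
            person_ids=[str(i) for i in range(n)],
            outcome_labels=("duration",), predictor_labels=("intercept", "x"))
        labels = melsm.parameter_labels(data)
        draws = np.zeros((2, 60, len(labels)))
        draws[:, :, labels.index("alpha_duration~x")] = b
        draws[:, :, labels.index("psi[alpha_duration,alpha_duration]")] = psi
        draws[:, :, labels.index("psi[omega_duration,omega_duration]")] = 1.0
        return MelsmPosterior(labels=labels, draws=draws, data=data,
                              spec=MelsmSpec(outcomes=("duration_min",)),
                              config=McmcConfig()), x

    def test_null_preserved(self):
        post, _ = self._posterior(b=0.0, psi=1.0)
        out = standardize_effects(post, predictors=("x",))
        row = out[(out.outcome == "alpha_duration") & (out.predictor == "x")]
        assert row["beta_median"].iloc[0] == 0.0

    def test_identity_when_sds_match(self):
        # with psi = 0 the outcome SD equals |b| * SD(x), so beta = 1
        post, x = self._posterior(b=1.0, psi=0.0)
        out = standardize_effects(post, predictors=("x",))
        row = out[(out.outcome == "alpha_duration") & (out.predictor == "x")]
        assert row["beta_median"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert row["n_dropped"].iloc[0] == 0


class TestIcc:
    def _nights(self, sd_b, sd_w, n=400, t=12, seed=0):
        rng = np.random.default_rng(seed)
        a = sd_b * rng.standard_normal(n)
        rows = []
        for i in range(n):
            for k in range(t):
                rows.append((f"p{i}", k, 0, a[i] + sd_w * rng.standard_normal(),
                             np.nan, np.nan))
        return pd.DataFrame(rows, columns=list(nv.sleep_records.NIGHT_COLUMNS))

    def test_zero_between_variance(self):
        assert icc(self._nights(0.0, 1.0)) == pytest.approx(0.0, abs=0.02)

    def test_equal_variances_give_half(self):
        assert icc(self._nights(1.0, 1.0)) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_single_night_errors(self):
        df = self._nights(1.0, 1.0, n=5, t=1)
        with pytest.raises(ValueError):
            icc(df)


class TestSampler:
    def test_single_person_is_a_precondition_error(self):
        _, series, cov = _fit_inputs(n_persons=30)
        with pytest.raises(ValueError):
            fit_melsm(series[:1], cov.iloc[:1], MelsmSpec(),
                      McmcConfig(n_iter=50, seed=0))

    def test_seeded_determinism(self):
        _, series, cov = _fit_inputs(n_persons=40)
        p1 = fit_melsm(series, cov, MelsmSpec(), McmcConfig(n_iter=200, seed=7))
        p2 = fit_melsm(series, cov, MelsmSpec(), McmcConfig(n_iter=200, seed=7))
        np.testing.assert_array_equal(p1.draws, p2.draws)

    def test_weekend_effect_recovery(self):
        cfg, series, cov = _fit_inputs(n_persons=120, seed=17)
        post = fit_melsm(series, cov, MelsmSpec(), McmcConfig(n_iter=800, seed=2))
        s = post.summary()
        for k, o in enumerate(("duration", "bedtime", "waketime")):
            row = s.loc[f"gamma_weekend[{o}]"]
            assert abs(row["mean"] - cfg.gamma_weekend[k]) < 4 * row["sd"]

    def test_persons_without_sleep_are_retained(self):
        _, series, cov = _fit_inputs(n_persons=60, seed=19)
        # posterior over between-level coefficients still fits with the
        # invalid-sleep persons present (their nights are all masked)
        post = fit_melsm(series, cov, MelsmSpec(), McmcConfig(n_iter=300, seed=0))
        assert len(post.data.person_ids) == 60


class TestConvergeAndDouble:
    class _Stub:
        def __init__(self, values):
            self.values = values

        def psr_vector(self):
            return pd.Series(self.values)

    def test_report_contains_two_snapshots_and_doubles(self):
        calls = []

        def fit(n_iter):
            calls.append(n_iter)
            # converges once n_iter reaches 400
            return self._Stub({"a": 2.0 if n_iter < 400 else 1.01})

        post, report = converge_and_double(fit, McmcConfig(n_iter=100))
        assert calls == [100, 200, 400, 800]
        assert report["iters_converged"] == 400
        assert report["iters_final"] == 800
        assert set(report) >= {"psr_first", "psr_doubled"}

    def test_cap_reached_names_worst_parameter(self):
        def fit(n_iter):
            return self._Stub({"bad_param": 3.0, "fine": 1.0})

        with pytest.raises(melsm.McmcError, match="bad_param"):
            converge_and_double(fit, McmcConfig(n_iter=100, max_iter=400))

    def test_stable_on_real_model(self):
        _, series, cov = _fit_inputs(n_persons=60, seed=23)
        data = melsm.build_design(series, cov, ("duration_min",))
        spec = MelsmSpec(outcomes=("duration_min",))

        def fit(n_iter):
            return melsm._fit_melsm_data(data, spec,
                                         McmcConfig(n_iter=n_iter, seed=3))

        post, report = converge_and_double(fit, McmcConfig(n_iter=600, seed=3))
        assert float(report["psr_doubled"].max()) <= \
               float(report["psr_first"].max()) + 0.02
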