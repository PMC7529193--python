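import numpy as np
import pytest

from rvvm import (
    GLMSpec,
    MeasurementRecord,
    NormalPrior,
    PooledPosterior,
    ProtocolSample,
    enumerate_completions,
    fit_generalized_glm,
    make_bernoulli,
    make_categorical,
    make_point_mass,
    sample_completion,
    summarize_glm,
)
from rvvm.glm import build_design, _make_log_post

FAST = dict(n_chains=2, n_warmup=400, n_draws=600)


def _logistic_sample(n, beta0, beta1, rng, n_uncertain=0):
    """Binary-response records with one numeric covariate; optionally the
    last records carry calibrated Bernoulli confidence measures instead of
    their realized response."""
    x = rng.normal(0.0, 1.0, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(float)
    records = []
    for i in range(n):
        if i >= n - n_uncertain:
            measure = make_bernoulli(float(p[i]))  # confidence = true success prob
        else:
            measure = make_point_mass(float(y[i]))
        records.append(MeasurementRecord(i, measure, covariates={"x": float(x[i])}))
    return ProtocolSample(records)


class TestCompletions:
    def test_two_bernoulli_cells_give_four_weighted_completions(self):
        s = ProtocolSample(
            [
                MeasurementRecord(0, make_bernoulli(0.9)),
                MeasurementRecord(1, make_bernoulli(0.5)),
            ]
        )
        comps = enumerate_completions(s, response="y")
        weights = sorted(c.weight for c in comps)
        assert weights == pytest.approx([0.05, 0.05, 0.45, 0.45])
        assert sum(c.weight for c in comps) == pytest.approx(1.0, abs=1e-10)

    def test_all_trivial_sample_has_single_completion(self):
        s = ProtocolSample(
            [MeasurementRecord(i, make_point_mass(v)) for i, v in enumerate([0, 1, 1])]
        )
        (comp,) = enumerate_completions(s, response="y")
        assert comp.weight == 1.0
        assert list(comp.dataset["y"]) == [0, 1, 1]

    def test_categorical_cell_contributes_its_support_size(self):
        s = ProtocolSample(
            [MeasurementRecord(0, make_categorical([0, 1, 2], [0.2, 0.3, 0.5]))]
        )
        assert len(enumerate_completions(s, response="y")) == 3

    def test_blowup_beyond_limit_points_to_monte_carlo(self):
        s = ProtocolSample(
            [MeasurementRecord(i, make_bernoulli(0.5)) for i in range(8)]
        )
        with pytest.raises(ValueError, match="sample_completion"):
            enumerate_completions(s, response="y", limit=100)

    def test_degenerate_cells_realize_deterministically(self, rng):
        s = ProtocolSample(
            [
                MeasurementRecord(0, make_point_mass(3.0)),
                MeasurementRecord(1, make_bernoulli(1.0)),
            ]
        )
        for _ in range(5):
            comp = sample_completion(s, rng, response="y")
            assert list(comp.dataset["y"]) == [3.0, 1.0]

    def test_sampled_completion_frequencies_match_product_measure(self, rng):
        s = ProtocolSample(
            [
                MeasurementRecord(0, make_bernoulli(0.7)),
                MeasurementRecord(1, make_bernoulli(0.2)),
            ]
        )
        n_rep = 4000
        counts = {}
        for _ in range(n_rep):
            comp = sample_completion(s, rng, response="y")
            key = tuple(comp.dataset["y"])
            counts[key] = counts.get(key, 0) + 1
        probs = {(1.0, 0.0): 0.56, (1.0, 1.0): 0.14, (0.0, 0.0): 0.24, (0.0, 1.0): 0.06}
        for key, p in probs.items():
            se = np.sqrt(p * (1 - p) / n_rep)
            assert abs(counts.get(key, 0) / n_rep - p) < 4 * se


class TestDesignMatrix:
    def test_interaction_terms_multiply_columns(self):
        s = ProtocolSample(
            [
                MeasurementRecord(0, make_point_mass(1), {"a": 2.0, "b": 3.0}),
                MeasurementRecord(1, make_point_mass(0), {"a": 1.0, "b": 5.0}),
            ]
        )
        (comp,) = enumerate_completions(s, response="y")
        spec = GLMSpec("logistic", "y", ("a", "b", "a:b"))
        X, y = build_design(comp.dataset, spec)
        assert np.allclose(X, [[1, 2, 3, 6], [1, 1, 5, 5]])
        assert list(y) == [1, 0]

    def test_unknown_covariate_rejected(self):
        s = ProtocolSample([MeasurementRecord(0, make_point_mass(1), {"a": 2.0})])
        (comp,) = enumerate_completions(s, response="y")
        with pytest.raises(ValueError, match="nope"):
            build_design(comp.dataset, GLMSpec("logistic", "y", ("nope",)))


def _quadrature_moments(log_post, b0_grid, b1_grid):
    """Posterior means/sds for a 2-parameter model by dense grid integration."""
    B0, B1 = np.meshgrid(b0_grid, b1_grid, indexing="ij")
    lp = np.array(
        [[log_post(np.array([b0, b1])) for b1 in b1_grid] for b0 in b0_grid]
    )
    w = np.exp(lp - lp.max())
    w /= w.sum()
    mean = np.array([(w * B0).sum(), (w * B1).sum()])
    sd = np.sqrt(
        np.array([(w * (B0 - mean[0]) ** 2).sum(), (w * (B1 - mean[1]) ** 2).sum()])
    )
    return mean, sd


class TestClassicalReductionFit:
    def test_all_trivial_logistic_matches_quadrature(self, rng):
        sample = _logistic_sample(80, 0.4, 1.0, rng)
        spec = GLMSpec("logistic", "y", ("x",))
        post = fit_generalized_glm(sample, spec, mode="exact", rng_seed=5, **FAST)
        assert len(post.completion_weights) == 1

        (comp,) = enumerate_completions(sample, response="y")
        X, y = build_design(comp.dataset, spec)
        log_post = _make_log_post(spec, X, y)
        grid = np.linspace(-2.5, 3.5, 241)
        q_mean, q_sd = _quadrature_moments(log_post, grid, grid)
        # RWM effective sample size is ~ draws/10; allow 4 of those ses
        assert np.all(np.abs(post.mean() - q_mean) < 0.2 * q_sd)
        assert np.all(np.abs(post.sd() - q_sd) < 0.2 * q_sd)

    def test_all_trivial_linear_matches_least_squares(self, rng):
        import statsmodels.api as sm

        n = 120
        x = rng.normal(size=n)
        y = 2.0 + 1.5 * x + rng.normal(scale=1.0, size=n)
        records = [
            MeasurementRecord(i, make_point_mass(float(y[i])), {"x": float(x[i])})
            for i in range(n)
        ]
        spec = GLMSpec("linear", "y", ("x",))
        post = fit_generalized_glm(
            ProtocolSample(records), spec, mode="exact", rng_seed=7, **FAST
        )
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        # with weak priors the posterior tracks OLS within its standard errors
        assert abs(post.mean()[0] - ols.params[0]) < 3 * ols.bse[0]
        assert abs(post.mean()[1] - ols.params[1]) < 3 * ols.bse[1]
        sigma_hat = np.sqrt(ols.mse_resid)
        assert abs(post.mean()[2] - sigma_hat) < 0.3 * sigma_hat


class TestPooling:
    def test_exact_and_mc_pooling_agree(self, rng):
        sample = _logistic_sample(60, 0.2, 0.8, rng, n_uncertain=3)
        spec = GLMSpec("logistic", "y", ("x",))
        exact = fit_generalized_glm(sample, spec, mode="exact", rng_seed=11, **FAST)
        mc = fit_generalized_glm(sample, spec, mode="mc", K=500, rng_seed=13, **FAST)
        assert len(exact.completion_weights) == 8
        sd = exact.sd()
        assert np.all(np.abs(exact.mean() - mc.mean()) < 0.25 * sd)

    def test_parameter_recovery_on_calibrated_data(self, rng):
        beta0, beta1 = 0.3, 1.0
        sample = _logistic_sample(150, beta0, beta1, rng, n_uncertain=4)
        spec = GLMSpec("logistic", "y", ("x",))
        post = fit_generalized_glm(sample, spec, mode="exact", rng_seed=17, **FAST)
        mean, sd = post.mean(), post.sd()
        assert abs(mean[0] - beta0) < 2 * sd[0]
        assert abs(mean[1] - beta1) < 2 * sd[1]

    def test_uncertain_records_inflate_posterior_dispersion(self, rng):
        # same realized data, once fully observed and once with confidence cells
        sample_rvvm = _logistic_sample(60, 0.2, 0.8, rng, n_uncertain=3)
        truth_records = []
        rng2 = np.random.default_rng(99)
        for r in sample_rvvm.records:
            if r.measure.is_point_mass:
                truth_records.append(r)
            else:
                y = float(rng2.random() < r.measure.prob_of(1.0))
                truth_records.append(
                    MeasurementRecord(r.unit_id, make_point_mass(y), r.covariates)
                )
        spec = GLMSpec("logistic", "y", ("x",))
        post_rvvm = fit_generalized_glm(sample_rvvm, spec, mode="exact", rng_seed=3, **FAST)
        post_truth = fit_generalized_glm(
            ProtocolSample(truth_records), spec, mode="exact", rng_seed=3, **FAST
        )
        # pooled-over-completions sd should not be materially tighter
        assert np.all(post_rvvm.sd() > 0.85 * post_truth.sd())

    def test_partial_information_retains_unobserved_subgroup(self):
        """Definitively sexed juveniles all female, yet completions keep
        positive mass on male juveniles — impossible under discard/impute."""
        records = [
            MeasurementRecord(0, make_point_mass(1), {"age": 0.0}),
            MeasurementRecord(1, make_point_mass(1), {"age": 0.0}),
            MeasurementRecord(2, make_bernoulli(0.7), {"age": 0.0}),
            MeasurementRecord(3, make_point_mass(0), {"age": 1.0}),
            MeasurementRecord(4, make_point_mass(1), {"age": 1.0}),
        ]
        comps = enumerate_completions(ProtocolSample(records), response="sex")
        male_juv_mass = sum(
            c.weight
            for c in comps
            if ((c.dataset["sex"] == 0) & (c.dataset["age"] == 0)).any()
        )
        assert male_juv_mass == pytest.approx(0.3)
        discard = ProtocolSample([r for r in records if r.measure.is_point_mass])
        (comp2,) = enumerate_completions(discard, response="sex")
        assert not ((comp2.dataset["sex"] == 0) & (comp2.dataset["age"] == 0)).any()


class TestSummaries:
    def _null_posterior(self, draws):
        spec = GLMSpec("logistic", "y", ("x",))
        return PooledPosterior(
            draws=draws,
            parameter_names=spec.parameter_names,
            completion_index=np.zeros(len(draws), dtype=int),
            completion_weights=np.array([1.0]),
            family="logistic",
            spec=spec,
        )

    def test_null_model_odds_are_one(self):
        post = self._null_posterior(np.zeros((10, 2)))
        table = summarize_glm(post, odds_at={"anyone": {"x": 3.0}})
        assert table.loc["odds @ anyone", "mean"] == pytest.approx(1.0)

    def test_intercept_log_two_gives_odds_two(self):
        draws = np.column_stack([np.full(5, np.log(2.0)), np.zeros(5)])
        post = self._null_posterior(draws)
        table = summarize_glm(post, odds_at={"base": {"x": 0.0}})
        assert table.loc["odds @ base", "mean"] == pytest.approx(2.0)

    def test_linear_fitted_mean(self):
        spec = GLMSpec("linear", "wc", ("sex",))
        draws = np.tile([10.0, 1.0, 0.5], (6, 1))
        post = PooledPosterior(
            draws=draws,
            parameter_names=spec.parameter_names,
            completion_index=np.zeros(6, dtype=int),
            completion_weights=np.array([1.0]),
            family="linear",
            spec=spec,
        )
        table = summarize_glm(post, odds_at={"female": {"sex": 1.0}})
        assert table.loc["fitted mean @ female", "mean"] == pytest.approx(11.0)

    def test_missing_setting_value_rejected(self):
        post = self._null_posterior(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="x"):
            summarize_glm(post, odds_at={"bad": {}})
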