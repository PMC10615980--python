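"""Probability kernel, likelihood, priors and identification constraints."""

import numpy as np
import pytest

import raterdrift as rd
from raterdrift.data import DimensionMismatchError, InvalidParameterError
from raterdrift.model import (
    category_probabilities,
    baseline_category_probabilities,
    constrain_steps,
    log_likelihood,
    log_posterior,
    log_prior,
    unconstrain_steps,
)

LOG_2PI = np.log(2 * np.pi)


def params_for(data, theta=None, beta=None, sigma=None, d=None):
    theta = np.zeros(data.J) if theta is None else theta
    beta = np.zeros((data.R, data.T)) if beta is None else beta
    sigma = np.ones(data.R) if sigma is None else sigma
    d = np.zeros((data.R, data.K)) if d is None else d
    return rd.ParameterSet(theta, beta, sigma, d)


class TestCategoryProbabilities:
    def test_zero_parameters_give_uniform_categories(self):
        p = category_probabilities(0.0, 0.0, np.zeros(5))
        np.testing.assert_allclose(p, 0.2, atol=1e-15)

    def test_depends_only_on_ability_minus_severity(self):
        d = np.array([0.0, -0.3, 0.8, 0.1, -0.6])
        base = category_probabilities(0.0, 0.0, d)
        for c in (-2.0, 0.7, 3.5):
            np.testing.assert_allclose(
                category_probabilities(c, c, d), base, atol=1e-14
            )

    def test_two_categories_collapse_to_logistic(self):
        p = category_probabilities(1.0, 0.0, np.zeros(2), D=1.7)
        assert abs(p[1] - 1.0 / (1.0 + np.exp(-1.7))) < 1e-12

    def test_normalization_over_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            K = rng.integers(2, 8)
            d = constrain_steps(rng.standard_normal(max(K - 2, 0)) * 2)
            p = category_probabilities(
                rng.normal(scale=3), rng.normal(scale=3), d
            )
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p > 0)

    def test_expected_score_monotone_in_ability_and_severity(self):
        d = constrain_steps(np.array([-0.8, -0.2, 0.3]))
        grid = np.linspace(-4, 4, 33)
        scores = np.arange(1, 6)
        exp_theta = [category_probabilities(t, 0.0, d) @ scores for t in grid]
        exp_beta = [category_probabilities(0.0, b, d) @ scores for b in grid]
        assert np.all(np.diff(exp_theta) > 0)
        assert np.all(np.diff(exp_beta) < 0)

    def test_extreme_logits_stay_finite_and_normalised(self):
        p = category_probabilities(40.0, -40.0, np.zeros(5))
        assert np.isfinite(p).all() and abs(p.sum() - 1.0) < 1e-12

    def test_nonfinite_input_raises(self):
        with pytest.raises(InvalidParameterError):
            category_probabilities(np.nan, 0.0, np.zeros(5))

    def test_nonzero_first_step_raises(self):
        with pytest.raises(InvalidParameterError):
            category_probabilities(0.0, 0.0, np.array([0.5, -0.5]))

    def test_shared_step_kernel_matches_rater_specific_kernel(self):
        d = constrain_steps(np.array([0.4, -0.9, 0.2]))
        np.testing.assert_array_equal(
            baseline_category_probabilities(0.3, -0.2, d),
            category_probabilities(0.3, -0.2, d),
        )


class TestStepConstraints:
    def test_constrain_example(self):
        np.testing.assert_allclose(
            constrain_steps([-0.8, -0.2, 0.3]), [0.0, -0.8, -0.2, 0.3, 0.7]
        )

    def test_zero_free_coordinates_give_zero_steps(self):
        np.testing.assert_array_equal(constrain_steps([0, 0, 0]), np.zeros(5))

    def test_round_trip_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            free = rng.standard_normal(rng.integers(0, 6))
            d = constrain_steps(free)
            assert d[0] == 0.0 and abs(d[1:].sum()) < 1e-12
            np.testing.assert_allclose(unconstrain_steps(d), free, atol=1e-14)

    def test_two_categories_have_no_free_coordinates(self):
        np.testing.assert_array_equal(constrain_steps([]), [0.0, 0.0])


class TestLogLikelihood:
    def test_empty_dataset_gives_zero(self):
        data = rd.RatingDataset([], [], [], [], J=3, R=2, T=2, K=5)
        assert log_likelihood(data, params_for(data)) == 0.0

    def test_single_uniform_observation(self):
        data = rd.RatingDataset([1], [1], [1], [3], J=1, R=1, T=1, K=5)
        assert abs(log_likelihood(data, params_for(data)) - np.log(0.2)) < 1e-12

    def test_additive_in_observations(self, tiny_data):
        truth = rd.draw_parameters(6, 3, 2, seed=11)
        total = log_likelihood(tiny_data, truth)
        parts = 0.0
        for i in range(tiny_data.n_obs):
            sub = rd.RatingDataset(
                tiny_data.examinee[i : i + 1], tiny_data.rater[i : i + 1],
                tiny_data.time[i : i + 1], tiny_data.score[i : i + 1],
                J=tiny_data.J, R=tiny_data.R, T=tiny_data.T, K=tiny_data.K,
            )
            parts += log_likelihood(sub, truth)
        assert abs(total - parts) < 1e-10

    def test_dimension_mismatch_names_axis(self, tiny_data):
        bad = rd.draw_parameters(6, 3, 2, seed=11)
        bad = rd.ParameterSet(bad.theta[:-1], bad.beta, bad.sigma, bad.d)
        with pytest.raises(DimensionMismatchError, match="examinee"):
            log_likelihood(tiny_data, bad)

    def test_matches_arbitrary_precision_oracle(self):
        # 5 observations evaluated with sympy at 50 digits
        sympy = pytest.importorskip("sympy")
        data = rd.RatingDataset(
            [1, 2, 3, 1, 2], [1, 1, 2, 2, 2], [1, 2, 1, 2, 1],
            [1, 3, 5, 2, 4], J=3, R=2, T=2, K=5,
        )
        rng = np.random.default_rng(8)
        truth = rd.draw_parameters(3, 2, 2, seed=8)
        expected = sympy.Float(0, 50)
        D = sympy.Rational(17, 10)
        for i in range(5):
            j, r, t, k = (
                data.examinee[i] - 1, data.rater[i] - 1,
                data.time[i] - 1, data.score[i],
            )
            x = sympy.Float(truth.theta[j], 50) - sympy.Float(truth.beta[r, t], 50)
            terms = []
            for l in range(1, 6):
                s = sympy.Float(0, 50)
                for m in range(l):
                    s += D * (x - sympy.Float(truth.d[r, m], 50))
                terms.append(sympy.exp(s))
            expected += sympy.log(terms[k - 1] / sum(terms))
        ours = log_likelihood(data, truth)
        assert abs(ours - float(expected.evalf(30))) < 1e-10

    def test_proposed_with_equal_step_rows_nests_baseline(self, tiny_data):
        truth = rd.draw_parameters(6, 3, 2, seed=11)
        shared = truth.d[0]
        nested = rd.ParameterSet(
            truth.theta, truth.beta, truth.sigma,
            np.tile(shared, (3, 1)),
        )
        base = rd.BaselineParameterSet(truth.theta, truth.beta, shared)
        assert log_likelihood(tiny_data, nested) == log_likelihood(tiny_data, base)


class TestLogPrior:
    def _chain_only(self, beta, sigma=1.0, T=None):
        beta = np.atleast_2d(np.asarray(beta, dtype=float))
        return rd.ParameterSet(
            np.empty(0), beta, np.array([sigma]), np.zeros((1, 2))
        )

    def test_markov_increment_term(self):
        # difference between T=2 and T=1 isolates one N(0 | 0, 1) step
        with_step = log_prior(self._chain_only([[0.0, 0.0]]))
        without = log_prior(self._chain_only([[0.0]]))
        assert abs((with_step - without) - (-0.5 * LOG_2PI)) < 1e-12

    def test_each_examinee_adds_standard_normal_density(self):
        base = self._chain_only([[0.0, 0.0]])
        plus = rd.ParameterSet(
            np.zeros(1), base.beta, base.sigma, base.d
        )
        assert abs(
            (log_prior(plus) - log_prior(base)) - (-0.5 * LOG_2PI)
        ) < 1e-12

    def test_zero_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            rd.ParameterSet(np.zeros(1), [[0.0, 0.0]], [0.0], np.zeros((1, 2)))

    def test_sigma_scale_matches_lognormal(self):
        from scipy import stats

        a = self._chain_only([[0.0]], sigma=0.5)
        b = self._chain_only([[0.0]], sigma=2.0)
        expected = (
            stats.lognorm.logpdf(0.5, s=1.0, scale=np.exp(-2.0))
            - stats.lognorm.logpdf(2.0, s=1.0, scale=np.exp(-2.0))
        )
        assert abs((log_prior(a) - log_prior(b)) - expected) < 1e-12


class TestLogPosterior:
    def test_equals_likelihood_plus_prior(self, tiny_data):
        truth = rd.draw_parameters(6, 3, 2, seed=11)
        assert abs(
            log_posterior(tiny_data, truth)
            - (log_likelihood(tiny_data, truth) + log_prior(truth))
        ) < 1e-12

    def test_empty_dataset_reduces_to_prior(self):
        data = rd.RatingDataset([], [], [], [], J=2, R=2, T=3, K=5)
        truth = rd.draw_parameters(2, 2, 3, seed=4)
        assert log_posterior(data, truth) == log_prior(truth)

    def test_finite_over_random_parameter_sweep(self, tiny_data):
        from raterdrift._density import PosteriorDensity

        dens = PosteriorDensity(tiny_data)
        rng = np.random.default_rng(3)
        vals = [
            dens.logp(rng.standard_normal(dens.n_params) * 2.0)
            for _ in range(10_000)
        ]
        assert np.all(np.isfinite(vals))


class TestSerialization:
    def test_parameter_set_json_round_trip(self, tmp_path):
        truth = rd.draw_parameters(4, 3, 2, seed=9)
        path = tmp_path / "params.json"
        truth.to_json(path)
        back = rd.ParameterSet.from_json(path)
        for name in ("theta", "beta", "sigma", "d"):
            np.testing.assert_allclose(
                getattr(back, name), getattr(truth, name), atol=1e-15
            )

    def test_dataset_csv_round_trip(self, tmp_path, tiny_data):
        path = tmp_path / "scores.csv"
        tiny_data.to_csv(path)
        assert path.read_text().splitlines()[0] == "examinee,rater,time,score"
        back = rd.RatingDataset.from_csv(path, K=tiny_data.K)
        np.testing.assert_array_equal(back.score, tiny_data.score)

    def test_out_of_range_score_is_rejected_not_clamped(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("examinee,rater,time,score\n1,1,1,9\n")
        with pytest.raises(ValueError, match="score"):
            rd.RatingDataset.from_csv(path, K=5)

    def test_duplicate_triple_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            rd.RatingDataset([1, 1], [1, 1], [1, 1], [2, 3], J=1, R=1, T=1, K=5)
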