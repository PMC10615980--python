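"""Sampler correctness, EAP estimates and convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

import raterdrift as rd
from raterdrift._density import PosteriorDensity
from raterdrift.inference import convergence_summary, eap, ess, rhat


class TestPosteriorDensity:
    def test_matches_reference_log_posterior(self, tiny_data):
        """Sampler density == readable model density + log-scale Jacobian."""
        dens = PosteriorDensity(tiny_data, "proposed")
        rng = np.random.default_rng(1)
        for _ in range(20):
            truth = rd.draw_parameters(6, 3, 2, seed=rng.integers(2**31))
            z = dens.pack(truth)
            expected = rd.log_posterior(tiny_data, truth) + np.log(truth.sigma).sum()
            assert abs(dens.logp(z) - expected) < 1e-6

    @pytest.mark.parametrize("variant", rd.VARIANTS)
    def test_gradient_matches_finite_differences(self, tiny_data, variant):
        dens = PosteriorDensity(tiny_data, variant)
        rng = np.random.default_rng(2)
        z = rng.standard_normal(dens.n_params)
        _, grad = dens.logp_grad(z)
        h = 1e-6
        for i in rng.choice(dens.n_params, size=8, replace=False):
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            fd = (dens.logp(zp) - dens.logp(zm)) / (2 * h)
            assert abs(grad[i] - fd) < 1e-4 * max(1.0, abs(fd))

    def test_pack_unpack_round_trip(self, tiny_data):
        dens = PosteriorDensity(tiny_data, "proposed")
        truth = rd.draw_parameters(6, 3, 2, seed=0)
        back = dens.unpack(dens.pack(truth))
        np.testing.assert_allclose(back.beta, truth.beta, atol=1e-14)
        np.testing.assert_allclose(back.sigma, truth.sigma, atol=1e-14)
        np.testing.assert_allclose(back.d, truth.d, atol=1e-14)

    def test_likelihood_temperature_scales_only_likelihood(self, tiny_data):
        cold = PosteriorDensity(tiny_data, "proposed", temper=0.25)
        full = PosteriorDensity(tiny_data, "proposed", temper=1.0)
        truth = rd.draw_parameters(6, 3, 2, seed=3)
        z = full.pack(truth)
        ll = rd.log_likelihood(tiny_data, truth)
        assert abs((full.logp(z) - cold.logp(z)) - 0.75 * ll) < 1e-8


class TestFit:
    def test_prior_only_posterior_recovers_standard_normal(self):
        """With no data the marginal posterior of theta_1 is its prior."""
        empty = rd.RatingDataset([], [], [], [], J=2, R=1, T=2, K=5)
        draws = rd.fit(empty, "proposed", config=rd.SamplerConfig(seed=5))
        th = draws.theta().reshape(-1, 2)[:, 0]
        assert th.size == 9000
        _, pvalue = stats.kstest(th, "norm")
        assert pvalue > 0.01

    def test_single_observation_still_returns_draws(self):
        data = rd.RatingDataset([1], [1], [1], [4], J=1, R=1, T=1, K=5)
        draws = rd.fit(
            data, "proposed",
            config=rd.SamplerConfig(chains=2, iterations=300, warmup=150, seed=1),
        )
        assert draws.z.shape == (2, 150, draws.density.n_params)
        assert np.isfinite(draws.z).all()

    def test_fit_is_deterministic_given_seed(self, tiny_data):
        cfg = rd.SamplerConfig(chains=2, iterations=300, warmup=150, seed=9)
        a = rd.fit(tiny_data, "proposed", config=cfg)
        b = rd.fit(tiny_data, "proposed", config=cfg)
        np.testing.assert_array_equal(a.z, b.z)

    def test_unknown_variant_rejected(self, tiny_data):
        with pytest.raises(ValueError, match="variant"):
            rd.fit(tiny_data, "markov_proposed")

    def test_sigma_draws_positive(self, small_study):
        _, _, draws = small_study
        assert np.all(draws.sigma() > 0)


class TestEap:
    def test_mean_of_draws(self, small_study):
        _, _, draws = small_study
        est = eap(draws)
        np.testing.assert_allclose(
            est.theta, draws.theta().mean(axis=(0, 1)), atol=1e-12
        )

    def test_satisfies_identification_constraints(self, small_study):
        _, _, draws = small_study
        est = eap(draws)
        assert np.all(est.d[:, 0] == 0)
        np.testing.assert_allclose(est.d[:, 1:].sum(axis=1), 0, atol=1e-12)

    def test_constant_draws_give_that_constant(self, small_study):
        _, _, draws = small_study
        import copy

        frozen = copy.copy(draws)
        frozen.z = np.broadcast_to(
            draws.z[0, 0], draws.z.shape
        ).copy()
        est = eap(frozen)
        ref = draws.density.unpack(draws.z[0, 0])
        np.testing.assert_allclose(est.theta, ref.theta, atol=1e-14)
        np.testing.assert_allclose(est.sigma, ref.sigma, atol=1e-14)

    def test_shrinks_towards_truth(self, small_study):
        truth, _, draws = small_study
        est = eap(draws)
        assert np.corrcoef(est.theta, truth.theta)[0, 1] > 0.7

    def test_ability_recovery_on_reference_fit(self, reference_fit):
        """EAP abilities track the generating abilities closely on the
        full-budget crossed fit."""
        truth, _, draws = reference_fit
        est = eap(draws)
        assert np.corrcoef(est.theta, truth.theta)[0, 1] > 0.85


class TestRhat:
    def test_long_iid_chains_near_one(self):
        rng = np.random.default_rng(10)
        value = rhat(rng.standard_normal((2, 10_000)))
        assert abs(value - 1.0) < 0.01

    def test_disjoint_constant_chains_flag_infinity(self):
        assert rhat(np.array([[1.0, 1, 1, 1], [2.0, 2, 2, 2]])) == np.inf

    def test_matches_hand_coded_split_formula_on_eight_numbers(self):
        arr = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        sp = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0], [3.0, 4.0]])
        w = sp.var(axis=1, ddof=1).mean()
        b = 2 * sp.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((2 - 1) / 2 * w + b / 2) / w)
        assert abs(rhat(arr) - expected) < 1e-12

    def test_requires_multiple_chains(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestEss:
    def test_iid_draws_near_total(self):
        rng = np.random.default_rng(11)
        value = ess(rng.standard_normal((3, 3000)))
        assert 8000 <= value <= 10_000

    def test_autocorrelated_draws_much_smaller(self):
        rng = np.random.default_rng(12)
        chains = np.empty((3, 3000))
        for c in range(3):
            e = rng.standard_normal(3000)
            chains[c, 0] = e[0]
            for i in range(1, 3000):
                chains[c, i] = 0.9 * chains[c, i - 1] + e[i]
        assert ess(chains) < 9000 / 5

    def test_constant_chains_flag_zero(self):
        assert ess(np.ones((2, 100))) == 0.0


class TestDiagnostics:
    def test_summary_consistent_with_per_parameter_loop(self, small_study):
        _, _, draws = small_study
        report = rd.diagnostics(draws)
        summary = convergence_summary(draws)
        assert abs(report.max_rhat - summary["rhat_max"]) < 1e-8
        assert abs(report.min_ess - summary["ess_min"]) < 1e-6
        assert report.divergent_count == summary["divergence_count"]

    def test_divergence_fraction_of_retained_transitions(self, small_study):
        _, _, draws = small_study
        assert 0 <= draws.divergence_fraction <= 1
        assert draws.divergence_count == draws.divergences.sum()


class TestShrinkage:
    def test_tight_drift_prior_smooths_severity_trajectories(self):
        """A skewed drift-scale prior yields flatter severity estimates
        than the i.i.d.-severity ablation on the same sparse data."""
        truth = rd.draw_parameters(60, 5, 4, seed=21)
        design = rd.systematic_link_design(60, 5, 2, 4, seed=22)
        data = rd.simulate_scores(truth, design, seed=23)
        cfg = rd.SamplerConfig(chains=2, iterations=1000, warmup=500, seed=24)
        entries = rd.prior_sensitivity_sweep(
            data, mu_values=[-5.0], config=cfg, include_no_markov=True
        )
        from raterdrift.experiments import mean_adjacent_change

        tight = next(e for e in entries if e.mu_sigma == -5.0)
        loose = next(e for e in entries if e.label == "no_markov")
        assert tight.data_hash == loose.data_hash
        assert (
            mean_adjacent_change(tight.beta_hat)
            < mean_adjacent_change(loose.beta_hat)
        )
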