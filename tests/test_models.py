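"""Transition matrix, transition sampling, and the four observation channels."""

import itertools

import numpy as np
import pytest

import pobds
from pobds.models import (
    BernoulliObs,
    GaussianObs,
    NegBinomialObs,
    PoissonObs,
    build_transition_matrix,
    loglik_all_states,
    obs_loglik,
    observation_model_from_config,
    sample_observation,
    sample_transition,
)
from pobds.network import StateIndexCodec, parse_boolnet

from .oracles import ref_obs_loglik, ref_transition_matrix, random_network, random_obs_model

IDENTITY2 = parse_boolnet("targets, factors\nA, A\nB, B")


class TestTransitionMatrix:
    def test_columns_sum_to_one_for_various_p(self):
        rng = np.random.default_rng(3)
        for d in (1, 2, 3, 4):
            net = random_network(d, rng)
            for p in (0.0, 0.01, 0.2, 0.5):
                M = build_transition_matrix(net, p).M
                np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)

    def test_p_zero_is_deterministic_map(self):
        rng = np.random.default_rng(4)
        net = random_network(3, rng)
        M = build_transition_matrix(net, 0.0).M
        assert set(np.unique(M)) <= {0.0, 1.0}
        assert np.all(M.sum(axis=0) == 1)

    def test_p_half_is_uniform(self):
        net = random_network(2, np.random.default_rng(5))
        M = build_transition_matrix(net, 0.5).M
        np.testing.assert_allclose(M, 0.25)

    def test_identity_network_hamming_structure(self):
        # d=2, f=identity, p=0.1: stay 0.81, one flip 0.09, two flips 0.01
        M = build_transition_matrix(IDENTITY2, 0.1).M
        np.testing.assert_allclose(np.diag(M), 0.81)
        assert M[0, 3] == pytest.approx(0.01)
        assert M[0, 1] == pytest.approx(0.09)

    def test_matches_first_principles_construction(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            net = random_network(3, rng)
            p = float(rng.uniform(0.01, 0.4))
            np.testing.assert_allclose(build_transition_matrix(net, p).M,
                                       ref_transition_matrix(net, p), atol=1e-14)

    def test_gene_permutation_conjugates_matrix(self):
        """Relabeling genes permutes states; M must commute with that permutation."""
        net = parse_boolnet("targets, factors\nA, !B\nB, A & B")
        swapped = parse_boolnet("targets, factors\nB, A & B\nA, !B")  # genes reordered
        p = 0.07
        M = build_transition_matrix(net, p).M
        Ms = build_transition_matrix(swapped, p).M
        # state permutation induced by swapping the two bits
        perm = [0b00, 0b10, 0b01, 0b11]
        P = np.eye(4)[perm]
        np.testing.assert_allclose(Ms, P @ M @ P.T, atol=1e-14)

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            build_transition_matrix(IDENTITY2, 0.6)


class TestSampleTransition:
    def test_p_zero_always_network_step(self, rng):
        net = random_network(3, rng)
        x = np.array([1, 0, 1])
        for _ in range(20):
            np.testing.assert_array_equal(sample_transition(net, 0.0, x, rng),
                                          pobds.network_step(net, x))

    def test_tiny_p_rarely_flips(self, rng):
        net = IDENTITY2
        x = np.array([1, 0])
        hits = sum(np.array_equal(sample_transition(net, 1e-9, x, rng), x)
                   for _ in range(10_000))
        assert hits >= 9_900

    def test_empirical_frequencies_match_matrix_column(self, rng):
        net = parse_boolnet("targets, factors\nA, !B\nB, A")
        p = 0.15
        codec = StateIndexCodec(2)
        x = codec.decode(2)
        M = build_transition_matrix(net, p).M
        n_draws = 40_000
        counts = np.zeros(4)
        for _ in range(n_draws):
            counts[codec.encode(sample_transition(net, p, x, rng))] += 1
        freq = counts / n_draws
        se = np.sqrt(M[:, 2] * (1 - M[:, 2]) / n_draws)
        assert np.all(np.abs(freq - M[:, 2]) <= 3 * se + 1e-12)


class TestObservationLikelihoods:
    def test_bernoulli_perfect_match(self):
        spec = BernoulliObs(q=0.05)
        x = np.array([1, 0, 1, 0])
        assert obs_loglik(spec, x, x) == pytest.approx(4 * np.log(0.95))

    def test_gaussian_uninformative_is_state_independent(self):
        spec = GaussianObs(mu0=2.0, sigma0=1.5, mu1=2.0, sigma1=1.5)
        y = np.array([0.3, 4.1, -1.0])
        vals = {obs_loglik(spec, y, np.array(x)) for x in itertools.product((0, 1), repeat=3)}
        assert max(vals) - min(vals) < 1e-12

    def test_poisson_mean_and_pmf_against_independent_formula(self):
        spec = PoissonObs(s=10.0, mu=0.5, delta=(1.0,))
        assert spec.mean(0, 1) == pytest.approx(10 * np.exp(1.5))
        y = np.array([7.0])
        for xj in (0, 1):
            x = np.array([xj])
            assert obs_loglik(spec, y, x) == pytest.approx(ref_obs_loglik(spec, y, x), abs=1e-10)

    @pytest.mark.parametrize("kind", ["bernoulli", "gaussian", "poisson", "negbinomial"])
    def test_loglik_matches_reference_on_random_draws(self, kind, rng):
        d = 3
        spec = random_obs_model(kind, d, rng)
        for _ in range(20):
            x = rng.integers(0, 2, size=d)
            y = sample_observation(spec, x, rng)
            assert obs_loglik(spec, y, x) == pytest.approx(ref_obs_loglik(spec, y, x), abs=1e-9)

    def test_loglik_all_states_consistent_with_scalar_version(self, rng):
        d = 3
        states = StateIndexCodec(d).all_states()
        for kind in ("bernoulli", "gaussian", "poisson", "negbinomial"):
            spec = random_obs_model(kind, d, rng)
            y = sample_observation(spec, np.array([1, 0, 1]), rng)
            vec = loglik_all_states(spec, np.asarray(y, dtype=float), states)
            for i, s in enumerate(states):
                assert vec[i] == pytest.approx(obs_loglik(spec, y, s), abs=1e-10)

    def test_bernoulli_mass_normalizes_over_all_y(self):
        spec = BernoulliObs(q=0.2)
        d = 4
        for x in (np.zeros(d, int), np.array([1, 0, 1, 1])):
            total = sum(np.exp(obs_loglik(spec, np.array(y), x))
                        for y in itertools.product((0, 1), repeat=d))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_genes_drop_their_factor(self):
        spec = GaussianObs(1, 2, 5, 2)
        x = np.array([1, 0])
        y = np.array([4.2, np.nan])
        expected = obs_loglik(spec, np.array([4.2]), np.array([1]))
        assert obs_loglik(spec, y, x) == pytest.approx(expected)

    def test_support_validation(self):
        with pytest.raises(ValueError):
            obs_loglik(BernoulliObs(0.1), np.array([0.5, 1.0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            obs_loglik(PoissonObs(10, 0.5, (1.0, 1.0)), np.array([-1.0, 2.0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            obs_loglik(GaussianObs(1, 2, 5, 2), np.array([1.0]), np.array([0, 1]))


class TestObservationSampling:
    def test_bernoulli_q_zero_is_exact(self, rng):
        spec = BernoulliObs(q=0.0)
        x = np.array([1, 0, 1])
        np.testing.assert_array_equal(sample_observation(spec, x, rng), x)

    def test_gaussian_sample_mean_clt_bound(self, rng):
        spec = GaussianObs(1, 2, 5, 2)
        n = 100_000
        draws = np.array([sample_observation(spec, np.array([1]), rng)[0] for _ in range(200)])
        # vectorized equivalent for the bulk of the draws
        bulk = rng.normal(spec.mu1, spec.sigma1, size=n - 200)
        all_draws = np.concatenate([draws, bulk])
        assert abs(all_draws.mean() - spec.mu1) <= 3 * spec.sigma1 / np.sqrt(n)

    def test_negbinomial_large_phi_approaches_poisson_variance(self, rng):
        lam = 10 * np.exp(0.5 + 1.0)  # shared mean
        nb = NegBinomialObs(s=10, mu=0.5, delta=(1.0,), phi=(5e4,))
        draws = np.array([nb.sample_gene_j(0, 1, rng) for _ in range(20_000)])
        assert draws.var() == pytest.approx(lam, rel=0.1)

    def test_moments_match_model(self, rng):
        spec = PoissonObs(s=5, mu=0.2, delta=(1.2, 0.8))
        x = np.array([1, 0])
        draws = np.array([sample_observation(spec, x, rng) for _ in range(20_000)])
        means = [spec.mean(0, 1), spec.mean(1, 0)]
        for j in range(2):
            assert draws[:, j].mean() == pytest.approx(means[j], rel=0.05)


class TestConfigConstruction:
    def test_named_construction(self):
        spec = observation_model_from_config("Bernoulli", {"q": 0.05})
        assert isinstance(spec, BernoulliObs) and spec.q == 0.05
        spec = observation_model_from_config("gaussian", {"mu0": 1, "sigma0": 2, "mu1": 5, "sigma1": 2})
        assert isinstance(spec, GaussianObs)

    def test_unknown_name_and_bad_params(self):
        with pytest.raises(ValueError):
            observation_model_from_config("Weird", {})
        with pytest.raises(ValueError):
            BernoulliObs(q=0.7)
        with pytest.raises(ValueError):
            GaussianObs(1, -2, 5, 2)
        with pytest.raises(ValueError):
            PoissonObs(s=-1, mu=0.5, delta=(1.0,))
        with pytest.raises(ValueError):
            NegBinomialObs(s=1, mu=0.5, delta=(1.0,), phi=(0.0,))
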