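import numpy as np
import pytest

from hmmdyn.hmm import (HMMModel, _forward_backward_logb, _gaussian_logpdf,
                        _initial_params, _pool_cohort, _run_em, decode_cohort,
                        fit_hmm, log_forward_backward, match_states,
                        n_hmm_params, select_model_order, viterbi)
from hmmdyn.validation import _enumerate, _random_instance


def _toy_model(K=2, d=2):
    means = np.array([[-1.0, 0.0], [1.0, 0.5]])[:K]
    covs = np.array([np.eye(d)] * K)
    A = np.array([[0.9, 0.1], [0.3, 0.7]])[:K, :K]
    A = A / A.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    return HMMModel(K, means, covs, A, pi)


class TestForwardBackward:
    def test_single_state_evidence_is_sum_of_log_densities(self, rng):
        d = 3
        model = HMMModel(1, np.zeros((1, d)), np.array([np.eye(d)]),
                         np.array([[1.0]]), np.array([1.0]))
        X = rng.normal(0, 1, (15, d))
        lz, gamma, xi = log_forward_backward(model, X)
        expected = _gaussian_logpdf(X, model.means, model.covariances).sum()
        assert lz == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(gamma, 1.0)

    def test_toy_chain_matches_exhaustive_enumeration(self, rng):
        model = _toy_model()
        X = rng.normal(0, 1, (6, 2))
        lz, gamma, xi = log_forward_backward(model, X)
        ref_lz, _ = _enumerate(model, X)
        assert lz == pytest.approx(ref_lz, abs=1e-8)

    def test_independent_sequences_add_evidence(self, rng):
        model = _toy_model()
        X = rng.normal(0, 1, (10, 2))
        lz, _, _ = log_forward_backward(model, X)
        total = sum(log_forward_backward(model, X)[0] for _ in range(2))
        assert total == pytest.approx(2 * lz, abs=1e-12)

    def test_posterior_normalization_on_random_instances(self, rng):
        for _ in range(25):
            model, X = _random_instance(rng)
            lz, gamma, xi = log_forward_backward(model, X)
            np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
            if len(X) > 1:
                np.testing.assert_allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-10)

    def test_agrees_with_hmmlearn_score(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        for _ in range(10):
            model, X = _random_instance(rng)
            if model.n_states < 2:
                continue
            ref = hmmlearn.GaussianHMM(n_components=model.n_states,
                                       covariance_type="full", init_params="")
            ref.startprob_ = model.initial_dist
            ref.transmat_ = model.transition
            ref.means_ = model.means
            ref.covars_ = model.covariances
            lz, _, _ = log_forward_backward(model, X)
            assert lz == pytest.approx(ref.score(X), abs=1e-8)

    def test_nonfinite_observations_rejected(self):
        model = _toy_model()
        X = np.zeros((5, 2))
        X[2, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            log_forward_backward(model, X)


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        model = HMMModel(1, np.zeros((1, 2)), np.array([np.eye(2)]),
                         np.array([[1.0]]), np.array([1.0]))
        assert (viterbi(model, rng.normal(0, 1, (8, 2))) == 1).all()

    def test_matches_enumerated_argmax(self, rng):
        for _ in range(20):
            model, X = _random_instance(rng)
            _, ref_path = _enumerate(model, X)
            np.testing.assert_array_equal(viterbi(model, X), ref_path)

    def test_sticky_dynamics_dominate_equal_emissions(self):
        # identical emissions in both states: the path is decided purely by
        # the sticky transitions from the forced initial state
        K, d = 2, 2
        means = np.zeros((K, d))
        covs = np.array([np.eye(d)] * K)
        A = np.array([[0.99, 0.01], [0.01, 0.99]])
        pi = np.array([0.0, 1.0])
        model = HMMModel(K, means, covs, A, pi)
        X = np.random.default_rng(1).normal(0, 1, (30, d))
        assert (viterbi(model, X) == 2).all()


class TestFit:
    def test_k1_closed_form(self, k3_syn):
        cohort = k3_syn.cohort
        model, paths = fit_hmm(cohort, 1, n_restarts=1, seed=0, max_iter=50)
        X, _ = _pool_cohort(cohort)
        np.testing.assert_allclose(model.means[0], X.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(X.T, ddof=0)
        ridge = 1e-6 * np.mean(np.diag(ml_cov)) * np.eye(X.shape[1])
        np.testing.assert_allclose(model.covariances[0], ml_cov + ridge, atol=1e-8)
        np.testing.assert_array_equal(model.transition, [[1.0]])
        assert all((p.decoded_path == 1).all() for p in paths)

    def test_same_seed_identical_models(self, k3_syn):
        a, _ = fit_hmm(k3_syn.cohort, 3, n_restarts=2, seed=4, tol=1e-5, max_iter=60)
        b, _ = fit_hmm(k3_syn.cohort, 3, n_restarts=2, seed=4, tol=1e-5, max_iter=60)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.covariances, b.covariances)
        np.testing.assert_array_equal(a.transition, b.transition)
        assert a.log_likelihood == b.log_likelihood

    def test_em_loglik_monotone(self, k3_fit):
        model, _ = k3_fit
        ll = np.asarray(model.fit_meta["ll_history"])
        assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()

    def test_recovers_planted_parameters(self, k3_syn, k3_fit):
        model, _ = k3_fit
        spec = k3_syn.spec
        ref = HMMModel(3, spec.state_means, spec.state_covs,
                       spec.base_transition, spec.initial_dist)
        perm = match_states(ref, model)
        assert np.abs(model.transition[np.ix_(perm, perm)]
                      - spec.base_transition).max() < 0.05
        for k in range(3):
            rel = (np.linalg.norm(model.means[perm[k]] - spec.state_means[k])
                   / np.linalg.norm(spec.state_means[k]))
            assert rel < 0.10

    def test_label_permutation_equivariance(self, k3_syn):
        X, bounds = _pool_cohort(k3_syn.cohort)
        means, covs, A, pi = _initial_params(X, 3, rng_seed=1)
        out = _run_em(X, bounds, means, covs, A, pi, tol=1e-6, max_iter=40)
        perm = np.array([2, 0, 1])
        out_p = _run_em(X, bounds, means[perm], covs[perm],
                        A[np.ix_(perm, perm)], pi[perm], tol=1e-6, max_iter=40)
        np.testing.assert_allclose(out_p[0], out[0][perm], atol=1e-8)
        np.testing.assert_allclose(out_p[2], out[2][np.ix_(perm, perm)], atol=1e-8)
        assert out_p[6][-1] == pytest.approx(out[6][-1], abs=1e-6)

    def test_posterior_rows_normalized_on_fit(self, k3_fit):
        _, paths = k3_fit
        for p in paths:
            np.testing.assert_allclose(p.posterior.sum(axis=1), 1.0, atol=1e-10)
            assert p.decoded_path.min() >= 1 and p.decoded_path.max() <= 3

    def test_viterbi_decoder_option(self, k3_syn):
        model, paths = fit_hmm(k3_syn.cohort, 2, n_restarts=1, seed=0,
                               tol=1e-4, max_iter=30, decoder="viterbi")
        for p in paths:
            np.testing.assert_array_equal(p.decoded_path, p.viterbi_path)

    def test_serialization_round_trip(self, k3_fit, tmp_path):
        model, _ = k3_fit
        model.to_json(tmp_path / "m.json")
        loaded = HMMModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(loaded.means, model.means)
        np.testing.assert_array_equal(loaded.covariances, model.covariances)
        np.testing.assert_array_equal(loaded.transition, model.transition)
        assert loaded.fit_meta["seed"] == model.fit_meta["seed"]


class TestOrderSelection:
    def test_single_candidate_is_chosen(self, k3_syn):
        report, fits = select_model_order(k3_syn.cohort, [1], n_restarts=1,
                                          seed=0, max_iter=30)
        assert report.chosen_K == 1
        assert 1 in fits

    def test_bic_formula(self, k3_fit, k3_syn):
        model, _ = k3_fit
        n_total = sum(ts.n_timepoints for ts in k3_syn.cohort.series)
        d = model.n_regions
        expected_params = (3 - 1) + 3 * 2 + 3 * d + 3 * d * (d + 1) // 2
        assert model.n_params == expected_params == n_hmm_params(3, d)
        assert model.bic(n_total) == pytest.approx(
            -2 * model.log_likelihood + expected_params * np.log(n_total))


class TestMatchStates:
    def test_identity(self, k3_fit):
        model, _ = k3_fit
        np.testing.assert_array_equal(match_states(model, model), [0, 1, 2])

    def test_reversed_states(self, k3_fit):
        model, _ = k3_fit
        rev = HMMModel(3, model.means[::-1], model.covariances[::-1],
                       model.transition[::-1, ::-1], model.initial_dist[::-1])
        np.testing.assert_array_equal(match_states(model, rev), [2, 1, 0])

    def test_recovers_random_permutation_vs_brute_force(self, rng):
        import itertools
        K, d = 4, 5
        means = rng.normal(0, 3, (K, d))
        covs = np.array([np.eye(d)] * K)
        A = np.full((K, K), 1.0 / K)
        pi = np.full(K, 1.0 / K)
        ref = HMMModel(K, means, covs, A, pi)
        perm = rng.permutation(K)
        noisy = HMMModel(K, means[perm] + rng.normal(0, 0.01, (K, d)), covs, A, pi)
        got = match_states(ref, noisy)
        # brute force over all 24 permutations
        best = min(itertools.permutations(range(K)),
                   key=lambda p: sum(np.linalg.norm(means[k] - noisy.means[p[k]])
                                     for k in range(K)))
        np.testing.assert_array_equal(got, best)
        # got[i] is the position of reference state i in the shuffled model
        np.testing.assert_array_equal(perm[got], np.arange(K))

    def test_unequal_k_rejected(self, k3_fit):
        model, _ = k3_fit
        small = HMMModel(2, model.means[:2], model.covariances[:2],
                         np.array([[0.5, 0.5], [0.5, 0.5]]), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="equal K"):
            match_states(model, small)
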