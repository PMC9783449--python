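"""VB HMM inference: forward-backward vs exhaustive enumeration, free-energy
monotonicity, parameter/state recovery, binarization, transition statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iedmap.exceptions import DomainError, ParameterError
from iedmap.tde_hmm import (
    HMMConfig,
    StateTimeCourse,
    binarize_states,
    empirical_transition_matrix,
    fit_hmm,
    forward_backward,
    free_energy,
    transition_stats,
)


def _enumerate_posteriors(log_obs, A, pi):
    """Brute force over all K^T state paths."""
    T, K = log_obs.shape
    gamma = np.zeros((T, K))
    xi = np.zeros((K, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = pi[path[0]] * np.exp(log_obs[0, path[0]])
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * np.exp(log_obs[t, path[t]])
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
        for t in range(T - 1):
            xi[path[t], path[t + 1]] += p
    return gamma / total, xi / total, np.log(total)


def _sample_hmm(rng, T, A, means, stds):
    K = A.shape[0]
    z = np.zeros(T, dtype=int)
    for t in range(1, T):
        z[t] = rng.choice(K, p=A[z[t - 1]])
    x = means[z] + stds[z] * rng.standard_normal((T, means.shape[1]))
    return z, x


class TestForwardBackward:
    @pytest.mark.parametrize("T,K,seed", [(3, 2, 0), (5, 3, 1), (8, 3, 2), (7, 2, 3)])
    def test_matches_exhaustive_enumeration(self, T, K, seed):
        rng = np.random.default_rng(seed)
        log_obs = rng.normal(size=(T, K))
        A = rng.dirichlet(np.ones(K), K)
        pi = rng.dirichlet(np.ones(K))
        gamma, xi, log_z = forward_backward(log_obs, A, pi)
        g_ref, xi_ref, lz_ref = _enumerate_posteriors(log_obs, A, pi)
        np.testing.assert_allclose(gamma, g_ref, atol=1e-10)
        np.testing.assert_allclose(xi, xi_ref, atol=1e-10)
        assert log_z == pytest.approx(lz_ref, abs=1e-10)

    def test_single_state_degenerate_chain(self):
        log_obs = np.log(np.full((6, 1), 0.3))
        gamma, _, log_z = forward_backward(log_obs, np.ones((1, 1)), np.ones(1))
        np.testing.assert_array_equal(gamma, np.ones((6, 1)))
        assert log_z == pytest.approx(6 * np.log(0.3))

    def test_rows_normalized(self, rng):
        gamma, _, _ = forward_backward(rng.normal(size=(200, 4)),
                                       rng.dirichlet(np.ones(4), 4),
                                       rng.dirichlet(np.ones(4)))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_nonfinite_log_obs_rejected(self):
        log_obs = np.zeros((4, 2))
        log_obs[1, 0] = np.nan
        with pytest.raises(DomainError):
            forward_backward(log_obs, np.full((2, 2), 0.5), np.full(2, 0.5))


class TestFitHMM:
    def test_two_state_variance_recovery(self, rng):
        """Data from a sticky 2-state HMM (variances 1 vs 25) is decoded at
        >= 95% accuracy after label matching, and the transition matrix is
        recovered within 0.05."""
        A = np.array([[0.98, 0.02], [0.02, 0.98]])
        z, x = _sample_hmm(rng, 10000, A, np.zeros((2, 2)), np.array([[1.0], [5.0]]))
        model = fit_hmm(x, HMMConfig(n_states=2, seed=1, n_restarts=3))
        hard = model.gamma.argmax(axis=1)
        acc = max(np.mean(hard == z), np.mean(hard == 1 - z))
        assert acc >= 0.95
        Ahat = model.transmat if np.mean(hard == z) >= np.mean(hard == 1 - z) \
            else model.transmat[::-1, ::-1]
        assert np.max(np.abs(Ahat - A)) <= 0.05

    def test_agrees_with_independent_em_implementation(self, rng):
        """Cross-check against hmmlearn's EM on the same dataset: both
        decoders must recover the same (true) segmentation."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        A = np.array([[0.97, 0.03], [0.03, 0.97]])
        z, x = _sample_hmm(rng, 5000, A, np.array([[0.0, 0.0], [0.0, 0.0]]),
                           np.array([[1.0], [4.0]]))
        ours = fit_hmm(x, HMMConfig(n_states=2, seed=2, n_restarts=3)).gamma.argmax(axis=1)
        ref_model = hmmlearn.GaussianHMM(n_components=2, covariance_type="full",
                                         n_iter=100, random_state=0)
        ref_model.fit(x)
        ref = ref_model.predict(x)
        acc_ours = max(np.mean(ours == z), np.mean(ours == 1 - z))
        acc_ref = max(np.mean(ref == z), np.mean(ref == 1 - z))
        assert acc_ours >= 0.95 and acc_ref >= 0.95

    def test_free_energy_nonincreasing_on_random_data(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((150, 3))
            model = fit_hmm(x, HMMConfig(n_states=2, seed=seed, n_restarts=1, max_iter=40))
            f = model.free_energy_trace
            diffs = np.diff(f)
            assert np.all(diffs <= 1e-8 * np.abs(f[:-1]) + 1e-9), f"seed {seed}: {diffs.max()}"

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((400, 3))
        cfg = HMMConfig(n_states=2, seed=42, n_restarts=2, max_iter=30)
        m1 = fit_hmm(x, cfg)
        m2 = fit_hmm(x, HMMConfig(n_states=2, seed=42, n_restarts=2, max_iter=30))
        np.testing.assert_array_equal(m1.gamma, m2.gamma)
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ParameterError):
            fit_hmm(rng.standard_normal((19, 2)), HMMConfig(n_states=2))

    def test_model_invariants(self, rng):
        x = rng.standard_normal((600, 3))
        model = fit_hmm(x, HMMConfig(n_states=3, seed=0, n_restarts=2, max_iter=50))
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(model.gamma.sum(axis=1), 1.0, atol=1e-9)
        for cov in model.covariances:
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_perturbed_posterior_raises_free_energy(self, rng):
        x = rng.standard_normal((300, 2))
        model = fit_hmm(x, HMMConfig(n_states=2, seed=3, n_restarts=1))
        f_star = free_energy(model, x)
        model.means = model.means + 0.5
        assert free_energy(model, x) > f_star


class TestBinarize:
    def test_threshold_rules(self):
        gamma = np.array([
            [0.70, 0.30, 0.0, 0.0, 0.0],
            [0.50, 0.50, 0.0, 0.0, 0.0],
            [0.99, 0.01, 0.0, 0.0, 0.0],
        ])
        stc = binarize_states(gamma, 2.0 / 3.0)
        assert stc.active[0, 0] and not stc.active[0, 1:].any()
        assert not stc.active[1].any()
        stc_strict = binarize_states(gamma, 1.0)
        assert not stc_strict.active.any()

    def test_mutual_exclusivity_guaranteed(self, rng):
        gamma = rng.dirichlet(np.ones(5), size=500)
        stc = binarize_states(gamma, 2.0 / 3.0)
        assert np.all(stc.active.sum(axis=1) <= 1)

    @given(st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=20, deadline=None)
    def test_threshold_at_or_below_half_rejected(self, thr):
        with pytest.raises(ParameterError):
            binarize_states(np.ones((4, 2)) * 0.5, thr)


class TestTransitionStats:
    def _stc(self, labels, K=2):
        active = np.zeros((len(labels), K), dtype=bool)
        for t, k in enumerate(labels):
            if k >= 0:
                active[t, k] = True
        return StateTimeCourse(active=active, fs=1.0, valid_offset=0)

    def test_visit_sequence_enumeration(self):
        stc = self._stc([0, 0, 1, 1, 0, 0])
        stats = empirical_transition_matrix(stc)
        assert stats.matrix[0, 1] == 1.0
        assert stats.matrix[1, 0] == 1.0

    def test_single_state_occupancy(self):
        stc = self._stc([0, 0, 0, 0])
        stats = empirical_transition_matrix(stc)
        assert stats.occupancy[0] == 1.0 and stats.occupancy[1] == 0.0
        assert not stats.row_defined[0]  # no outgoing transition: flagged

    def test_rows_stochastic_on_defined_rows(self):
        stc = self._stc([0, 1, 0, 1, 1, 0, -1, 1])
        stats = empirical_transition_matrix(stc)
        sums = stats.matrix[stats.row_defined].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_model_variant_row_stochastic(self, rng):
        x = rng.standard_normal((400, 2))
        model = fit_hmm(x, HMMConfig(n_states=2, seed=4, n_restarts=1, max_iter=30))
        stats = transition_stats(model=model)
        np.testing.assert_allclose(stats.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert stats.kind == "model"
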