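import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sbtmig import hmm, simulator
from sbtmig.hmm import (HmmParams, default_init, fit_em, fit_two_state, forward_loglik,
                        posterior_probs, stationary_distribution, viterbi_decode)

from .oracles import enum_loglik, enum_posteriors, enum_viterbi, random_hmm_instance


def _params(initial, P, means, sds, zeros=()):
    labels = tuple(f"s{i}" for i in range(len(initial)))
    return HmmParams(P, means, sds, initial, state_labels=labels, structural_zeros=zeros)


class TestForwardLoglik:
    def test_single_obs_single_state_closed_form(self):
        from scipy.stats import norm
        p = _params([1.0], np.array([[1.0]]), [2.0], [3.0])
        assert forward_loglik([1.3], p) == pytest.approx(norm.logpdf(1.3, 2.0, 3.0), abs=1e-12)

    def test_matches_enumeration_two_states(self, rng):
        obs, initial, P, means, sds, _ = random_hmm_instance(rng, 2, 3)
        ll = forward_loglik(obs, _params(initial, P, means, sds))
        assert ll == pytest.approx(enum_loglik(obs, initial, P, means, sds), abs=1e-10)

    def test_label_permutation_invariance(self, rng):
        obs, initial, P, means, sds, _ = random_hmm_instance(rng, 3, 6)
        perm = np.array([2, 0, 1])
        ll1 = forward_loglik(obs, _params(initial, P, means, sds))
        ll2 = forward_loglik(obs, _params(initial[perm], P[np.ix_(perm, perm)], means[perm], sds[perm]))
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_no_underflow_on_long_series(self, generative_params, rng):
        _, obs = simulator.simulate_observations(generative_params, 10_000, 1, rng)
        ll = forward_loglik(obs[0], generative_params)
        assert np.isfinite(ll)

    def test_non_finite_observation_identified(self, generative_params):
        with pytest.raises(ValueError, match="index"):
            forward_loglik([1.0, np.nan, 2.0], generative_params)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_forward_posterior_viterbi_match_enumeration(data):
    """Scaled recursions agree with brute-force path enumeration (T<=8, S<=3)."""
    seed = data.draw(st.integers(0, 2**31 - 1))
    n_states = data.draw(st.sampled_from([2, 3]))
    n_obs = data.draw(st.integers(1, 8))
    with_zeros = data.draw(st.booleans()) and n_states == 3
    rng = np.random.default_rng(seed)
    obs, initial, P, means, sds, zeros = random_hmm_instance(rng, n_states, n_obs, with_zeros)
    params = _params(initial, P, means, sds, zeros)
    assert forward_loglik(obs, params) == pytest.approx(
        enum_loglik(obs, initial, P, means, sds), abs=1e-10)
    np.testing.assert_allclose(posterior_probs(obs, params),
                               enum_posteriors(obs, initial, P, means, sds), atol=1e-10)
    vit = viterbi_decode(obs, params)
    oracle = enum_viterbi(obs, initial, P, means, sds)
    # paths must carry identical probability (distinct ties are acceptable)
    def logp(path):
        from scipy.stats import norm
        lp = np.log(initial[path[0]]) + norm.logpdf(obs[0], means[path[0]], sds[path[0]])
        for t in range(1, len(obs)):
            lp += np.log(P[path[t - 1], path[t]]) + norm.logpdf(obs[t], means[path[t]], sds[path[t]])
        return lp
    assert logp(vit) == pytest.approx(logp(oracle), abs=1e-9)


class TestViterbi:
    def test_single_observation_closed_form(self, rng):
        obs, initial, P, means, sds, _ = random_hmm_instance(rng, 3, 1)
        from scipy.stats import norm
        expected = np.argmax(initial * norm.pdf(obs[0], means, sds))
        assert viterbi_decode(obs, _params(initial, P, means, sds))[0] == expected

    def test_resident_data_gives_resident_path(self, generative_params):
        rng = np.random.default_rng(5)
        obs = rng.normal(0.0, 14.0, 300)
        path = viterbi_decode(obs, generative_params)
        assert np.mean(path == hmm.RESIDENT) > 0.95

    def test_forbidden_transitions_never_used(self, generative_params, rng):
        _, obs = simulator.simulate_observations(generative_params, 2000, 1, rng)
        path = viterbi_decode(obs[0], generative_params)
        pairs = set(zip(path[:-1], path[1:]))
        assert (hmm.OUTWARD, hmm.INWARD) not in pairs
        assert (hmm.INWARD, hmm.OUTWARD) not in pairs


class TestPosteriors:
    def test_one_state_model_posterior_one(self):
        p = _params([1.0], np.array([[1.0]]), [0.0], [1.0])
        assert np.allclose(posterior_probs([0.3, -0.1, 2.0], p), 1.0)

    def test_rows_sum_to_one(self, generative_params, rng):
        _, obs = simulator.simulate_observations(generative_params, 400, 1, rng)
        post = posterior_probs(obs[0], generative_params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_model_symmetric_posteriors(self):
        p = _params([0.5, 0.5], np.array([[0.8, 0.2], [0.2, 0.8]]), [-1.0, 1.0], [1.0, 1.0])
        post = posterior_probs([-2.0, 0.0, 2.0], p)
        np.testing.assert_allclose(post, post[::-1, ::-1], atol=1e-12)


class TestStationaryDistribution:
    def test_symmetric_two_state(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_defining_property(self, rng):
        for _ in range(20):
            P = rng.dirichlet(np.ones(3), size=3)
            pi = stationary_distribution(P)
            np.testing.assert_allclose(pi @ P, pi, atol=1e-12)
            assert np.all(pi >= 0)

    def test_reducible_chain_errors(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_occupancy_construction_round_trip(self):
        P = simulator.transition_matrix_for_occupancy([0.57, 0.25, 0.18], persistence=0.95)
        np.testing.assert_allclose(stationary_distribution(P), [0.57, 0.25, 0.18], atol=1e-10)


class TestFitEm:
    def test_monotone_loglik_from_truth_init(self, generative_params, rng):
        _, obs = simulator.simulate_observations(generative_params, 300, 5, rng)
        res = fit_em(list(obs), init=generative_params, n_restarts=1, max_iter=50)
        assert np.all(np.diff(res.loglik_history) >= -1e-6)

    def test_parameter_recovery(self, recovery_simulation, recovery_fit, generative_params):
        """Pooled EM at the real-data scale recovers the generative parameters."""
        p = recovery_fit.params
        # 100 x 500 steps: Monte-Carlo SE of each state mean is ~sd/sqrt(n_state)
        n_eff = 50_000 * np.array([0.57, 0.25, 0.18])
        se = generative_params.sds / np.sqrt(n_eff)
        assert np.all(np.abs(p.means - generative_params.means) < 4 * se + 0.2)
        assert np.all(np.abs(p.sds - generative_params.sds) < 1.0)
        free = [(i, j) for i in range(3) for j in range(3) if (i, j) not in p.structural_zeros]
        for i, j in free:
            assert p.transition[i, j] == pytest.approx(
                generative_params.transition[i, j], abs=0.02)

    def test_replicate_recovery_median_error(self, generative_params):
        """Median |error| of emission estimates stays below 1 km/day across replicates."""
        mu_errs, sd_errs = [], []
        for rep in range(20):
            _, obs = simulator.simulate_observations(
                generative_params, 500, 100, np.random.default_rng(9000 + rep))
            p = fit_em(list(obs), n_restarts=2, random_state=rep).params
            mu_errs.append(np.abs(p.means - generative_params.means))
            sd_errs.append(np.abs(p.sds - generative_params.sds))
        assert np.all(np.median(mu_errs, axis=0) < 1.0)
        assert np.all(np.median(sd_errs, axis=0) < 1.0)

    def test_structural_zeros_exact_after_fit(self, recovery_fit):
        P = recovery_fit.params.transition
        assert P[hmm.OUTWARD, hmm.INWARD] == 0.0
        assert P[hmm.INWARD, hmm.OUTWARD] == 0.0

    def test_state_relabeling_rule(self, recovery_fit):
        m = recovery_fit.params.means
        assert m[hmm.OUTWARD] > m[hmm.RESIDENT] > m[hmm.INWARD]
        assert abs(m[hmm.RESIDENT]) == min(abs(m))

    def test_all_zero_observations_resident_dominated(self):
        rng = np.random.default_rng(3)
        obs = [rng.normal(0, 1, 200) for _ in range(3)]
        res = fit_em(obs, n_restarts=2, max_iter=100)
        path = np.concatenate([viterbi_decode(o, res.params) for o in obs])
        assert np.mean(path == hmm.RESIDENT) > 0.5

    def test_variance_collapse_errors(self):
        obs = [np.zeros(50), np.zeros(50)]
        with pytest.raises(ValueError, match="variance"):
            fit_em(obs, n_restarts=1)

    def test_non_convergence_warns(self, generative_params, rng):
        _, obs = simulator.simulate_observations(generative_params, 200, 2, rng)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit_em(list(obs), max_iter=2, n_restarts=1)
        assert not res.converged


class TestTwoStateModel:
    def test_one_way_outward_recovery(self, rng):
        P2 = np.array([[0.95, 0.05], [0.07, 0.93]])
        truth = HmmParams(P2, [0.0, 39.0], [14.0, 21.6],
                          state_labels=hmm.STATE_LABELS_2, structural_zeros=())
        states = np.vstack([simulator.simulate_states(P2, 400, rng) for _ in range(30)])
        obs = rng.normal(truth.means[states], truth.sds[states])
        res = fit_two_state(list(obs))
        se = 21.6 / np.sqrt(0.4 * 30 * 400)
        assert res.params.means[1] == pytest.approx(39.0, abs=4 * se + 0.2)

    def test_three_state_loglik_dominates_nested_two_state(self, rng):
        P2 = np.array([[0.95, 0.05], [0.07, 0.93]])
        states = np.vstack([simulator.simulate_states(P2, 300, rng) for _ in range(5)])
        obs = rng.normal(np.array([0.0, 39.0])[states], np.array([14.0, 21.6])[states])
        ll2 = fit_two_state(list(obs), n_restarts=2).loglik
        ll3 = fit_em(list(obs), n_restarts=2).loglik
        assert ll3 >= ll2 - 1e-6

    def test_two_state_decoding_has_no_inward(self, rng):
        P2 = np.array([[0.9, 0.1], [0.1, 0.9]])
        p = HmmParams(P2, [0.0, 39.0], [14.0, 21.6],
                      state_labels=hmm.STATE_LABELS_2, structural_zeros=())
        obs = rng.normal(10, 20, 200)
        assert set(viterbi_decode(obs, p)) <= {0, 1}


class TestSerialization:
    def test_yaml_round_trip(self, generative_params, tmp_path):
        path = tmp_path / "model.yaml"
        hmm.save_params(generative_params, path)
        back = hmm.load_params(path)
        np.testing.assert_array_equal(back.transition, generative_params.transition)
        np.testing.assert_array_equal(back.means, generative_params.means)
        np.testing.assert_array_equal(back.sds, generative_params.sds)
        assert back.state_labels == generative_params.state_labels
        assert back.structural_zeros == generative_params.structural_zeros

    def test_json_round_trip(self, generative_params, tmp_path):
        path = tmp_path / "model.json"
        hmm.save_params(generative_params, path)
        back = hmm.load_params(path)
        np.testing.assert_array_equal(back.transition, generative_params.transition)


class TestCrossCheckAgainstHmmlearn:
    """Independent library implementation as an external oracle (unconstrained case)."""

    def test_loglik_matches_gaussian_hmm(self, rng):
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        P = np.array([[0.85, 0.15], [0.25, 0.75]])
        initial = np.array([0.6, 0.4])
        means, sds = np.array([0.0, 5.0]), np.array([1.5, 2.5])
        obs = rng.normal(2.0, 3.0, 200)
        mine = forward_loglik(obs, _params(initial, P, means, sds))
        ref = hmmlearn_hmm.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_, ref.transmat_ = initial, P
        ref.means_, ref.covars_ = means.reshape(-1, 1), (sds ** 2).reshape(-1, 1)
        assert mine == pytest.approx(ref.score(obs.reshape(-1, 1)), abs=1e-8)
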