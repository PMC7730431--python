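"""Discrete HMM: forward/Viterbi vs exhaustive enumeration, EM training,
fork-coded path planning over the airway junction graph."""

import itertools

import numpy as np
import pytest

from broncholoc.airway import generate_tree
from broncholoc.hmm import (
    HmmModel,
    forward_likelihood,
    forward_log_likelihood,
    load_hmm,
    plan_path,
    sample_sequences,
    save_hmm,
    train_baum_welch,
    viterbi_path,
)


def enumerate_likelihood(model, obs):
    """Brute-force sum over all hidden paths."""
    n = model.n_states
    total = 0.0
    for states in itertools.product(range(n), repeat=len(obs)):
        p = model.pi[states[0]] * model.B[states[0], obs[0]]
        for t in range(1, len(obs)):
            p *= model.A[states[t - 1], states[t]] * model.B[states[t], obs[t]]
        total += p
    return total


def enumerate_viterbi(model, obs):
    n = model.n_states
    best_p, best_states = -1.0, None
    for states in itertools.product(range(n), repeat=len(obs)):
        p = model.pi[states[0]] * model.B[states[0], obs[0]]
        for t in range(1, len(obs)):
            p *= model.A[states[t - 1], states[t]] * model.B[states[t], obs[t]]
        if p > best_p:
            best_p, best_states = p, list(states)
    return best_states, best_p


class TestForward:
    def test_degenerate_single_state_chain_certain(self):
        m = HmmModel(np.array([[1.0]]), np.array([[1.0, 0.0]]), np.array([1.0]))
        assert forward_likelihood(m, [0, 0, 0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("length", [1, 2, 3, 4])
    def test_total_probability_over_all_sequences_is_one(self, length):
        m = HmmModel.random(3, 3, seed=5)
        total = sum(
            forward_likelihood(m, list(obs))
            for obs in itertools.product(range(3), repeat=length)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, seed):
        m = HmmModel.random(3, 3, seed=seed)
        rng = np.random.default_rng(seed)
        for _ in range(5):
            obs = rng.integers(0, 3, size=4).tolist()
            assert forward_likelihood(m, obs) == pytest.approx(
                enumerate_likelihood(m, obs), rel=1e-12, abs=1e-12
            )

    def test_out_of_range_symbol_rejected(self):
        m = HmmModel.random(2, 2, seed=0)
        with pytest.raises(ValueError):
            forward_likelihood(m, [0, 5])


class TestViterbi:
    def test_deterministic_model_yields_consistent_path(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])  # strict alternation
        B = np.array([[1.0, 0.0], [0.0, 1.0]])  # state i emits symbol i
        m = HmmModel(A, B, np.array([1.0, 0.0]))
        states, logp = viterbi_path(m, [0, 1, 0, 1])
        assert states == [0, 1, 0, 1]
        assert logp == pytest.approx(0.0)  # probability one

    def test_length_one_closed_form(self):
        m = HmmModel.random(3, 3, seed=9)
        for sym in range(3):
            states, _ = viterbi_path(m, [sym])
            assert states[0] == int(np.argmax(m.pi * m.B[:, sym]))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_argmax(self, seed):
        m = HmmModel.random(3, 3, seed=seed)
        rng = np.random.default_rng(seed)
        for _ in range(4):
            obs = rng.integers(0, 3, size=5).tolist()
            states, logp = viterbi_path(m, obs)
            want_states, want_p = enumerate_viterbi(m, obs)
            assert np.exp(logp) == pytest.approx(want_p, rel=1e-10)
            assert states == want_states


class TestBaumWelch:
    def test_loglik_monotone_nondecreasing(self):
        planted = HmmModel.random(3, 3, seed=1)
        seqs = sample_sequences(planted, 30, 8, seed=2)
        m = train_baum_welch(seqs, n_states=3, seed=4, tol=1e-6, max_iters=30)
        hist = np.array(m.log_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_stops_on_mean_loglik_change_rule(self):
        planted = HmmModel.random(3, 3, seed=1)
        seqs = sample_sequences(planted, 20, 6, seed=2)
        m = train_baum_welch(seqs, n_states=3, seed=4, tol=0.01, max_iters=500)
        hist = m.log_history
        assert len(hist) < 500
        assert abs(hist[-1] - hist[-2]) < 0.01
        # every earlier consecutive change was at or above the tolerance
        assert all(abs(b - a) >= 0.01 for a, b in zip(hist[:-2], hist[1:-1]))

    def test_infinite_tolerance_stops_after_first_comparison(self):
        seqs = [[0, 1, 2, 0]] * 3
        m = train_baum_welch(seqs, n_states=2, seed=0, tol=np.inf, max_iters=50)
        assert len(m.log_history) <= 2  # one update iteration performed

    def test_training_improves_on_random_init(self):
        planted = HmmModel(
            np.array([[0.9, 0.1, 0.0], [0.0, 0.9, 0.1], [0.1, 0.0, 0.9]]),
            np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]]),
            np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        train_seqs = sample_sequences(planted, 100, 10, seed=3)
        init = HmmModel.random(3, 3, seed=6)
        fitted = train_baum_welch(train_seqs, n_states=3, seed=6, tol=1e-4, max_iters=100)
        mean_init = np.mean([forward_log_likelihood(init, s) for s in train_seqs])
        mean_fit = np.mean([forward_log_likelihood(fitted, s) for s in train_seqs])
        assert mean_fit >= mean_init

    def test_recovery_close_to_planted_model_on_heldout(self):
        planted = HmmModel(
            np.array([[0.85, 0.1, 0.05], [0.05, 0.85, 0.1], [0.1, 0.05, 0.85]]),
            np.array([[0.98, 0.01, 0.01], [0.01, 0.98, 0.01], [0.01, 0.01, 0.98]]),
            np.array([0.6, 0.25, 0.15]),
        )
        train_seqs = sample_sequences(planted, 200, 12, seed=3)
        heldout = sample_sequences(planted, 50, 12, seed=30)
        fitted = train_baum_welch(train_seqs, n_states=3, seed=8, tol=1e-4, max_iters=200)
        ll_planted = np.mean([forward_log_likelihood(planted, s) for s in heldout])
        ll_fitted = np.mean([forward_log_likelihood(fitted, s) for s in heldout])
        assert abs(ll_fitted - ll_planted) / abs(ll_planted) < 0.05

    def test_deterministic_given_seed(self):
        seqs = sample_sequences(HmmModel.random(3, 3, seed=1), 20, 6, seed=2)
        m1 = train_baum_welch(seqs, n_states=3, seed=5, max_iters=10, tol=1e-9)
        m2 = train_baum_welch(seqs, n_states=3, seed=5, max_iters=10, tol=1e-9)
        assert np.array_equal(m1.A, m2.A) and np.array_equal(m1.B, m2.B)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_baum_welch([], n_states=3)

    def test_cross_check_against_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        m = HmmModel.random(3, 3, seed=13)
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = m.pi
        ref.transmat_ = m.A
        ref.emissionprob_ = m.B
        obs = np.array([[0, 2, 1, 1, 0, 2]]).T
        want = ref.score(obs)
        got = forward_log_likelihood(m, obs.ravel().tolist())
        assert got == pytest.approx(want, rel=1e-10)


class TestPlanPath:
    def test_source_equals_target_empty_code(self):
        tree = generate_tree(3, seed=11)
        model = HmmModel.random(3, 3, seed=0)
        code, nodes, polyline, ll = plan_path(model, tree, "J1", "J1")
        assert code == [] and nodes == ["J1"]
        assert polyline.shape == (0, 3)

    def test_leftmost_leaf_coded_all_zeros(self):
        tree = generate_tree(3, seed=11)
        model = HmmModel.random(3, 3, seed=0)
        # follow fork 0 from the root inlet to a leaf
        node = "J0"
        while tree.graph.out_degree(node):
            node = tree.children_of(node)[0]
        code, nodes, polyline, _ = plan_path(model, tree, "J0", node)
        assert code == [0, 0, 0]
        assert len(polyline) >= 2

    def test_unreachable_target_rejected(self):
        tree = generate_tree(2, seed=1)
        model = HmmModel.random(3, 3, seed=0)
        leaves = tree.leaf_ids
        with pytest.raises(ValueError):
            plan_path(model, tree, leaves[0], leaves[1])  # no directed route

    def test_code_likelihood_matches_forward(self):
        tree = generate_tree(3, seed=11)
        model = HmmModel.random(3, 3, seed=2)
        leaf = tree.leaf_ids[-1]
        code, _, _, ll = plan_path(model, tree, "J0", leaf)
        assert ll == pytest.approx(forward_log_likelihood(model, code))


class TestPersistence:
    def test_roundtrip(self, tmp_path):
        m = HmmModel.random(3, 3, seed=2)
        path = tmp_path / "hmm.json"
        save_hmm(m, path)
        loaded = load_hmm(path)
        assert np.allclose(loaded.A, m.A) and np.allclose(loaded.pi, m.pi)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            HmmModel(np.array([[0.5, 0.2], [0.5, 0.5]]), np.eye(2), np.array([0.5, 0.5]))
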