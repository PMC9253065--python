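"""Supervised successor learning: architecture, training, evaluation."""

import numpy as np
import pytest

from cogmap.environments import sample_state_pairs
from cogmap.grammar import sample_word_pairs
from cogmap.supervised import (
    TrainingConfig,
    architecture_sweep,
    bayes_accuracy_ceiling,
    evaluate,
    init_network,
    predict_distribution,
    predicted_tp_matrix,
    rmse,
    train,
)


class TestInitNetwork:
    @pytest.mark.parametrize(
        "n, frac, hidden", [(100, 1.0, 100), (40, 1.0, 40), (100, 0.3, 30)]
    )
    def test_layer_sizes(self, n, frac, hidden):
        net = init_network(n, hidden_fraction=frac, seed=0)
        assert (net.n_inputs, net.hidden_size, net.n_outputs) == (n, hidden, n)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError, match="hidden_fraction"):
            init_network(100, hidden_fraction=0.0)

    def test_seeded_init_reproducible(self):
        a, b = (init_network(30, seed=5) for _ in range(2))
        assert all(np.array_equal(x, y) for x, y in zip(a.parameters(), b.parameters()))


class TestPrediction:
    def test_distribution_normalized(self):
        net = init_network(40, seed=1)
        p = predict_distribution(net, 7)
        assert p.shape == (40,)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-6

    def test_zero_weight_network_is_uniform(self):
        net = init_network(25, seed=0)
        for p in net.parameters():
            p[:] = 0.0
        np.testing.assert_allclose(predict_distribution(net, 3), 1 / 25)

    def test_out_of_range_state(self):
        net = init_network(10, seed=0)
        with pytest.raises(IndexError):
            predict_distribution(net, 10)

    def test_tp_matrix_rows_stochastic(self):
        net = init_network(30, seed=2)
        T = predicted_tp_matrix(net).T
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-9)


class TestTraining:
    def test_single_pair_memorized(self):
        net = init_network(5, seed=0)
        net, hist = train(
            net,
            np.array([[2, 4]]),
            TrainingConfig(epochs=300, validation_split=0.0, plateau_tol=0),
        )
        assert evaluate(net, np.array([[2, 4]])) == 1.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train(init_network(5, seed=0), np.empty((0, 2), dtype=int))

    def test_deterministic_given_seed(self, room10, moore):
        pairs = sample_state_pairs(room10, moore, 300, rng=0)
        cfg = TrainingConfig(epochs=20, seed=4, plateau_tol=0)
        n1, h1 = train(init_network(100, seed=4), pairs, cfg)
        n2, h2 = train(init_network(100, seed=4), pairs, cfg)
        assert h1.loss == h2.loss
        assert np.array_equal(n1.W1, n2.W1)

    def test_history_lengths_match_epochs(self, grammar_fixture):
        vocab, rules = grammar_fixture
        pairs = sample_word_pairs(vocab, rules, 500, rng=0)
        _, hist = train(init_network(40, seed=0), pairs,
                        TrainingConfig(epochs=30, plateau_tol=0))
        assert hist.epochs_run == 30
        assert len(hist.acc_train) == len(hist.acc_val) == len(hist.loss) == 30

    def test_plateau_detection_stops_early(self, room10, moore):
        pairs = sample_state_pairs(room10, moore, 2_000, rng=1)
        _, hist = train(init_network(100, seed=1), pairs,
                        TrainingConfig(epochs=5000, seed=1))
        assert hist.stopped_at_plateau
        assert hist.epochs_run < 5000
        # loss indeed flat over the detection window
        w = 50
        assert abs(hist.loss[-1 - w] - hist.loss[-1]) < 1e-4

    def test_converged_rows_approach_transition_rows(self, room10, room10_T, moore):
        # cross-entropy optimum is the transition row, not a one-hot
        pairs = sample_state_pairs(room10, moore, 10_000, rng=2)
        net, _ = train(init_network(100, seed=2), pairs,
                       TrainingConfig(epochs=500, seed=2))
        pred = predicted_tp_matrix(net).T
        assert rmse(pred, room10_T.T) < 0.02
        s = room10.to_flat(4, 4)
        neighborhood = np.flatnonzero(room10_T.T[s])
        assert pred[s, neighborhood].sum() > 0.95

    def test_accuracy_bounded_by_bayes_ceiling(self, room10, room10_T, moore):
        ceiling = bayes_accuracy_ceiling(room10_T)
        assert abs(ceiling - 0.134444) < 1e-4
        pairs = sample_state_pairs(room10, moore, 10_000, rng=3)
        net, hist = train(init_network(100, seed=3), pairs,
                          TrainingConfig(epochs=500, seed=3))
        fresh = sample_state_pairs(room10, moore, 100_000, rng=103)
        acc = evaluate(net, fresh)
        assert acc <= ceiling + 0.01
        assert acc > ceiling - 0.02


class TestEvaluation:
    @pytest.mark.parametrize("n_states, chance", [(100, 0.01), (40, 0.025)])
    def test_uniform_random_predictor_chance_level(self, n_states, chance):
        rng = np.random.default_rng(0)
        n = 100_000
        guesses = rng.integers(n_states, size=n)
        labels = rng.integers(n_states, size=n)
        acc = float(np.mean(guesses == labels))
        se = np.sqrt(chance * (1 - chance) / n)
        assert abs(acc - chance) <= 3 * se

    def test_rmse_identity_zero(self):
        A = np.random.default_rng(1).random((8, 8))
        assert rmse(A, A) == 0.0

    def test_rmse_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestArchitectureSweep:
    def test_single_fraction_single_row(self, grammar_fixture, language_T):
        vocab, rules = grammar_fixture
        pairs = sample_word_pairs(vocab, rules, 1_000, rng=0)
        cfg = TrainingConfig(epochs=30, seed=0, plateau_tol=0)
        table = architecture_sweep(pairs, language_T, [1.0], cfg)
        assert len(table) == 1
        assert table[0]["hidden_size"] == 40

    def test_language_rmse_flat_across_fractions(self, grammar_fixture, language_T):
        vocab, rules = grammar_fixture
        pairs = sample_word_pairs(vocab, rules, 5_000, rng=5)
        cfg = TrainingConfig(epochs=50, seed=5, plateau_tol=0)
        table = architecture_sweep(pairs, language_T, [0.3, 0.6, 1.0], cfg)
        rmses = [row["rmse"] for row in table]
        assert max(rmses) - min(rmses) < 0.02
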