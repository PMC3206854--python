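import numpy as np
import pytest

from pepmotif.encoding import EncodingConfig, encode_instance, encode_peptides
from pepmotif.network import (
    TrainSchedule,
    TrainedNetwork,
    _forward_rows,
    _gradient_step,
    best_core,
    forward,
    train_network,
)

from conftest import make_random_network, random_peptides


def loss_and_output(W1, w2, x, t):
    out = _forward_rows(W1, w2, x[None, :])[0]
    return 0.5 * (out - t) ** 2, out


class TestForward:
    def test_zero_weights_give_half(self):
        cfg = EncodingConfig(scheme="sparse", motif_len=3)
        net = TrainedNetwork(np.zeros((4, 61)), np.zeros(5), cfg, 4, 0)
        x = encode_instance("ACD", 0, cfg).vector
        assert forward(net, x) == pytest.approx(0.5)

    def test_output_strictly_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            net = make_random_network(motif_len=3, seed=i)
            x = rng.normal(size=net.config.input_dim)
            out = forward(net, x)
            assert 0.0 < out < 1.0

    def test_hand_computed_toy(self):
        # 2 inputs, 1 hidden unit: input (1,0), hidden weights (1,0), zero
        # biases, output weight 1 -> sigmoid(sigmoid(1)) ~ 0.6750
        W1 = np.array([[1.0, 0.0, 0.0]])  # last column is the bias
        w2 = np.array([1.0, 0.0])
        out = _forward_rows(W1, w2, np.array([[1.0, 0.0]]))[0]
        assert out == pytest.approx(0.6750, abs=1e-4)

    def test_dimension_mismatch(self):
        net = make_random_network(motif_len=3)
        with pytest.raises(ValueError):
            forward(net, np.zeros(10))


class TestBestCore:
    def test_single_candidate(self):
        net = make_random_network(motif_len=9)
        off, _ = best_core(net, "ACDEFGHIK")
        assert off == 0

    def test_argmax_matches_independent_scan(self):
        net = make_random_network(motif_len=9, seed=4)
        pep = "ACDEFGHIKLMNPQR"  # 15-mer, 7 candidate offsets
        scores = [
            forward(net, encode_instance(pep, o, net.config).vector)
            for o in range(7)
        ]
        off, score = best_core(net, pep)
        assert off == int(np.argmax(scores))
        assert score == pytest.approx(max(scores))

    def test_tie_breaks_to_smallest_offset(self):
        cfg = EncodingConfig(scheme="sparse", motif_len=3)
        net = TrainedNetwork(np.zeros((2, 61)), np.zeros(3), cfg, 2, 0)
        off, score = best_core(net, "ACDEFG")  # all offsets score 0.5
        assert off == 0 and score == pytest.approx(0.5)

    def test_short_peptide_rejected(self):
        net = make_random_network(motif_len=9)
        with pytest.raises(ValueError):
            best_core(net, "ACD")


class TestGradient:
    @pytest.mark.parametrize("trial", range(5))
    def test_backprop_matches_finite_differences(self, trial):
        """Central finite differences on the squared-error loss agree with
        the backprop update direction to < 1e-4 relative error."""
        rng = np.random.default_rng(trial)
        H, D = int(rng.integers(1, 5)), int(rng.integers(2, 8))
        W1 = rng.normal(0, 0.8, size=(H, D + 1))
        w2 = rng.normal(0, 0.8, size=H + 1)
        x = rng.normal(size=D)
        t = float(rng.uniform())
        lr = 1.0
        W1_new, w2_new = W1.copy(), w2.copy()
        _gradient_step(W1_new, w2_new, x, t, lr)
        analytic = np.concatenate(
            [((W1 - W1_new) / lr).ravel(), (w2 - w2_new) / lr]
        )
        eps = 1e-5
        numeric = np.empty_like(analytic)
        k = 0
        for arr, arr_id in ((W1, 0), (w2, 1)):
            flat = arr.ravel()
            for j in range(flat.size):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = loss_and_output(W1, w2, x, t)
                flat[j] = orig - eps
                lm, _ = loss_and_output(W1, w2, x, t)
                flat[j] = orig
                numeric[k] = (lp - lm) / (2 * eps)
                k += 1
        denom = np.maximum(np.abs(numeric), 1e-8)
        rel = np.abs(analytic - numeric) / denom
        assert rel.max() < 1e-4


class TestTrainNetwork:
    def _toy_data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        peptides = random_peptides(n, (9, 9), seed=seed)
        # learnable rule: target high iff the peptide contains a W
        targets = [0.9 if "W" in p else 0.1 for p in peptides]
        return peptides, targets

    def test_training_reduces_rmse(self):
        from pepmotif.network import TrainedNetwork, init_weights, score_batch

        peptides, targets = self._toy_data(80)
        targets_arr = np.array(targets)
        cfg = EncodingConfig(scheme="sparse", motif_len=9)
        enc = encode_peptides(peptides, cfg)
        W1, w2 = init_weights(3, cfg.input_dim, 1)
        untrained = TrainedNetwork(W1, w2, cfg, 3, 1)
        rmse_init = np.sqrt(
            np.mean((score_batch(untrained, enc)[1] - targets_arr) ** 2)
        )
        net = train_network(
            peptides, targets, TrainSchedule(n_iterations=200), cfg, 3, seed=1
        )
        rmse_trained = np.sqrt(
            np.mean((score_batch(net, enc)[1] - targets_arr) ** 2)
        )
        assert rmse_trained < rmse_init

    def test_determinism_bit_identical(self):
        peptides, targets = self._toy_data()
        cfg = EncodingConfig(scheme="blosum", motif_len=5)
        sched = TrainSchedule(n_iterations=10)
        a = train_network(peptides, targets, sched, cfg, 3, seed=7)
        b = train_network(peptides, targets, sched, cfg, 3, seed=7)
        assert np.array_equal(a.weights_in, b.weights_in)
        assert np.array_equal(a.weights_out, b.weights_out)
        c = train_network(peptides, targets, sched, cfg, 3, seed=8)
        assert not np.array_equal(a.weights_in, c.weights_in)

    def test_memorizes_single_peptide(self):
        cfg = EncodingConfig(scheme="sparse", motif_len=5)
        sched = TrainSchedule(n_iterations=500)
        net = train_network(["ACDEFGH"], [0.8], sched, cfg, 3, seed=0)
        _, score = best_core(net, "ACDEFGH")
        assert abs(score - 0.8) < 0.05

    def test_stop_on_best_test_returns_best_epoch(self):
        peptides, targets = self._toy_data(60, seed=3)
        stop_p, stop_t = self._toy_data(20, seed=4)
        cfg = EncodingConfig(scheme="sparse", motif_len=9)
        net = train_network(
            peptides, targets,
            TrainSchedule(n_iterations=30, stop_on_best_test=True),
            cfg, 3, seed=2, stop_peptides=stop_p, stop_targets=stop_t,
        )
        final = train_network(
            peptides, targets,
            TrainSchedule(n_iterations=30, stop_on_best_test=False),
            cfg, 3, seed=2, stop_peptides=stop_p, stop_targets=stop_t,
        )
        enc = encode_peptides(stop_p, cfg)
        from pepmotif.network import score_batch

        rmse_best = np.sqrt(np.mean((score_batch(net, enc)[1] - np.array(stop_t)) ** 2))
        rmse_final = np.sqrt(np.mean((score_batch(final, enc)[1] - np.array(stop_t)) ** 2))
        assert net.stop_rmse == pytest.approx(rmse_best)
        assert rmse_best <= rmse_final + 1e-12

    def test_stop_set_does_not_change_training(self):
        """Fold hygiene: the stopping set is only read for the RMSE — with
        stopping off, its values cannot change the returned weights."""
        peptides, targets = self._toy_data()
        stop_p, stop_t = self._toy_data(10, seed=9)
        cfg = EncodingConfig(scheme="sparse", motif_len=9)
        sched = TrainSchedule(n_iterations=10, stop_on_best_test=False)
        a = train_network(peptides, targets, sched, cfg, 3, seed=5,
                          stop_peptides=stop_p, stop_targets=stop_t)
        b = train_network(peptides, targets, sched, cfg, 3, seed=5,
                          stop_peptides=stop_p, stop_targets=[1.0 - t for t in stop_t])
        assert np.array_equal(a.weights_in, b.weights_in)

    def test_empty_training_set(self):
        cfg = EncodingConfig(scheme="sparse", motif_len=5)
        with pytest.raises(ValueError):
            train_network([], [], TrainSchedule(n_iterations=1), cfg, 3, seed=0)

    def test_targets_outside_unit_interval_rejected(self):
        cfg = EncodingConfig(scheme="sparse", motif_len=5)
        with pytest.raises(ValueError):
            train_network(["ACDEF"], [1.5], TrainSchedule(n_iterations=1), cfg, 3, 0)
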