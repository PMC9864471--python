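import dataclasses

import numpy as np
import pytest

import corrgcn as cg
from corrgcn.gcnn import loss_and_grads


@pytest.fixture
def tiny_cfg():
    return cg.GCNNConfig(
        m=3, conv_channels=(2,), fc_sizes=(4,), n_classes=2,
        dropout_rate=0.0, batch_size=16, seed=0,
    )


def brute_force_graph_convolve(signal, rf, kernel, bias):
    """Independent triple-loop evaluation of the graph convolution."""
    F = signal.shape[0]
    c_in, W, c_out = kernel.shape
    out = np.zeros((F, c_out))
    for f in range(F):
        for o in range(c_out):
            acc = bias[o]
            for k in range(W):
                for c in range(c_in):
                    acc += signal[rf[f][k], c] * kernel[c, k, o]
            out[f, o] = acc
    return out


class TestInitModel:
    def test_same_seed_bit_identical(self, tiny_cfg, tiny_graph):
        p1 = cg.init_model(tiny_cfg, tiny_graph, seed=42)
        p2 = cg.init_model(tiny_cfg, tiny_graph, seed=42)
        for a, b in zip(p1.flat(), p2.flat()):
            np.testing.assert_array_equal(a, b)

    def test_full_profile_flatten_width(self, rng):
        """Default architecture over 65 features flattens to 65*512 = 33,280."""
        X = rng.standard_normal((100, 65))
        fm = cg.FeatureMatrix(X, [f"f{i}" for i in range(65)], np.array(["s"] * 100, dtype=object))
        g = cg.select_neighborhoods(cg.similarity_matrix(fm), m=9)
        params = cg.init_model(cg.GCNNConfig(), g)
        assert params.fc_weights[0].shape[0] == 65 * 512 == 33280
        assert params.fc_weights[-1].shape[1] == 2
        params4 = cg.init_model(cg.GCNNConfig(n_classes=4), g)
        assert params4.fc_weights[-1].shape[1] == 4
        assert all(np.all(b == 0) for b in params.conv_biases + params.fc_biases)

    def test_width_mismatch_rejected(self, tiny_graph):
        with pytest.raises(ValueError, match="incompatible"):
            cg.init_model(cg.GCNNConfig(m=5, conv_channels=(2,), fc_sizes=(4,)), tiny_graph)


class TestGraphConvolve:
    def test_zero_kernel_gives_zero(self, tiny_graph, rng):
        sig = rng.standard_normal((6, 2))
        out = cg.graph_convolve(sig, tiny_graph, np.zeros((2, 3, 4)), np.zeros(4))
        np.testing.assert_array_equal(out, 0.0)

    def test_center_tap_identity(self, tiny_graph, rng):
        """A kernel that is 1 only at (c=0, k=0, o=0) copies the input
        signal through the center node of every star."""
        sig = rng.standard_normal((6, 1))
        kernel = np.zeros((1, 3, 1))
        kernel[0, 0, 0] = 1.0
        out = cg.graph_convolve(sig, tiny_graph, kernel, np.zeros(1))
        np.testing.assert_allclose(out, sig)

    def test_matches_triple_loop_oracle(self, tiny_graph, rng):
        sig = rng.standard_normal((6, 2))
        kernel = rng.standard_normal((2, 3, 4))
        bias = rng.standard_normal(4)
        out = cg.graph_convolve(sig, tiny_graph, kernel, bias)
        expect = brute_force_graph_convolve(sig, tiny_graph.receptive_fields, kernel, bias)
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_include_self_off_widens_receptive_field(self, tiny_fm, rng):
        g = cg.select_neighborhoods(cg.similarity_matrix(tiny_fm), m=3, include_self=False)
        assert g.width == 4
        sig = rng.standard_normal((6, 2))
        kernel = rng.standard_normal((2, 4, 3))
        out = cg.graph_convolve(sig, g, kernel, np.zeros(3))
        expect = brute_force_graph_convolve(sig, g.receptive_fields, kernel, np.zeros(3))
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_shape_mismatch(self, tiny_graph, rng):
        with pytest.raises(ValueError):
            cg.graph_convolve(rng.standard_normal((6, 2)), tiny_graph,
                              np.zeros((2, 5, 4)), np.zeros(4))


class TestForward:
    def test_zero_weights_uniform_probabilities(self, tiny_cfg, tiny_graph):
        params = cg.init_model(tiny_cfg, tiny_graph)
        for t in params.flat():
            t[...] = 0.0
        probs = cg.forward(params, tiny_cfg, tiny_graph, np.random.default_rng(0).standard_normal((5, 6)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-12)

    def test_rows_sum_to_one(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph)
        probs = cg.forward(params, tiny_cfg, tiny_graph, rng.standard_normal((17, 6)))
        assert probs.min() >= 0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_per_row(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph, seed=3)
        X = rng.standard_normal((8, 6))
        joint = cg.forward(params, tiny_cfg, tiny_graph, X)
        single = np.vstack([cg.forward(params, tiny_cfg, tiny_graph, X[i : i + 1]) for i in range(8)])
        np.testing.assert_allclose(joint, single, atol=1e-12)

    def test_initial_loss_is_log_k_with_zero_output_layer(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph, seed=1)
        params.fc_weights[-1][...] = 0.0
        params.fc_biases[-1][...] = 0.0
        X = rng.standard_normal((32, 6))
        y = np.repeat([0, 1], 16)
        loss, _ = loss_and_grads(params, tiny_cfg, tiny_graph, X, y, train_mode=False)
        assert loss == pytest.approx(np.log(2), abs=1e-10)


class TestGradients:
    def test_analytic_matches_finite_difference(self, tiny_cfg, tiny_graph, rng):
        """Finite-difference check of every parameter tensor on a tiny model."""
        params = cg.init_model(tiny_cfg, tiny_graph, seed=0)
        X = rng.standard_normal((12, 6))
        y = rng.integers(0, 2, 12)
        _, grads = loss_and_grads(params, tiny_cfg, tiny_graph, X, y, train_mode=False)
        eps = 1e-6
        for t, gt in zip(params.flat(), grads.flat()):
            flat_idx = np.linspace(0, t.size - 1, min(t.size, 8)).astype(int)
            for fi in flat_idx:
                ix = np.unravel_index(fi, t.shape)
                old = t[ix]
                t[ix] = old + eps
                lp, _ = loss_and_grads(params, tiny_cfg, tiny_graph, X, y, train_mode=False)
                t[ix] = old - eps
                lm, _ = loss_and_grads(params, tiny_cfg, tiny_graph, X, y, train_mode=False)
                t[ix] = old
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(gt[ix]), 1e-8)
                assert abs(num - gt[ix]) / denom < 1e-4

    def test_permutation_consistency(self, tiny_cfg, tiny_fm, rng):
        """Relabeling features (and permuting the graph and the flatten
        order accordingly) leaves class probabilities unchanged."""
        g = cg.select_neighborhoods(cg.similarity_matrix(tiny_fm), m=3)
        params = cg.init_model(tiny_cfg, g, seed=5)
        X = rng.standard_normal((10, 6))
        base = cg.forward(params, tiny_cfg, g, X)

        perm = rng.permutation(6)
        inv = np.argsort(perm)
        g_p = cg.NeighborhoodGraph(
            g.m, g.include_self,
            inv[g.neighbor_indices][perm],
            g.neighbor_similarities[perm],
            [g.feature_names[i] for i in perm],
        )
        params_p = params.copy()
        c_last = params.conv_kernels[-1].shape[-1]
        w0 = params.fc_weights[0].reshape(6, c_last, -1)
        params_p.fc_weights[0] = w0[perm].reshape(6 * c_last, -1)
        out = cg.forward(params_p, tiny_cfg, g_p, X[:, perm])
        np.testing.assert_allclose(out, base, atol=1e-10)


class TestTraining:
    def test_zero_epochs_returns_params_unchanged(self, tiny_cfg, tiny_graph, rng):
        cfg = dataclasses.replace(tiny_cfg, max_epochs=0)
        params = cg.init_model(cfg, tiny_graph, seed=2)
        X, y = rng.standard_normal((20, 6)), rng.integers(0, 2, 20)
        out, hist = cg.train(params, cfg, tiny_graph, (X, y), (X, y))
        assert hist.n_epochs == 0
        for a, b in zip(out.flat(), params.flat()):
            np.testing.assert_array_equal(a, b)

    def test_fixed_seed_identical_history(self, tiny_cfg, tiny_graph, rng):
        cfg = dataclasses.replace(tiny_cfg, max_epochs=4, dropout_rate=0.1)
        X, y = rng.standard_normal((60, 6)), rng.integers(0, 2, 60)
        params = cg.init_model(cfg, tiny_graph, seed=0)
        _, h1 = cg.train(params, cfg, tiny_graph, (X[:48], y[:48]), (X[48:], y[48:]))
        _, h2 = cg.train(params, cfg, tiny_graph, (X[:48], y[:48]), (X[48:], y[48:]))
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_learns_separable_toy_problem(self, tiny_cfg, tiny_graph, rng):
        cfg = dataclasses.replace(tiny_cfg, max_epochs=30, patience=30, learning_rate=0.01)
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 6)) + 3.0 * y[:, None]
        params = cg.init_model(cfg, tiny_graph, seed=0)
        trained, hist = cg.train(params, cfg, tiny_graph, (X, y), (X, y))
        preds = cg.predict(trained, cfg, tiny_graph, X)
        assert (preds == y).mean() > 0.95
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_bad_labels_rejected(self, tiny_cfg, tiny_graph, rng):
        X = rng.standard_normal((20, 6))
        params = cg.init_model(tiny_cfg, tiny_graph)
        with pytest.raises(ValueError, match="labels"):
            cg.train(params, tiny_cfg, tiny_graph, (X, np.full(20, 7)), (X, np.zeros(20, int)))


class TestPredict:
    def test_argmax_and_tie_break(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph)
        for t in params.flat():
            t[...] = 0.0  # uniform probabilities -> exact tie -> class 0
        preds = cg.predict(params, tiny_cfg, tiny_graph, rng.standard_normal((7, 6)))
        assert preds.tolist() == [0] * 7

    def test_feature_name_mismatch(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph)
        fm = cg.FeatureMatrix(
            rng.standard_normal((4, 6)), [f"g{i}" for i in range(6)],
            np.array(["s"] * 4, dtype=object),
        )
        with pytest.raises(ValueError, match="feature names"):
            cg.predict(params, tiny_cfg, tiny_graph, fm)

    def test_output_length(self, tiny_cfg, tiny_graph, rng):
        params = cg.init_model(tiny_cfg, tiny_graph)
        assert len(cg.predict(params, tiny_cfg, tiny_graph, rng.standard_normal((13, 6)))) == 13


def test_checkpoint_round_trip(tmp_path, tiny_cfg, tiny_graph):
    params = cg.init_model(tiny_cfg, tiny_graph, seed=9)
    p = tmp_path / "ckpt.npz"
    cg.save_checkpoint(p, params, tiny_cfg)
    back_params, back_cfg = cg.load_checkpoint(p)
    assert back_cfg == tiny_cfg
    for a, b in zip(params.flat(), back_params.flat()):
        np.testing.assert_array_equal(a, b)
    assert back_params.feature_names == params.feature_names
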