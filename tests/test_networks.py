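import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    c1_forward_loops,
    c2_forward_loops,
    dense_forward_loops,
    finite_difference_grads,
)
from ssvepkit import networks as nw

TINY = dict(n_fs=12, n_ch=3, c1_maps=2, c2_kernel=3, f3_units=2,
            nn_hidden=(6, 4), n_classes=3)


def tiny_spec(arch, **over):
    return nw.NetworkSpec(arch, **{**TINY, **over})


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert nw.sigmoid(0.0) == 0.5

    def test_odd_symmetry(self):
        s = np.linspace(-30, 30, 101)
        np.testing.assert_allclose(nw.sigmoid(s) + nw.sigmoid(-s), 1.0, atol=1e-15)

    def test_extreme_inputs_saturate_cleanly(self):
        with np.errstate(over="raise"):
            assert nw.sigmoid(700.0) == 1.0
            assert nw.sigmoid(-700.0) < 1e-300


class TestSpec:
    def test_c2_units_from_valid_convolution(self):
        assert nw.NetworkSpec("cnn1").c2_units == 110

    def test_nn_input_vector_length(self):
        assert nw.NetworkSpec("nn").input_size == 960

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            nw.NetworkSpec("cnn3")
        with pytest.raises(ValueError):
            nw.NetworkSpec("cnn1", n_fs=5, c2_kernel=11)
        with pytest.raises(ValueError):
            nw.NetworkSpec("cnn2", f3_units=0)


class TestForwardOracles:
    def test_zero_weights_give_half_everywhere(self):
        spec = tiny_spec("cnn1")
        w = {k: np.zeros_like(v) for k, v in nw.init_weights(spec, 0).items()}
        acts = nw.forward(spec, w, np.random.default_rng(0).random((2, 12, 3)))
        for key in ("c1", "c2", "out"):
            assert np.all(acts[key] == 0.5)

    def test_one_hot_c1_kernel_selects_channel(self):
        spec = tiny_spec("cnn1", c1_maps=1)
        w = nw.init_weights(spec, 0)
        w["c1_w"] = np.array([[0.0, 1.0, 0.0]])
        w["c1_b"] = np.zeros(1)
        X = np.random.default_rng(1).random((1, 12, 3))
        acts = nw.forward(spec, w, X)
        np.testing.assert_allclose(acts["c1"][0, 0], nw.sigmoid(X[0, :, 1]), atol=1e-15)

    def test_delta_c2_kernel_passes_map_through(self):
        spec = tiny_spec("cnn1", c1_maps=1)
        w = nw.init_weights(spec, 0)
        w["c2_w"] = np.zeros((1, 1, 3))
        w["c2_w"][0, 0, 0] = 1.0
        w["c2_b"] = np.zeros(1)
        X = np.random.default_rng(2).random((1, 12, 3))
        acts = nw.forward(spec, w, X)
        np.testing.assert_allclose(
            acts["c2"][0, 0], nw.sigmoid(acts["c1"][0, 0, :10]), atol=1e-15
        )

    @pytest.mark.parametrize("arch", ["cnn1", "cnn2"])
    def test_matches_nested_loop_oracles(self, arch):
        """Vectorized forward pass equals the scalar triple/quadruple loops."""
        spec = tiny_spec(arch)
        rng = np.random.default_rng(11)
        w = nw.init_weights(spec, 4)
        X = rng.random((3, spec.n_fs, spec.n_ch))
        acts = nw.forward(spec, w, X)
        for b in range(3):
            x1 = c1_forward_loops(X[b], w["c1_w"], w["c1_b"])
            np.testing.assert_allclose(acts["c1"][b], x1, atol=1e-12)
            x2 = c2_forward_loops(x1, w["c2_w"], w["c2_b"])
            np.testing.assert_allclose(acts["c2"][b], x2, atol=1e-12)
            flat = x2.reshape(-1)
            if arch == "cnn2":
                f3 = dense_forward_loops(flat, w["f3_w"], w["f3_b"])
                np.testing.assert_allclose(acts["f3"][b], f3, atol=1e-12)
                flat = f3
            out = dense_forward_loops(flat, w["out_w"], w["out_b"])
            np.testing.assert_allclose(acts["out"][b], out, atol=1e-12)

    def test_nn_matches_dense_oracle(self):
        spec = tiny_spec("nn")
        rng = np.random.default_rng(12)
        w = nw.init_weights(spec, 5)
        X = rng.random((2, spec.n_fs, spec.n_ch))
        acts = nw.forward(spec, w, X)
        for b in range(2):
            x = X[b].reshape(-1)
            for name in spec.layer_names():
                x = dense_forward_loops(x, w[f"{name}_w"], w[f"{name}_b"])
            np.testing.assert_allclose(acts["out"][b], x, atol=1e-12)

    def test_shape_mismatch_raises(self):
        spec = tiny_spec("cnn1")
        w = nw.init_weights(spec, 0)
        with pytest.raises(ValueError, match="does not match"):
            nw.forward(spec, w, np.zeros((2, 5, 3)))


class TestInitWeights:
    @pytest.mark.parametrize("arch", ["cnn1", "cnn2", "nn"])
    def test_bound_respected_over_seeds(self, arch):
        spec = nw.NetworkSpec(arch)
        bounds = {
            "c1_w": np.sqrt(6 / (spec.n_ch + spec.c1_maps)),
            "c2_w": np.sqrt(6 / (spec.c1_maps * spec.c2_kernel * 2)),
            "f3_w": np.sqrt(6 / (880 + 3)),
        }
        for seed in range(10):
            w = nw.init_weights(spec, seed)
            for key, arr in w.items():
                if key.endswith("_b"):
                    assert np.all(arr == 0.0)
                elif key in bounds:
                    assert np.max(np.abs(arr)) <= bounds[key]

    def test_deterministic_per_seed(self):
        a = nw.init_weights(nw.NetworkSpec("cnn1"), 3)
        b = nw.init_weights(nw.NetworkSpec("cnn1"), 3)
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_large_layer_mean_near_zero(self):
        w = nw.init_weights(nw.NetworkSpec("nn"), 0)["h1_w"]  # 500 x 960
        limit = np.sqrt(6 / (960 + 500))
        se = limit / np.sqrt(3) / np.sqrt(w.size)
        assert abs(w.mean()) < 3 * se

    @pytest.mark.parametrize(
        "arch,shared", [("cnn1", False), ("cnn1", True), ("cnn2", False), ("nn", False)]
    )
    def test_parameter_count_identity(self, arch, shared):
        """The weight store holds exactly the topology-implied parameter count."""
        spec = nw.NetworkSpec(arch, c2_shared_kernel=shared)
        w = nw.init_weights(spec, 0)
        assert sum(a.size for a in w.values()) == nw.n_parameters(spec)

    def test_default_cnn1_parameter_breakdown(self):
        # C1: 8*(8+1); C2: 8 output maps x 8 input maps x 11 taps + 8 biases;
        # L3: 5 x (880 + 1)
        assert nw.n_parameters(nw.NetworkSpec("cnn1")) == 72 + 712 + 4405


class TestGradients:
    @pytest.mark.parametrize(
        "arch,shared",
        [("cnn1", False), ("cnn1", True), ("cnn2", False), ("nn", False)],
    )
    @pytest.mark.parametrize("loss", ["mse", "cross_entropy"])
    def test_backprop_matches_central_finite_differences(self, arch, shared, loss):
        """Analytic gradients agree with finite differences for every weight."""
        spec = tiny_spec(arch, c2_shared_kernel=shared)
        rng = np.random.default_rng(21)
        w = nw.init_weights(spec, 8)
        X = rng.random((4, spec.n_fs, spec.n_ch))
        T = np.eye(spec.n_classes)[rng.integers(0, spec.n_classes, 4)]
        _, grads, _ = nw.loss_and_grads(spec, w, X, T, loss)
        fd = finite_difference_grads(
            lambda: nw.loss_and_grads(spec, w, X, T, loss)[0], w
        )
        for key in w:
            denom = np.maximum(np.abs(grads[key]) + np.abs(fd[key]), 1e-6)
            assert np.max(np.abs(grads[key] - fd[key]) / denom) < 1e-5, key


class TestTraining:
    def test_separable_classes_reach_low_error(self):
        """Well-separated Gaussian blobs are fit to <=5% training error."""
        spec = nw.NetworkSpec("nn", n_fs=2, n_ch=1, nn_hidden=(8,), n_classes=3)
        rng = np.random.default_rng(0)
        centers = np.array([[0.1, 0.1], [0.9, 0.1], [0.5, 0.9]])
        X = np.concatenate(
            [centers[i] + 0.05 * rng.standard_normal((40, 2)) for i in range(3)]
        )[:, :, None]
        y = np.repeat([9.0, 11.0, 13.0], 40)
        model = nw.train(spec, X, y, nw.TrainingConfig(seed=1, batch_size=1))
        assert model.history[-1] <= 0.05

    def test_single_iteration_budget(self):
        spec = tiny_spec("cnn1")
        X = np.random.default_rng(0).random((6, 12, 3))
        y = np.array([9.0, 11.0, 13.0] * 2)
        model = nw.train(spec, X, y, nw.TrainingConfig(max_iterations=1))
        assert model.stopped_at == 1 and model.history.size == 1

    def test_stopping_rule_halts_on_plateau(self):
        spec = tiny_spec("cnn1")
        X = np.random.default_rng(0).random((6, 12, 3))
        y = np.array([9.0, 11.0, 13.0] * 2)
        model = nw.train(spec, X, y, nw.TrainingConfig(max_iterations=50))
        if model.stopped_at < 50:  # rule fired: improvement over window < 0.5 pp
            w = model.config.stop_window
            assert model.history[-1 - w] - model.history[-1] < 0.005
            assert model.stopped_at > w

    def test_training_deterministic(self):
        spec = tiny_spec("cnn1")
        X = np.random.default_rng(0).random((9, 12, 3))
        y = np.array([9.0, 11.0, 13.0] * 3)
        cfg = nw.TrainingConfig(max_iterations=3, seed=5)
        a = nw.train(spec, X, y, cfg)
        b = nw.train(spec, X, y, cfg)
        assert all(np.array_equal(a.weights[k], b.weights[k]) for k in a.weights)
        np.testing.assert_array_equal(a.history, b.history)

    def test_missing_class_rejected(self):
        spec = tiny_spec("cnn1")
        X = np.random.default_rng(0).random((4, 12, 3))
        with pytest.raises(ValueError, match="classes"):
            nw.train(spec, X, np.array([9.0, 9.0, 11.0, 11.0]))


class TestPredictAndInspect:
    @pytest.fixture(scope="class")
    def model(self):
        spec = tiny_spec("cnn2")
        X = np.random.default_rng(0).random((9, 12, 3))
        y = np.array([9.0, 11.0, 13.0] * 3)
        return nw.train(spec, X, y, nw.TrainingConfig(max_iterations=2))

    def test_argmax_tie_breaks_to_lowest_class(self):
        spec = tiny_spec("cnn1")
        w = {k: np.zeros_like(v) for k, v in nw.init_weights(spec, 0).items()}
        model = nw.TrainedModel(
            spec, w, np.array([9.0, 11.0, 13.0]), np.zeros(1), 1, nw.TrainingConfig()
        )
        # all outputs exactly 0.5 -> lowest class index wins
        assert nw.predict(model, np.random.random((2, 12, 3))).tolist() == [9.0, 9.0]

    def test_activation_shapes(self, model):
        X = np.random.default_rng(1).random((5, 12, 3))
        assert nw.extract_activations(model, X, "c2").shape == (5, 2, 10)
        assert nw.extract_activations(model, X, "f3").shape == (5, 2)

    def test_f3_unavailable_on_cnn1(self):
        spec = tiny_spec("cnn1")
        model = nw.TrainedModel(
            spec, nw.init_weights(spec, 0), np.arange(3), np.zeros(1), 1,
            nw.TrainingConfig(),
        )
        with pytest.raises(ValueError, match="not available"):
            nw.extract_activations(model, np.zeros((1, 12, 3)), "f3")

    def test_model_roundtrip(self, model, tmp_path):
        path = tmp_path / "model.npz"
        model.save_npz(path)
        loaded = nw.TrainedModel.load_npz(path)
        X = np.random.default_rng(2).random((4, 12, 3))
        np.testing.assert_array_equal(nw.predict(model, X), nw.predict(loaded, X))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_outputs_strictly_inside_unit_interval(self, seed):
        spec = tiny_spec("cnn2")
        rng = np.random.default_rng(seed)
        w = nw.init_weights(spec, seed % 100)
        out = nw.forward(spec, w, rng.random((2, 12, 3)))["out"]
        assert np.all(out > 0.0) and np.all(out < 1.0)
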