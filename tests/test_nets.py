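"""Regressor construction, backprop correctness, training and persistence."""

import numpy as np
import pytest

from craniomark import _nn
from craniomark.errors import FormatError, InputError, ParameterError
from craniomark.nets import (
    RegressorSpec,
    TrainingConfig,
    build_regressor,
    load_weights,
    save_weights,
    train,
)

TINY = dict(blocks=(1,), block_type="basic", base_channels=2, width_scale=1.0,
            head="flatten")


def _toy_dataset(rng, n=40, shape=(12, 12, 8), n_out=3):
    """Random binary stacks with targets linear in the voxel content."""
    x = (rng.random((n, *shape)) > 0.7).astype(np.uint8)
    w = rng.normal(size=(np.prod(shape), n_out))
    y = x.reshape(n, -1) @ w + 5.0
    return x, y


class TestBuild:
    def test_phase1_output_dimensionality(self):
        spec = RegressorSpec(input_shape=(96, 96, 81), n_outputs=48,
                             blocks=(1,), block_type="basic",
                             base_channels=64, width_scale=0.05, head="avgpool")
        model = build_regressor(spec)
        out = model.forward(np.zeros((2, 1, 96, 96, 81), dtype=np.float32))
        assert out.shape == (2, 48)

    def test_refinement_output_dimensionality_and_linear_head(self, rng):
        spec = RegressorSpec(input_shape=(20, 20, 12), n_outputs=3, **TINY)
        model = build_regressor(spec)
        x = rng.random((2, 20, 20, 12))
        out = model.predict(x)
        assert out.shape == (2, 3)
        assert np.isfinite(out).all()
        # a linear head is unbounded: scaling the scaler scales outputs
        model.target_std = np.full(3, 100.0, dtype=np.float32)
        assert np.abs(model.predict(x)).max() > 1.0

    def test_default_depth_is_fifty_layers(self):
        # 1 stem conv + 3*(3+4+6+3) block convs + 1 dense = 50 weight layers
        spec = RegressorSpec(input_shape=(96, 96, 81), n_outputs=48)
        n_conv = 1 + 3 * sum(spec.blocks)
        assert n_conv + 1 == 50

    def test_invalid_specs(self):
        with pytest.raises(ParameterError):
            RegressorSpec(input_shape=(96, 96, 81), n_outputs=7)
        with pytest.raises(ParameterError):
            RegressorSpec(input_shape=(96, 96, 81), n_outputs=48, width_scale=0.0)
        with pytest.raises(ParameterError):
            # four stride-2 stages cannot fit a 4-voxel extent
            build_regressor(
                RegressorSpec(input_shape=(16, 16, 4), n_outputs=3,
                              blocks=(1, 1, 1, 1), block_type="basic",
                              base_channels=2)
            )


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic gradients agree with central differences (float64)."""
        spec = RegressorSpec(input_shape=(8, 8, 6), n_outputs=3, **TINY, seed=1)
        model = build_regressor(spec)
        for p in model.params():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        x = rng.random((2, 1, 8, 8, 6))
        y = rng.random((2, 3))

        pred = model.forward(x)
        _, g = _nn.mse_loss(pred, y)
        model.net.backward(g.astype(np.float64))

        def loss():
            return float(np.mean((model.forward(x) - y) ** 2))

        for p in model.params():
            flat = p.value.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + 1e-6
                lp = loss()
                flat[i] = old - 1e-6
                lm = loss()
                flat[i] = old
                num = (lp - lm) / 2e-6
                ana = p.grad.ravel()[i]
                assert abs(num - ana) <= 1e-5 + 1e-4 * abs(num)

    def test_bottleneck_block_shapes(self, rng):
        block = _nn.bottleneck_block(4, 2, stride=2, rng=np.random.default_rng(0))
        x = rng.random((1, 4, 8, 8, 8)).astype(np.float32)
        y = block.forward(x)
        assert y.shape == (1, 8, 4, 4, 4)
        dx = block.backward(np.ones_like(y))
        assert dx.shape == x.shape


class TestTraining:
    def test_loss_decreases(self, rng):
        x, y = _toy_dataset(rng)
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY, seed=2)
        model = build_regressor(spec)
        train(model, (x, y), TrainingConfig(batch_size=8, epochs=8, seed=0,
                                            learning_rate=3e-3))
        assert model.history[-1] < model.history[0]

    def test_constant_targets_are_fit_exactly(self, rng):
        x = (rng.random((30, 12, 12, 8)) > 0.7).astype(np.uint8)
        c = np.array([7.0, -3.0, 42.0])
        y = np.tile(c, (30, 1))
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY, seed=3)
        model = build_regressor(spec)
        train(model, (x, y), TrainingConfig(batch_size=8, epochs=20, seed=0,
                                            learning_rate=3e-3))
        assert model.history[-1] < 1e-2
        np.testing.assert_allclose(model.predict(x[:5]), np.tile(c, (5, 1)), atol=0.5)

    def test_duplicated_dataset_reaches_same_minimum(self, rng):
        x = (rng.random((20, 12, 12, 8)) > 0.7).astype(np.uint8)
        c = np.array([1.0, 2.0, 3.0])
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY, seed=4)
        model = build_regressor(spec)
        xd = np.concatenate([x, x])
        yd = np.tile(c, (40, 1))
        train(model, (xd, yd), TrainingConfig(batch_size=8, epochs=20, seed=0,
                                              learning_rate=3e-3))
        np.testing.assert_allclose(model.predict(x[:5]), np.tile(c, (5, 1)), atol=0.5)

    def test_empty_or_mismatched_dataset(self, rng):
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY)
        model = build_regressor(spec)
        with pytest.raises(InputError):
            train(model, (np.zeros((0, 12, 12, 8)), np.zeros((0, 3))),
                  TrainingConfig(epochs=1))
        x, _ = _toy_dataset(rng, n=4)
        with pytest.raises(InputError):
            train(model, (x, np.zeros((4, 48))), TrainingConfig(epochs=1))


class TestPersistence:
    def test_save_load_bit_identical_predictions(self, tmp_path, rng):
        x, y = _toy_dataset(rng, n=16)
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY, seed=5)
        model = build_regressor(spec)
        path = train(model, (x, y), TrainingConfig(batch_size=8, epochs=2, seed=0),
                     out_path=tmp_path / "m.w")
        assert path.exists()
        loaded = load_weights(path)
        np.testing.assert_array_equal(loaded.predict(x), model.predict(x))

    def test_corrupt_file_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.w"
        bad.write_bytes(b"not a weights file at all")
        with pytest.raises(FormatError):
            load_weights(bad)
        with pytest.raises(FormatError):
            load_weights(tmp_path / "missing.w")

    def test_spec_mismatch_detected(self, tmp_path, rng):
        spec = RegressorSpec(input_shape=(12, 12, 8), n_outputs=3, **TINY, seed=6)
        model = build_regressor(spec)
        save_weights(model, tmp_path / "m.w")
        other = RegressorSpec(input_shape=(20, 20, 8), n_outputs=3, **TINY, seed=6)
        with pytest.raises(FormatError):
            load_weights(tmp_path / "m.w", expected_spec=other)
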