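"""Architecture arithmetic, network numerics, training and the majority rule.

Unit tests run the network at reduced block sizes (the convolution and
pooling arithmetic is size-generic); the canonical 16x16x200 geometry is
pinned by the layer-shape anchor test.
"""

import numpy as np
import pytest

from microflow import flow_classifier as fc
from microflow._network import ConvNet3D

SMALL = (12, 12, 14)  # smallest shape the 7/5/2 layer stack accepts comfortably


class TestLayerOutputShapes:
    def test_canonical_block_flattens_to_6840(self):
        shapes = fc.layer_output_shapes(input_shape=(16, 16, 200))
        assert shapes == [(10, 10, 194, 8), (6, 6, 190, 8), (3, 3, 95, 8), (6840,)]

    def test_minimal_input_for_first_conv(self):
        assert fc.layer_output_shapes(input_shape=(7, 7, 7))[0] == (1, 1, 1, 8)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            fc.layer_output_shapes(input_shape=(6, 6, 6))


class TestNormalizeBlock:
    def test_linear_rescale(self):
        block = np.array([[[10.0, 20.0, 30.0]]])
        out = fc.normalize_block(block)
        np.testing.assert_allclose(out, [[[0.0, 0.5, 1.0]]])

    def test_constant_block_maps_to_zeros(self):
        out = fc.normalize_block(np.full((4, 4, 4), 9.0))
        assert out.max() == 0.0

    def test_idempotent_on_unit_range(self):
        rng = np.random.default_rng(0)
        b = rng.random((4, 4, 4))
        b[0, 0, 0], b[1, 1, 1] = 0.0, 1.0
        np.testing.assert_allclose(fc.normalize_block(fc.normalize_block(b)),
                                   fc.normalize_block(b), atol=1e-7)

    def test_nonfinite_rejected(self):
        b = np.ones((2, 2, 2))
        b[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            fc.normalize_block(b)


class TestNetworkNumerics:
    def test_gradients_match_finite_differences(self):
        """Backprop through both convolutions, pooling and the MLP agrees
        with central finite differences."""
        net = ConvNet3D(SMALL, hidden=5, seed=3)
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        rng = np.random.default_rng(0)
        x = rng.random((3,) + SMALL).astype(np.float32)
        y = np.array([0, 1, 1])
        _, grads = net.loss_and_grads(x, y)
        eps = 1e-6
        for k, p in net.params.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = net.loss_and_grads(x, y)
                p[idx] = orig - eps
                lm, _ = net.loss_and_grads(x, y)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k][idx] == pytest.approx(num, rel=1e-3, abs=1e-6), k

    def test_softmax_outputs_sum_to_one(self):
        net = ConvNet3D(SMALL, hidden=4, seed=0)
        rng = np.random.default_rng(1)
        prob = net.predict_proba(rng.random((5,) + SMALL).astype(np.float32))
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-6)
        assert (prob >= 0).all() and (prob <= 1).all()

    def test_inference_deterministic(self):
        net = ConvNet3D(SMALL, hidden=4, seed=0)
        rng = np.random.default_rng(2)
        x = rng.random((4,) + SMALL).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))


class TestTrainCNN:
    def test_learns_separable_fixture(self, separable_blocks):
        """On blocks separable by temporal variance the training error
        falls below 0.1 within a modest number of epochs."""
        blocks, labels = separable_blocks
        cfg = fc.CNNConfig(input_shape=blocks.shape[1:], max_epochs=18, seed=0)
        model, hist = fc.train_cnn(blocks, labels, cfg)
        assert min(hist.error_rate) < 0.1
        assert all(np.isfinite(hist.loss))
        # loss trend is downward: 5-epoch moving average decreases overall
        ma = np.convolve(hist.loss, np.ones(5) / 5, mode="valid")
        assert ma[-1] < ma[0]

    def test_seeded_training_reproducible(self, separable_blocks):
        blocks, labels = separable_blocks
        cfg = fc.CNNConfig(input_shape=blocks.shape[1:], max_epochs=2, seed=7)
        m1, h1 = fc.train_cnn(blocks[:40], labels[:40], cfg)
        m2, h2 = fc.train_cnn(blocks[:40], labels[:40], cfg)
        assert h1.loss == h2.loss
        np.testing.assert_array_equal(m1.predict_proba(blocks[:4]),
                                      m2.predict_proba(blocks[:4]))

    def test_single_class_rejected(self):
        blocks = np.zeros((4,) + SMALL, dtype=np.float32)
        with pytest.raises(ValueError, match="each class"):
            fc.train_cnn(blocks, np.ones(4, dtype=int),
                         fc.CNNConfig(input_shape=SMALL))


class TestPredictAndDecide:
    def test_predict_pixel_in_unit_interval(self):
        model = fc.CNNModel(fc.CNNConfig(input_shape=SMALL, mlp_hidden=4, seed=0))
        rng = np.random.default_rng(0)
        p = fc.predict_pixel(model, rng.random(SMALL).astype(np.float32))
        assert 0.0 <= p <= 1.0

    def test_shape_mismatch_rejected(self):
        model = fc.CNNModel(fc.CNNConfig(input_shape=SMALL, mlp_hidden=4, seed=0))
        with pytest.raises(ValueError, match="match the model input"):
            model.predict_proba(np.zeros((1, 8, 8, 8), dtype=np.float32))

    def test_three_of_four_is_flowing(self):
        d = fc.decide_vessel([0.9, 0.8, 0.7, 0.2])
        assert d.flowing_fraction == 0.75
        assert d.vessel_flowing

    def test_none_flowing(self):
        d = fc.decide_vessel([0.1, 0.2, 0.3, 0.4])
        assert d.flowing_fraction == 0.0
        assert not d.vessel_flowing

    def test_exact_half_is_not_flowing(self):
        d = fc.decide_vessel([0.9, 0.9, 0.1, 0.1])
        assert d.flowing_fraction == 0.5
        assert not d.vessel_flowing  # strictly-greater-than majority

    def test_threshold_boundary_is_inclusive(self):
        d = fc.decide_vessel([0.5, 0.5, 0.5])
        assert d.pixel_labels.tolist() == [1, 1, 1]
        assert d.vessel_flowing

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fc.decide_vessel([])

    def test_monotone_in_pixel_probabilities(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            probs = rng.random(6)
            base = fc.decide_vessel(probs)
            if base.vessel_flowing:
                raised = probs.copy()
                raised[rng.integers(0, 6)] = 1.0
                assert fc.decide_vessel(raised).vessel_flowing


class TestLogisticBaseline:
    def test_beats_chance_on_separable_fixture(self, separable_blocks):
        blocks, labels = separable_blocks
        model = fc.train_logistic_baseline(blocks, labels, seed=0)
        acc = ((model.predict_proba(blocks) >= 0.5).astype(int) == labels).mean()
        assert acc > 0.5

    def test_coefficient_length_is_flattened_block(self, separable_blocks):
        blocks, labels = separable_blocks
        model = fc.train_logistic_baseline(blocks[:40], labels[:40], seed=0)
        assert model.clf.coef_.shape == (1, int(np.prod(blocks.shape[1:])))
        assert model.coef_length == int(np.prod(blocks.shape[1:]))

    def test_deterministic_for_seed(self, separable_blocks):
        blocks, labels = separable_blocks
        m1 = fc.train_logistic_baseline(blocks[:40], labels[:40], seed=3)
        m2 = fc.train_logistic_baseline(blocks[:40], labels[:40], seed=3)
        np.testing.assert_array_equal(m1.predict_proba(blocks[:5]),
                                      m2.predict_proba(blocks[:5]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            fc.train_logistic_baseline(np.zeros((4,) + SMALL, dtype=np.float32),
                                       np.zeros(4, dtype=int))
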