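import dataclasses

import numpy as np
import pytest

from radiomap import secnn
from radiomap.layers import sigmoid
from radiomap.mapping import MappingSet, build_mappings, fit_normalizer, spiral_layout
from radiomap.secnn import (
    ConvStackConfig,
    SEBlockParams,
    TrainConfig,
    bce_grad,
    bce_loss,
    build_model,
    excite,
    se_block,
    se_scale,
    squeeze,
    train,
    predict,
)
from radiomap.selection import SelectedFeatures
from radiomap.split import TrainValSplit

SMALL = ConvStackConfig(filters=(8, 8), se_reduction=4, dense_units=8,
                        input_side=8, dropout_rate=0.0)


def se_block_bruteforce(u, params):
    """Loop-based oracle for squeeze → excite → scale on one tensor."""
    c, h, w = u.shape
    z = np.array([u[ch].sum() / (h * w) for ch in range(c)])
    hidden = params.W1 @ z
    hidden = np.where(hidden > 0, hidden, 0.0)
    s = 1.0 / (1.0 + np.exp(-(params.W2 @ hidden)))
    out = np.empty_like(u)
    for ch in range(c):
        out[ch] = s[ch] * u[ch]
    return out


def _random_se_params(c, r, rng):
    return SEBlockParams(c, r, rng.normal(size=(c // r, c)), rng.normal(size=(c, c // r)))


class TestSEPrimitives:
    def test_squeeze_of_constant_channel_is_the_constant(self):
        u = np.full((3, 4, 5), 0.0)
        u[1] = 7.5
        np.testing.assert_allclose(squeeze(u), [0.0, 7.5, 0.0])

    def test_squeeze_direct_mean(self):
        u = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        np.testing.assert_allclose(squeeze(u), [2.5])

    def test_squeeze_linearity(self, rng):
        u, v = rng.normal(size=(2, 4, 3, 3))
        np.testing.assert_allclose(
            squeeze(2.0 * u - 3.0 * v), 2.0 * squeeze(u) - 3.0 * squeeze(v), atol=1e-12
        )

    def test_excite_zero_weights_gives_half_gates(self):
        params = SEBlockParams(4, 2, np.zeros((2, 4)), np.zeros((4, 2)))
        np.testing.assert_allclose(excite(np.ones(4), params), 0.5)

    def test_excite_hand_computed_two_channel_example(self):
        # C=2, r=1: W1 = [[1, -1], [2, 0]], W2 = [[1, 0], [-1, 1]]
        params = SEBlockParams(2, 1,
                               np.array([[1.0, -1.0], [2.0, 0.0]]),
                               np.array([[1.0, 0.0], [-1.0, 1.0]]))
        z = np.array([1.0, 3.0])
        hidden = np.maximum(params.W1 @ z, 0)        # [0, 2]
        expected = sigmoid(params.W2 @ hidden)       # sigmoid([0, 2])
        np.testing.assert_allclose(excite(z, params), expected, atol=1e-9)
        np.testing.assert_allclose(expected, [0.5, 1 / (1 + np.exp(-2.0))], atol=1e-9)

    def test_excite_range_is_open_unit_interval(self, rng):
        params = _random_se_params(8, 4, rng)
        s = excite(rng.normal(size=8) * 10, params)
        assert ((s > 0) & (s < 1)).all()

    def test_se_scale_identity_and_annihilation(self, rng):
        u = rng.normal(size=(3, 4, 4))
        np.testing.assert_array_equal(se_scale(u, np.ones(3)), u)
        np.testing.assert_array_equal(se_scale(u, np.zeros(3)), 0.0 * u)

    def test_se_block_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            c = int(rng.integers(1, 9))
            r = int(rng.choice([d for d in range(1, c + 1) if c % d == 0]))
            h = int(rng.integers(1, 9))
            u = rng.normal(size=(c, h, h))
            params = _random_se_params(c, r, rng)
            np.testing.assert_allclose(
                se_block(u, params), se_block_bruteforce(u, params), atol=1e-6
            )


class TestBCE:
    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([0.0, 1.0, 1.0])
        assert bce_loss(y, y) < 1e-5

    def test_half_probability_single_sample_is_ln2(self):
        assert abs(bce_loss(np.array([0.5]), np.array([1.0])) - np.log(2)) < 1e-12

    def test_gradient_matches_central_finite_differences(self, rng):
        y_true = (rng.random(20) < 0.5).astype(float)
        y_pred = rng.uniform(0.05, 0.95, 20)
        g = bce_grad(y_pred, y_true)
        eps = 1e-6
        for i in range(20):
            yp, ym = y_pred.copy(), y_pred.copy()
            yp[i] += eps
            ym[i] -= eps
            num = (bce_loss(yp, y_true) - bce_loss(ym, y_true)) / (2 * eps)
            assert abs(num - g[i]) / max(abs(num), 1e-8) < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5, 0.5]), np.array([1.0]))


class TestBuildModel:
    def test_cnn_equals_secnn_minus_se_parameter_count(self):
        se = build_model("secnn", seed=0)
        plain = build_model("cnn", seed=0)
        f1, f2 = se.config.filters
        r = se.config.se_reduction
        se_terms = 2 * f1 * f1 // r + 2 * f2 * f2 // r
        assert se.n_params - plain.n_params == se_terms

    def test_seeded_init_is_reproducible(self):
        a = build_model("secnn", SMALL, seed=5)
        b = build_model("secnn", SMALL, seed=5)
        for pa, pb in zip(a.params, b.params, strict=True):
            np.testing.assert_array_equal(pa, pb)

    @pytest.mark.parametrize("kind", ["secnn", "cnn", "cnn1d"])
    def test_forward_gives_probabilities(self, kind, rng):
        net = build_model(kind, SMALL, seed=1)
        x = rng.normal(size=(3, 1, 8, 8)) if kind != "cnn1d" else rng.normal(size=(3, 1, 64))
        p = net.forward(x)
        assert p.shape == (3,) and ((p > 0) & (p < 1)).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            build_model("vgg")
        with pytest.raises(ValueError):
            ConvStackConfig(filters=(30, 64))  # 30 not divisible by r=8
        with pytest.raises(ValueError):
            ConvStackConfig(n_conv_layers=3)

    def test_gate_override_makes_secnn_equal_cnn_with_shared_weights(self, rng):
        se_net = build_model("secnn", SMALL, seed=2)
        cnn_net = build_model("cnn", dataclasses.replace(SMALL, use_se=False), seed=3)
        shared = [lyr for lyr in se_net.layers if lyr.params and not hasattr(lyr, "gate_override")]
        targets = [lyr for lyr in cnn_net.layers if lyr.params]
        for src, dst in zip(shared, targets, strict=True):
            for ps, pd in zip(src.params, dst.params):
                pd[...] = ps
        for blk in se_net.se_blocks():
            blk.gate_override = 1.0
        x = rng.normal(size=(4, 1, 8, 8))
        np.testing.assert_allclose(se_net.forward(x), cnn_net.forward(x), atol=1e-6)


def _toy_mappings(n=60, side=8, d=2.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    vals = rng.standard_normal((n, side, side))
    vals[:, :2, :2] += d * y[:, None, None]  # informative corner cells
    ids = [f"P{i}" for i in range(n)]
    names = [f"original_glcm_M{i}" for i in range(side * side)]
    return MappingSet(ids, vals, spiral_layout(side), names), y, ids


class TestTraining:
    def _split(self, ids, frac=0.75):
        cut = int(len(ids) * frac)
        return TrainValSplit(tuple(ids[:cut]), tuple(ids[cut:]))

    def test_zero_learning_rate_flat_val_loss_stops_after_patience(self):
        mappings, y, ids = _toy_mappings()
        tc = TrainConfig(batch_size=16, learning_rate=0.0, patience=5,
                         max_epochs=50, seed=0)
        net = build_model("cnn", dataclasses.replace(SMALL, use_se=False), seed=0)
        trained = train(net, mappings, y, self._split(ids), tc)
        assert trained.stopped_epoch == 1 + tc.patience
        assert len(trained.history) == trained.stopped_epoch

    def test_improving_run_reaches_max_epochs(self):
        mappings, y, ids = _toy_mappings(d=3.0)
        tc = TrainConfig(batch_size=16, patience=5, max_epochs=3, seed=0)
        net = build_model("secnn", SMALL, seed=0)
        trained = train(net, mappings, y, self._split(ids), tc)
        assert trained.stopped_epoch == 3

    def test_best_validation_weights_are_restored(self):
        mappings, y, ids = _toy_mappings()
        split = self._split(ids)
        tc = TrainConfig(batch_size=16, patience=3, max_epochs=12, seed=1)
        net = build_model("cnn", dataclasses.replace(SMALL, use_se=False), seed=1)
        trained = train(net, mappings, y, split, tc)
        idx = {pid: i for i, pid in enumerate(ids)}
        va = [idx[p] for p in split.val_ids]
        p_va = predict(trained, MappingSet([ids[i] for i in va], mappings.values[va],
                                          mappings.layout, mappings.feature_names))
        val_loss = bce_loss(p_va, y[va].astype(float), reduction="mean")
        assert abs(val_loss - trained.history["val_loss"].min()) < 1e-9

    def test_training_is_deterministic_given_seed(self):
        mappings, y, ids = _toy_mappings()
        tc = TrainConfig(batch_size=16, max_epochs=3, seed=7)
        h = []
        for _ in range(2):
            net = build_model("secnn", SMALL, seed=7)
            trained = train(net, mappings, y, self._split(ids), tc)
            h.append(trained.history)
        assert h[0].equals(h[1])

    def test_single_class_training_labels_rejected(self):
        mappings, y, ids = _toy_mappings()
        tc = TrainConfig(batch_size=16, max_epochs=2, seed=0)
        net = build_model("cnn", dataclasses.replace(SMALL, use_se=False), seed=0)
        with pytest.raises(ValueError):
            train(net, mappings, np.ones_like(y), self._split(ids), tc)

    def test_learned_model_orders_classes_and_predicts_deterministically(self):
        mappings, y, ids = _toy_mappings(n=120, d=2.5)
        tc = TrainConfig(batch_size=20, patience=5, max_epochs=15, seed=2)
        net = build_model("secnn", SMALL, seed=2)
        trained = train(net, mappings, y, self._split(ids), tc)
        p1 = predict(trained, mappings)
        p2 = predict(trained, mappings)
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert p1[y == 1].mean() > p1[y == 0].mean()

    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path):
        mappings, y, ids = _toy_mappings()
        tc = TrainConfig(batch_size=16, max_epochs=2, seed=3)
        net = build_model("secnn", SMALL, seed=3)
        trained = train(net, mappings, y, self._split(ids), tc)
        secnn.save_checkpoint(trained, tmp_path / "ckpt")
        loaded = secnn.load_checkpoint(tmp_path / "ckpt")
        np.testing.assert_allclose(predict(loaded, mappings), predict(trained, mappings),
                                   atol=1e-12)
        assert loaded.stopped_epoch == trained.stopped_epoch
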