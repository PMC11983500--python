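"""Feature-matching network: weight normalization, the analytic loss values,
frozen-source guarantees and the informativeness of learned weights."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import PlantedSource
from chtlm import nn
from chtlm.encoders import EncoderSpec, TrainHyper, build_encoder, fit_encoder, train_source
from chtlm.feature_matching import (
    MatchPair,
    TransferHyper,
    WeightNet,
    default_candidate_pairs,
    matching_loss,
    pair_weights,
    transfer_train,
)


class TestPairWeights:
    def test_nonnegative_and_mean_one(self, rng):
        wn = WeightNet(8, rng=np.random.default_rng(0))
        w = pair_weights(wn, rng.normal(size=(5, 8, 4, 4)))
        assert np.all(w.data >= 0)
        assert np.allclose(w.data.mean(axis=1), 1.0, atol=1e-6)

    def test_zeroed_final_layer_gives_uniform_weights(self, rng):
        wn = WeightNet(6, rng=np.random.default_rng(0))
        wn.fc2.weight.data[:] = 0.0
        wn.fc2.bias.data[:] = 0.0
        w = pair_weights(wn, rng.normal(size=(3, 6, 4, 4)))
        assert np.allclose(w.data, 1.0)

    def test_different_maps_give_different_weights(self, rng):
        wn = WeightNet(8, rng=np.random.default_rng(1))
        w1 = pair_weights(wn, rng.normal(size=(1, 8, 4, 4)))
        w2 = pair_weights(wn, rng.normal(size=(1, 8, 4, 4)))
        assert not np.allclose(w1.data, w2.data)

    def test_channel_mismatch_rejected(self, rng):
        wn = WeightNet(8, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            pair_weights(wn, rng.normal(size=(1, 5, 4, 4)))


class TestMatchingLoss:
    def test_coincident_maps_give_zero_loss(self, rng):
        pair = MatchPair(0, 0, 4, 4, identity_init=True)
        m = rng.normal(size=(3, 4, 6, 6)).astype(np.float32)
        loss = matching_loss(m, m, pair, np.ones((3, 4)))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-10)

    def test_zero_weights_give_zero_loss(self, rng):
        pair = MatchPair(0, 0, 4, 4, identity_init=True)
        a = rng.normal(size=(2, 4, 6, 6))
        b = rng.normal(size=(2, 4, 6, 6))
        loss = matching_loss(a, b, pair, np.zeros((2, 4)))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_unit_vectors_at_right_angle_give_two(self):
        # C=1 maps holding 2-D unit vectors u=(1,0), v=(0,1): ||u-v||^2 = 2-2cos90 = 2
        pair = MatchPair(0, 0, 1, 1, identity_init=True)
        u = np.array([1.0, 0.0]).reshape(1, 1, 2, 1)
        v = np.array([0.0, 1.0]).reshape(1, 1, 2, 1)
        loss = matching_loss(u, v, pair, np.ones((1, 1)))
        assert float(loss.data) == pytest.approx(2.0, abs=1e-6)

    def test_unit_vectors_general_angle(self):
        pair = MatchPair(0, 0, 1, 1, identity_init=True)
        for theta in (0.3, 1.0, 2.5):
            u = np.array([1.0, 0.0]).reshape(1, 1, 2, 1)
            v = np.array([np.cos(theta), np.sin(theta)]).reshape(1, 1, 2, 1)
            loss = matching_loss(u, v, pair, np.ones((1, 1)))
            assert float(loss.data) == pytest.approx(2 - 2 * np.cos(theta), abs=1e-5)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_loss_is_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        pair = MatchPair(0, 0, 3, 5, rng=np.random.default_rng(seed))
        wn = WeightNet(3, rng=np.random.default_rng(seed))
        s = r.normal(size=(2, 3, 5, 5))
        t = r.normal(size=(2, 5, 4, 4))
        w = pair_weights(wn, s)
        assert float(matching_loss(s, t, pair, w).data) >= 0.0

    def test_shape_mismatch_rejected(self, rng):
        pair = MatchPair(0, 0, 3, 5)
        with pytest.raises(ValueError, match="mismatch"):
            matching_loss(rng.normal(size=(1, 4, 5, 5)), rng.normal(size=(1, 5, 4, 4)),
                          pair, np.ones((1, 3)))


class TestGradientFlow:
    def test_target_and_weight_net_receive_gradients_source_does_not(self, rng):
        pair = MatchPair(0, 0, 4, 4, rng=np.random.default_rng(0))
        wn = WeightNet(4, rng=np.random.default_rng(0))
        s_const = nn.Tensor(rng.normal(size=(2, 4, 5, 5)))  # frozen source map
        t = nn.Tensor(rng.normal(size=(2, 4, 5, 5)), requires_grad=True)
        w = pair_weights(wn, s_const)
        loss = matching_loss(s_const, t, pair, w)
        loss.backward()
        assert t.grad is not None and np.abs(t.grad).max() > 0
        assert pair.aligner.weight.grad is not None
        assert any(p.grad is not None and np.abs(p.grad).max() > 0 for p in wn.parameters())
        assert s_const.grad is None


def _tiny_target_data(seed, n=24, planes=4, hw=12):
    r = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    X = r.normal(size=(n, planes, hw, hw)).astype(np.float32)
    # class-dependent pattern in the first plane
    X[y == 1, 0, : hw // 2, :] += 1.5
    return X, y


class TestTransferTrain:
    def test_beta_zero_reduces_to_plain_training(self):
        X, y = _tiny_target_data(0)
        h = TransferHyper(beta=0.0, epochs=2, seed=5)
        planted = PlantedSource(in_channels=X.shape[1], width=8)
        t1 = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=9))
        t1, _, _ = transfer_train(planted, t1, None, X, y, h)
        t2 = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=9))
        fit_encoder(t2, X, y, TrainHyper(epochs=2, seed=5))
        assert t1.weights_hash() == t2.weights_hash()

    def test_source_weights_unchanged_by_transfer(self):
        X, y = _tiny_target_data(1)
        cfg_src = EncoderSpec("tiny34", in_channels=X.shape[1], n_classes=2, seed=2)
        source = build_encoder(cfg_src)
        source, _ = train_source(source, X, y, TrainHyper(epochs=1, seed=2))
        before = source.weights_hash()
        target = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=3))
        transfer_train(source, target, None, X, y, TransferHyper(beta=0.5, epochs=2, seed=3))
        assert source.weights_hash() == before

    def test_unfrozen_source_rejected(self):
        X, y = _tiny_target_data(2)
        source = build_encoder(EncoderSpec("tiny34", in_channels=X.shape[1], n_classes=2, seed=2))
        target = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=3))
        with pytest.raises(ValueError, match="frozen"):
            transfer_train(source, target, None, X, y, TransferHyper(epochs=1))

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            TransferHyper(beta=-0.1)

    def test_single_class_rejected(self):
        X, y = _tiny_target_data(3)
        planted = PlantedSource(in_channels=X.shape[1])
        target = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=3))
        with pytest.raises(ValueError, match="classes"):
            transfer_train(planted, target, None, X, np.zeros_like(y), TransferHyper(epochs=1))

    def test_history_records_both_components(self):
        X, y = _tiny_target_data(4)
        planted = PlantedSource(in_channels=X.shape[1])
        target = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1], n_classes=2, seed=3))
        _, _, hist = transfer_train(planted, target, None, X, y,
                                    TransferHyper(beta=0.5, epochs=3, seed=0,
                                                  candidate_pairs=((0, 0),)))
        assert len(hist["ce"]) == 3 and len(hist["extra"]) == 3
        assert all(v > 0 for v in hist["extra"])


def test_default_candidate_pairs_are_coarse_to_fine():
    pairs = default_candidate_pairs(4)
    assert len(pairs) == 10
    assert all(k >= d for k, d in pairs)


class TestWeightInformativeness:
    def test_signal_channels_outweigh_noise_channels(self):
        """With a planted source whose first half of channels carry the class
        signal and second half pure noise, transfer training should learn
        larger weights on the signal channels (>= 4/5 seeds)."""
        wins = 0
        for seed in range(5):
            X, y = _tiny_target_data(100 + seed, n=32, planes=4, hw=12)
            planted = PlantedSource(in_channels=X.shape[1], width=8, map_hw=8, seed=seed)
            target = build_encoder(EncoderSpec("tiny18", in_channels=X.shape[1],
                                               n_classes=2, seed=seed))
            hyper = TransferHyper(beta=1.0, epochs=6, seed=seed, candidate_pairs=((0, 0),))
            _, matcher, _ = transfer_train(planted, target, None, X, y, hyper)
            from chtlm.feature_matching import _precompute_source_maps

            maps = _precompute_source_maps(planted, X)
            w = matcher.mean_channel_weights({0: maps[0]})[(0, 0)]
            if w[:4].mean() > w[4:].mean():
                wins += 1
        assert wins >= 4
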