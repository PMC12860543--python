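"""McEUN architecture, loss closed forms, training protocol, inference."""

import numpy as np
import pytest

from ctless.nn.layers import BIAS_INIT
from ctless.segnet import (
    LossConfig,
    McEUN,
    TrainConfig,
    default_loss_weights,
    dice_coefficient,
    normalize_input,
    predict_segments,
    train_mceun,
    train_mceun_cv,
    weighted_cross_entropy,
)


def test_architecture_contract():
    net = McEUN(K=6, base_filters=4, seed=0)
    x = np.random.default_rng(0).random((2, 16, 16, 16), dtype=np.float32)
    # bottleneck: 5-layer encoder with two stride-2 layers -> spatial / 4
    from ctless.nn.autodiff import Tensor

    t = Tensor(x)
    e = net.enc5(net.enc4(net.enc3(net.enc2(net.enc1(t)))))
    assert e.data.shape[1:] == (4, 4, 4)
    assert e.data.shape[0] == 4 * net.base_filters  # filters doubled twice
    probs = net.forward(x)
    assert probs.data.shape == (6, 16, 16, 16)
    np.testing.assert_allclose(probs.data.sum(axis=0), 1.0, atol=1e-5)
    assert len(net.decoders) == 6
    with pytest.raises(ValueError):
        net.forward(np.zeros((3, 16, 16, 16), np.float32))  # needs 2 channels
    with pytest.raises(ValueError):
        net.forward(np.zeros((2, 18, 18, 18), np.float32))  # grid % 4 != 0


def test_biases_initialized_to_constant():
    net = McEUN(K=2, base_filters=4, seed=1)
    assert np.all(net.enc1.b.data == np.float32(BIAS_INIT))
    assert np.all(net.decoders[0]["conv3"].b.data == np.float32(BIAS_INIT))


def test_channel_roles_are_asymmetric():
    net = McEUN(K=3, base_filters=4, seed=2)
    rng = np.random.default_rng(5)
    a, b = rng.random((16, 16, 16)), rng.random((16, 16, 16))
    p1 = net.forward(np.stack([a, b]).astype(np.float32)).data
    p2 = net.forward(np.stack([b, a]).astype(np.float32)).data
    assert not np.allclose(p1, p2)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _one_hot(labels, K):
    return np.stack([(labels == k) for k in range(K)]).astype(float)


def test_loss_zero_at_point_mass():
    labels = np.random.default_rng(0).integers(0, 3, (4, 4, 4))
    truth = _one_hot(labels, 3)
    cfg = LossConfig(weights=np.ones(3))
    loss = weighted_cross_entropy(truth, truth, cfg)
    # 0*log 0 := 0 via clipping; loss bounded by the clip epsilon
    assert loss < 1e-4


def test_loss_uniform_prediction_closed_form():
    """p == 0.5 everywhere gives exactly N * ln2 * sum(w_k)."""
    K, n = 6, 4
    N = n**3
    w = np.array([0.5, 1.0, 1.5, 2.0, 0.25, 0.75])
    truth = _one_hot(np.random.default_rng(1).integers(0, K, (n, n, n)), K)
    pred = np.full((K, n, n, n), 0.5)
    loss = weighted_cross_entropy(pred, truth, LossConfig(weights=w))
    assert abs(loss - N * np.log(2) * w.sum()) < 1e-9


def test_loss_linear_in_weights_and_loop_oracle():
    """Vectorized loss equals a brute-force per-voxel double loop to 1e-10."""
    K, n = 4, 4
    rng = np.random.default_rng(3)
    pred = rng.dirichlet(np.ones(K), size=(n, n, n)).transpose(3, 0, 1, 2)
    truth = _one_hot(rng.integers(0, K, (n, n, n)), K)
    w = rng.random(K) + 0.1
    cfg = LossConfig(weights=w)
    loss = weighted_cross_entropy(pred, truth, cfg)
    # independent oracle: explicit sum over voxels and regions
    eps = cfg.eps
    p = np.clip(pred, eps, 1 - eps)
    oracle = 0.0
    for i in np.ndindex((n, n, n)):
        for k in range(K):
            phi, phat = truth[(k,) + i], p[(k,) + i]
            oracle += w[k] * (-phi * np.log(phat) - (1 - phi) * np.log(1 - phat))
    assert abs(loss - oracle) < 1e-10
    doubled = weighted_cross_entropy(pred, truth, LossConfig(weights=2 * w))
    assert abs(doubled - 2 * loss) < 1e-8


def test_loss_validation():
    with pytest.raises(ValueError):
        LossConfig(weights=np.zeros(3))
    cfg = LossConfig(weights=np.ones(2))
    with pytest.raises(ValueError):
        weighted_cross_entropy(np.ones((3, 2, 2, 2)) / 3, _one_hot(np.zeros((2, 2, 2)), 3), cfg)


# ---------------------------------------------------------------------------
# normalization, weights
# ---------------------------------------------------------------------------

def test_normalize_input_properties():
    v = np.random.default_rng(0).random((5, 5, 5)) * 10
    out = normalize_input(v)
    assert out.max() == 1.0
    np.testing.assert_allclose(normalize_input(out), out)  # idempotent
    zero = normalize_input(np.zeros((3, 3, 3)))
    assert np.all(zero == 0)


def test_default_loss_weights_inverse_frequency():
    truths = [np.zeros((4, 4, 4), int)]
    truths[0][0, 0, 0] = 1  # region 1 is rare
    w = default_loss_weights(truths, 2)
    assert w[1] > w[0]
    assert abs(w.sum() - 2.0) < 1e-12


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _toy_sample(n=16, seed=0):
    """Blocky label volume with intensity-coded channels."""
    rng = np.random.default_rng(seed)
    labels = np.zeros((n, n, n), np.uint8)
    labels[:, : n // 2] = 1
    labels[n // 2:, :, : n // 4] = 2
    sc = labels * 0.3 + 0.1 + rng.normal(0, 0.02, labels.shape)
    pp = (labels == 1) * 0.8 + 0.1 + rng.normal(0, 0.02, labels.shape)
    return np.clip(sc, 0, None), np.clip(pp, 0, None), labels


def test_single_sample_overfit_reaches_high_dice():
    """Capacity sanity: 150 epochs on one sample segments it with Dice > 0.95."""
    sc, pp, labels = _toy_sample()
    cfg = TrainConfig(epochs=150, lr=3e-3, base_filters=4, batch_size=1,
                      dropout_rate=0.0, patch_size=None, seed=0)
    net, hist = train_mceun([(sc, pp, labels)], cfg, K=3)
    assert hist["train_loss"][-1] < hist["train_loss"][0]
    seg = predict_segments(normalize_input(sc), normalize_input(pp), net)
    for k in range(3):
        assert dice_coefficient(seg.labels == k, labels == k) > 0.95


def test_training_is_bit_reproducible():
    sc, pp, labels = _toy_sample()
    cfg = TrainConfig(epochs=2, base_filters=2, batch_size=1, patch_size=None, seed=3)
    n1, h1 = train_mceun([(sc, pp, labels)], cfg, K=3)
    n2, h2 = train_mceun([(sc, pp, labels)], cfg, K=3)
    assert h1["train_loss"] == h2["train_loss"]
    assert all(np.array_equal(p.data, q.data)
               for p, q in zip(n1.parameters(), n2.parameters()))
    assert h1["reproducibility"].startswith("bitwise")


def test_cv_epoch_selection_runs_and_picks_minimum():
    data = [_toy_sample(seed=s) for s in range(4)]
    cfg = TrainConfig(epochs=3, base_filters=2, batch_size=2, patch_size=None,
                      seed=1, folds=2)
    net, hist = train_mceun_cv(data, cfg, K=3)
    assert len(hist["cv_mean_val_loss"]) == 3
    assert hist["selected_epochs"] == int(np.argmin(hist["cv_mean_val_loss"])) + 1


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        train_mceun([], TrainConfig())


def test_predict_output_is_partition():
    net = McEUN(K=4, base_filters=2, seed=0)
    rng = np.random.default_rng(1)
    seg = predict_segments(rng.random((16, 16, 16)), rng.random((16, 16, 16)), net)
    assert seg.K == 4
    assert seg.source == "predicted"
    np.testing.assert_array_equal(seg.one_hot().sum(axis=0), 1.0)


def test_checkpoint_roundtrip(tmp_path):
    net = McEUN(K=3, base_filters=2, seed=9)
    x = np.random.default_rng(2).random((2, 8, 8, 8), dtype=np.float32)
    before = net.forward(x).data
    path = str(tmp_path / "ckpt.npz")
    net.save(path, arch_yaml=str(tmp_path / "arch.yaml"))
    again = McEUN.load(path)
    np.testing.assert_array_equal(again.forward(x).data, before)
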