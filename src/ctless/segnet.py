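"""Multi-channel-input, multi-decoder U-net (McEUN) for attenuation-region
segmentation, with its weighted cross-entropy loss and training protocol.

The network takes two 3-D channels — the scatter-window reconstruction (the
initial attenuation-map estimate) and the photopeak-window reconstruction
(anatomic assistance) — and segments the grid into K attenuation regions.
The encoder has five 3x3x3 convolutional layers, two of them with stride 2,
reducing the grid by a factor of 4 and doubling the filter count at each
downsampling.  One decoder per region maps the shared encoding back to a
single-channel score volume through three {transposed convolution +
convolution} blocks with halving filter counts; skip connections from the
encoder pass through additive attention gates.  The K decoder outputs are
concatenated and a per-voxel softmax yields region probabilities.

Training: weighted per-region binary cross-entropy (per-voxel), Glorot
normal kernel initialization, biases at 0.03, dropout 0.1 at the bottleneck,
Adam, minibatches by gradient accumulation, optional k-fold cross-validation
for epoch selection.  Pure NumPy arithmetic makes training bit-reproducible
for a fixed seed (declared in the training log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml

from . import nn
from .mumap import SegmentationMap
from .nn.autodiff import F32, Tensor

log = logging.getLogger(__name__)


@dataclass
class LossConfig:
    """Per-region weights for the cross-entropy loss."""

    weights: np.ndarray
    eps: float = 1e-7

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError("need non-negative weights with at least one > 0")


def weighted_cross_entropy(pred: np.ndarray, truth: SegmentationMap | np.ndarray,
                           cfg: LossConfig) -> float:
    """Weighted per-voxel, per-region binary cross-entropy (scalar sum).

    ``pred`` holds (K, ...) class probabilities; ``truth`` a SegmentationMap
    or (K, ...) one-hot array.  ``0 * log 0`` is treated as 0 via probability
    clipping at ``cfg.eps``.
    """
    t = truth.one_hot() if isinstance(truth, SegmentationMap) else np.asarray(truth, float)
    p = np.asarray(pred, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"pred shape {p.shape} != truth shape {t.shape}")
    if cfg.weights.size != p.shape[0]:
        raise ValueError("weight count does not match region count")
    p = np.clip(p, cfg.eps, 1.0 - cfg.eps)
    w = cfg.weights.reshape((-1,) + (1,) * (p.ndim - 1))
    return float(np.sum(w * (-t * np.log(p) - (1.0 - t) * np.log(1.0 - p))))


def normalize_input(volume: np.ndarray) -> np.ndarray:
    """Scale a volume from [0, max] to [0, 1] (all-zero input passes through)."""
    m = float(np.max(volume))
    if m <= 0:
        log.warning("normalize_input: volume has no positive values")
        return np.zeros_like(np.asarray(volume, dtype=np.float64))
    return np.asarray(volume, dtype=np.float64) / m


class McEUN:
    """The segmentation operator D_Theta."""

    def __init__(self, K: int = 6, base_filters: int = 8, in_channels: int = 2,
                 dropout_rate: float = 0.1, leaky_slope: float = 0.1, seed: int = 0):
        self.K = K
        self.base_filters = base_filters
        self.in_channels = in_channels
        self.dropout_rate = dropout_rate
        self.leaky_slope = leaky_slope
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        F = base_filters
        kw = dict(rng=rng, leaky_slope=leaky_slope)

        # encoder: five conv layers, two with stride 2 (grid / 4)
        self.enc1 = nn.Conv3d(in_channels, F, 1, **kw)
        self.enc2 = nn.Conv3d(F, 2 * F, 2, **kw)
        self.enc3 = nn.Conv3d(2 * F, 2 * F, 1, **kw)
        self.enc4 = nn.Conv3d(2 * F, 4 * F, 2, **kw)
        self.enc5 = nn.Conv3d(4 * F, 4 * F, 1, **kw)

        # one decoder per region: three {transposed conv + conv} blocks with
        # halving filters; the last block is stride-1 (output on the input grid)
        Fh = max(F // 2, 2)
        self.decoders = []
        for _ in range(K):
            dec = {
                "up1": nn.ConvTranspose3d(4 * F, 2 * F, 2, **kw),
                "att1": nn.AttentionGate(2 * F, 2 * F, F, **kw),
                "conv1": nn.Conv3d(4 * F, 2 * F, 1, **kw),
                "up2": nn.ConvTranspose3d(2 * F, F, 2, **kw),
                "att2": nn.AttentionGate(F, F, max(F // 2, 1), **kw),
                "conv2": nn.Conv3d(2 * F, F, 1, **kw),
                "up3": nn.ConvTranspose3d(F, Fh, 1, **kw),
                "conv3": nn.Conv3d(Fh, 1, 1, **kw),
            }
            self.decoders.append(dec)

    # -- plumbing ------------------------------------------------------------
    def parameters(self):
        params = []
        for layer in (self.enc1, self.enc2, self.enc3, self.enc4, self.enc5):
            params += layer.parameters()
        for dec in self.decoders:
            for layer in dec.values():
                params += layer.parameters()
        return params

    def architecture(self) -> dict:
        return {
            "K": self.K,
            "base_filters": self.base_filters,
            "in_channels": self.in_channels,
            "dropout_rate": self.dropout_rate,
            "leaky_slope": self.leaky_slope,
            "seed": self.seed,
            "encoder_layers": 5,
            "stride2_layers": 2,
            "decoder_blocks": 3,
            "attention_gates": True,
        }

    # -- forward -------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        """Per-voxel region probabilities for a (2, n, n, n) input."""
        if x.shape[0] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {x.shape[0]}")
        n = x.shape[1]
        if any(s % 4 != 0 for s in x.shape[1:]):
            raise ValueError(f"grid {x.shape[1:]} not divisible by 4")
        t = Tensor(x.astype(F32))
        e1 = self.enc1(t)                        # (F, n)
        e2 = self.enc2(e1)                       # (2F, n/2)
        e3 = self.enc3(e2)                       # (2F, n/2)
        e4 = self.enc4(e3)                       # (4F, n/4)
        e5 = self.enc5(e4)                       # (4F, n/4) bottleneck
        e5 = nn.dropout(e5, self.dropout_rate, self._dropout_rng, training)

        outs = []
        for dec in self.decoders:
            u1 = dec["up1"](e5)                  # (2F, n/2)
            s1 = dec["att1"](e3, u1)
            d1 = dec["conv1"](nn.concat([u1, s1]))
            u2 = dec["up2"](d1)                  # (F, n)
            s2 = dec["att2"](e1, u2)
            d2 = dec["conv2"](nn.concat([u2, s2]))
            u3 = dec["up3"](d2)                  # (F/2, n), stride-1 block
            outs.append(dec["conv3"](u3))        # (1, n)
        logits = nn.concat(outs)                 # (K, n)
        assert logits.data.shape == (self.K, n, n, n)
        return nn.channel_softmax(logits)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str, arch_yaml: str | None = None) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez_compressed(path, **arrays,
                            arch=np.frombuffer(
                                yaml.safe_dump(self.architecture()).encode(), dtype=np.uint8))
        if arch_yaml:
            with open(arch_yaml, "w") as fh:
                yaml.safe_dump(self.architecture(), fh)

    @classmethod
    def load(cls, path: str) -> "McEUN":
        with np.load(path) as z:
            arch = yaml.safe_load(bytes(z["arch"]).decode())
            net = cls(K=arch["K"], base_filters=arch["base_filters"],
                      in_channels=arch["in_channels"], dropout_rate=arch["dropout_rate"],
                      leaky_slope=arch["leaky_slope"], seed=arch["seed"])
            for i, p in enumerate(net.parameters()):
                p.data = z[f"p{i}"].astype(F32)
        return net


@dataclass
class TrainConfig:
    epochs: int = 40
    lr: float = 1e-3
    batch_size: int = 4
    dropout_rate: float = 0.1
    base_filters: int = 8
    leaky_slope: float = 0.1
    loss_weights: np.ndarray | None = None
    seed: int = 0
    folds: int = 5
    #: train on random sub-volume patches (the network is fully convolutional;
    #: None trains on full volumes).  Must be divisible by 4.
    patch_size: int | None = 24
    patches_per_sample: int = 2
    #: random left-right mirror augmentation of training samples
    flip_augmentation: bool = True
    #: halve the learning rate every this many epochs (None = constant)
    lr_halving_epochs: int | None = None


def stack_inputs(f_sc: np.ndarray, f_pp: np.ndarray) -> np.ndarray:
    """Normalize both reconstructions to [0, 1] and stack as 2 channels."""
    return np.stack([normalize_input(f_sc), normalize_input(f_pp)]).astype(F32)


def default_loss_weights(truths: list[np.ndarray], K: int) -> np.ndarray:
    """w_k proportional to inverse region voxel frequency, sum w_k = K.

    Regions absent from the training truths get the mean weight of the
    present ones (an absent region only contributes false-positive
    suppression terms; an unbounded inverse-frequency weight there would
    drown the present regions).
    """
    counts = np.zeros(K)
    for t in truths:
        counts += np.bincount(np.asarray(t).ravel(), minlength=K)
    present = counts > 0
    if not present.any():
        raise ValueError("no labeled voxels in the training truths")
    w = np.zeros(K)
    w[present] = 1.0 / counts[present]
    w[~present] = w[present].mean()
    return w * (K / w.sum())


def _sample_loss_and_grads(net: McEUN, x: np.ndarray, truth_onehot: np.ndarray,
                           weights: np.ndarray, training: bool) -> float:
    probs = net.forward(x, training=training)
    loss = nn.weighted_bce(probs, truth_onehot, weights)
    if training:
        loss.backward()
    return float(loss.data)


def train_mceun(dataset: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                config: TrainConfig | None = None,
                validation: list | None = None,
                net: McEUN | None = None,
                K: int = 6) -> tuple[McEUN, dict]:
    """Train the McEUN on (f_sc, f_pp, truth_labels) triples.

    Inputs are normalized per volume; the truth is an integer label volume.
    Returns the trained network and a log with per-epoch train (and
    validation) loss.  Aborts with a diagnostic on NaN loss.  Fully seeded
    and bit-reproducible (single-threaded NumPy arithmetic).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)

    xs = [stack_inputs(sc, pp) for sc, pp, _ in dataset]
    truths = [np.asarray(t) for _, _, t in dataset]
    onehots = [np.stack([(t == k) for k in range(K)]).astype(np.float64) for t in truths]
    weights = (np.asarray(config.loss_weights, dtype=np.float64)
               if config.loss_weights is not None
               else default_loss_weights(truths, K))

    if net is None:
        net = McEUN(K=K, base_filters=config.base_filters,
                    dropout_rate=config.dropout_rate,
                    leaky_slope=config.leaky_slope, seed=config.seed)
    params = net.parameters()
    opt = nn.Adam(params, lr=config.lr)

    val_sets = None
    if validation:
        val_sets = [(stack_inputs(sc, pp),
                     np.stack([(np.asarray(t) == k) for k in range(K)]).astype(np.float64))
                    for sc, pp, t in validation]

    patch = config.patch_size
    vol_shape = xs[0].shape[1:]
    use_patches = patch is not None and any(s > patch for s in vol_shape)
    if use_patches and patch % 4 != 0:
        raise ValueError("patch_size must be divisible by 4")

    def _draw(i):
        """(input, truth) pair: a random (optionally mirrored) patch."""
        if use_patches:
            corner = [rng.integers(0, s - patch + 1) if s > patch else 0 for s in vol_shape]
            sl = (slice(None),) + tuple(slice(c, c + patch) for c in corner)
            xi, ti = xs[i][sl], onehots[i][sl]
        else:
            xi, ti = xs[i], onehots[i]
        if config.flip_augmentation and rng.random() < 0.5:
            xi, ti = xi[:, ::-1], ti[:, ::-1]  # left-right mirror
        return np.ascontiguousarray(xi), np.ascontiguousarray(ti)

    history = {"train_loss": [], "val_loss": [], "seed": config.seed,
               "patch_size": patch if use_patches else None,
               "reproducibility": "bitwise (seeded, single-threaded numpy)"}
    reps = config.patches_per_sample if use_patches else 1
    order = np.repeat(np.arange(len(xs)), reps)
    for epoch in range(config.epochs):
        if config.lr_halving_epochs:
            opt.lr = config.lr * 0.5 ** (epoch // config.lr_halving_epochs)
        rng.shuffle(order)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for i in idx:
                xi, ti = _draw(i)
                # per-voxel loss normalization keeps lr grid-size independent
                batch_loss += _sample_loss_and_grads(
                    net, xi, ti, weights / xi[0].size, training=True)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}, samples {idx.tolist()}")
            for p in params:
                if p.grad is not None:
                    p.grad /= len(idx)
            opt.step()
            epoch_loss += batch_loss
        history["train_loss"].append(epoch_loss / len(order))
        if val_sets is not None:
            vl = float(np.mean([
                weighted_cross_entropy(
                    net.forward(x, training=False).data, t,
                    LossConfig(weights / x[0].size))
                for x, t in val_sets]))
            history["val_loss"].append(vl)
    return net, history


def train_mceun_cv(dataset, config: TrainConfig | None = None, K: int = 6):
    """k-fold cross-validation to pick the epoch count, then a final fit.

    The epoch is chosen where the mean validation loss across folds is
    minimal; the final network is trained on the full dataset for that many
    epochs.  Returns (net, log) with the CV curves attached.
    """
    config = config or TrainConfig()
    n = len(dataset)
    folds = min(config.folds, n)
    if folds < 2:
        raise ValueError("cross-validation requires at least 2 folds/samples")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    fold_val = []
    for f in range(folds):
        val_idx = set(perm[f::folds].tolist())
        train = [dataset[i] for i in range(n) if i not in val_idx]
        val = [dataset[i] for i in range(n) if i in val_idx]
        _, hist = train_mceun(train, config, validation=val, K=K)
        fold_val.append(hist["val_loss"])
    mean_val = np.mean(np.asarray(fold_val), axis=0)
    best_epoch = int(np.argmin(mean_val)) + 1
    final_cfg = TrainConfig(**{**config.__dict__, "epochs": best_epoch})
    net, hist = train_mceun(dataset, final_cfg, K=K)
    hist["cv_mean_val_loss"] = mean_val.tolist()
    hist["selected_epochs"] = best_epoch
    return net, hist


def predict_segments(f_sc: np.ndarray, f_pp: np.ndarray, net: McEUN) -> SegmentationMap:
    """Segment one subject: argmax over the K softmax outputs (a partition).

    Inputs should be normalized to [0, 1]; larger values trigger a warning
    and are normalized here.
    """
    if np.max(f_sc) > 1.0 + 1e-6 or np.max(f_pp) > 1.0 + 1e-6:
        log.warning("predict_segments: inputs exceed [0, 1]; normalizing")
    x = stack_inputs(f_sc, f_pp)
    probs = net.forward(x, training=False).data
    return SegmentationMap(labels=np.argmax(probs, axis=0).astype(np.uint8),
                           K=net.K, source="predicted")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
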