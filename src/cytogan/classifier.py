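"""VGG-style benign/malignant classifier and the two-step training procedure.

The backbone is VGG-16 (or ``vgg_tiny``, a width/depth-reduced variant with
the same block-pool structure for desk-scale work) with the original fully
connected layers replaced by a new head of 1024, 256 and 2 units; the two
output units pass through a softmax, and the malignant probability is the
malignancy score.  Training happens in two steps: *pretraining* updates every
parameter of the network on GAN-generated images; *fine-tuning* then updates
only the fully connected head on real patches, leaving every convolutional
parameter bitwise untouched.  Both steps share the same optimizer settings
(Adam; the full-scale reference setting is lr 1e-6, beta1 0.9, beta2 0.999,
minibatch 32).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import nn

HEAD_UNITS = (1024, 256, 2)

VGG16_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
VGG_TINY_BLOCKS = ((1, 16), (2, 32), (2, 64))

LABEL_TO_INT = {"benign": 0, "malignant": 1}


@dataclass(frozen=True)
class BackboneConfig:
    family: str = "vgg_tiny"
    input_size: int = 32
    conv_blocks: tuple[tuple[int, int], ...] | None = None
    head_units: tuple[int, int, int] = HEAD_UNITS
    init: str = "random"  # or "imagenet_weights"
    weights_path: str | None = None

    def __post_init__(self):
        if self.family not in ("vgg16", "vgg_tiny"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.head_units) != 3 or self.head_units[-1] != 2:
            raise ValueError("head must be three fully connected layers ending in 2 units")
        blocks = self.blocks
        if self.input_size % (2 ** len(blocks)):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{len(blocks)} pooling stages")
        if self.input_size < 2 ** len(blocks):
            raise ValueError("input too small for the pooling depth")

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        if self.conv_blocks is not None:
            return self.conv_blocks
        return VGG16_BLOCKS if self.family == "vgg16" else VGG_TINY_BLOCKS


@dataclass(frozen=True)
class TwoStepPlan:
    """Hyperparameters shared by pretraining and fine-tuning.

    The freeze policy is fixed by the procedure itself: pretraining trains all
    layers, fine-tuning trains the FC head only.  The full-scale reference
    learning rate is 1e-6; desk-scale runs use a larger one.
    """

    epochs: int = 10
    minibatch: int = 32
    learning_rate: float = 1e-6
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0

    @classmethod
    def reference(cls, epochs: int = 10) -> "TwoStepPlan":
        return cls(epochs=epochs)


class Classifier:
    """Network with parameter groups tagged conv / head."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        layers = []
        in_ch = 3
        for n_convs, ch in config.blocks:
            for _ in range(n_convs):
                layers += [nn.Conv2d(in_ch, ch, 3, rng), nn.ReLU()]
                in_ch = ch
            layers.append(nn.MaxPool2())
        self.features = nn.Sequential(layers)
        spatial = config.input_size // (2 ** len(config.blocks))
        flat = in_ch * spatial * spatial
        u1, u2, u3 = config.head_units
        self.head = nn.Sequential([
            nn.Flatten(),
            nn.Dense(flat, u1, rng), nn.ReLU(),
            nn.Dense(u1, u2, rng), nn.ReLU(),
            nn.Dense(u2, u3, rng, gain=1.0),
        ])
        self.head_dims = ((flat, u1), (u1, u2), (u2, u3))
        self.init_used = config.init
        if config.init == "imagenet_weights":
            self._load_imagenet(config.weights_path)

    def _load_imagenet(self, weights_path) -> None:
        """Load conv weights from a user-supplied .npz checkpoint.

        Without a checkpoint (offline), falls back to random initialization
        and records ``init_used = 'random_fallback'`` so reports can label the
        baseline arm honestly.
        """
        if weights_path is None or not Path(weights_path).exists():
            self.init_used = "random_fallback"
            return
        with np.load(weights_path) as data:
            for i, p in enumerate(self.conv_params()):
                key = f"conv_{i}"
                if key in data and data[key].shape == p.value.shape:
                    p.value[...] = data[key]
        self.init_used = "imagenet_weights"

    def conv_params(self) -> list[nn.Param]:
        return self.features.params()

    def head_params(self) -> list[nn.Param]:
        return self.head.params()

    def params(self) -> list[nn.Param]:
        return self.conv_params() + self.head_params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.head.forward(self.features.forward(x, train=train), train=train)

    def backward(self, dlogits: np.ndarray, through_conv: bool = True) -> None:
        g = self.head.backward(dlogits)
        if through_conv:
            self.features.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))


def build_classifier(config: BackboneConfig, seed: int = 0) -> Classifier:
    return Classifier(config, seed=seed)


# ---------------------------------------------------------------------------
# data handling


def _load_batchable(manifest: pd.DataFrame, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest images as float32 NCHW in [-1, 1] plus int labels."""
    imgs, labels = [], []
    for rec in manifest.itertuples(index=False):
        img = np.asarray(Image.open(rec.path).convert("RGB"))
        if img.shape[0] != input_size:
            img = np.asarray(Image.fromarray(img).resize((input_size, input_size), Image.NEAREST))
        imgs.append(img)
        labels.append(LABEL_TO_INT[rec.label])
    x = np.stack(imgs).astype(nn.DTYPE) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2)), np.asarray(labels)


def images_to_input(images: np.ndarray, input_size: int) -> np.ndarray:
    """uint8 NHWC -> float32 NCHW in [-1, 1], nearest-resized to input_size."""
    if images.shape[1] != input_size:
        images = np.stack([
            np.asarray(Image.fromarray(im).resize((input_size, input_size), Image.NEAREST))
            for im in images])
    x = images.astype(nn.DTYPE) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _train(network: Classifier, x: np.ndarray, y: np.ndarray, plan: TwoStepPlan,
           trainable: str) -> list[float]:
    if len(x) == 0:
        raise ValueError("empty training set")
    params = network.params() if trainable == "all" else network.head_params()
    opt = nn.Adam(params, plan.learning_rate, plan.beta1, plan.beta2)
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed))
    losses = []
    for _ in range(plan.epochs):
        order = rng.permutation(len(x))
        epoch_loss = 0.0
        nb = 0
        for b0 in range(0, len(x), plan.minibatch):
            idx = order[b0:b0 + plan.minibatch]
            logits = network.forward(x[idx], train=True)
            loss, d = nn.softmax_cross_entropy(logits, y[idx])
            opt.zero_grad()
            network.backward(d, through_conv=(trainable == "all"))
            opt.step()
            epoch_loss += loss
            nb += 1
        losses.append(epoch_loss / nb)
    return losses


def pretrain(network: Classifier, gan_manifest: pd.DataFrame, plan: TwoStepPlan) -> list[float]:
    """Step one: train the entire network on GAN-generated, GAN-labeled images."""
    x, y = _load_batchable(gan_manifest, network.config.input_size)
    return _train(network, x, y, plan, trainable="all")


def _labels_to_int(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        return np.asarray([LABEL_TO_INT[l] for l in labels])
    return labels.astype(int)


def pretrain_on_arrays(network: Classifier, images: np.ndarray, labels: np.ndarray,
                       plan: TwoStepPlan) -> list[float]:
    x = images_to_input(images, network.config.input_size)
    return _train(network, x, _labels_to_int(labels), plan, trainable="all")


def fine_tune(network: Classifier, real_manifest: pd.DataFrame, plan: TwoStepPlan) -> list[float]:
    """Step two: update only the fully connected head; conv weights are frozen."""
    x, y = _load_batchable(real_manifest, network.config.input_size)
    return _train(network, x, y, plan, trainable="head")


def fine_tune_on_arrays(network: Classifier, images: np.ndarray, labels: np.ndarray,
                        plan: TwoStepPlan) -> list[float]:
    x = images_to_input(images, network.config.input_size)
    return _train(network, x, _labels_to_int(labels), plan, trainable="head")


def predict(network: Classifier, manifest: pd.DataFrame, cutoff: float = 0.5) -> pd.DataFrame:
    """Score manifest patches; returns patch_id, score, pred_label, true_label.

    The score is the softmax malignant probability; ties at the cut-off
    classify as malignant.
    """
    x, _ = _load_batchable(manifest, network.config.input_size)
    return _predict_from_input(network, x, manifest, cutoff)


def predict_on_arrays(network: Classifier, images: np.ndarray, labels,
                      cutoff: float = 0.5) -> pd.DataFrame:
    x = images_to_input(images, network.config.input_size)
    manifest = pd.DataFrame({"path": [f"array_{i}" for i in range(len(images))],
                             "label": list(labels)})
    return _predict_from_input(network, x, manifest, cutoff)


def _predict_from_input(network, x, manifest, cutoff):
    scores = []
    for b0 in range(0, len(x), 64):
        p = network.predict_proba(x[b0:b0 + 64])
        scores.append(p[:, 1])
    scores = np.concatenate(scores) if scores else np.empty(0)
    return pd.DataFrame({
        "patch_id": manifest["path"].to_numpy(),
        "score": scores.astype(np.float64),
        "pred_label": np.where(scores >= cutoff, "malignant", "benign"),
        "true_label": manifest["label"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# checkpoints


def save_classifier(network: Classifier, path) -> None:
    arrays = {f"conv_{i}": p.value for i, p in enumerate(network.conv_params())}
    arrays |= {f"head_{i}": p.value for i, p in enumerate(network.head_params())}
    np.savez(path, **arrays)


def load_classifier(config: BackboneConfig, path) -> Classifier:
    net = Classifier(config)
    with np.load(path) as data:
        for i, p in enumerate(net.conv_params()):
            p.value[...] = data[f"conv_{i}"]
        for i, p in enumerate(net.head_params()):
            p.value[...] = data[f"head_{i}"]
    return net
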