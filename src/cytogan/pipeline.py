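"""Desk-scale orchestration of the full two-step experiment.

Wires the stages together on synthetic cytology data: render patches, train
one GAN per class, sample synthetic images, pretrain the classifier on them,
fine-tune the fully connected head on real patches, and score a held-out
set.  The three pretraining arms mirror the study design:

- ``PGGAN``  — progressive GAN samples for pretraining, then fine-tuning;
- ``DCGAN``  — direct (non-progressive) GAN samples, then fine-tuning;
- ``ImageNet`` — no GAN pretraining; ImageNet conv weights when a checkpoint
  is supplied, otherwise a labeled random-init fallback, with only the head
  trained (the conv stack stays frozen either way).

Everything runs on CPU at reduced size (32x32 patches, vgg_tiny, few-stage
GAN schedules); the structure, freeze policy and evaluation protocol are the
full pipeline's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier as clf
from . import evalstats, gan, synthcyto


@dataclass(frozen=True)
class ScaledExperimentConfig:
    image_size: int = 32
    n_per_class: int = 120
    gan_max_resolution: int = 8          # 2-stage progressive schedule: 4 -> 8
    gan_feature_maps: tuple[int, ...] = (32, 32)
    gan_epochs_per_stage: int = 12
    gan_minibatch: int = 16
    gan_samples_per_class: int = 150
    dcgan_base_channels: int = 32
    dcgan_epochs: int = 24
    pretrain_epochs: int = 8
    finetune_epochs: int = 15
    desk_learning_rate: float = 1e-3
    seed: int = 0

    def schedule(self) -> gan.StageSchedule:
        res, r = [], 4
        while r <= self.gan_max_resolution:
            res.append(r)
            r *= 2
        return gan.StageSchedule(tuple(res), self.gan_feature_maps,
                                 epochs_per_stage=self.gan_epochs_per_stage)


def _backbone(cfg: ScaledExperimentConfig) -> clf.BackboneConfig:
    return clf.BackboneConfig(family="vgg_tiny", input_size=cfg.image_size)


def make_synthetic_dataset(cfg: ScaledExperimentConfig):
    spec = synthcyto.SyntheticDatasetSpec(
        n_per_class=cfg.n_per_class, image_size=cfg.image_size, seed=cfg.seed)
    return synthcyto.render_dataset_arrays(spec)


def train_gans(images: np.ndarray, labels: np.ndarray, cfg: ScaledExperimentConfig,
               arch: str = "pggan", seed: int | None = None) -> dict[str, gan.GanBundle]:
    """Train one generator per class on the given real images."""
    seed = cfg.seed if seed is None else seed
    bundles = {}
    for k, label in enumerate(("benign", "malignant")):
        cls_imgs = images[labels == label]
        tcfg = gan.GanTrainConfig(minibatch=cfg.gan_minibatch, seed=seed + 17 * k + 1)
        if arch == "pggan":
            schedule = cfg.schedule()
            bundle = gan.build_pggan(schedule, class_tag=label, seed=seed + 17 * k)
            reals = gan._to_uint8(gan.downsample_to(gan._to_float(cls_imgs),
                                                    schedule.resolutions[-1]))
            gan.train_pggan(bundle, reals, tcfg)
        elif arch == "dcgan":
            bundle = gan.build_dcgan(resolution=cfg.image_size,
                                     base_channels=cfg.dcgan_base_channels,
                                     class_tag=label, seed=seed + 17 * k)
            dcfg = gan.GanTrainConfig(learning_rate=2e-4, beta1=0.5, beta2=0.999,
                                      minibatch=cfg.gan_minibatch, seed=seed + 17 * k + 1)
            gan.train_dcgan(bundle, cls_imgs, dcfg, epochs=cfg.dcgan_epochs)
        else:
            raise ValueError(f"unknown GAN arch {arch!r}")
        bundles[label] = bundle
    return bundles


def sample_gan_training_set(bundles: dict[str, gan.GanBundle], n_per_class: int,
                            seed: int) -> tuple[np.ndarray, np.ndarray]:
    imgs, labels = [], []
    for k, (label, bundle) in enumerate(sorted(bundles.items())):
        imgs.append(gan.sample_images(bundle, n_per_class, seed=seed + k))
        labels += [label] * n_per_class
    return np.concatenate(imgs), np.asarray(labels)


def train_method(method: str, train_images: np.ndarray, train_labels: np.ndarray,
                 cfg: ScaledExperimentConfig, seed: int | None = None,
                 imagenet_weights: str | None = None) -> clf.Classifier:
    """Build + (pre)train one arm of the comparison; returns the fitted network."""
    seed = cfg.seed if seed is None else seed
    net = clf.build_classifier(
        clf.BackboneConfig(family="vgg_tiny", input_size=cfg.image_size,
                           init="imagenet_weights" if method == "ImageNet" else "random",
                           weights_path=imagenet_weights),
        seed=seed)
    plan = clf.TwoStepPlan(epochs=cfg.pretrain_epochs, learning_rate=cfg.desk_learning_rate,
                           seed=seed + 1)
    if method in ("PGGAN", "DCGAN"):
        bundles = train_gans(train_images, train_labels, cfg,
                             arch=method.lower(), seed=seed + 2)
        gan_imgs, gan_labels = sample_gan_training_set(
            bundles, cfg.gan_samples_per_class, seed=seed + 3)
        clf.pretrain_on_arrays(net, gan_imgs, gan_labels, plan)
    elif method != "ImageNet":
        raise ValueError(f"unknown pretraining method {method!r}")
    ft_plan = clf.TwoStepPlan(epochs=cfg.finetune_epochs, learning_rate=cfg.desk_learning_rate,
                              seed=seed + 4)
    clf.fine_tune_on_arrays(net, train_images, train_labels, ft_plan)
    return net


def holdout_experiment(cfg: ScaledExperimentConfig, methods=("PGGAN", "ImageNet"),
                       holdout_fraction: float = 0.33, seed: int | None = None):
    """Single stratified holdout run; returns {method: EvalReport}."""
    seed = cfg.seed if seed is None else seed
    images, labels, cases = make_synthetic_dataset(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed + 7))
    test_mask = np.zeros(len(images), dtype=bool)
    for label in ("benign", "malignant"):
        idx = np.flatnonzero(labels == label)
        take = rng.choice(idx, size=int(round(holdout_fraction * len(idx))), replace=False)
        test_mask[take] = True
    reports = {}
    for method in methods:
        net = train_method(method, images[~test_mask], labels[~test_mask], cfg, seed=seed)
        records = clf.predict_on_arrays(net, images[test_mask], labels[test_mask])
        reports[method] = evalstats.EvalReport.from_records(records)
    return reports


def crossval_comparison(cfg: ScaledExperimentConfig,
                        methods=("ImageNet", "DCGAN", "PGGAN"),
                        plan: evalstats.SplitPlan | None = None):
    """Three-method comparison under the holdout + k-fold protocol.

    Returns (table, reports, split_manifest-like DataFrame).  Fold predictions
    are pooled per method before the confusion matrix is computed.
    """
    images, labels, cases = make_synthetic_dataset(cfg)
    manifest = pd.DataFrame({
        "path": np.arange(len(images)).astype(str),
        "case_id": cases,
        "label": labels,
        "split": "unassigned",
    })
    if plan is None:
        plan = evalstats.SplitPlan(validation_holdout=max(10, len(images) // 6),
                                   cv_folds=3, grouping="case", seed=cfg.seed)

    def trainer(method, train_manifest, test_manifest, fold_idx):
        tr = train_manifest.index.to_numpy()
        te = test_manifest.index.to_numpy()
        net = train_method(method, images[tr], labels[tr], cfg,
                           seed=cfg.seed + 100 * fold_idx)
        return clf.predict_on_arrays(net, images[te], labels[te])

    return evalstats.run_comparison(manifest, {m: m for m in methods}, plan, trainer)
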