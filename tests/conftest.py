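import numpy as np
import pytest

from cytogan import pipeline, synthcyto


@pytest.fixture(scope="session")
def two_step_accuracies():
    """5-seed held-out accuracies of the scaled two-step experiment.

    Conditions: synthetic 32x32 cytology patches, 90 per class with a third
    held out (so the fine-tuning set is small, 60 per class), a 2-stage
    progressive GAN providing a large pretraining set, vgg_tiny backbone.
    The baseline arm trains the head only from random initialization.
    Shared session-wide because each seed trains two GANs and two classifiers.
    """
    cfg = pipeline.ScaledExperimentConfig(n_per_class=90)
    accs = {"PGGAN": [], "ImageNet": []}
    for seed in range(5):
        reports = pipeline.holdout_experiment(cfg, methods=("PGGAN", "ImageNet"), seed=seed)
        for method, report in reports.items():
            accs[method].append(report.accuracy)
    return accs


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 + 60 synthetic 32x32 patches with labels, shared across tests."""
    spec = synthcyto.SyntheticDatasetSpec(n_per_class=60, image_size=32, seed=11)
    return synthcyto.render_dataset_arrays(spec)


@pytest.fixture(scope="session")
def tiny_manifest_dir(tmp_path_factory):
    """A small on-disk dataset (PNGs + manifest)."""
    out = tmp_path_factory.mktemp("tinyset")
    spec = synthcyto.SyntheticDatasetSpec(n_per_class=12, image_size=32, seed=21)
    manifest = synthcyto.generate_dataset(spec, out)
    return out, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
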