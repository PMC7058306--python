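"""Progressive GAN construction/training, losses, SWD, DCGAN baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytogan import gan, synthcyto
from cytogan.gan import (GanTrainConfig, LatentSpec, StageSchedule, build_dcgan,
                         build_pggan, fade_in_alpha, sample_images,
                         sliced_wasserstein_distance, train_pggan, wasserstein_losses)

TINY_SCHEDULE = StageSchedule((4, 8), (16, 16), epochs_per_stage=2)


# ---------------------------------------------------------------------------
# schedule / fade-in


def test_default_schedule_follows_reference_feature_maps():
    s = StageSchedule.default(256)
    assert s.resolutions == (4, 8, 16, 32, 64, 128, 256)
    assert s.feature_maps == (512, 512, 512, 256, 128, 64, 32)


def test_schedule_rejects_bad_resolutions():
    with pytest.raises(ValueError):
        StageSchedule((4, 8, 32), (8, 8, 8))
    with pytest.raises(ValueError):
        StageSchedule((8, 16), (8, 8))
    with pytest.raises(ValueError):
        StageSchedule((4, 8), (8,))


def test_fade_in_alpha_linear_and_clamped():
    assert fade_in_alpha(0, 10) == 0.0
    assert fade_in_alpha(5, 10) == 0.5
    assert fade_in_alpha(10, 10) == 1.0
    assert fade_in_alpha(25, 10) == 1.0
    with pytest.raises(ValueError):
        fade_in_alpha(-1, 10)
    with pytest.raises(ValueError):
        fade_in_alpha(0, 0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(steps=st.integers(1, 1000), a=st.integers(0, 2000), b=st.integers(0, 2000))
def test_fade_in_alpha_monotone_in_step(steps, a, b):
    lo, hi = sorted((a, b))
    assert 0.0 <= fade_in_alpha(lo, steps) <= fade_in_alpha(hi, steps) <= 1.0


# ---------------------------------------------------------------------------
# losses


def test_wasserstein_loss_formulas():
    d, g = wasserstein_losses([1.0, 1.0], [0.0, 0.0], 0.0)
    assert d == -1.0 and g == 0.0
    d, g = wasserstein_losses([0.5, 0.7], [0.5, 0.7], 0.0)
    assert d == pytest.approx(0.0)
    _, g = wasserstein_losses([1.0], [0.0, 0.0, 0.0], 0.0)
    assert g == 0.0
    d, _ = wasserstein_losses([0.0], [0.0], gradient_penalty=2.0, gp_weight=10.0)
    assert d == 20.0
    with pytest.raises(ValueError):
        wasserstein_losses([], [1.0], 0.0)


# ---------------------------------------------------------------------------
# sliced Wasserstein distance


def test_swd_identical_sets_zero(rng):
    a = rng.standard_normal((20, 12))
    assert sliced_wasserstein_distance(a, a.copy()) == 0.0


def test_swd_matches_1d_sorted_oracle():
    """In 1-D every unit projection is +/-1, so SWD = mean |sorted a - sorted b|."""
    a = np.array([[0.0], [1.0]])
    b = np.array([[2.0], [3.0]])
    assert sliced_wasserstein_distance(a, b, n_projections=8, seed=0) == pytest.approx(2.0, abs=1e-9)
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 1, (30, 1))
    b = rng.uniform(0, 1, (30, 1))
    oracle = np.abs(np.sort(a.ravel()) - np.sort(b.ravel())).mean()
    assert sliced_wasserstein_distance(a, b, n_projections=16, seed=3) == pytest.approx(oracle, abs=1e-9)


def test_swd_symmetric_nonnegative(rng):
    a = rng.standard_normal((15, 6))
    b = rng.standard_normal((15, 6))
    ab = sliced_wasserstein_distance(a, b, seed=2)
    ba = sliced_wasserstein_distance(b, a, seed=2)
    assert ab == pytest.approx(ba, abs=1e-12)
    assert ab >= 0


def test_swd_rejects_mismatched_shapes(rng):
    with pytest.raises(ValueError):
        sliced_wasserstein_distance(rng.normal(size=(10, 3)), rng.normal(size=(10, 4)))


# ---------------------------------------------------------------------------
# progressive construction


def test_pggan_output_resolution_per_stage(rng):
    schedule = StageSchedule((4, 8, 16), (16, 16, 8), epochs_per_stage=1)
    bundle = build_pggan(schedule, LatentSpec(32), seed=0)
    z = rng.standard_normal((2, 32))
    for stage, res in enumerate(schedule.resolutions):
        out = bundle.generator.forward(z, stage, 1.0, train=False)
        assert out.shape == (2, 3, res, res)
        assert res == 4 * 2**stage


def test_pggan_full_schedule_reaches_256():
    schedule = StageSchedule.default(256)
    assert len(schedule.resolutions) == 7
    # constructing the full-size net is GPU-scale; check the schedule algebra
    assert schedule.resolutions[-1] == 256


def test_generator_output_bounded(rng):
    bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=1)
    bundle.stage = 1
    imgs = sample_images(bundle, 3, seed=0)
    assert imgs.shape == (3, 8, 8, 3)
    assert imgs.dtype == np.uint8


def test_sampling_deterministic_and_seed_sensitive():
    bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=1)
    a = sample_images(bundle, 4, seed=9)
    b = sample_images(bundle, 4, seed=9)
    c = sample_images(bundle, 4, seed=10)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


# ---------------------------------------------------------------------------
# training


@pytest.fixture(scope="module")
def tiny_reals():
    spec = synthcyto.SyntheticDatasetSpec(n_per_class=32, image_size=16, seed=77)
    images, labels, _ = synthcyto.render_dataset_arrays(spec)
    pooled = gan.downsample_to(gan._to_float(images[labels == "malignant"]), 8)
    return gan._to_uint8(pooled)


def test_train_pggan_two_stages_completes(tiny_reals):
    bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=2)
    log = train_pggan(bundle, tiny_reals, GanTrainConfig(minibatch=16, seed=3))
    assert log["stages"] == [4, 8]
    assert bundle.stage == 1
    assert sample_images(bundle, 2, seed=0).shape == (2, 8, 8, 3)


def test_train_pggan_deterministic(tiny_reals):
    def run():
        bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=2)
        train_pggan(bundle, tiny_reals, GanTrainConfig(minibatch=16, seed=3))
        return np.concatenate([p.value.ravel() for p in bundle.generator.params()])

    assert np.array_equal(run(), run())


def test_trained_generator_beats_noise_on_swd(tiny_reals):
    """After training, SWD(real, generated) < SWD(real, uniform noise)."""
    schedule = StageSchedule((4, 8), (16, 16), epochs_per_stage=100)
    bundle = build_pggan(schedule, LatentSpec(16), seed=4)
    train_pggan(bundle, tiny_reals, GanTrainConfig(minibatch=16, seed=5))
    fake = sample_images(bundle, 32, seed=6).reshape(32, -1).astype(np.float64)
    real = tiny_reals[:32].reshape(32, -1).astype(np.float64)
    noise = np.random.default_rng(7).uniform(0, 255, real.shape)
    swd_fake = sliced_wasserstein_distance(real, fake, seed=8)
    swd_noise = sliced_wasserstein_distance(real, noise, seed=8)
    assert swd_fake < 0.8 * swd_noise


def test_train_rejects_wrong_size(tiny_reals):
    bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=2)
    with pytest.raises(ValueError):
        train_pggan(bundle, tiny_reals[:, :4, :4, :], GanTrainConfig())


# ---------------------------------------------------------------------------
# DCGAN baseline


def test_dcgan_layer_counts_and_output_shape():
    bundle = build_dcgan(LatentSpec(128), resolution=256, base_channels=16, seed=0)
    g = gan.count_layers(bundle.generator)
    d = gan.count_layers(bundle.discriminator)
    assert g["conv"] == 5 and g["upscale"] == 4
    assert d["conv"] == 6 and d["dense"] == 1
    out = sample_images(bundle, 1, seed=0)
    assert out.shape == (1, 256, 256, 3)


def test_dcgan_sampling_deterministic():
    bundle = build_dcgan(LatentSpec(32), resolution=32, base_channels=16, seed=1)
    assert np.array_equal(sample_images(bundle, 2, seed=3), sample_images(bundle, 2, seed=3))


def test_dcgan_training_step_runs(tiny_reals):
    reals32 = np.repeat(np.repeat(tiny_reals, 4, axis=1), 4, axis=2)  # 8 -> 32 px
    bundle = build_dcgan(LatentSpec(16), resolution=32, base_channels=16, seed=1)
    cfg = GanTrainConfig(learning_rate=2e-4, beta1=0.5, minibatch=16, seed=2)
    log = gan.train_dcgan(bundle, reals32, cfg, epochs=2)
    assert len(log["d_loss"]) == 2


# ---------------------------------------------------------------------------
# checkpoints


def test_bundle_checkpoint_roundtrip(tmp_path, tiny_reals):
    bundle = build_pggan(TINY_SCHEDULE, LatentSpec(16), seed=2)
    train_pggan(bundle, tiny_reals, GanTrainConfig(minibatch=16, seed=3))
    gan.save_bundle(bundle, tmp_path / "ckpt")
    loaded = gan.load_bundle(tmp_path / "ckpt")
    assert np.array_equal(sample_images(loaded, 3, seed=1), sample_images(bundle, 3, seed=1))
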