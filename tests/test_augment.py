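"""Augmentation family: permutations, filters, exact-count set building."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from cytogan import augment as aug
from cytogan.augment import (AugmentConfig, apply_color_gain, apply_filter,
                             apply_geometric, build_augmented_set, enumerate_variants)


@pytest.fixture
def img(rng):
    return rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)


def test_identity_geometric(img):
    assert np.array_equal(apply_geometric(img, 0, "none"), img)


def test_rotation_four_times_is_identity(img):
    out = img
    for _ in range(4):
        out = apply_geometric(out, 90, "none")
    assert np.array_equal(out, img)


def test_rotation_180_moves_corner():
    img = np.zeros((256, 256, 3), dtype=np.uint8)
    img[0, 0] = (255, 1, 2)
    out = apply_geometric(img, 180, "none")
    assert tuple(out[255, 255]) == (255, 1, 2)


@pytest.mark.parametrize("rotation", aug.ROTATIONS)
@pytest.mark.parametrize("flip", aug.FLIPS)
def test_geometric_ops_are_pixel_permutations(img, rotation, flip):
    out = apply_geometric(img, rotation, flip)
    assert out.shape == img.shape
    assert np.array_equal(np.sort(out.reshape(-1, 3), axis=0),
                          np.sort(img.reshape(-1, 3), axis=0))


def test_geometric_rejects_non_square(rng):
    with pytest.raises(ValueError):
        apply_geometric(rng.integers(0, 255, (8, 10, 3), dtype=np.uint8), 90, "none")


def test_color_gain_identity_scale_and_clip(img):
    assert np.array_equal(apply_color_gain(img, (1, 1, 1)), img)
    px = np.array([[[100, 50, 50]]], dtype=np.uint8)
    assert tuple(apply_color_gain(px, (2, 1, 1))[0, 0]) == (200, 50, 50)
    px = np.array([[[200, 0, 0]]], dtype=np.uint8)
    assert tuple(apply_color_gain(px, (2, 1, 1))[0, 0]) == (255, 0, 0)
    with pytest.raises(ValueError):
        apply_color_gain(px, (0, 1, 1))


def test_filters_fix_constant_images():
    const = np.full((16, 16, 3), 77, dtype=np.uint8)
    assert np.array_equal(apply_filter(const, "gaussian", 1.5), const)
    assert np.array_equal(apply_filter(const, "edge_enhance", 1.5, 1.0), const)
    with pytest.raises(ValueError):
        apply_filter(const, "median")


def test_gaussian_impulse_peak_matches_kernel():
    """Blur of a unit impulse reproduces the normalized Gaussian kernel peak."""
    sigma = 1.0
    impulse = np.zeros((9, 9, 3))
    impulse[4, 4] = 1000.0
    blurred = gaussian_filter(impulse[:, :, 0], sigma)
    # oracle: explicit normalized kernel evaluated on the same truncated grid
    r = int(4 * sigma + 0.5)
    xs = np.arange(-r, r + 1)
    k1 = np.exp(-xs**2 / (2 * sigma**2))
    k1 /= k1.sum()
    peak = k1[r] ** 2  # separable 2-D peak weight
    assert abs(blurred[4, 4] / 1000.0 - peak) < 1e-6


def test_gaussian_preserves_mean_intensity(img):
    out = apply_filter(img, "gaussian", 2.0)
    assert abs(out.mean() - img.mean()) < 1.0


def test_enumerate_variants_product_and_uniqueness(img):
    config = AugmentConfig(color_gains=((1.0, 1.0, 1.0),))
    variants = enumerate_variants(img, config)
    assert len(variants) == 4 * 2 * 1 * 3 == 24
    descriptors = [d for d, _ in variants]
    assert len(set(descriptors)) == len(descriptors)
    assert aug.IDENTITY_DESCRIPTOR in descriptors


def test_enumerate_identity_only(img):
    config = AugmentConfig(rotations=(0,), flips=("none",),
                           color_gains=((1.0, 1.0, 1.0),), filters=("identity",))
    variants = enumerate_variants(img, config)
    assert len(variants) == 1
    assert np.array_equal(variants[0][1], img)


def test_config_requires_identity_members():
    with pytest.raises(ValueError):
        AugmentConfig(rotations=(90, 180))
    with pytest.raises(ValueError):
        AugmentConfig(color_gains=((0.9, 0.9, 0.9),))


def test_build_augmented_set_exact_counts(tiny_manifest_dir, tmp_path):
    _, manifest = tiny_manifest_dir
    config = AugmentConfig(target_count_per_class=40, seed=3)
    out = build_augmented_set(manifest, config, tmp_path / "aug")
    counts = out.groupby("label").size()
    assert (counts == 40).all()
    # every original appears exactly once untransformed
    for label, group in out.groupby("label"):
        ident = group[(group["rotation"] == 0) & (group["flip"] == "none")
                      & (group["gains"] == "1x1x1") & (group["filter"] == "identity")]
        assert sorted(ident["origin_path"]) == sorted(
            manifest[manifest["label"] == label]["path"])
    # no duplicate (origin, descriptor) pairs
    key = out[["origin_path", "rotation", "flip", "gains", "filter"]].apply(tuple, axis=1)
    assert key.is_unique


def test_build_augmented_set_target_equals_originals(tiny_manifest_dir, tmp_path):
    _, manifest = tiny_manifest_dir
    config = AugmentConfig(target_count_per_class=12, seed=0)
    out = build_augmented_set(manifest, config, tmp_path / "aug0")
    assert (out["filter"] == "identity").all() and (out["rotation"] == 0).all()


def test_build_augmented_set_deterministic(tiny_manifest_dir, tmp_path):
    _, manifest = tiny_manifest_dir
    config = AugmentConfig(target_count_per_class=30, seed=9)
    a = build_augmented_set(manifest, config, tmp_path / "a")
    b = build_augmented_set(manifest, config, tmp_path / "b")
    cols = ["origin_path", "rotation", "flip", "gains", "filter"]
    assert a[cols].equals(b[cols])


def test_build_augmented_set_capacity_errors(tiny_manifest_dir, tmp_path):
    _, manifest = tiny_manifest_dir
    with pytest.raises(ValueError):
        build_augmented_set(manifest, AugmentConfig(target_count_per_class=5), tmp_path / "x")
    huge = AugmentConfig(rotations=(0,), flips=("none",), color_gains=((1.0, 1.0, 1.0),),
                         filters=("identity",), target_count_per_class=13)
    with pytest.raises(ValueError):
        build_augmented_set(manifest, huge, tmp_path / "y")
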