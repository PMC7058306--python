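"""Data augmentation: rotations, flips, per-channel color gain, spatial filters.

The augmentation family mirrors what is useful for manually focused cytology
fields: right-angle rotations and a horizontal flip (lossless pixel
permutations), per-channel gain jitter standing in for staining/color
variation, and two spatial filters — a Gaussian blur and an unsharp-mask edge
enhancement — emulating the focus variation of manually acquired microscope
images.  ``build_augmented_set`` expands a manifest to an exact per-class
target count, always keeping every original once, sampling the remainder
without replacement from the enumerated variant pool.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

ROTATIONS = (0, 90, 180, 270)
FLIPS = ("none", "horizontal")
FILTERS = ("identity", "edge_enhance", "gaussian")

AUG_COLUMNS = ["path", "case_id", "label", "split", "origin_path", "rotation", "flip", "gains", "filter"]


@dataclass(frozen=True)
class AugmentConfig:
    rotations: tuple[int, ...] = ROTATIONS
    flips: tuple[str, ...] = FLIPS
    color_gains: tuple[tuple[float, float, float], ...] = (
        (1.0, 1.0, 1.0),
        (0.9, 1.0, 1.1),
        (1.1, 1.0, 0.9),
        (0.9, 0.9, 0.9),
        (1.1, 1.1, 1.1),
    )
    filters: tuple[str, ...] = FILTERS
    gaussian_sigma: float = 1.5
    edge_amount: float = 1.0
    target_count_per_class: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if 0 not in self.rotations:
            raise ValueError("rotations must include the identity 0")
        if "none" not in self.flips:
            raise ValueError("flips must include 'none'")
        if (1.0, 1.0, 1.0) not in tuple(tuple(g) for g in self.color_gains):
            raise ValueError("color_gains must include the identity (1,1,1)")
        if "identity" not in self.filters:
            raise ValueError("filters must include 'identity'")

    @property
    def variants_per_image(self) -> int:
        return len(self.rotations) * len(self.flips) * len(self.color_gains) * len(self.filters)


IDENTITY_DESCRIPTOR = (0, "none", (1.0, 1.0, 1.0), "identity")


def apply_geometric(image: np.ndarray, rotation: int, flip: str) -> np.ndarray:
    """Right-angle rotation then optional horizontal flip; an exact pixel permutation."""
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"geometric augmentation needs a square image, got {image.shape[:2]}")
    if rotation not in ROTATIONS:
        raise ValueError(f"rotation must be one of {ROTATIONS}")
    if flip not in FLIPS:
        raise ValueError(f"flip must be one of {FLIPS}")
    out = np.rot90(image, k=rotation // 90)
    if flip == "horizontal":
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def apply_color_gain(image: np.ndarray, gains) -> np.ndarray:
    gains = np.asarray(gains, dtype=np.float64)
    if gains.shape != (3,) or np.any(gains <= 0):
        raise ValueError(f"gains must be 3 positive values, got {gains}")
    out = image.astype(np.float64) * gains[None, None, :]
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_filter(image: np.ndarray, name: str, sigma: float = 1.5, edge_amount: float = 1.0) -> np.ndarray:
    if name == "identity":
        return image.copy()
    if name not in FILTERS:
        raise ValueError(f"unknown filter {name!r}")
    x = image.astype(np.float64)
    blurred = np.stack([gaussian_filter(x[:, :, c], sigma) for c in range(3)], axis=-1)
    if name == "gaussian":
        out = blurred
    else:  # unsharp mask: I + a * (I - G*I)
        out = x + edge_amount * (x - blurred)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def apply_descriptor(image: np.ndarray, desc, config: AugmentConfig) -> np.ndarray:
    rotation, flip, gains, filt = desc
    out = apply_geometric(image, rotation, flip)
    out = apply_color_gain(out, gains)
    return apply_filter(out, filt, config.gaussian_sigma, config.edge_amount)


def enumerate_descriptors(config: AugmentConfig):
    """All (rotation, flip, gains, filter) tuples; the identity is always present."""
    return [
        (r, f, tuple(g), flt)
        for r, f, g, flt in itertools.product(
            config.rotations, config.flips, config.color_gains, config.filters)
    ]


def enumerate_variants(patch: np.ndarray, config: AugmentConfig):
    """Return [(descriptor, image)] over the full Cartesian product."""
    return [(d, apply_descriptor(patch, d, config)) for d in enumerate_descriptors(config)]


def build_augmented_set(manifest: pd.DataFrame, config: AugmentConfig, out_dir) -> pd.DataFrame:
    """Expand each class to exactly ``target_count_per_class`` images.

    Every original appears once untransformed; the remainder is drawn without
    replacement from the non-identity variant pool with the config seed, so no
    (origin, descriptor) pair repeats.  Writes PNGs plus the augmented manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    descriptors = enumerate_descriptors(config)
    non_identity = [d for d in descriptors if d != IDENTITY_DESCRIPTOR]
    target = config.target_count_per_class

    rows = []
    for label, group in manifest.groupby("label", sort=True):
        group = group.reset_index(drop=True)
        n_orig = len(group)
        pool = n_orig * len(non_identity)
        if not (n_orig <= target <= n_orig + pool):
            raise ValueError(
                f"class {label!r}: target {target} outside [{n_orig}, {n_orig + pool}] "
                f"reachable with {len(descriptors)} variants per image")
        # identity first, then a without-replacement sample of (image, variant) pairs
        chosen = [(i, IDENTITY_DESCRIPTOR) for i in range(n_orig)]
        extra = rng.choice(pool, size=target - n_orig, replace=False)
        chosen += [(int(k) % n_orig, non_identity[int(k) // n_orig]) for k in np.sort(extra)]

        for j, (i, desc) in enumerate(chosen):
            rec = group.iloc[i]
            img = np.asarray(Image.open(rec["path"]).convert("RGB"))
            aug = apply_descriptor(img, desc, config)
            path = out / f"{label}_{j:06d}.png"
            Image.fromarray(aug).save(path)
            rows.append({
                "path": str(path),
                "case_id": rec["case_id"],
                "label": label,
                "split": rec.get("split", "unassigned"),
                "origin_path": rec["path"],
                "rotation": desc[0],
                "flip": desc[1],
                "gains": "x".join(f"{g:g}" for g in desc[2]),
                "filter": desc[3],
            })
    aug_manifest = pd.DataFrame(rows, columns=AUG_COLUMNS)
    aug_manifest.to_csv(out / "manifest.csv", index=False)
    return aug_manifest
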