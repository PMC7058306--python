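"""Seeded synthetic cytology-like patch generator.

Renders Papanicolaou-flavoured RGB patches: clumps of overlapping cells drawn
as cytoplasm ellipses with interior nucleus ellipses carrying chromatin
speckle, over a light background, finished with a global focus blur.  The
malignant parameterization has larger nuclei, a higher nucleus-to-cytoplasm
(N:C) area ratio and coarser chromatin — the morphologic atypia cues a
cytologist reads — so the two classes are separable by simple intensity
statistics and every downstream stage (augmentation, GAN training, two-step
classification) can be exercised end to end without clinical data.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse

MANIFEST_COLUMNS = ["path", "case_id", "label", "split"]

_BACKGROUND = np.array([232.0, 229.0, 234.0])  # pale grey-violet slide background


@dataclass(frozen=True)
class CellRenderParams:
    """Rendering knobs for one class. Lengths are in pixels of the output patch."""

    nucleus_radius_range: tuple[float, float]
    n_cells_range: tuple[int, int]
    nc_ratio_range: tuple[float, float]
    chromatin_noise_sd: float
    clump_spread: float
    focus_blur_sd_range: tuple[float, float]
    stain_palette: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self):
        for name in ("nucleus_radius_range", "nc_ratio_range", "focus_blur_sd_range", "n_cells_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if not (0 < self.nc_ratio_range[0] and self.nc_ratio_range[1] <= 1):
            raise ValueError("nc_ratio_range must lie in (0, 1]")
        if self.nucleus_radius_range[0] <= 0:
            raise ValueError("nucleus radii must be positive")


def default_params(label: str, image_size: int = 256) -> CellRenderParams:
    """Class defaults; nucleus radii scale with patch size (fractions of size)."""
    s = float(image_size)
    if label == "benign":
        return CellRenderParams(
            nucleus_radius_range=(0.030 * s, 0.045 * s),
            n_cells_range=(4, 9),
            nc_ratio_range=(0.25, 0.40),
            chromatin_noise_sd=10.0,
            clump_spread=0.16 * s,
            focus_blur_sd_range=(0.002 * s, 0.008 * s),
            stain_palette=((168.0, 196.0, 188.0), (95.0, 62.0, 118.0)),
        )
    if label == "malignant":
        return CellRenderParams(
            nucleus_radius_range=(0.060 * s, 0.090 * s),
            n_cells_range=(4, 9),
            nc_ratio_range=(0.55, 0.80),
            chromatin_noise_sd=28.0,
            clump_spread=0.16 * s,
            focus_blur_sd_range=(0.002 * s, 0.008 * s),
            stain_palette=((186.0, 160.0, 196.0), (52.0, 28.0, 72.0)),
        )
    raise ValueError(f"unknown label {label!r}")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_per_class: int
    image_size: int = 256
    benign_params: CellRenderParams | None = None
    malignant_params: CellRenderParams | None = None
    seed: int = 0
    patches_per_case: int = 5

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        s = self.image_size
        if s < 4 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of 2 >= 4")

    def params_for(self, label: str) -> CellRenderParams:
        p = self.benign_params if label == "benign" else self.malignant_params
        return p if p is not None else default_params(label, self.image_size)


def render_patch(params: CellRenderParams, size: int, seed: int):
    """Render one patch.

    Returns ``(image, mask)``: a (size, size, 3) uint8 image and a boolean
    nucleus mask.  Identical arguments give bit-identical output.
    """
    if size < 16:
        raise ValueError(f"patch size must be >= 16, got {size}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    brightness = rng.uniform(0.95, 1.05)
    img = np.ones((size, size, 3), dtype=np.float64) * _BACKGROUND * brightness
    mask = np.zeros((size, size), dtype=bool)

    cyto_rgb = np.array(params.stain_palette[0], dtype=np.float64)
    nuc_rgb = np.array(params.stain_palette[1], dtype=np.float64)

    lo, hi = params.n_cells_range
    n_cells = int(rng.integers(lo, hi + 1))
    center = np.array([size / 2.0, size / 2.0]) + rng.normal(0, size * 0.06, 2)

    # cytoplasm first for the whole clump, nuclei on top
    cells = []
    for _ in range(n_cells):
        pos = center + rng.normal(0, params.clump_spread, 2)
        r_nuc = rng.uniform(*params.nucleus_radius_range)
        nc = rng.uniform(*params.nc_ratio_range)
        r_cyto = r_nuc / np.sqrt(nc)
        ecc = rng.uniform(0.75, 1.3)
        theta = rng.uniform(0, np.pi)
        cells.append((pos, r_nuc, r_cyto, ecc, theta))

    for pos, r_nuc, r_cyto, ecc, theta in cells:
        rr, cc = ellipse(pos[0], pos[1], max(r_cyto * ecc, 1.0), max(r_cyto / ecc, 1.0),
                         shape=(size, size), rotation=theta)
        shade = rng.uniform(0.9, 1.1)
        img[rr, cc] = 0.45 * img[rr, cc] + 0.55 * cyto_rgb * shade

    for pos, r_nuc, r_cyto, ecc, theta in cells:
        off = rng.normal(0, 0.15 * r_cyto, 2)
        rr, cc = ellipse(pos[0] + off[0], pos[1] + off[1],
                         max(r_nuc * ecc, 0.8), max(r_nuc / ecc, 0.8),
                         shape=(size, size), rotation=theta)
        if rr.size == 0:
            continue
        speckle = rng.normal(0.0, params.chromatin_noise_sd, (rr.size, 3))
        img[rr, cc] = nuc_rgb + speckle
        mask[rr, cc] = True

    sigma = rng.uniform(*params.focus_blur_sd_range)
    if sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], sigma)

    return np.clip(img, 0, 255).astype(np.uint8), mask


def _patch_seed(base_seed: int, label: str, index: int) -> int:
    h = hashlib.sha256(f"{base_seed}:{label}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little")


def generate_dataset(spec: SyntheticDatasetSpec, out_dir) -> pd.DataFrame:
    """Write 2*n_per_class PNG patches plus a manifest CSV; return the manifest.

    Patches are grouped into synthetic "cases" of ``spec.patches_per_case``
    patches each so case-grouped cross-validation is meaningful downstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in ("benign", "malignant"):
        params = spec.params_for(label)
        for i in range(spec.n_per_class):
            img, _ = render_patch(params, spec.image_size, _patch_seed(spec.seed, label, i))
            name = f"{label}_{i:05d}.png"
            Image.fromarray(img).save(out / name)
            rows.append({
                "path": str(out / name),
                "case_id": f"{label[0]}{i // spec.patches_per_case:04d}",
                "label": label,
                "split": "unassigned",
            })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def render_dataset_arrays(spec: SyntheticDatasetSpec):
    """In-memory variant of :func:`generate_dataset`.

    Returns ``(images, labels, case_ids)`` with the same per-patch seeds as
    the on-disk generator, so both routes produce identical pixels.
    """
    images, labels, cases = [], [], []
    for label in ("benign", "malignant"):
        params = spec.params_for(label)
        for i in range(spec.n_per_class):
            img, _ = render_patch(params, spec.image_size, _patch_seed(spec.seed, label, i))
            images.append(img)
            labels.append(label)
            cases.append(f"{label[0]}{i // spec.patches_per_case:04d}")
    return np.stack(images), np.asarray(labels), np.asarray(cases)


def load_images(manifest: pd.DataFrame) -> np.ndarray:
    """Load manifest rows into a (N, H, W, 3) uint8 array, in row order."""
    return np.stack([np.asarray(Image.open(p).convert("RGB")) for p in manifest["path"]])


def dark_fraction(images: np.ndarray, threshold: float = 128.0) -> np.ndarray:
    """Per-image fraction of pixels whose mean channel value is below threshold.

    A cheap proxy for nuclear area: nuclei are the dark objects in a
    Papanicolaou-like patch.
    """
    gray = images.astype(np.float64).mean(axis=-1)
    return (gray < threshold).mean(axis=(1, 2))
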