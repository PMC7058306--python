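"""Tile microscopy fields into non-overlapping patches and apply expert labels.

A 1280x960 microscope field tiled at 256 yields floor(1280/256) x
floor(960/256) = 5 x 3 = 15 patches; leftover right/bottom margins are
discarded so every patch is exactly patch_size square.  Patches from benign
cases are labeled benign wholesale; patches from malignant cases carry the
cytopathologists' per-patch review (a selection table) and are labeled
malignant or excluded.  Excluded patches stay in the manifest, flagged, for
auditability.

The manifest is a pandas DataFrame with columns
``path, case_id, label, split, source, row, col``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

FULL_COLUMNS = ["path", "case_id", "label", "split", "source", "row", "col"]
LABELS = ("benign", "malignant", "excluded")


@dataclass(frozen=True)
class PatchRecord:
    source: str
    row: int
    col: int
    x0: int
    y0: int
    label: str = "unlabeled"


class MissingAnnotationError(KeyError):
    """A malignant-case patch has no entry in the selection table."""


def tile_image(image: np.ndarray, patch_size: int) -> list[PatchRecord]:
    """Split an H x W x 3 array into non-overlapping patch records, row-major."""
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError(f"expected a non-empty RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    return [
        PatchRecord(source="", row=r, col=c, x0=c * patch_size, y0=r * patch_size)
        for r in range(h // patch_size)
        for c in range(w // patch_size)
    ]


def extract_patch(image: np.ndarray, rec: PatchRecord, patch_size: int) -> np.ndarray:
    return image[rec.y0 : rec.y0 + patch_size, rec.x0 : rec.x0 + patch_size]


def label_patches(patches: list[PatchRecord], case_diagnosis: str,
                  selection: dict[tuple[str, int, int], bool] | None = None) -> list[PatchRecord]:
    """Assign labels from the case diagnosis plus the per-patch review table.

    selection maps (source, row, col) -> contains_malignant.  It is mandatory
    for malignant cases (fail loud on a missing key); for benign cases it is
    optional and, when given, False entries are excluded (e.g. empty
    background patches).
    """
    if case_diagnosis not in ("benign", "malignant"):
        raise ValueError(f"unknown diagnosis {case_diagnosis!r}")
    out = []
    for p in patches:
        key = (p.source, p.row, p.col)
        if case_diagnosis == "benign":
            keep = selection.get(key, True) if selection else True
            label = "benign" if keep else "excluded"
        else:
            if selection is None or key not in selection:
                raise MissingAnnotationError(
                    f"malignant-case patch {key} missing from the selection table")
            label = "malignant" if selection[key] else "excluded"
        out.append(PatchRecord(p.source, p.row, p.col, p.x0, p.y0, label))
    return out


def read_selection_table(path) -> dict[tuple[str, int, int], bool]:
    df = pd.read_csv(path)
    expected = {"source", "row", "col", "contains_malignant"}
    if not expected.issubset(df.columns):
        raise ValueError(f"selection table needs columns {sorted(expected)}, got {list(df.columns)}")
    table = {}
    for rec in df.itertuples(index=False):
        key = (rec.source, int(rec.row), int(rec.col))
        if key in table:
            raise ValueError(f"duplicate selection key {key}")
        table[key] = bool(rec.contains_malignant)
    return table


def records_to_manifest(records: list[PatchRecord], case_id: str, patch_dir: str) -> pd.DataFrame:
    rows = [{
        "path": str(Path(patch_dir) / f"{case_id}_r{p.row}_c{p.col}.png"),
        "case_id": case_id,
        "label": p.label,
        "split": "unassigned",
        "source": p.source,
        "row": p.row,
        "col": p.col,
    } for p in records]
    return pd.DataFrame(rows, columns=FULL_COLUMNS)


def tile_case(image_path, case_id: str, case_diagnosis: str, patch_size: int,
              out_dir, selection=None) -> pd.DataFrame:
    """Tile one source image, label its patches, write patch PNGs + manifest rows."""
    img = np.asarray(Image.open(image_path).convert("RGB"))
    patches = tile_image(img, patch_size)
    patches = [PatchRecord(str(image_path), p.row, p.col, p.x0, p.y0) for p in patches]
    patches = label_patches(patches, case_diagnosis, selection)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = records_to_manifest(patches, case_id, str(out))
    for p, path in zip(patches, manifest["path"]):
        Image.fromarray(extract_patch(img, p, patch_size)).save(path)
    return manifest


def validate_patch(image: np.ndarray, patch_size: int | None = None) -> None:
    """Raise unless image is square 8-bit RGB (optionally of a given size)."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected uint8, got {image.dtype}")
    if image.shape[0] != image.shape[1]:
        raise ValueError(f"expected square patch, got {image.shape[:2]}")
    if patch_size is not None and image.shape[0] != patch_size:
        raise ValueError(f"expected size {patch_size}, got {image.shape[0]}")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    required = {"path", "case_id", "label", "split"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "label": str, "split": str})
    required = {"path", "case_id", "label", "split"}
    if not required.issubset(df.columns):
        raise ValueError(f"malformed manifest header: {list(df.columns)}")
    # pandas reads an all-empty column as float NaN; normalize to str
    for col in ("path", "case_id", "label", "split"):
        df[col] = df[col].astype(str) if len(df) else df[col].astype(object)
    return df
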