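"""Manifest and image I/O.

A dataset is a directory of PNG/JPEG images plus a manifest CSV whose
``image_path`` column is resolved relative to the manifest's own directory,
followed by ``patient_id``, ``eye`` and one binary column per lesion label.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["read_manifest", "label_columns", "label_matrix", "load_images"]

_META_COLUMNS = ("image_path", "patient_id", "eye", "split")


def read_manifest(path) -> pd.DataFrame:
    """Load a manifest CSV, remembering its directory for path resolution."""
    path = Path(path)
    manifest = pd.read_csv(path)
    if "image_path" not in manifest.columns:
        raise ValueError(f"{path}: manifest lacks an image_path column")
    manifest.attrs["base_dir"] = str(path.parent)
    return manifest


def label_columns(manifest: pd.DataFrame) -> list[str]:
    """The manifest columns that carry binary lesion annotations."""
    cols = [c for c in manifest.columns if c not in _META_COLUMNS]
    if not cols:
        raise ValueError("manifest has no label columns")
    return cols


def label_matrix(manifest: pd.DataFrame,
                 labels: list[str] | None = None) -> np.ndarray:
    """Binary n x N matrix for the given (or inferred) label columns."""
    labels = labels or label_columns(manifest)
    Y = manifest[labels].to_numpy()
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("label columns must be binary")
    return Y.astype(np.int64)


def load_images(manifest: pd.DataFrame, base_dir=None,
                expected_size: int | None = None) -> np.ndarray:
    """Read every manifest image into a (n, H, W, 3) uint8 array."""
    if base_dir is None:
        base_dir = manifest.attrs.get("base_dir", ".")
    base_dir = Path(base_dir)
    out = []
    for rel in manifest["image_path"]:
        img_path = base_dir / rel
        if not img_path.exists():
            raise FileNotFoundError(f"manifest image missing: {img_path}")
        img = np.asarray(Image.open(img_path).convert("RGB"))
        if expected_size is not None and img.shape[:2] != (expected_size,
                                                           expected_size):
            raise ValueError(
                f"{img_path}: image is {img.shape[1]}x{img.shape[0]}, "
                f"expected {expected_size}")
        out.append(img)
    return np.stack(out)
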