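"""File formats: pyramidal TIFF slides, label maps with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from fibroquant.exceptions import FormatError


def write_pyramid_tiff(path, pyramid: list[np.ndarray]) -> None:
    """Write a multi-page pyramidal RGB TIFF (page k = level k)."""
    if not pyramid:
        raise FormatError("empty pyramid")
    with tifffile.TiffWriter(path) as tw:
        for level in pyramid:
            tw.write(np.asarray(level), photometric="rgb")


def read_pyramid_tiff(path) -> list[np.ndarray]:
    """Read a multi-page TIFF back into a list of levels (level 0 first)."""
    with tifffile.TiffFile(path) as tf:
        levels = [page.asarray() for page in tf.pages]
    if not levels:
        raise FormatError(f"no image pages in {path}")
    levels.sort(key=lambda a: -(a.shape[0] * a.shape[1]))
    return levels


def write_label_map(path, labels: np.ndarray, classes: tuple[str, ...]) -> None:
    """Single-channel label TIFF plus a JSON sidecar naming the labels."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint8), photometric="minisblack")
    sidecar = {str(i): c for i, c in enumerate(classes)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_label_map(path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    labels = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    classes = tuple(sidecar[str(i)] for i in range(len(sidecar)))
    return labels, classes


#: Fig-2-style false colours for exported class maps
EXCLUSION_PALETTE = {
    "background": (240, 230, 80),   # yellow
    "fibrotic_mass": (70, 170, 70),  # green
    "alveolar_tissue": (70, 90, 200),  # blue
    "bronchus": (200, 60, 60),      # red
}
COLLAGEN_PALETTE = {
    "background": (240, 230, 80),
    "lung_tissue": (200, 60, 60),
    "collagen": (70, 90, 200),
}


def class_map_overlay(labels: np.ndarray, classes: tuple[str, ...], palette: dict) -> np.ndarray:
    """False-colour RGB rendering of a class map (unclassified = black)."""
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for i, name in enumerate(classes):
        out[labels == i] = palette.get(name, (128, 128, 128))
    return out
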