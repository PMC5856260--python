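"""Class maps and ROI masks shared between the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fibroquant.exceptions import ParameterError

#: label value for pixels outside the classification mask
UNCLASSIFIED: int = -1

# canonical class lists for the two detection models
EXCLUSION_CLASSES = ("background", "fibrotic_mass", "alveolar_tissue", "bronchus")
COLLAGEN_CLASSES = ("background", "lung_tissue", "collagen")


@dataclass
class TissueClassMap:
    """Per-pixel class labels at a stated pyramid scale.

    ``labels[y, x]`` indexes into ``classes``; :data:`UNCLASSIFIED` marks
    pixels outside the classification mask.  ``scale`` is the linear
    downsampling factor relative to level 0.
    """

    labels: np.ndarray
    classes: tuple[str, ...]
    scale: int = 1
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ParameterError("labels must be a 2-D raster")
        self.classes = tuple(self.classes)
        if self.scale < 1:
            raise ParameterError("scale must be >= 1")
        lo, hi = int(self.labels.min(initial=0)), int(self.labels.max(initial=0))
        if lo < UNCLASSIFIED or hi >= len(self.classes):
            raise ParameterError("labels outside class list range")

    def index_of(self, name: str) -> int:
        try:
            return self.classes.index(name)
        except ValueError:
            raise ParameterError(f"class {name!r} not in {self.classes}") from None

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.labels == self.index_of(name)))

    def class_counts(self) -> dict[str, int]:
        return {c: self.count(c) for c in self.classes}

    def class_fractions(self) -> dict[str, float]:
        total = self.labels.size
        return {c: n / total for c, n in self.class_counts().items()}

    @property
    def n_unclassified(self) -> int:
        return int(np.count_nonzero(self.labels == UNCLASSIFIED))


@dataclass
class ROIMask:
    """Boolean region-of-interest raster at a stated scale."""

    mask: np.ndarray
    scale: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ParameterError("mask must be a 2-D raster")
        if self.scale < 1:
            raise ParameterError("scale must be >= 1")

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def is_empty(self) -> bool:
        return self.n_pixels == 0
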