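"""Low-magnification exclusion map, alveolar ROI and % fibrotic masses.

The low-magnification model discriminates four classes (background,
fibrotic masses, alveolar tissue, bronchi with their constitutive
peri-bronchial collagen).  The % fibrotic masses readout normalizes the
fibrotic-mass area to the parenchyma (mass + alveolar tissue), excluding
bronchi and background from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from fibroquant.classifier import TissueClassifier, classify
from fibroquant.exceptions import ConfigurationError, FormatError, UndefinedReadoutError
from fibroquant.maps import EXCLUSION_CLASSES, ROIMask, TissueClassMap

logger = logging.getLogger(__name__)

DEFAULT_TARGET_PIXELS = 1_000_000


def select_low_mag_level(
    pyramid: list[np.ndarray], target_pixels: int = DEFAULT_TARGET_PIXELS
) -> tuple[int, int]:
    """Pyramid level whose pixel count is closest to ``target_pixels``.

    Returns ``(level_index, scale)`` where scale is the linear
    downsampling factor relative to level 0.
    """
    if not pyramid:
        raise FormatError("empty pyramid")
    counts = [lvl.shape[0] * lvl.shape[1] for lvl in pyramid]
    level = int(np.argmin([abs(c - target_pixels) for c in counts]))
    scale = int(round(pyramid[0].shape[1] / pyramid[level].shape[1]))
    return level, max(1, scale)


def compute_exclusion_map(
    low_mag_image: np.ndarray,
    clf_low: TissueClassifier,
    scale: int = 1,
    pixel_size_um: float | None = None,
) -> TissueClassMap:
    """Classify every low-magnification pixel into the four tissue classes."""
    if tuple(clf_low.classes) != EXCLUSION_CLASSES and set(clf_low.classes) != set(
        EXCLUSION_CLASSES
    ):
        raise ConfigurationError(
            f"low-mag classifier classes {clf_low.classes} != {EXCLUSION_CLASSES}"
        )
    tmap = classify(low_mag_image, clf_low, mask=None, scale=scale, pixel_size_um=pixel_size_um)
    assert tmap.n_unclassified == 0
    return tmap


def derive_roi(tmap: TissueClassMap) -> ROIMask:
    """ROI = alveolar tissue; bronchi (and their collagen), masses and
    background are excluded."""
    mask = tmap.labels == tmap.index_of("alveolar_tissue")
    if not mask.any():
        logger.warning("ROI is empty: no alveolar tissue classified")
    return ROIMask(mask=mask, scale=tmap.scale)


def fibrotic_mass_percent(tmap: TissueClassMap) -> float:
    """100 * mass / (mass + alveolar tissue)."""
    m = tmap.count("fibrotic_mass")
    a = tmap.count("alveolar_tissue")
    if m + a == 0:
        raise UndefinedReadoutError("no parenchymal tissue classified (collapsed/empty slide)")
    return 100.0 * m / (m + a)


@dataclass(frozen=True)
class QCFlag:
    flagged: bool
    reasons: tuple[str, ...] = ()


def qc_flag_collapsed(
    tmap: TissueClassMap,
    min_tissue_fraction: float = 0.05,
    min_alveolar_fraction: float = 0.05,
) -> QCFlag:
    """Flag (never delete) slides that look collapsed or empty.

    A slide is flagged when the non-background tissue fraction or the
    alveolar fraction falls strictly below its threshold; flagged slides
    are excluded from group statistics by default downstream.
    """
    fr = tmap.class_fractions()
    tissue = 1.0 - fr.get("background", 0.0)
    reasons = []
    if tissue < min_tissue_fraction:
        reasons.append(f"tissue fraction {tissue:.3f} < {min_tissue_fraction}")
    if fr.get("alveolar_tissue", 0.0) < min_alveolar_fraction:
        reasons.append(
            f"alveolar fraction {fr.get('alveolar_tissue', 0.0):.3f} < {min_alveolar_fraction}"
        )
    return QCFlag(flagged=bool(reasons), reasons=tuple(reasons))
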