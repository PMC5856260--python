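"""Tiled full-resolution collagen quantification within the alveolar ROI.

The level-0 image is divided into 512x512 tiles; each tile is classified
independently (map step) with a halo of floor(structure_size/2) pixels so
that window features at tile borders equal the untiled computation, and
the per-tile class counts are summed (reduce step).  Readouts:

- alveolar collagen % = 100 * collagen / (collagen + lung tissue) within
  the ROI (alveolar lumen air is excluded from the denominator);
- total collagen %   = 100 * (alveolar collagen + fibrotic-mass area) /
  (fibrotic-mass area + alveolar wall tissue area), i.e. fibrotic masses
  are treated as collagen-bearing and bronchi are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from fibroquant.classifier import TissueClassifier
from fibroquant.exceptions import (
    AggregationError,
    BoundsError,
    ConfigurationError,
    DependencyError,
    ParameterError,
    UndefinedReadoutError,
)
from fibroquant.features import feature_maps
from fibroquant.maps import COLLAGEN_CLASSES, ROIMask, TissueClassMap
from fibroquant import roi as roi_mod

DEFAULT_TILE_SIZE = 512

TOTAL_COLLAGEN_FORMULA = (
    "100 * (alveolar_collagen_px + fibrotic_mass_px@level0) / "
    "(fibrotic_mass_px@level0 + collagen_px + lung_tissue_px); fibrotic masses are "
    "counted as collagen-bearing tissue, bronchi and air are excluded from both terms"
)


@dataclass(frozen=True)
class Tile:
    """Half-open level-0 tile [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.x0 < 0 or self.y0 < 0:
            raise ParameterError(f"invalid tile {self}")

    @property
    def tile_id(self) -> str:
        return f"{self.x0}_{self.y0}"


@dataclass
class TileResult:
    tile_id: str
    counts: dict[str, int]
    roi_pixels: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.roi_pixels:
            raise AggregationError("class counts must sum to the ROI pixel count")


@dataclass
class AggregatedCounts:
    counts: dict[str, int]
    roi_pixels: int
    n_tiles: int


@dataclass
class SlideQuantification:
    """Per-slide readouts plus QC flags and model provenance."""

    slide_id: str
    fibrotic_mass_percent: float | None
    alveolar_collagen_percent: float | None
    total_collagen_percent: float | None
    roi_area_px: int
    qc_flagged: bool
    qc_reasons: tuple[str, ...]
    model_hashes: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "fibrotic_mass_percent": self.fibrotic_mass_percent,
            "alveolar_collagen_percent": self.alveolar_collagen_percent,
            "total_collagen_percent": self.total_collagen_percent,
            "roi_area_px": self.roi_area_px,
            "qc_excluded": self.qc_flagged,
            "qc_reasons": ";".join(self.qc_reasons),
        }


def tile_grid(width: int, height: int, tile_size: int = DEFAULT_TILE_SIZE) -> list[Tile]:
    """Non-overlapping tiles covering [0,width) x [0,height) exactly once."""
    if width < 1 or height < 1 or tile_size < 1:
        raise ParameterError("width, height and tile_size must be positive")
    tiles = []
    for y0 in range(0, height, tile_size):
        for x0 in range(0, width, tile_size):
            tiles.append(
                Tile(x0=x0, y0=y0, width=min(tile_size, width - x0),
                     height=min(tile_size, height - y0))
            )
    return tiles


def upsample_roi(
    roi: ROIMask, tile: Tile, level0_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Nearest-neighbour ROI raster at level 0 for one tile.

    A level-0 pixel is in-ROI iff its containing low-magnification pixel
    is; indices are clipped to the low-mag raster when the level-0 extent
    is not an exact multiple of the scale.
    """
    s = roi.scale
    h_lo, w_lo = roi.mask.shape
    if level0_shape is None:
        level0_shape = (h_lo * s, w_lo * s)
    h0, w0 = level0_shape
    if tile.x0 + tile.width > w0 or tile.y0 + tile.height > h0:
        raise BoundsError(f"tile {tile} outside level-0 image {w0}x{h0}")
    ys = np.minimum(np.arange(tile.y0, tile.y0 + tile.height) // s, h_lo - 1)
    xs = np.minimum(np.arange(tile.x0, tile.x0 + tile.width) // s, w_lo - 1)
    return roi.mask[np.ix_(ys, xs)]


def _check_high_classes(clf: TissueClassifier) -> None:
    if set(clf.classes) != set(COLLAGEN_CLASSES):
        raise ConfigurationError(
            f"high-mag classifier classes {clf.classes} != {COLLAGEN_CLASSES}"
        )


def map_tile(
    image: np.ndarray,
    tile: Tile,
    roi: ROIMask | np.ndarray,
    clf_high: TissueClassifier,
) -> TileResult:
    """Map step: classify the ROI pixels of one tile.

    ``image`` is the level-0 raster from which the tile plus its feature
    halo is read; ``roi`` is either the low-mag ROI mask or a precomputed
    level-0 boolean raster for this tile.
    """
    _check_high_classes(clf_high)
    h0, w0 = image.shape[:2]
    if tile.x0 + tile.width > w0 or tile.y0 + tile.height > h0:
        raise BoundsError(f"tile {tile} outside image {w0}x{h0}")
    if isinstance(roi, ROIMask):
        tile_roi = upsample_roi(roi, tile, (h0, w0))
    else:
        tile_roi = np.asarray(roi, dtype=bool)
        if tile_roi.shape != (tile.height, tile.width):
            raise ParameterError("tile ROI raster shape mismatch")

    zero = {c: 0 for c in clf_high.classes}
    if not tile_roi.any():
        return TileResult(tile_id=tile.tile_id, counts=zero, roi_pixels=0)

    halo = clf_high.cfg.radius
    y0 = max(0, tile.y0 - halo)
    x0 = max(0, tile.x0 - halo)
    y1 = min(h0, tile.y0 + tile.height + halo)
    x1 = min(w0, tile.x0 + tile.width + halo)
    sub = image[y0:y1, x0:x1]
    maps = feature_maps(sub, clf_high.cfg)
    oy, ox = tile.y0 - y0, tile.x0 - x0
    maps = maps[oy:oy + tile.height, ox:ox + tile.width]
    feats = maps[tile_roi]
    preds = clf_high.predict(feats)
    counts = dict(zero)
    for cid, cnt in zip(*np.unique(preds, return_counts=True)):
        counts[clf_high.classes[int(cid)]] = int(cnt)
    return TileResult(tile_id=tile.tile_id, counts=counts, roi_pixels=int(tile_roi.sum()))


def reduce_tiles(results: Iterable[TileResult]) -> AggregatedCounts:
    """Reduce step: elementwise sum of tile counts (order-independent)."""
    results = list(results)
    ids = [r.tile_id for r in results]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AggregationError(f"duplicate tile ids: {dupes}")
    counts: dict[str, int] = {}
    roi_pixels = 0
    for r in results:
        for c, n in r.counts.items():
            counts[c] = counts.get(c, 0) + int(n)
        roi_pixels += r.roi_pixels
    return AggregatedCounts(counts=counts, roi_pixels=roi_pixels, n_tiles=len(results))


def alveolar_collagen_percent(agg: AggregatedCounts) -> float:
    """100 * collagen / (collagen + lung tissue) within the ROI."""
    coll = agg.counts.get("collagen", 0)
    tissue = agg.counts.get("lung_tissue", 0)
    if coll + tissue == 0:
        raise UndefinedReadoutError("no alveolar wall tissue classified within the ROI")
    return 100.0 * coll / (coll + tissue)


def total_collagen_percent(agg: AggregatedCounts, exclusion_map: TissueClassMap) -> float:
    """Total collagen over parenchymal tissue; see TOTAL_COLLAGEN_FORMULA."""
    if agg is None or exclusion_map is None:
        raise DependencyError("both pipeline stages are required for total collagen")
    coll = agg.counts.get("collagen", 0)
    tissue = agg.counts.get("lung_tissue", 0)
    mass_area0 = exclusion_map.count("fibrotic_mass") * exclusion_map.scale ** 2
    denom = mass_area0 + coll + tissue
    if denom == 0:
        raise UndefinedReadoutError("no parenchymal tissue found")
    return 100.0 * (coll + mass_area0) / denom


def quantify_slide(
    pyramid: Sequence[np.ndarray],
    clf_low: TissueClassifier,
    clf_high: TissueClassifier,
    slide_id: str = "slide",
    pixel_size_um: float | None = None,
    tile_size: int = DEFAULT_TILE_SIZE,
    target_low_mag_pixels: int = roi_mod.DEFAULT_TARGET_PIXELS,
    min_tissue_fraction: float = 0.05,
    min_alveolar_fraction: float = 0.05,
    qc_override_exclude: bool = False,
) -> SlideQuantification:
    """Run the full two-stage quantification on one pyramidal slide."""
    level, scale = roi_mod.select_low_mag_level(pyramid, target_low_mag_pixels)
    excl = roi_mod.compute_exclusion_map(
        pyramid[level], clf_low, scale=scale, pixel_size_um=pixel_size_um
    )
    qc = roi_mod.qc_flag_collapsed(excl, min_tissue_fraction, min_alveolar_fraction)
    qc_reasons = list(qc.reasons)
    if qc_override_exclude:
        qc_reasons.append("manual override exclusion")
    flagged = qc.flagged or qc_override_exclude

    roi_mask = roi_mod.derive_roi(excl)
    level0 = pyramid[0]
    h0, w0 = level0.shape[:2]

    mass_pct = alv_pct = total_pct = None
    agg = AggregatedCounts(counts={c: 0 for c in clf_high.classes}, roi_pixels=0, n_tiles=0)
    if not flagged:
        try:
            mass_pct = roi_mod.fibrotic_mass_percent(excl)
        except UndefinedReadoutError:
            flagged = True
            qc_reasons.append("undefined fibrotic-mass readout (no parenchyma)")
        results = [
            map_tile(level0, t, roi_mask, clf_high) for t in tile_grid(w0, h0, tile_size)
        ]
        agg = reduce_tiles(results)
        try:
            alv_pct = alveolar_collagen_percent(agg)
            total_pct = total_collagen_percent(agg, excl)
        except UndefinedReadoutError:
            flagged = True
            qc_reasons.append("undefined collagen readout (empty ROI)")
    if flagged:
        mass_pct = alv_pct = total_pct = None

    return SlideQuantification(
        slide_id=slide_id,
        fibrotic_mass_percent=mass_pct,
        alveolar_collagen_percent=alv_pct,
        total_collagen_percent=total_pct,
        roi_area_px=agg.roi_pixels,
        qc_flagged=flagged,
        qc_reasons=tuple(qc_reasons),
        model_hashes={"low": clf_low.model_hash(), "high": clf_high.model_hash()},
        metadata={
            "low_mag_level": level,
            "low_mag_scale": scale,
            "tile_size": tile_size,
            "n_tiles": agg.n_tiles,
            "total_collagen_formula": TOTAL_COLLAGEN_FORMULA,
        },
    )
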