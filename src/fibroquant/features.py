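"""Per-pixel feature extraction over a square structure-size window.

For every pixel a square window of edge length ``structure_size`` (the
"structure size") centred on the pixel is considered.  Per colour channel
the features are the window mean, min, max, variance and the edge factor

    edge_factor = 1/(|W|-1) * sum_{p' in W} (p' - p)^2

where ``W`` is the set of window pixels (including the centre, whose term
is zero) and ``p`` the centre pixel value.  At image borders the window is
clipped and all formulas use the actual ``|W|``.

Window sums are computed on integer pixel data via int64 summed-area
tables, so the vectorised maps are *exact* and therefore identical whether
an image is processed whole or in halo-padded tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from fibroquant.exceptions import BoundsError, DegenerateWindowError, ParameterError

#: "intensity" is the single-pixel (centre) intensity; the remaining
#: statistics are aggregates over the structure-size window
STATS = ("intensity", "mean", "min", "max", "variance", "edge_factor")
DEFAULT_CHANNELS = ("R", "G", "B")
_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


@dataclass(frozen=True)
class FeatureConfig:
    """Which per-pixel features to compute and over what window."""

    structure_size: int = 5
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    stats: tuple[str, ...] = STATS

    def __post_init__(self) -> None:
        ss = self.structure_size
        if not isinstance(ss, (int, np.integer)) or ss < 3 or ss % 2 == 0:
            raise ParameterError(f"structure_size must be an odd integer >= 3, got {ss!r}")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "stats", tuple(self.stats))
        if not self.stats:
            raise ParameterError("stats must be non-empty")
        if len(set(self.stats)) != len(self.stats):
            raise ParameterError("duplicate stats in FeatureConfig")
        unknown = set(self.stats) - set(STATS)
        if unknown:
            raise ParameterError(f"unknown stats: {sorted(unknown)}")
        for ch in self.channels:
            if ch not in _CHANNEL_INDEX:
                raise ParameterError(f"unknown channel {ch!r}")

    @property
    def radius(self) -> int:
        return self.structure_size // 2

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"{ch}_{st}" for ch in self.channels for st in self.stats)

    @property
    def n_features(self) -> int:
        return len(self.channels) * len(self.stats)

    def to_dict(self) -> dict:
        return {
            "structure_size": int(self.structure_size),
            "channels": list(self.channels),
            "stats": list(self.stats),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            structure_size=int(d["structure_size"]),
            channels=tuple(d["channels"]),
            stats=tuple(d["stats"]),
        )


def edge_factor(window_values: np.ndarray, center_value: float) -> float:
    """Mean squared deviation of window pixels from the centre pixel.

    ``window_values`` is the full window W including the centre pixel.
    """
    w = np.asarray(window_values, dtype=np.float64).ravel()
    if w.size < 2:
        raise DegenerateWindowError(f"window has {w.size} pixel(s); need >= 2")
    if not (np.all(np.isfinite(w)) and np.isfinite(center_value)):
        raise ParameterError("non-finite window values")
    d = w - float(center_value)
    return float(np.dot(d, d) / (w.size - 1))


def _check_channels(image: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ParameterError(f"expected HxWxC image, got shape {image.shape}")
    need = max(_CHANNEL_INDEX[c] for c in cfg.channels)
    if image.shape[2] <= need:
        raise ParameterError(
            f"image has {image.shape[2]} channel(s); config needs channel index {need}"
        )
    return image


def pixel_features(image: np.ndarray, x: int, y: int, cfg: FeatureConfig) -> np.ndarray:
    """Feature vector at pixel ``(x, y)`` (x = column, y = row), computed naively.

    This is the straightforward windowed implementation; :func:`feature_block`
    is the vectorised counterpart and must agree with it.
    """
    image = _check_channels(image, cfg)
    h, w = image.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise BoundsError(f"pixel ({x}, {y}) outside {w}x{h} image")
    r = cfg.radius
    y0, y1 = max(0, y - r), min(h, y + r + 1)
    x0, x1 = max(0, x - r), min(w, x + r + 1)
    out = np.empty(cfg.n_features, dtype=np.float64)
    i = 0
    for ch in cfg.channels:
        win = image[y0:y1, x0:x1, _CHANNEL_INDEX[ch]].astype(np.float64)
        center = float(image[y, x, _CHANNEL_INDEX[ch]])
        for st in cfg.stats:
            if st == "intensity":
                out[i] = center
            elif st == "mean":
                out[i] = win.mean()
            elif st == "min":
                out[i] = win.min()
            elif st == "max":
                out[i] = win.max()
            elif st == "variance":
                out[i] = win.var()
            else:  # edge_factor
                out[i] = edge_factor(win, center)
            i += 1
    return out


def _sat(a: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero top/left border, exact in int64."""
    h, w = a.shape
    p = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(a, axis=0, dtype=np.int64, out=p[1:, 1:])
    np.cumsum(p[1:, 1:], axis=1, out=p[1:, 1:])
    return p


def _window_sum(p: np.ndarray, r: int) -> np.ndarray:
    h, w = p.shape[0] - 1, p.shape[1] - 1
    y0 = np.clip(np.arange(h) - r, 0, h)
    y1 = np.clip(np.arange(h) + r + 1, 0, h)
    x0 = np.clip(np.arange(w) - r, 0, w)
    x1 = np.clip(np.arange(w) + r + 1, 0, w)
    return p[y1[:, None], x1[None, :]] - p[y0[:, None], x1[None, :]] \
        - p[y1[:, None], x0[None, :]] + p[y0[:, None], x0[None, :]]


def feature_maps(image: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Dense per-pixel feature maps, shape (H, W, n_features)."""
    image = _check_channels(image, cfg)
    h, w = image.shape[:2]
    r = cfg.radius
    # clipped window pixel counts
    ny = np.clip(np.arange(h) + r + 1, 0, h) - np.clip(np.arange(h) - r, 0, h)
    nx = np.clip(np.arange(w) + r + 1, 0, w) - np.clip(np.arange(w) - r, 0, w)
    n = (ny[:, None] * nx[None, :]).astype(np.int64)
    out = np.empty((h, w, cfg.n_features), dtype=np.float64)
    i = 0
    for ch in cfg.channels:
        band = image[:, :, _CHANNEL_INDEX[ch]]
        a = band.astype(np.int64)
        s = _window_sum(_sat(a), r)
        s2 = _window_sum(_sat(a * a), r)
        c = a  # centre values
        for st in cfg.stats:
            if st == "intensity":
                out[:, :, i] = band
            elif st == "mean":
                out[:, :, i] = s / n
            elif st == "min":
                out[:, :, i] = ndi.minimum_filter(band, size=cfg.structure_size, mode="nearest")
            elif st == "max":
                out[:, :, i] = ndi.maximum_filter(band, size=cfg.structure_size, mode="nearest")
            elif st == "variance":
                m = s / n
                out[:, :, i] = np.maximum(s2 / n - m * m, 0.0)
            else:  # edge_factor
                out[:, :, i] = np.maximum((s2 - 2 * c * s + n * c * c) / (n - 1), 0.0)
            i += 1
    return out


def feature_block(
    image: np.ndarray, cfg: FeatureConfig, mask: np.ndarray | None = None
) -> np.ndarray:
    """Feature matrix over masked pixels in row-major scan order."""
    image = _check_channels(image, cfg)
    maps = feature_maps(image, cfg)
    if mask is None:
        return maps.reshape(-1, cfg.n_features)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape[:2]:
        raise ParameterError(f"mask shape {mask.shape} != image shape {image.shape[:2]}")
    return maps[mask]


def features_at(image: np.ndarray, cfg: FeatureConfig, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Feature rows at explicit pixel positions (vectorised)."""
    maps = feature_maps(image, cfg)
    return maps[np.asarray(ys, dtype=np.intp), np.asarray(xs, dtype=np.intp)]
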