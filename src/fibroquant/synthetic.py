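"""Synthetic Masson's-trichrome-like slide generator with exact ground truth.

Slides are rendered from a generative layout: a lung-lobe silhouette on a
near-white background, a lacy alveolar septal lattice (thin red walls with
air-filled lumina), blue collagen painted on a controllable fraction of
septal pixels, dense fibrotic masses (clumpy collagen with cellular
speckle), and ring-shaped bronchi with a peri-bronchial collagen collar.
Stain drift is modelled as a global HSV hue rotation plus an intensity
gain and never alters the ground-truth label maps.

Two label views are provided: the coarse 5-class map (background,
fibrotic_mass, alveolar_tissue, bronchus, alveolar_collagen — the alveolar
label covers the whole lacy region including lumina) and the fine render
map (background, lung_tissue, collagen) that drives the colouring and the
high-magnification model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from shapely.geometry import box
from skimage.color import hsv2rgb, rgb2hsv

from fibroquant.annotations import AnnotationEntry, AnnotationSet
from fibroquant.exceptions import MissingClassError, ParameterError
from fibroquant.maps import COLLAGEN_CLASSES, EXCLUSION_CLASSES

logger = logging.getLogger(__name__)

# coarse ground-truth labels
GT_CLASSES = ("background", "fibrotic_mass", "alveolar_tissue", "bronchus", "alveolar_collagen")
LBL_BACKGROUND, LBL_MASS, LBL_ALVEOLAR, LBL_BRONCHUS, LBL_COLLAGEN = range(5)

# fine render labels
RENDER_CLASSES = COLLAGEN_CLASSES  # ("background", "lung_tissue", "collagen")
RM_BACKGROUND, RM_TISSUE, RM_COLLAGEN = range(3)

_MAX_PYRAMID_DIM = 1024


def _check_rgb(name: str, rgb) -> tuple[int, int, int]:
    rgb = tuple(int(v) for v in rgb)
    if len(rgb) != 3 or any(not (0 <= v <= 255) for v in rgb):
        raise ParameterError(f"{name} must be an RGB triple in [0,255]^3, got {rgb}")
    return rgb


@dataclass(frozen=True)
class StainProfile:
    """Named colour triples plus global hue/intensity drift."""

    collagen_rgb: tuple[int, int, int] = (72, 96, 178)
    tissue_rgb: tuple[int, int, int] = (198, 96, 120)
    background_rgb: tuple[int, int, int] = (246, 243, 246)
    hue_shift_deg: float = 0.0
    intensity_scale: float = 1.0
    name: str = "default"

    def __post_init__(self) -> None:
        object.__setattr__(self, "collagen_rgb", _check_rgb("collagen_rgb", self.collagen_rgb))
        object.__setattr__(self, "tissue_rgb", _check_rgb("tissue_rgb", self.tissue_rgb))
        object.__setattr__(
            self, "background_rgb", _check_rgb("background_rgb", self.background_rgb)
        )
        if not np.isfinite(self.hue_shift_deg) or abs(self.hue_shift_deg) > 180:
            raise ParameterError(f"hue_shift_deg out of range: {self.hue_shift_deg}")
        if not np.isfinite(self.intensity_scale) or not (0.1 <= self.intensity_scale <= 3.0):
            raise ParameterError(f"intensity_scale out of range: {self.intensity_scale}")


@dataclass(frozen=True)
class SyntheticSlideParams:
    """Generator knobs for one synthetic slide."""

    width_px: int = 512
    height_px: int = 512
    fibrotic_mass_fraction: float = 0.0
    alveolar_collagen_fraction: float = 0.0
    n_bronchi: int = 0
    stain_profile: StainProfile = field(default_factory=StainProfile)
    noise_sd: float = 4.0
    pixel_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.width_px) < 64 or int(self.height_px) < 64:
            raise ParameterError("width_px and height_px must be >= 64")
        for fname in ("fibrotic_mass_fraction", "alveolar_collagen_fraction"):
            v = getattr(self, fname)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ParameterError(f"{fname} must be a finite fraction in [0,1], got {v}")
        if int(self.n_bronchi) < 0:
            raise ParameterError("n_bronchi must be non-negative")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")


@dataclass
class GroundTruth:
    """Exact per-pixel labels for a generated slide."""

    label_map: np.ndarray  # coarse 5-class labels (GT_CLASSES)
    render_map: np.ndarray  # fine 3-class labels (RENDER_CLASSES)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map, dtype=np.uint8)
        self.render_map = np.asarray(self.render_map, dtype=np.uint8)
        if self.label_map.shape != self.render_map.shape:
            raise ParameterError("label_map and render_map shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def view(self, name: str) -> tuple[np.ndarray, tuple[str, ...]]:
        """Label raster + class names for a model view.

        "full": the 5 coarse labels; "exclusion": the 4 low-magnification
        classes (alveolar collagen merged into alveolar tissue);
        "collagen": the 3 high-magnification classes.
        """
        if name == "full":
            return self.label_map, GT_CLASSES
        if name == "exclusion":
            lab = self.label_map.copy()
            lab[lab == LBL_COLLAGEN] = LBL_ALVEOLAR
            return lab, EXCLUSION_CLASSES
        if name == "collagen":
            return self.render_map, RENDER_CLASSES
        raise ParameterError(f"unknown view {name!r}")

    def mass_fraction(self) -> float:
        """Fibrotic-mass pixels over parenchymal tissue area (mass + alveolar region)."""
        m = int(np.count_nonzero(self.label_map == LBL_MASS))
        a = int(np.count_nonzero(self.label_map == LBL_ALVEOLAR))
        c = int(np.count_nonzero(self.label_map == LBL_COLLAGEN))
        denom = m + a + c
        return m / denom if denom else 0.0

    def collagen_fraction(self) -> float:
        """Alveolar-collagen pixels over alveolar wall pixels (collagen + septal tissue)."""
        coll = int(np.count_nonzero(self.label_map == LBL_COLLAGEN))
        sept = int(
            np.count_nonzero(
                (self.render_map == RM_TISSUE) & (self.label_map == LBL_ALVEOLAR)
            )
        )
        denom = coll + sept
        return coll / denom if denom else 0.0


# ---------------------------------------------------------------------------
# field helpers

def _smooth_unit_field(shape: tuple[int, int], rng: np.random.Generator,
                       scale: int = 8, sigma: float = 3.0) -> np.ndarray:
    """Smooth random field rescaled to [0, 1]."""
    h, w = shape
    lo = rng.standard_normal((h // scale + 2, w // scale + 2))
    lo = ndi.gaussian_filter(lo, sigma)
    f = ndi.zoom(lo, scale, order=1)[:h, :w]
    rng_span = np.ptp(f)
    return (f - f.min()) / (rng_span if rng_span > 0 else 1.0)


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy * yy + xx * xx <= r * r
    return yy[keep], xx[keep]


def _paint_disk(mask: np.ndarray, cy: int, cx: int, radius: int,
                allowed: np.ndarray | None = None) -> None:
    h, w = mask.shape
    dy, dx = _disk_offsets(radius)
    ys = cy + dy
    xs = cx + dx
    ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    ys, xs = ys[ok], xs[ok]
    if allowed is not None:
        keep = allowed[ys, xs]
        ys, xs = ys[keep], xs[keep]
    mask[ys, xs] = True


# ---------------------------------------------------------------------------
# slide generation

def _layout(params: SyntheticSlideParams, rng: np.random.Generator):
    """Geometric layout masks (everything except colours/noise)."""
    h, w = int(params.height_px), int(params.width_px)
    shape = (h, w)

    silhouette_field = _smooth_unit_field(shape, rng, scale=8, sigma=5.0)
    thr = np.quantile(silhouette_field, 0.35)
    silhouette = silhouette_field > thr

    # --- bronchi: ring of tissue, collar of collagen, air lumen -----------
    bronchus_lumen = np.zeros(shape, dtype=bool)
    bronchus_ring = np.zeros(shape, dtype=bool)
    bronchus_collar = np.zeros(shape, dtype=bool)
    if params.n_bronchi > 0:
        edt = ndi.distance_transform_edt(silhouette)
        base_r = max(10.0, 0.065 * min(h, w))
        for _ in range(int(params.n_bronchi)):
            r_out = base_r * rng.uniform(0.85, 1.2)
            need = 1.3 * r_out
            cand = np.argwhere(edt > need)
            if len(cand) == 0:
                r_out = max(5.0, float(edt.max()) / 1.45)
                cand = np.argwhere(edt > 1.3 * r_out)
                if len(cand) == 0:
                    continue
            cy, cx = cand[rng.integers(len(cand))]
            yy, xx = np.mgrid[0:h, 0:w]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            lum = d2 <= (0.30 * r_out) ** 2
            ring = (d2 <= r_out ** 2) & ~lum
            collar = (d2 <= (1.15 * r_out) ** 2) & ~lum & ~ring & silhouette
            bronchus_lumen |= lum & silhouette
            bronchus_ring |= ring & silhouette
            bronchus_collar |= collar

    bronchus_any = bronchus_lumen | bronchus_ring | bronchus_collar

    # --- fibrotic masses: union of disks until area target met ------------
    mass = np.zeros(shape, dtype=bool)
    parenchyma = silhouette & ~bronchus_any
    denom = int(np.count_nonzero(parenchyma))
    target = float(params.fibrotic_mass_fraction)
    if target > 0 and denom > 0:
        coords = np.argwhere(parenchyma)
        guard = 0
        while guard < 10000:
            guard += 1
            cur = np.count_nonzero(mass) / denom
            remaining = target - cur
            if remaining <= 0.002:
                break
            rem_px = remaining * denom
            radius = int(np.clip(np.sqrt(rem_px / np.pi), 4, 0.08 * min(h, w) + 12))
            cy, cx = coords[rng.integers(len(coords))]
            _paint_disk(mass, cy, cx, radius, allowed=parenchyma)

    # --- alveolar septal lattice ------------------------------------------
    alv_region = parenchyma & ~mass
    septum = np.zeros(shape, dtype=bool)
    if alv_region.any():
        spacing = 14.0
        gx = np.arange(spacing / 2, w, spacing)
        gy = np.arange(spacing / 2, h, spacing)
        pts = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1).reshape(-1, 2)
        pts = pts + rng.uniform(-0.45, 0.45, size=pts.shape) * spacing
        tree = cKDTree(pts)
        coords = np.argwhere(alv_region)
        d, _ = tree.query(coords.astype(np.float64), k=2)
        width_field = 1.6 + 3.4 * _smooth_unit_field(shape, rng, scale=8, sigma=2.0)
        ridge = (d[:, 1] - d[:, 0]) < width_field[coords[:, 0], coords[:, 1]]
        septum[coords[ridge, 0], coords[ridge, 1]] = True
        # pleural wall along the silhouette edge
        interior = ndi.binary_erosion(silhouette, np.ones((5, 5)))
        septum |= alv_region & ~interior

    # --- alveolar collagen painted on septa -------------------------------
    collagen = np.zeros(shape, dtype=bool)
    target_c = float(params.alveolar_collagen_fraction)
    if target_c > 0 and septum.any():
        sept_coords = np.argwhere(septum)
        guard = 0
        while guard < 40000:
            guard += 1
            n_c = np.count_nonzero(collagen)
            n_s = np.count_nonzero(septum & ~collagen)
            if n_c + n_s == 0 or n_c / (n_c + n_s) >= target_c:
                break
            cy, cx = sept_coords[rng.integers(len(sept_coords))]
            _paint_disk(collagen, cy, cx, int(rng.integers(4, 9)), allowed=alv_region)

    septum |= collagen  # thickened walls are wall tissue too

    return {
        "silhouette": silhouette,
        "bronchus_lumen": bronchus_lumen,
        "bronchus_ring": bronchus_ring,
        "bronchus_collar": bronchus_collar,
        "mass": mass,
        "alv_region": alv_region,
        "septum": septum,
        "collagen": collagen,
    }


def _build_maps(shape, layout, rng_texture) -> tuple[np.ndarray, np.ndarray]:
    label = np.full(shape, LBL_BACKGROUND, dtype=np.uint8)
    render = np.full(shape, RM_BACKGROUND, dtype=np.uint8)

    label[layout["alv_region"]] = LBL_ALVEOLAR
    label[layout["mass"]] = LBL_MASS
    br = layout["bronchus_lumen"] | layout["bronchus_ring"] | layout["bronchus_collar"]
    label[br] = LBL_BRONCHUS
    coll = layout["collagen"] & layout["alv_region"]
    label[coll] = LBL_COLLAGEN

    sept = layout["septum"] & layout["alv_region"]
    render[sept] = RM_TISSUE
    render[coll] = RM_COLLAGEN
    render[layout["bronchus_ring"]] = RM_TISSUE
    render[layout["bronchus_collar"]] = RM_COLLAGEN

    mass = layout["mass"]
    if mass.any():
        clump = _smooth_unit_field(shape, rng_texture, scale=4, sigma=1.2)
        thr = np.quantile(clump[mass], 0.25)
        render[mass & (clump >= thr)] = RM_COLLAGEN
        render[mass & (clump < thr)] = RM_TISSUE
    return label, render


def _render_rgb(render: np.ndarray, stain: StainProfile,
                noise_sd: float, rng_noise: np.random.Generator,
                dense_collagen: np.ndarray | None = None) -> np.ndarray:
    palette = np.array(
        [stain.background_rgb, stain.tissue_rgb, stain.collagen_rgb], dtype=np.float64
    )
    img = palette[render] / 255.0
    if dense_collagen is not None and dense_collagen.any():
        # constitutive peri-bronchial collagen stains denser/darker
        img[dense_collagen] *= 0.62
    if stain.hue_shift_deg != 0.0 or stain.intensity_scale != 1.0:
        hsv = rgb2hsv(img)
        hsv[:, :, 0] = (hsv[:, :, 0] + stain.hue_shift_deg / 360.0) % 1.0
        img = hsv2rgb(hsv)
        img = img * stain.intensity_scale
    img = img * 255.0
    if noise_sd > 0:
        img = img + rng_noise.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x mean-pool; odd trailing rows/columns are dropped."""
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    a = img[: h2 * 2, : w2 * 2].astype(np.float64)
    out = (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2]) / 4.0
    return np.round(out).astype(img.dtype)


def build_pyramid(level0: np.ndarray, max_dim: int = _MAX_PYRAMID_DIM) -> list[np.ndarray]:
    """Half-resolution pyramid levels until max dimension <= max_dim."""
    levels = [level0]
    while max(levels[-1].shape[:2]) > max_dim:
        levels.append(_downsample2(levels[-1]))
    return levels


def generate_slide(params: SyntheticSlideParams) -> tuple[list[np.ndarray], GroundTruth]:
    """Generate one pyramidal slide plus its full-resolution ground truth.

    Deterministic given ``params.seed``; the stain profile affects only the
    rendered colours, never the label maps.
    """
    ss = np.random.SeedSequence(int(params.seed))
    rng_geom, rng_texture, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))

    shape = (int(params.height_px), int(params.width_px))
    layout = _layout(params, rng_geom)
    label, render = _build_maps(shape, layout, rng_texture)
    level0 = _render_rgb(render, params.stain_profile, params.noise_sd, rng_noise,
                         dense_collagen=layout["bronchus_collar"])
    gt = GroundTruth(label_map=label, render_map=render, pixel_size_um=params.pixel_size_um)

    realized = gt.mass_fraction()
    if abs(realized - params.fibrotic_mass_fraction) > 0.02:
        logger.warning(
            "realized mass fraction %.3f deviates from target %.3f",
            realized, params.fibrotic_mass_fraction,
        )
    return build_pyramid(level0), gt


# ---------------------------------------------------------------------------
# simulated rater annotations

_DEFAULT_EROSION = {"exclusion": 12, "collagen": 2, "full": 2}
_RECT_SIZES = (
    (32, 32), (24, 24), (16, 16), (12, 12), (8, 8), (8, 3), (3, 8),
    (6, 6), (4, 4), (6, 2), (2, 6), (3, 3), (2, 2), (4, 1), (1, 4), (1, 1),
)


def generate_annotations(
    gt: GroundTruth,
    n_regions_per_class: int = 5,
    min_area_px: int = 64,
    seed: int = 0,
    view: str = "exclusion",
    classes: tuple[str, ...] | None = None,
    erosion_radius: int | None = None,
    image_id: str = "slide",
    level: int = 0,
) -> AnnotationSet:
    """Simulate a rater drawing representative rectangular annotations.

    Polygons are placed fully interior to their class region after erosion
    by ``erosion_radius`` (defaults to the model's feature-window radius)
    so that every training pixel's window is pure.
    """
    labels, class_names = gt.view(view)
    if classes is None:
        classes = class_names
    if erosion_radius is None:
        erosion_radius = _DEFAULT_EROSION[view]
    if n_regions_per_class < 1:
        raise ParameterError("n_regions_per_class must be >= 1")

    missing = [c for c in classes if c not in class_names]
    if missing:
        raise MissingClassError(missing)
    rng = np.random.default_rng(int(seed))
    h, w = labels.shape

    # the high-magnification model operates inside the alveolar ROI only, so
    # its training annotations avoid bronchus territory (incl. the dense
    # peri-bronchial collagen collar, which never enters the ROI)
    domain = None
    if view == "collagen":
        domain = gt.label_map != LBL_BRONCHUS

    def _class_mask(c: str) -> np.ndarray:
        mask = labels == class_names.index(c)
        return mask & domain if domain is not None else mask

    absent = [
        c for c in classes if np.count_nonzero(_class_mask(c)) < max(1, int(min_area_px))
    ]
    if absent:
        raise MissingClassError(absent)

    entries: list[AnnotationEntry] = []
    for cls in classes:
        mask = _class_mask(cls)
        r = int(erosion_radius)
        eroded = mask
        while r > 0:
            eroded = ndi.binary_erosion(mask, np.ones((2 * r + 1, 2 * r + 1)))
            if eroded.any():
                break
            r //= 2  # thin structures: relax the purity margin
        if not eroded.any():
            eroded = mask
        if r != erosion_radius:
            logger.warning("class %s: erosion radius relaxed %d -> %d", cls, erosion_radius, r)
        coords = np.argwhere(eroded)
        for _ in range(int(n_regions_per_class)):
            y, x = coords[rng.integers(len(coords))]
            for ph, pw in _RECT_SIZES:
                y0 = int(np.clip(y - ph // 2, 0, h - ph)) if ph <= h else 0
                x0 = int(np.clip(x - pw // 2, 0, w - pw)) if pw <= w else 0
                if ph > h or pw > w:
                    continue
                if eroded[y0:y0 + ph, x0:x0 + pw].all():
                    entries.append(
                        AnnotationEntry(
                            image_id=image_id,
                            level=level,
                            polygon=box(x0, y0, x0 + pw, y0 + ph),
                            class_label=cls,
                        )
                    )
                    break
    return AnnotationSet(entries)


# ---------------------------------------------------------------------------
# multi-slide studies

@dataclass(frozen=True)
class GroupSpec:
    """Parameter distribution for one study group."""

    name: str
    n_slides: int
    mass_fraction: tuple[float, float] = (0.0, 0.05)
    collagen_fraction: tuple[float, float] = (0.0, 0.04)
    n_bronchi: tuple[int, int] = (1, 3)
    hue_shift_deg: tuple[float, float] = (-15.0, 15.0)
    intensity_scale: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 4.0
    timepoint: str = "D14"

    def __post_init__(self) -> None:
        if self.n_slides < 1:
            raise ParameterError(f"group {self.name!r}: n_slides must be >= 1")


@dataclass
class StudyResult:
    slides: dict[str, list[np.ndarray]]
    truths: dict[str, "GroundTruth"]
    metadata: pd.DataFrame


def generate_study(
    group_specs: list[GroupSpec],
    seed: int = 0,
    width_px: int = 384,
    height_px: int = 384,
    pixel_size_um: float = 1.0,
) -> StudyResult:
    """Generate a study of slides over named groups with a metadata table."""
    if not group_specs:
        raise ParameterError("group_specs must be non-empty")
    rng = np.random.default_rng(int(seed))
    slides: dict[str, list[np.ndarray]] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    for spec in group_specs:
        for i in range(int(spec.n_slides)):
            slide_id = f"s{int(seed)}_{spec.name}_{i:02d}"
            mass = float(rng.uniform(*spec.mass_fraction))
            coll = float(rng.uniform(*spec.collagen_fraction))
            nbr = int(rng.integers(spec.n_bronchi[0], spec.n_bronchi[1] + 1))
            hue = float(rng.uniform(*spec.hue_shift_deg))
            gain = float(rng.uniform(*spec.intensity_scale))
            slide_seed = int(rng.integers(2**31 - 1))
            stain = StainProfile(hue_shift_deg=hue, intensity_scale=gain,
                                 name=f"drift_h{hue:+.1f}_g{gain:.2f}")
            params = SyntheticSlideParams(
                width_px=width_px, height_px=height_px,
                fibrotic_mass_fraction=mass, alveolar_collagen_fraction=coll,
                n_bronchi=nbr, stain_profile=stain, noise_sd=spec.noise_sd,
                pixel_size_um=pixel_size_um, seed=slide_seed,
            )
            pyramid, gt = generate_slide(params)
            slides[slide_id] = pyramid
            truths[slide_id] = gt
            rows.append(
                {
                    "slide_id": slide_id,
                    "animal_id": slide_id,
                    "group": spec.name,
                    "timepoint": spec.timepoint,
                    "true_mass_fraction": mass,
                    "true_collagen_fraction": coll,
                    "realized_mass_fraction": gt.mass_fraction(),
                    "realized_collagen_fraction": gt.collagen_fraction(),
                    "stain_profile_id": stain.name,
                    "hue_shift_deg": hue,
                    "intensity_scale": gain,
                    "n_bronchi": nbr,
                    "seed": slide_seed,
                    "width_px": width_px,
                    "height_px": height_px,
                }
            )
    return StudyResult(slides=slides, truths=truths, metadata=pd.DataFrame(rows))
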