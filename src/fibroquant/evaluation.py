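"""Standard evaluation protocols for the assay on synthetic fixtures.

These routines are the shared backbone of the test suite and the
acceptance report: a six-slide fixture set spanning the stain-drift range
(hue shift -15..+15 degrees, intensity gain 0.8..1.2), a 40,000-pixel
training set with stratified 10-fold cross-validation for each detection
model, compact quantification models, and the readout-recovery and
group-separation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fibroquant.annotations import AnnotationSet
from fibroquant.classifier import (
    CVReport,
    SVMConfig,
    TissueClassifier,
    TrainingSet,
    build_training_set,
    cross_validate,
    train,
)
from fibroquant.features import FeatureConfig
from fibroquant.quantify import quantify_slide
from fibroquant.synthetic import (
    GroundTruth,
    StainProfile,
    SyntheticSlideParams,
    generate_annotations,
    generate_slide,
)

#: default structure sizes: large window at low magnification for context,
#: small window at full resolution
LOW_MAG_STRUCTURE_SIZE = 25
HIGH_MAG_STRUCTURE_SIZE = 5

#: quantification-grade high-magnification config: at full resolution the
#: discriminating signal is the single-pixel stain colour; a minimal
#: local-contrast window avoids smearing 1-2 px septal structures
HIGH_MAG_QUANT_CONFIG = FeatureConfig(structure_size=3, stats=("intensity",))

# fixture burden levels spanning saline-like to heavily fibrotic
_FIXTURE_MASS = (0.10, 0.20, 0.30, 0.40, 0.15, 0.35)
_FIXTURE_COLLAGEN = (0.03, 0.06, 0.09, 0.12, 0.05, 0.15)


@dataclass
class FixtureSet:
    images: dict[str, np.ndarray]
    truths: dict[str, GroundTruth]


def stain_range_fixtures(
    seed: int, n_slides: int = 6, width_px: int = 640, height_px: int = 640,
    n_bronchi: int = 3,
) -> FixtureSet:
    """Fixture slides covering hue shifts +/-15 deg and gains 0.8-1.2."""
    hues = np.linspace(-15.0, 15.0, n_slides)
    gains = np.linspace(0.8, 1.2, n_slides)
    images: dict[str, np.ndarray] = {}
    truths: dict[str, GroundTruth] = {}
    for i in range(n_slides):
        params = SyntheticSlideParams(
            width_px=width_px, height_px=height_px,
            fibrotic_mass_fraction=_FIXTURE_MASS[i % len(_FIXTURE_MASS)],
            alveolar_collagen_fraction=_FIXTURE_COLLAGEN[i % len(_FIXTURE_COLLAGEN)],
            n_bronchi=n_bronchi, seed=int(seed) * 1000 + i,
            stain_profile=StainProfile(
                hue_shift_deg=float(hues[i]), intensity_scale=float(gains[i]),
                name=f"drift_{i}",
            ),
        )
        pyramid, gt = generate_slide(params)
        images[f"fixture_{i}"] = pyramid[0]
        truths[f"fixture_{i}"] = gt
    return FixtureSet(images=images, truths=truths)


def build_model_training_sets(
    fixtures: FixtureSet,
    seed: int,
    n_samples_total: int = 40_000,
    n_regions_per_class: int = 16,
    erosion_low: int | None = None,
    erosion_high: int | None = None,
) -> tuple[TrainingSet, TrainingSet]:
    """40,000 pixels over every class and picture, split between the two models.

    The low-magnification 4-class model and the high-magnification 3-class
    model each receive half the pixel budget; sampling is uniform over the
    pooled annotation pixels of all fixture images.
    """
    lo_entries, hi_entries = [], []
    for i, (image_id, gt) in enumerate(fixtures.truths.items()):
        lo_entries += generate_annotations(
            gt, n_regions_per_class=n_regions_per_class, min_area_px=32,
            seed=int(seed) + 10 + i, view="exclusion",
            erosion_radius=erosion_low, image_id=image_id,
        ).entries
        hi_entries += generate_annotations(
            gt, n_regions_per_class=n_regions_per_class, min_area_px=32,
            seed=int(seed) + 50 + i, view="collagen",
            erosion_radius=erosion_high, image_id=image_id,
        ).entries
    half = n_samples_total // 2
    ts_low = build_training_set(
        fixtures.images, AnnotationSet(lo_entries),
        FeatureConfig(LOW_MAG_STRUCTURE_SIZE), n_samples=half, seed=int(seed) + 1,
    )
    ts_high = build_training_set(
        fixtures.images, AnnotationSet(hi_entries),
        FeatureConfig(HIGH_MAG_STRUCTURE_SIZE),
        n_samples=n_samples_total - half, seed=int(seed) + 2,
    )
    return ts_low, ts_high


@dataclass
class CVBenchmark:
    report_low: CVReport
    report_high: CVReport
    n_low: int
    n_high: int

    @property
    def mean_accuracy(self) -> float:
        """Sample-weighted mean fold accuracy over both detection models."""
        return (
            self.n_low * self.report_low.mean_accuracy
            + self.n_high * self.report_high.mean_accuracy
        ) / (self.n_low + self.n_high)


def stain_range_cv(seed: int, n_samples_total: int = 40_000, k: int = 10) -> CVBenchmark:
    """The cross-validation benchmark on the stain-drift fixture study."""
    fixtures = stain_range_fixtures(seed)
    ts_low, ts_high = build_model_training_sets(fixtures, seed, n_samples_total)
    rep_low = cross_validate(ts_low, k=k, seed=int(seed) + 3)
    rep_high = cross_validate(ts_high, k=k, seed=int(seed) + 4)
    return CVBenchmark(
        report_low=rep_low, report_high=rep_high,
        n_low=ts_low.n_samples, n_high=ts_high.n_samples,
    )


def train_quantification_models(
    seed: int,
    width_px: int = 384,
    n_slides: int = 4,
    n_samples: int = 10_000,
    n_regions_per_class: int = 24,
) -> tuple[TissueClassifier, TissueClassifier]:
    """Compact model pair for whole-slide quantification experiments.

    Annotations use a small purity margin (erosion 3 at low magnification,
    none at high magnification) so the training pixels cover the boundary
    windows that dominate thin alveolar structures; the thin classes
    (collagen, septal tissue) receive extra annotation regions because
    their rectangles are necessarily tiny.
    """
    fixtures = stain_range_fixtures(seed, n_slides=n_slides,
                                    width_px=width_px, height_px=width_px,
                                    n_bronchi=4)
    lo_entries, hi_entries = [], []
    for i, (image_id, gt) in enumerate(fixtures.truths.items()):
        lo_entries += generate_annotations(
            gt, n_regions_per_class=n_regions_per_class, min_area_px=32,
            seed=int(seed) + 10 + i, view="exclusion", erosion_radius=3,
            image_id=image_id,
        ).entries
        hi_entries += generate_annotations(
            gt, n_regions_per_class=2 * n_regions_per_class, min_area_px=32,
            seed=int(seed) + 50 + i, view="collagen", erosion_radius=0,
            classes=("collagen", "lung_tissue"), image_id=image_id,
        ).entries
        hi_entries += generate_annotations(
            gt, n_regions_per_class=max(4, n_regions_per_class // 2), min_area_px=32,
            seed=int(seed) + 150 + i, view="collagen", erosion_radius=0,
            classes=("background",), image_id=image_id,
        ).entries
    ts_low = build_training_set(
        fixtures.images, AnnotationSet(lo_entries),
        FeatureConfig(LOW_MAG_STRUCTURE_SIZE), n_samples=n_samples, seed=int(seed) + 1,
    )
    ts_high = build_training_set(
        fixtures.images, AnnotationSet(hi_entries),
        HIGH_MAG_QUANT_CONFIG, n_samples=n_samples, seed=int(seed) + 2,
    )
    cfg = SVMConfig(seed=int(seed))
    return train(ts_low, cfg), train(ts_high, cfg)


@dataclass
class RecoveryResult:
    true_mass_percent: list[float]
    est_mass_percent: list[float]
    true_collagen_fraction: list[float]
    est_collagen_percent: list[float]

    @property
    def mass_mae(self) -> float:
        return float(np.mean(np.abs(
            np.asarray(self.est_mass_percent) - np.asarray(self.true_mass_percent)
        )))

    @property
    def collagen_spearman(self) -> float:
        from scipy.stats import spearmanr
        return float(spearmanr(self.true_collagen_fraction, self.est_collagen_percent).statistic)


def readout_recovery(
    clf_low: TissueClassifier,
    clf_high: TissueClassifier,
    seed: int,
    n_slides: int = 10,
    width_px: int = 384,
    mass_range: tuple[float, float] = (0.05, 0.45),
    collagen_range: tuple[float, float] = (0.02, 0.15),
) -> RecoveryResult:
    """Quantify fresh slides spanning the burden range against generator truth."""
    masses = np.linspace(*mass_range, n_slides)
    collagens = np.linspace(*collagen_range, n_slides)
    hues = np.linspace(-15.0, 15.0, n_slides)
    gains = np.linspace(0.8, 1.2, n_slides)
    res = RecoveryResult([], [], [], [])
    for j in range(n_slides):
        params = SyntheticSlideParams(
            width_px=width_px, height_px=width_px,
            fibrotic_mass_fraction=float(masses[j]),
            alveolar_collagen_fraction=float(collagens[j]),
            n_bronchi=2, seed=int(seed) * 7919 + j,
            stain_profile=StainProfile(hue_shift_deg=float(hues[j]),
                                       intensity_scale=float(gains[j])),
        )
        pyramid, gt = generate_slide(params)
        q = quantify_slide(pyramid, clf_low, clf_high, slide_id=f"recovery_{j}")
        res.true_mass_percent.append(100.0 * gt.mass_fraction())
        res.est_mass_percent.append(q.fibrotic_mass_percent)
        res.true_collagen_fraction.append(gt.collagen_fraction())
        res.est_collagen_percent.append(q.alveolar_collagen_percent)
    return res
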