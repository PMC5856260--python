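"""Synthetic slide generator: ground-truth contracts, determinism, studies."""

import numpy as np
import pytest

from fibroquant.annotations import from_geojson, rasterize_polygon, to_geojson
from fibroquant.exceptions import MissingClassError, ParameterError
from fibroquant.synthetic import (
    GT_CLASSES,
    LBL_ALVEOLAR,
    LBL_BACKGROUND,
    LBL_MASS,
    GroupSpec,
    StainProfile,
    SyntheticSlideParams,
    build_pyramid,
    generate_annotations,
    generate_slide,
    generate_study,
)


class TestParams:
    def test_defaults_valid(self):
        SyntheticSlideParams()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"width_px": 32},
            {"height_px": 10},
            {"fibrotic_mass_fraction": -0.1},
            {"fibrotic_mass_fraction": 1.5},
            {"alveolar_collagen_fraction": float("nan")},
            {"n_bronchi": -1},
            {"noise_sd": -2.0},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ParameterError):
            SyntheticSlideParams(**kwargs)

    def test_invalid_stain(self):
        with pytest.raises(ParameterError):
            StainProfile(collagen_rgb=(300, 0, 0))
        with pytest.raises(ParameterError):
            StainProfile(hue_shift_deg=400)


class TestGenerateSlide:
    def test_nothing_requested_nothing_drawn(self):
        params = SyntheticSlideParams(
            width_px=128, height_px=128, fibrotic_mass_fraction=0.0,
            alveolar_collagen_fraction=0.0, n_bronchi=0, seed=3,
        )
        _, gt = generate_slide(params)
        labels = set(np.unique(gt.label_map))
        assert labels == {LBL_BACKGROUND, LBL_ALVEOLAR}

    def test_mass_fraction_within_tolerance(self):
        params = SyntheticSlideParams(
            width_px=384, height_px=384, fibrotic_mass_fraction=0.30, seed=1,
        )
        _, gt = generate_slide(params)
        # brute-force pixel count on the emitted label map
        mass = np.count_nonzero(gt.label_map == LBL_MASS)
        tissue = np.count_nonzero(np.isin(gt.label_map, [1, 2, 4]))
        assert 0.28 <= mass / tissue <= 0.32

    def test_seeded_determinism(self):
        params = SyntheticSlideParams(
            width_px=128, height_px=128, fibrotic_mass_fraction=0.2,
            alveolar_collagen_fraction=0.05, n_bronchi=1, seed=11,
        )
        pyr_a, gt_a = generate_slide(params)
        pyr_b, gt_b = generate_slide(params)
        for a, b in zip(pyr_a, pyr_b):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(gt_a.label_map, gt_b.label_map)

    def test_label_partition(self):
        _, gt = generate_slide(SyntheticSlideParams(
            width_px=160, height_px=160, fibrotic_mass_fraction=0.2,
            alveolar_collagen_fraction=0.08, n_bronchi=2, seed=4,
        ))
        fractions = [
            np.count_nonzero(gt.label_map == i) / gt.label_map.size
            for i in range(len(GT_CLASSES))
        ]
        assert sum(fractions) == pytest.approx(1.0, abs=0)
        assert gt.label_map.max() < len(GT_CLASSES)

    def test_mass_monotone_in_expectation(self):
        # over >= 5 seeds, higher requested fraction => more mass pixels
        lows, highs = [], []
        for seed in range(5):
            _, gt_lo = generate_slide(SyntheticSlideParams(
                width_px=192, height_px=192, fibrotic_mass_fraction=0.10, seed=seed))
            _, gt_hi = generate_slide(SyntheticSlideParams(
                width_px=192, height_px=192, fibrotic_mass_fraction=0.35, seed=seed))
            lows.append(np.count_nonzero(gt_lo.label_map == LBL_MASS))
            highs.append(np.count_nonzero(gt_hi.label_map == LBL_MASS))
        assert np.mean(highs) > np.mean(lows)

    def test_stain_drift_does_not_touch_ground_truth(self):
        base = dict(width_px=160, height_px=160, fibrotic_mass_fraction=0.25,
                    alveolar_collagen_fraction=0.06, n_bronchi=1, seed=9)
        pyr_a, gt_a = generate_slide(SyntheticSlideParams(**base))
        pyr_b, gt_b = generate_slide(SyntheticSlideParams(
            **base, stain_profile=StainProfile(hue_shift_deg=14.0, intensity_scale=0.82)))
        np.testing.assert_array_equal(gt_a.label_map, gt_b.label_map)
        np.testing.assert_array_equal(gt_a.render_map, gt_b.render_map)
        assert (pyr_a[0] != pyr_b[0]).any()

    def test_collagen_subset_of_alveolar_region(self):
        _, gt = generate_slide(SyntheticSlideParams(
            width_px=192, height_px=192, alveolar_collagen_fraction=0.10, seed=2))
        # collagen pixels must lie in the region generated as alveolar tissue:
        # merging collagen back into alveolar in the exclusion view is lossless
        excl, _ = gt.view("exclusion")
        assert np.all(excl[gt.label_map == 4] == LBL_ALVEOLAR)

    def test_pyramid_levels_halve(self):
        pyr, _ = generate_slide(SyntheticSlideParams(width_px=2048, height_px=1536, seed=1))
        assert len(pyr) == 2
        assert pyr[0].shape[:2] == (1536, 2048)
        assert pyr[1].shape[:2] == (768, 1024)
        assert max(pyr[-1].shape[:2]) <= 1024

    def test_build_pyramid_small_image_single_level(self):
        img = np.zeros((256, 256, 3), dtype=np.uint8)
        assert len(build_pyramid(img)) == 1


@pytest.fixture(scope="module")
def gt():
    _, gt = generate_slide(SyntheticSlideParams(
        width_px=320, height_px=320, fibrotic_mass_fraction=0.25,
        alveolar_collagen_fraction=0.08, n_bronchi=2, seed=21))
    return gt


class TestGenerateAnnotations:
    def test_missing_class_error(self):
        _, gt = generate_slide(SyntheticSlideParams(
            width_px=128, height_px=128, fibrotic_mass_fraction=0.0,
            n_bronchi=0, seed=5))
        with pytest.raises(MissingClassError) as exc:
            generate_annotations(gt, view="exclusion", classes=("fibrotic_mass",))
        assert "fibrotic_mass" in str(exc.value)

    def test_polygon_count_and_purity(self, gt):
        ann = generate_annotations(gt, n_regions_per_class=3, min_area_px=16, seed=7,
                                   view="exclusion")
        assert len(ann) == 12  # 3 regions x 4 classes
        labels, names = gt.view("exclusion")
        for entry in ann:
            ys, xs = rasterize_polygon(entry.polygon, labels.shape)
            assert ys.size > 0
            assert np.all(labels[ys, xs] == names.index(entry.class_label))

    def test_high_mag_purity(self, gt):
        ann = generate_annotations(gt, n_regions_per_class=4, min_area_px=16, seed=8,
                                   view="collagen")
        labels, names = gt.view("collagen")
        for entry in ann:
            ys, xs = rasterize_polygon(entry.polygon, labels.shape)
            assert np.all(labels[ys, xs] == names.index(entry.class_label))

    def test_seeded_determinism(self, gt):
        a = generate_annotations(gt, seed=13)
        b = generate_annotations(gt, seed=13)
        assert [e.polygon.wkt for e in a] == [e.polygon.wkt for e in b]

    def test_geojson_roundtrip(self, gt, tmp_path):
        ann = generate_annotations(gt, n_regions_per_class=2, seed=3, image_id="img0")
        path = tmp_path / "ann.geojson"
        to_geojson(ann, path)
        back = from_geojson(path)
        assert len(back) == len(ann)
        assert [e.class_label for e in back] == [e.class_label for e in ann]
        assert all(a.polygon.equals(b.polygon) for a, b in zip(ann, back))


class TestGenerateStudy:
    def test_minimal_study(self):
        study = generate_study([GroupSpec("only", 1)], seed=1, width_px=96, height_px=96)
        assert len(study.slides) == 1
        assert len(study.metadata) == 1

    def test_empty_specs_error(self):
        with pytest.raises(ParameterError):
            generate_study([], seed=1)

    def test_bad_group_error(self):
        with pytest.raises(ParameterError):
            GroupSpec("x", 0)

    def test_group_means_separate(self):
        study = generate_study(
            [
                GroupSpec("saline_like", 10, mass_fraction=(0.01, 0.03)),
                GroupSpec("bleomycin_like", 10, mass_fraction=(0.38, 0.42)),
            ],
            seed=2, width_px=96, height_px=96,
        )
        md = study.metadata
        assert len(md) == 20
        means = md.groupby("group")["true_mass_fraction"].mean()
        assert means["bleomycin_like"] - means["saline_like"] > 0.3

    def test_two_seeds_disjoint(self):
        a = generate_study([GroupSpec("g", 2)], seed=1, width_px=96, height_px=96)
        b = generate_study([GroupSpec("g", 2)], seed=2, width_px=96, height_px=96)
        assert set(a.slides).isdisjoint(set(b.slides))
        img_a = next(iter(a.slides.values()))[0]
        img_b = next(iter(b.slides.values()))[0]
        assert (img_a != img_b).any()

    def test_metadata_columns(self):
        study = generate_study([GroupSpec("g", 2, timepoint="D28")], seed=3,
                               width_px=96, height_px=96)
        for col in ("slide_id", "group", "timepoint", "true_mass_fraction",
                    "stain_profile_id", "seed"):
            assert col in study.metadata.columns
        assert (study.metadata["timepoint"] == "D28").all()
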