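"""Training-set assembly, SVM training, cross-validation, classification."""

import numpy as np
import pytest
from shapely.geometry import box

from fibroquant.annotations import AnnotationEntry, AnnotationSet, rasterize_polygon
from fibroquant.classifier import (
    SVMConfig,
    TrainingSet,
    build_training_set,
    classify,
    cross_validate,
    load_classifier,
    save_classifier,
    train,
)
from fibroquant.exceptions import (
    ConfigurationError,
    ConflictError,
    DegenerateTrainingError,
    StratificationError,
)
from fibroquant.features import FeatureConfig
from fibroquant.maps import UNCLASSIFIED


def two_band_image(h=300, w=300):
    """Top half dark, bottom half bright: two trivially separable classes."""
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[: h // 2] = 40
    img[h // 2:] = 210
    return img


def gaussian_training_set(n=400, n_features=4, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, size=(n // 2, n_features))
    x1 = rng.normal(sep, 1, size=(n - n // 2, n_features))
    feats = np.vstack([x0, x1])
    labels = np.r_[np.zeros(n // 2, np.int16), np.ones(n - n // 2, np.int16)]
    prov = np.rec.fromarrays(
        [np.array(["synthetic"] * n), np.zeros(n, np.int64), np.zeros(n, np.int64)],
        names=("image_id", "x", "y"),
    )
    return TrainingSet(features=feats, labels=labels, classes=("a", "b"),
                       provenance=prov, cfg=FeatureConfig(), sampling_seed=seed)


class TestBuildTrainingSet:
    def make_inputs(self, h=300, w=300):
        img = two_band_image(h, w)
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(10, 10, w - 10, h // 2 - 10), "dark"),
            AnnotationEntry("img", 0, box(10, h // 2 + 10, w - 10, h - 10), "bright"),
        ])
        return {"img": img}, ann

    def test_exact_40000_rows_with_ample_pool(self):
        images, ann = self.make_inputs()
        # pool = 2 * 280 * 130 = 72,800 > 40,000
        ts = build_training_set(images, ann, FeatureConfig(structure_size=3),
                                n_samples=40_000, seed=0)
        assert ts.n_samples == 40_000

    def test_small_pool_uses_all_and_warns(self, caplog):
        img = two_band_image(60, 60)
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(5, 5, 55, 25), "dark"),
            AnnotationEntry("img", 0, box(5, 35, 55, 55), "bright"),
        ])
        with caplog.at_level("WARNING", logger="fibroquant.classifier"):
            ts = build_training_set({"img": img}, ann, FeatureConfig(3),
                                    n_samples=40_000, seed=0)
        assert ts.n_samples == 50 * 20 * 2
        assert any("using all" in r.message for r in caplog.records)

    def test_provenance_pixels_carry_their_label(self):
        images, ann = self.make_inputs()
        ts = build_training_set(images, ann, FeatureConfig(3), n_samples=500, seed=1)
        # re-rasterize: every provenance pixel must be inside a polygon of its class
        by_class = {}
        for entry in ann:
            ys, xs = rasterize_polygon(entry.polygon, (300, 300))
            by_class.setdefault(entry.class_label, set()).update(zip(ys.tolist(), xs.tolist()))
        for row, label in zip(ts.provenance, ts.labels):
            cls = ts.classes[label]
            assert (int(row.y), int(row.x)) in by_class[cls]

    def test_conflicting_overlap_raises(self):
        img = two_band_image()
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(10, 10, 100, 100), "dark"),
            AnnotationEntry("img", 0, box(50, 50, 150, 140), "bright"),
        ])
        with pytest.raises(ConflictError, match="bright/dark"):
            build_training_set({"img": img}, ann, FeatureConfig(3), n_samples=100)

    def test_single_class_rejected(self):
        img = two_band_image()
        ann = AnnotationSet([AnnotationEntry("img", 0, box(10, 10, 50, 50), "dark")])
        with pytest.raises(DegenerateTrainingError):
            build_training_set({"img": img}, ann, FeatureConfig(3), n_samples=100)

    def test_sampling_reproducible(self):
        images, ann = self.make_inputs()
        a = build_training_set(images, ann, FeatureConfig(3), n_samples=1000, seed=9)
        b = build_training_set(images, ann, FeatureConfig(3), n_samples=1000, seed=9)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestTrain:
    def test_separable_blobs_perfect_resubstitution(self):
        ts = gaussian_training_set()
        clf = train(ts)
        assert clf.resubstitution_accuracy == 1.0

    def test_predicts_every_class(self):
        ts = gaussian_training_set()
        clf = train(ts)
        preds = clf.predict(ts.features)
        assert set(np.unique(preds)) == {0, 1}

    def test_single_class_error(self):
        ts = gaussian_training_set()
        ts.labels[:] = 0
        with pytest.raises(DegenerateTrainingError):
            train(ts)

    def test_deterministic_given_seed(self, rng):
        ts = gaussian_training_set()
        probe = rng.normal(4, 3, size=(200, 4))
        p1 = train(ts, SVMConfig(seed=1)).predict(probe)
        p2 = train(ts, SVMConfig(seed=1)).predict(probe)
        np.testing.assert_array_equal(p1, p2)

    def test_standardization_constants_stored(self):
        ts = gaussian_training_set()
        clf = train(ts)
        np.testing.assert_allclose(clf.scaler_mean, ts.features.mean(axis=0))
        np.testing.assert_allclose(clf.scaler_std, ts.features.std(axis=0))
        # round-trip: standardize then destandardize leaves features unchanged
        x = clf.standardize(ts.features) * clf.scaler_std + clf.scaler_mean
        np.testing.assert_allclose(x, ts.features, rtol=1e-12)

    def test_persistence_roundtrip(self, tmp_path, rng):
        ts = gaussian_training_set()
        clf = train(ts)
        path = tmp_path / "model.fqm"
        save_classifier(clf, path)
        back = load_classifier(path)
        probe = rng.normal(4, 3, size=(100, 4))
        np.testing.assert_array_equal(clf.predict(probe), back.predict(probe))
        assert back.classes == clf.classes
        assert back.model_hash() == clf.model_hash()


class TestCrossValidate:
    def test_separable_mean_accuracy_one(self):
        rep = cross_validate(gaussian_training_set(), k=10, seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.fold_accuracies))

    def test_shuffled_labels_near_chance(self):
        # permutation null: balanced 2-class, expect ~0.5 over 20 repeats
        accs = []
        for rep_i in range(20):
            ts = gaussian_training_set(n=300, sep=8.0, seed=rep_i)
            rng = np.random.default_rng(1000 + rep_i)
            ts.labels = rng.permutation(ts.labels)
            accs.append(cross_validate(ts, k=5, seed=rep_i).mean_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_stratification_error(self):
        ts = gaussian_training_set(n=30)
        ts.labels[:] = 0
        ts.labels[:5] = 1  # class with 5 < k samples
        with pytest.raises(StratificationError):
            cross_validate(ts, k=10)

    def test_partition_validity(self):
        ts = gaussian_training_set(n=403)
        rep = cross_validate(ts, k=10, seed=3)
        folds = rep.fold_test_indices
        all_idx = np.concatenate(folds)
        assert len(all_idx) == ts.n_samples          # each sample tested once
        assert len(np.unique(all_idx)) == ts.n_samples  # disjoint folds
        for cid in (0, 1):
            per_fold = [np.count_nonzero(ts.labels[f] == cid) for f in folds]
            assert max(per_fold) - min(per_fold) <= 1  # stratified within 1

    def test_confusion_conservation(self):
        ts = gaussian_training_set(n=250)
        rep = cross_validate(ts, k=5, seed=1)
        assert rep.confusion.sum() == ts.n_samples
        for cid, cnt in ts.class_counts().items():
            assert rep.confusion[ts.classes.index(cid)].sum() == cnt


class TestClassify:
    def test_two_band_image_roundtrip(self):
        img = two_band_image(100, 100)
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(10, 10, 90, 40), "dark"),
            AnnotationEntry("img", 0, box(10, 60, 90, 90), "bright"),
        ])
        ts = build_training_set({"img": img}, ann, FeatureConfig(3), n_samples=2000, seed=0)
        clf = train(ts)
        tmap = classify(img, clf)
        # agreement on the annotated regions >= resubstitution accuracy
        top = tmap.labels[10:40, 10:90]
        bot = tmap.labels[60:90, 10:90]
        agree = np.mean(np.r_[(top == clf.classes.index("dark")).ravel(),
                              (bot == clf.classes.index("bright")).ravel()])
        assert agree >= clf.resubstitution_accuracy

    def test_empty_mask_all_unclassified(self):
        ts = gaussian_training_set()
        # features cfg expects RGB; use a real image-trained classifier instead
        img = two_band_image(64, 64)
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(5, 5, 60, 25), "dark"),
            AnnotationEntry("img", 0, box(5, 40, 60, 60), "bright"),
        ])
        clf = train(build_training_set({"img": img}, ann, FeatureConfig(3), n_samples=500))
        tmap = classify(img, clf, mask=np.zeros((64, 64), bool))
        assert np.all(tmap.labels == UNCLASSIFIED)

    def test_channel_mismatch(self):
        img = two_band_image(64, 64)
        ann = AnnotationSet([
            AnnotationEntry("img", 0, box(5, 5, 60, 25), "dark"),
            AnnotationEntry("img", 0, box(5, 40, 60, 60), "bright"),
        ])
        clf = train(build_training_set({"img": img}, ann, FeatureConfig(3), n_samples=500))
        with pytest.raises(ConfigurationError):
            classify(img[:, :, :1], clf)

    def test_agreement_with_ground_truth(self, quant_models, probe_slide):
        from scipy import ndimage as ndi

        clf_low, _ = quant_models
        pyramid, gt = probe_slide
        tmap = classify(pyramid[0], clf_low)
        truth, names = gt.view("exclusion")
        # overall agreement away from class borders (2-px erosion)
        sel_any = np.zeros(truth.shape, bool)
        agree = np.zeros(truth.shape, bool)
        for t, name in enumerate(names):
            sel = ndi.binary_erosion(truth == t, np.ones((5, 5)))
            sel_any |= sel
            agree[sel] = tmap.labels[sel] == tmap.index_of(name)
        assert agree[sel_any].mean() >= 0.9
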