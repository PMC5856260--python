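"""SVM pixel classifier: training-set assembly, training, CV, classification.

The training set is drawn uniformly at random over the pooled annotation
pixels of all images and classes (40,000 pixels by default, without
replacement whenever the pool is large enough).  The classifier is an RBF
support-vector machine on standardized windowed features; model quality is
estimated by stratified 10-fold cross-validation.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import pickle
import zipfile
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from fibroquant.annotations import AnnotationSet, rasterize_polygon
from fibroquant.exceptions import (
    ConfigurationError,
    ConflictError,
    DegenerateTrainingError,
    MissingClassError,
    ParameterError,
    StratificationError,
)
from fibroquant.features import FeatureConfig, feature_maps
from fibroquant.maps import UNCLASSIFIED, TissueClassMap

logger = logging.getLogger(__name__)

DEFAULT_N_SAMPLES = 40_000


@dataclass(frozen=True)
class SVMConfig:
    """SVM hyperparameters. Kernel scale "auto" means 1/n_features."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "auto"
    class_weight: str | None = "balanced"
    cache_mb: float = 500.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "class_weight": self.class_weight,
            "cache_mb": self.cache_mb,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVMConfig":
        return cls(**d)


@dataclass
class TrainingSet:
    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) int class ids
    classes: tuple[str, ...]
    provenance: np.ndarray  # structured (image_id, x, y) per row
    cfg: FeatureConfig
    sampling_seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(self.features.shape[0])

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.count_nonzero(self.labels == i)) for i, c in enumerate(self.classes)}


@dataclass
class CVReport:
    fold_accuracies: list[float]
    confusion: np.ndarray  # (k_classes, k_classes), rows = true class
    classes: tuple[str, ...]
    fold_test_indices: list[np.ndarray] | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }


@dataclass
class TissueClassifier:
    """Fitted SVM plus feature configuration and standardization constants."""

    svm: SVC
    classes: tuple[str, ...]
    cfg: FeatureConfig
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    svm_config: SVMConfig
    resubstitution_accuracy: float | None = None
    training_hash: str | None = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise DegenerateTrainingError("class list must have >= 2 entries")
        if not (np.all(np.isfinite(self.scaler_mean)) and np.all(np.isfinite(self.scaler_std))):
            raise ParameterError("standardization constants must be finite")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_std

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.standardize(features)).astype(np.int16)

    def model_hash(self) -> str:
        header = json.dumps(
            {
                "classes": list(self.classes),
                "cfg": self.cfg.to_dict(),
                "svm_config": self.svm_config.to_dict(),
                "scaler_mean": self.scaler_mean.tolist(),
                "scaler_std": self.scaler_std.tolist(),
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(header + pickle.dumps(self.svm)).hexdigest()[:16]


# ---------------------------------------------------------------------------
# training-set assembly

def build_training_set(
    images: Mapping[str, np.ndarray],
    annotations: AnnotationSet,
    cfg: FeatureConfig,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
) -> TrainingSet:
    """Sample pixels uniformly over the union of all annotation regions.

    Sampling is without replacement whenever the pooled annotation pixels
    number at least ``n_samples``; otherwise all pixels are used and a
    warning is logged.
    """
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    classes = tuple(sorted(annotations.class_labels))
    if len(classes) < 2:
        raise DegenerateTrainingError("need annotations for at least 2 classes")
    class_index = {c: i for i, c in enumerate(classes)}

    pool_img: list[np.ndarray] = []
    pool_y: list[np.ndarray] = []
    pool_x: list[np.ndarray] = []
    pool_lbl: list[np.ndarray] = []
    pixels_per_class = {c: 0 for c in classes}

    image_ids = list(images.keys())
    for img_pos, image_id in enumerate(image_ids):
        subset = annotations.for_image(image_id)
        if len(subset) == 0:
            continue
        img = np.asarray(images[image_id])
        lab = np.full(img.shape[:2], -1, dtype=np.int16)
        conflicts: set[tuple[str, str]] = set()
        for entry in subset:
            ys, xs = rasterize_polygon(entry.polygon, img.shape[:2])
            if ys.size == 0:
                raise MissingClassError([entry.class_label])
            cid = class_index[entry.class_label]
            prev = lab[ys, xs]
            bad = (prev >= 0) & (prev != cid)
            if np.any(bad):
                for p in np.unique(prev[bad]):
                    conflicts.add(tuple(sorted((classes[p], entry.class_label))))
            lab[ys, xs] = cid
        if conflicts:
            raise ConflictError(
                f"overlapping annotations of different classes on {image_id!r}: "
                + ", ".join(f"{a}/{b}" for a, b in sorted(conflicts))
            )
        ys, xs = np.nonzero(lab >= 0)
        pool_img.append(np.full(ys.size, img_pos, dtype=np.int32))
        pool_y.append(ys)
        pool_x.append(xs)
        pool_lbl.append(lab[ys, xs])
        for cid, cnt in zip(*np.unique(lab[ys, xs], return_counts=True)):
            pixels_per_class[classes[cid]] += int(cnt)

    empty = [c for c, n in pixels_per_class.items() if n == 0]
    if empty:
        raise MissingClassError(empty)

    img_idx = np.concatenate(pool_img)
    ys = np.concatenate(pool_y)
    xs = np.concatenate(pool_x)
    lbl = np.concatenate(pool_lbl).astype(np.int16)

    rng = np.random.default_rng(int(seed))
    total = img_idx.size
    if total >= n_samples:
        take = rng.choice(total, size=n_samples, replace=False)
        take.sort()
    else:
        logger.warning(
            "annotation pool has %d pixels < requested %d; using all", total, n_samples
        )
        take = np.arange(total)
    img_idx, ys, xs, lbl = img_idx[take], ys[take], xs[take], lbl[take]

    feats = np.empty((take.size, cfg.n_features), dtype=np.float64)
    for img_pos, image_id in enumerate(image_ids):
        sel = img_idx == img_pos
        if not np.any(sel):
            continue
        maps = feature_maps(np.asarray(images[image_id]), cfg)
        feats[sel] = maps[ys[sel], xs[sel]]

    provenance = np.rec.fromarrays(
        [np.array([image_ids[i] for i in img_idx]), xs.astype(np.int64), ys.astype(np.int64)],
        names=("image_id", "x", "y"),
    )
    return TrainingSet(
        features=feats, labels=lbl, classes=classes,
        provenance=provenance, cfg=cfg, sampling_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# training / evaluation

def _fit_svm(x: np.ndarray, y: np.ndarray, svm_config: SVMConfig) -> SVC:
    gamma = svm_config.gamma
    if gamma == "auto":
        gamma = 1.0 / x.shape[1]
    svm = SVC(
        kernel=svm_config.kernel,
        C=svm_config.C,
        gamma=gamma,
        class_weight=svm_config.class_weight,
        cache_size=svm_config.cache_mb,
        random_state=svm_config.seed,
    )
    svm.fit(x, y)
    return svm


def _standardization(features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = features.mean(axis=0)
    std = features.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def train(
    ts: TrainingSet,
    svm_config: SVMConfig | None = None,
    resub_cap: int = 8000,
) -> TissueClassifier:
    """Train the SVM on standardized features.

    Resubstitution accuracy is estimated on a stratified subsample of at
    most ``resub_cap`` training rows (prediction on the full 40k set would
    double the training cost for a diagnostic number).
    """
    if len(ts.classes) < 2 or np.unique(ts.labels).size < 2:
        raise DegenerateTrainingError("training set must contain >= 2 classes")
    svm_config = svm_config or SVMConfig()
    mean, std = _standardization(ts.features)
    x = (ts.features - mean) / std
    svm = _fit_svm(x, ts.labels, svm_config)

    rng = np.random.default_rng(svm_config.seed)
    resub = None
    if resub_cap and ts.n_samples > 0:
        idx = []
        per_class = max(2, resub_cap // len(ts.classes))
        for cid in range(len(ts.classes)):
            rows = np.nonzero(ts.labels == cid)[0]
            if rows.size > per_class:
                rows = rng.choice(rows, size=per_class, replace=False)
            idx.append(rows)
        idx = np.concatenate(idx)
        pred = svm.predict(x[idx])
        resub = float(np.mean(pred == ts.labels[idx]))

    h = hashlib.sha256()
    h.update(ts.features.tobytes())
    h.update(ts.labels.tobytes())
    return TissueClassifier(
        svm=svm, classes=ts.classes, cfg=ts.cfg,
        scaler_mean=mean, scaler_std=std, svm_config=svm_config,
        resubstitution_accuracy=resub, training_hash=h.hexdigest()[:16],
    )


def cross_validate(
    ts: TrainingSet,
    k: int = 10,
    seed: int = 0,
    svm_config: SVMConfig | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation; every sample is tested once."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    counts = ts.class_counts()
    short = [c for c, n in counts.items() if n < k]
    if short:
        raise StratificationError(
            f"classes with fewer samples than k={k} folds: {short} (counts {counts})"
        )
    svm_config = svm_config or SVMConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    n_classes = len(ts.classes)
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    accs: list[float] = []
    fold_test_indices: list[np.ndarray] = []
    for train_idx, test_idx in skf.split(ts.features, ts.labels):
        fold_test_indices.append(test_idx)
        mean, std = _standardization(ts.features[train_idx])
        x_tr = (ts.features[train_idx] - mean) / std
        x_te = (ts.features[test_idx] - mean) / std
        svm = _fit_svm(x_tr, ts.labels[train_idx], svm_config)
        pred = svm.predict(x_te)
        truth = ts.labels[test_idx]
        accs.append(float(np.mean(pred == truth)))
        conf += confusion_matrix(truth, pred, labels=np.arange(n_classes))
    return CVReport(
        fold_accuracies=accs, confusion=conf, classes=ts.classes,
        fold_test_indices=fold_test_indices,
    )


# ---------------------------------------------------------------------------
# pixel classification

def classify(
    image: np.ndarray,
    clf: TissueClassifier,
    mask: np.ndarray | None = None,
    scale: int = 1,
    pixel_size_um: float | None = None,
    chunk: int = 250_000,
) -> TissueClassMap:
    """Classify every (masked) pixel; pixels outside the mask are unclassified."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < len(clf.cfg.channels):
        raise ConfigurationError(
            f"image shape {image.shape} incompatible with channels {clf.cfg.channels}"
        )
    h, w = image.shape[:2]
    labels = np.full((h, w), UNCLASSIFIED, dtype=np.int16)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ConfigurationError("mask shape mismatch")
        if not mask.any():
            return TissueClassMap(labels, clf.classes, scale=scale, pixel_size_um=pixel_size_um)
    maps = feature_maps(image, clf.cfg)
    if mask is None:
        feats = maps.reshape(-1, clf.cfg.n_features)
    else:
        feats = maps[mask]
    preds = np.empty(feats.shape[0], dtype=np.int16)
    for start in range(0, feats.shape[0], chunk):
        preds[start:start + chunk] = clf.predict(feats[start:start + chunk])
    if mask is None:
        labels = preds.reshape(h, w)
    else:
        labels[mask] = preds
    return TissueClassMap(labels, clf.classes, scale=scale, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# persistence: single archive = JSON header + pickled coefficient block

def save_classifier(clf: TissueClassifier, path) -> None:
    header = {
        "format": "fibroquant-model-v1",
        "classes": list(clf.classes),
        "feature_config": clf.cfg.to_dict(),
        "scaler_mean": clf.scaler_mean.tolist(),
        "scaler_std": clf.scaler_std.tolist(),
        "svm_config": clf.svm_config.to_dict(),
        "resubstitution_accuracy": clf.resubstitution_accuracy,
        "training_hash": clf.training_hash,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        buf = io.BytesIO()
        pickle.dump(clf.svm, buf)
        zf.writestr("svm.pkl", buf.getvalue())


def load_classifier(path) -> TissueClassifier:
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json"))
        if header.get("format") != "fibroquant-model-v1":
            raise ConfigurationError(f"unrecognized model file {path}")
        svm = pickle.loads(zf.read("svm.pkl"))
    return TissueClassifier(
        svm=svm,
        classes=tuple(header["classes"]),
        cfg=FeatureConfig.from_dict(header["feature_config"]),
        scaler_mean=np.asarray(header["scaler_mean"], dtype=np.float64),
        scaler_std=np.asarray(header["scaler_std"], dtype=np.float64),
        svm_config=SVMConfig.from_dict(header["svm_config"]),
        resubstitution_accuracy=header.get("resubstitution_accuracy"),
        training_hash=header.get("training_hash"),
    )
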