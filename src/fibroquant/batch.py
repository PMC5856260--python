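"""Batch quantification of a slide directory into a study table."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from fibroquant.classifier import load_classifier
from fibroquant.exceptions import ConfigurationError, FibroquantError
from fibroquant.io import read_pyramid_tiff
from fibroquant.quantify import quantify_slide

logger = logging.getLogger(__name__)

STUDY_COLUMNS = (
    "slide_id",
    "animal_id",
    "group",
    "timepoint",
    "fibrotic_mass_percent",
    "alveolar_collagen_percent",
    "total_collagen_percent",
    "roi_area_px",
    "qc_excluded",
    "qc_reasons",
    "status",
)


def load_batch_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for key in ("slides_dir", "low_model", "high_model", "output_dir"):
        if key not in cfg:
            raise ConfigurationError(f"config missing required key {key!r}")
    return cfg


def run_batch(config_path) -> tuple[pd.DataFrame, int]:
    """Quantify every slide named by the config; returns (table, n_failures).

    Unreadable slides become failure rows and the batch continues; a
    missing model aborts with :class:`ConfigurationError`.
    """
    cfg = load_batch_config(config_path)
    base = Path(config_path).parent
    slides_dir = (base / cfg["slides_dir"]).resolve()
    out_dir = (base / cfg["output_dir"]).resolve()
    out_dir.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out_dir / "batch.log")
    fh.setLevel(logging.INFO)
    logging.getLogger("fibroquant").addHandler(fh)

    try:
        for key in ("low_model", "high_model"):
            if not (base / cfg[key]).exists():
                raise ConfigurationError(f"model file not found: {cfg[key]}")
        clf_low = load_classifier(base / cfg["low_model"])
        clf_high = load_classifier(base / cfg["high_model"])

        meta = None
        if cfg.get("metadata"):
            meta = pd.read_csv(base / cfg["metadata"]).set_index("slide_id")

        qc_cfg = cfg.get("qc") or {}
        override = set(qc_cfg.get("override_exclude") or [])

        slide_files = sorted(slides_dir.glob("*.tif")) + sorted(slides_dir.glob("*.tiff"))
        if not slide_files:
            raise ConfigurationError(f"no .tif slides found in {slides_dir}")

        rows = []
        n_failures = 0
        for path in slide_files:
            slide_id = path.stem
            t0 = time.perf_counter()
            try:
                pyramid = read_pyramid_tiff(path)
                q = quantify_slide(
                    pyramid, clf_low, clf_high, slide_id=slide_id,
                    tile_size=int(cfg.get("tile_size", 512)),
                    target_low_mag_pixels=int(cfg.get("target_low_mag_pixels", 1_000_000)),
                    min_tissue_fraction=float(qc_cfg.get("min_tissue_fraction", 0.05)),
                    min_alveolar_fraction=float(qc_cfg.get("min_alveolar_fraction", 0.05)),
                    qc_override_exclude=slide_id in override,
                )
                row = q.to_row()
                row["status"] = "ok"
                logger.info(
                    "slide %s quantified in %.2fs (models %s)",
                    slide_id, time.perf_counter() - t0, q.model_hashes,
                )
            except (FibroquantError, OSError, ValueError) as exc:
                n_failures += 1
                logger.error("slide %s failed: %s", slide_id, exc)
                row = {
                    "slide_id": slide_id,
                    "fibrotic_mass_percent": None,
                    "alveolar_collagen_percent": None,
                    "total_collagen_percent": None,
                    "roi_area_px": 0,
                    "qc_excluded": True,
                    "qc_reasons": f"failed: {exc}",
                    "status": "failed",
                }
            row.setdefault("animal_id", slide_id)
            row.setdefault("group", "")
            row.setdefault("timepoint", "")
            if meta is not None and slide_id in meta.index:
                for col in ("animal_id", "group", "timepoint"):
                    if col in meta.columns:
                        row[col] = meta.loc[slide_id, col]
            rows.append(row)

        table = pd.DataFrame(rows, columns=list(STUDY_COLUMNS))
        table.to_csv(out_dir / "study_table.csv", index=False)
        return table, n_failures
    finally:
        logging.getLogger("fibroquant").removeHandler(fh)
        fh.close()
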