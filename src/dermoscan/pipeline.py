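"""End-to-end orchestration: preprocess -> segment -> features -> train -> evaluate.

A run is fully described by a manifest CSV (columns: path, mask_path?, label?)
plus a :class:`RunConfig`; identical (manifest, config) pairs reproduce
identical metrics.  Outputs (features CSV, predicted-mask PNGs, model file,
metrics JSON, run report JSON, log) all land in the configured output
directory and are listed in the run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import __version__
from .classify import (
    AnnConfig,
    LabeledDataset,
    SvmConfig,
    predict,
    split_dataset,
    train_ann,
    train_svm,
)
from .evaluate import compute_metrics, confusion_matrix
from .features import FEATURE_NAMES, extract_feature_vector
from .io import load_image, load_mask, save_mask
from .preprocess import PreprocessConfig, preprocess_pipeline
from .segment import (
    RegionGrowParams,
    SnakeParams,
    adaptive_snake,
    region_growing,
    segmentation_accuracy,
)

__all__ = ["RunConfig", "run_pipeline", "segment_image"]

logger = logging.getLogger("dermoscan.pipeline")

SCHEMA_VERSION = 1
POSITIVE_CLASS = "malignant"


@dataclass
class RunConfig:
    """One JSON-serialisable document driving a full pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation_method: str = "as"  # "as" (adaptive snake) | "rg" (region growing)
    snake: SnakeParams = field(default_factory=SnakeParams)
    region_grow: RegionGrowParams = field(default_factory=RegionGrowParams)
    glcm_levels: int = 8
    classifier: str = "ann"  # "ann" | "svm"
    ann: AnnConfig = field(default_factory=AnnConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    train_fraction: float = 0.8
    seed: int = 0
    working_size: tuple[int, int] | None = None  # (H, W) resize before segmentation
    output_dir: str = "results"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.segmentation_method not in ("as", "rg"):
            raise ValueError("segmentation_method must be 'as' or 'rg'")
        if self.classifier not in ("ann", "svm"):
            raise ValueError("classifier must be 'ann' or 'svm'")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.working_size is not None:
            d["working_size"] = list(self.working_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "snake" in d and isinstance(d["snake"], dict):
            d["snake"] = SnakeParams(**d["snake"])
        if "region_grow" in d and isinstance(d["region_grow"], dict):
            rg = dict(d["region_grow"])
            if rg.get("seed") is not None:
                rg["seed"] = tuple(rg["seed"])
            d["region_grow"] = RegionGrowParams(**rg)
        if "ann" in d and isinstance(d["ann"], dict):
            ann = dict(d["ann"])
            if "hidden_layers" in ann:
                ann["hidden_layers"] = tuple(ann["hidden_layers"])
            d["ann"] = AnnConfig(**ann)
        if "svm" in d and isinstance(d["svm"], dict):
            d["svm"] = SvmConfig(**d["svm"])
        if d.get("working_size") is not None:
            d["working_size"] = tuple(d["working_size"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def segment_image(gray: np.ndarray, config: RunConfig) -> np.ndarray:
    """Segment a preprocessed grayscale image per the configured method,
    optionally at a fixed working size (bilinear for images, nearest for the
    mask on the way back)."""
    original_shape = gray.shape
    work = gray
    if config.working_size is not None and tuple(config.working_size) != original_shape:
        work = (
            _sk_resize(gray, config.working_size, order=1, preserve_range=True)
            .round()
            .astype(np.uint8)
        )
    if config.segmentation_method == "as":
        mask = adaptive_snake(work, config.snake).mask
    else:
        mask = region_growing(work, config.region_grow)
    if mask.shape != original_shape:
        mask = _sk_resize(mask.astype(float), original_shape, order=0, preserve_range=True) > 0.5
    return mask


def run_pipeline(manifest: str | Path, config: RunConfig) -> dict:
    """Execute the full pipeline over a manifest; returns the run report dict.

    Per-image failures are logged and skipped (counted in the report);
    configuration errors abort.
    """
    t0 = time.time()
    manifest = Path(manifest)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("dermoscan")
    root.addHandler(handler)
    outputs: list[str] = [str(log_path)]
    timings: dict[str, float] = {}
    failures: list[dict] = []
    try:
        table = pd.read_csv(manifest)
        if "path" not in table.columns:
            raise ValueError("manifest must have a 'path' column")
        base = manifest.parent

        rows: list[pd.Series] = []
        labels: list[str] = []
        ids: list[str] = []
        seg_scores: list[float] = []
        masks_dir = outdir / "masks"
        stage_t = time.time()
        for _, row in table.iterrows():
            img_id = str(row["path"])
            try:
                image = load_image(base / img_id)
                gray = preprocess_pipeline(image, config.preprocess)
                mask = segment_image(gray, config)
                mask_out = masks_dir / (Path(img_id).stem + "_pred.png")
                save_mask(mask, mask_out)
                outputs.append(str(mask_out))
                if "mask_path" in table.columns and pd.notna(row.get("mask_path")):
                    truth = load_mask(base / str(row["mask_path"]))
                    seg_scores.append(segmentation_accuracy(mask, truth).accuracy)
                vec = extract_feature_vector(
                    image, gray, mask, levels=config.glcm_levels, image_id=img_id
                )
                rows.append(vec)
                ids.append(img_id)
                if "label" in table.columns and pd.notna(row.get("label")):
                    labels.append(str(row["label"]))
            except Exception as exc:  # noqa: BLE001 - per-image resilience
                logger.warning("image %s failed: %s", img_id, exc)
                failures.append({"path": img_id, "error": str(exc)})
        timings["preprocess_segment_features"] = time.time() - stage_t

        features_df = pd.DataFrame(rows, columns=FEATURE_NAMES)
        features_path = outdir / "features.csv"
        out_df = features_df.copy()
        out_df.insert(0, "path", ids)
        if labels and len(labels) == len(ids):
            out_df["label"] = labels
        out_df.to_csv(features_path, index=False)
        outputs.append(str(features_path))

        report: dict = {
            "dermoscan_version": __version__,
            "schema_version": config.schema_version,
            "config": config.to_dict(),
            "manifest": str(manifest),
            "n_images": int(len(table)),
            "n_failures": len(failures),
            "failures": failures,
            "seeds": {"split": config.seed, "ann": config.ann.seed, "svm": config.svm.seed},
        }
        if seg_scores:
            report["segmentation"] = {
                "n_scored": len(seg_scores),
                "mean_pixel_accuracy": float(np.mean(seg_scores)),
            }

        if labels and len(labels) == len(ids) and len(set(labels)) >= 2:
            stage_t = time.time()
            data = LabeledDataset(X=features_df, y=np.array(labels), ids=ids)
            train, test = split_dataset(data, config.train_fraction, seed=config.seed)
            if config.classifier == "ann":
                model = train_ann(train, config.ann)
            else:
                model = train_svm(train, config.svm)
            preds = predict(model, test.X)
            cm = confusion_matrix(test.y, preds, positive_class=POSITIVE_CLASS)
            metrics = compute_metrics(cm)
            timings["train_evaluate"] = time.time() - stage_t

            model_path = outdir / "model.joblib"
            joblib.dump({"version": __version__, "model": model}, model_path)
            outputs.append(str(model_path))

            metrics_path = outdir / "metrics.json"
            payload = {
                "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
                "metrics": metrics.as_dict(),
                "positive_class": POSITIVE_CLASS,
                "n_train": len(train),
                "n_test": len(test),
            }
            metrics_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            outputs.append(str(metrics_path))
            report["classification"] = payload

        timings["total"] = time.time() - t0
        report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
        report["outputs"] = outputs + [str(outdir / "run_report.json")]
        report_path = outdir / "run_report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
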