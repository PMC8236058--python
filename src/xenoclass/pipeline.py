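"""End-to-end orchestration: delineate -> measure -> classify -> evaluate.

Every run writes its artifacts (cell labels, feature table, predictions,
overlay, metrics) into one output directory together with a ``run_meta.json``
stamp carrying the config hash and seed; re-running the same config reproduces
the feature table bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as xio
from .catalog import K_VALUES, catalog_names
from .classify import CellClassifier
from .contextual import assemble_feature_matrix, extract_contextual_features
from .delineate import DelineationParams, delineate_cells, summarize_cells
from .intrinsic import compute_intrinsic_features
from .metrics import evaluate_classification

__all__ = ["RunConfig", "measure_features", "run_pipeline", "DataError"]

log = logging.getLogger("xenoclass")


class DataError(ValueError):
    """Inconsistent or missing input data (maps to exit code 3 in the CLI)."""


@dataclass
class RunConfig:
    image_path: str
    nuclei_path: str
    out_dir: str
    model_path: str | None = None
    truth_path: str | None = None  # CSV with cell_id and class columns
    calibration: float = 0.5
    delta_um: float = 2.0
    k_values: tuple[int, ...] = K_VALUES
    seed: int = 0
    measure_only: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.k_values = tuple(sorted(int(k) for k in self.k_values))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def measure_features(
    image: xio.CalibratedImage,
    nuclei: np.ndarray,
    delta_um: float = 2.0,
    k_values: tuple[int, ...] = K_VALUES,
    cells: np.ndarray | None = None,
):
    """Delineate (unless cell labels are given) and compute the full 484-value
    descriptor per cell. Returns (cells, records, features DataFrame)."""
    if nuclei.shape != image.shape:
        raise DataError("image and nuclei label rasters differ in shape")
    if cells is None:
        cells = delineate_cells(
            nuclei, DelineationParams(delta_um=delta_um, calibration=image.calibration)
        )
    records = summarize_cells(nuclei, cells, image.calibration)
    intrinsic = compute_intrinsic_features(image, nuclei, cells, records)
    nd, org = extract_contextual_features(records, intrinsic, k_values)
    features = assemble_feature_matrix(intrinsic, nd, org)
    return cells, records, features


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the analysis stages described by ``config``; returns artifact paths."""
    os.makedirs(config.out_dir, exist_ok=True)
    _setup_logging(config)
    log.info("run config hash %s (seed %d)", config.config_hash()[:12], config.seed)

    image = xio.read_image(config.image_path, config.calibration)
    nuclei = xio.read_label_image(config.nuclei_path)
    if nuclei.shape != image.shape:
        raise DataError("image and nuclei label rasters differ in shape")

    artifacts: dict[str, str] = {}

    cells, records, features = measure_features(
        image, nuclei, config.delta_um, config.k_values
    )
    cells_path = os.path.join(config.out_dir, "cells.tif")
    xio.write_label_image(cells_path, cells)
    artifacts["cells"] = cells_path
    log.info("delineated %d cells", len(records))

    feat_path = os.path.join(config.out_dir, "features.csv")
    xio.write_feature_table(records, features, feat_path)
    artifacts["features"] = feat_path
    log.info("wrote %d x %d feature table", *features.shape)

    if config.measure_only:
        _stamp(config, artifacts)
        return artifacts

    if config.model_path is None:
        raise DataError("no model path given; use measure_only to stop after features")
    model = CellClassifier.load(config.model_path)
    model.check_compatible(catalog_names())
    proba = model.predict_proba(features.to_numpy())
    pred = model.classes_[np.argmax(proba, axis=1)]
    pred_df = pd.DataFrame(
        {
            "cell_id": [r.cell_label for r in records],
            "class": pred,
        }
    )
    for ci, cname in enumerate(model.classes_):
        pred_df[f"prob_{cname}"] = proba[:, ci]
    pred_path = os.path.join(config.out_dir, "predictions.csv")
    pred_df.to_csv(pred_path, index=False)
    artifacts["predictions"] = pred_path

    overlay = xio.render_overlay(
        image, cells, dict(zip(pred_df["cell_id"], pred_df["class"]))
    )
    overlay_path = os.path.join(config.out_dir, "overlay.png")
    xio.write_image(overlay_path, overlay)
    artifacts["overlay"] = overlay_path

    if config.truth_path:
        truth = pd.read_csv(config.truth_path)
        merged = pred_df.merge(truth[["cell_id", "class"]], on="cell_id",
                               suffixes=("_pred", "_true"))
        if len(merged) == 0:
            raise DataError("truth table shares no cell ids with predictions")
        class_names = list(model.classes_)
        m = evaluate_classification(
            merged["class_true"].to_numpy(),
            merged["class_pred"].to_numpy(),
            merged[[f"prob_{c}" for c in class_names]].to_numpy(),
            class_names,
        )
        metrics_path = os.path.join(config.out_dir, "metrics.json")
        with open(metrics_path, "w") as fh:
            json.dump(
                {"accuracy": m.accuracy, "per_class": m.per_class}, fh, indent=1
            )
        artifacts["metrics"] = metrics_path
        log.info("classification accuracy %.4f", m.accuracy)

    _stamp(config, artifacts)
    return artifacts


def _stamp(config: RunConfig, artifacts: dict[str, str]) -> None:
    meta = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": artifacts,
    }
    path = os.path.join(config.out_dir, "run_meta.json")
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    artifacts["run_meta"] = path


def _setup_logging(config: RunConfig) -> None:
    log.setLevel(config.log_level.upper())
    log.handlers = [
        logging.StreamHandler(),
        logging.FileHandler(os.path.join(config.out_dir, "run.log"), mode="w"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)
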