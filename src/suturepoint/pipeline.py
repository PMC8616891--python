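"""File-level orchestration: train / predict / evaluate from directories and CSVs.

Thin wrappers over :class:`~suturepoint.model.SutureDetectionModel` and the
evaluation library for shell-driven use: datasets are directories written by
:func:`suturepoint.synthetic.generate_dataset` (PNG + labelme JSON +
``manifest.json``), predictions travel as a CSV with columns
``image_id,row,col,score``, and evaluation reports are emitted as CSV and
JSON mirroring the (dataset, radius) table structure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codec import PointSet, save_heatmap_png
from .matching import radius_sweep, rmse_localisation, summarise_rmse
from .model import RunConfig, SutureDetectionModel, cross_validate, load_dataset
from .synthetic import read_labelme

__all__ = [
    "train",
    "predict",
    "evaluate",
    "crossval",
    "write_predictions_csv",
    "read_predictions_csv",
]


def train(config: RunConfig, train_dir, out_path, val_dir=None,
          verbose: bool = False):
    """Train on a dataset directory and write checkpoint + log next to ``out_path``."""
    images, points, _ = load_dataset(train_dir)
    model = SutureDetectionModel(images, points, config)
    if val_dir is not None:
        val_images, val_points, _ = load_dataset(val_dir)
        results = model.fit(val_images, val_points, verbose=verbose)
    else:
        results = model.fit(verbose=verbose)
    results.save(out_path)
    return results


def write_predictions_csv(predictions: dict[str, PointSet], path,
                          scores: dict[str, Sequence[float]] | None = None) -> None:
    """Write per-image point predictions as ``image_id,row,col,score``."""
    rows = []
    for image_id in sorted(predictions):
        ps = predictions[image_id]
        sc = (scores or {}).get(image_id, [1.0] * len(ps))
        for (r, c), s in zip(ps.points, sc):
            rows.append({"image_id": image_id, "row": r, "col": c, "score": s})
    pd.DataFrame(rows, columns=["image_id", "row", "col", "score"]) \
        .to_csv(path, index=False)


def read_predictions_csv(path, height: int, width: int) -> dict[str, PointSet]:
    """Read a predictions CSV back into per-image :class:`PointSet` objects."""
    df = pd.read_csv(path)
    out: dict[str, PointSet] = {}
    for image_id, sub in df.groupby("image_id"):
        out[str(image_id)] = PointSet(sub[["row", "col"]].to_numpy(), height, width)
    return out


def predict(checkpoint_path, images_dir, out_csv, decode_threshold: float = 0.5,
            heatmap_dir=None) -> dict[str, PointSet]:
    """Run a saved detector over every PNG in a directory.

    Writes the predictions CSV (and optionally the stage-2 heatmaps as
    16-bit PNGs) and returns the decoded point sets keyed by image id.
    """
    import imageio.v3 as iio

    from .codec import decode_points
    from .layers import load_checkpoint
    from .model import _InferenceMode, _prepare_images

    detector = load_checkpoint(checkpoint_path)
    images_dir = Path(images_dir)
    paths = sorted(images_dir.glob("*.png"))
    if not paths:
        raise ValueError(f"no PNG images found in {images_dir}")
    predictions: dict[str, PointSet] = {}
    with _InferenceMode(detector):
        for p in paths:
            batch = _prepare_images(iio.imread(p)[None])
            hm = detector.forward(batch).stage2.numpy()[0, 0]
            predictions[p.stem] = decode_points(hm, decode_threshold)
            if heatmap_dir is not None:
                Path(heatmap_dir).mkdir(parents=True, exist_ok=True)
                save_heatmap_png(hm, Path(heatmap_dir) / f"{p.stem}_stage2.png")
    write_predictions_csv(predictions, out_csv)
    return predictions


def evaluate(pred_csv, annotations_dir, radii: Sequence[float] = (6.0, 8.0, 10.0),
             out_prefix=None, pooling: str = "pooled") -> dict:
    """Score a predictions CSV against labelme annotations.

    Every predicted ``image_id`` must have a matching ``<image_id>.json``
    annotation.  Emits ``<out_prefix>_metrics.csv`` / ``.json`` when an
    output prefix is given; returns the metrics table and RMSE report.
    """
    annotations_dir = Path(annotations_dir)
    ann_paths = {p.stem: p for p in annotations_dir.glob("*.json")
                 if p.name != "manifest.json"}
    gts = {stem: read_labelme(p) for stem, p in ann_paths.items()}
    if not gts:
        raise ValueError(f"no annotations found in {annotations_dir}")
    sample = next(iter(gts.values()))
    preds = read_predictions_csv(pred_csv, sample.height, sample.width)
    missing = sorted(set(preds) - set(gts))
    if missing:
        raise ValueError(f"predictions reference unannotated image_ids: {missing}")
    ids = sorted(gts)
    empty = PointSet(np.empty((0, 2)), sample.height, sample.width)
    pred_list = [preds.get(i, empty) for i in ids]
    gt_list = [gts[i] for i in ids]
    metrics = radius_sweep(pred_list, gt_list, list(radii), pooling=pooling)
    rmse = summarise_rmse(rmse_localisation(p, g)
                          for p, g in zip(pred_list, gt_list) if len(g))
    report = {"metrics": metrics, "rmse": rmse}
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        metrics.assign(rmse=rmse.rmse,
                       n_images_scored=rmse.n_images_scored,
                       n_images_total=rmse.n_images_total) \
            .to_csv(f"{out_prefix}_metrics.csv", index=False)
        payload = {"metrics": metrics.to_dict(orient="records"),
                   "rmse": {"rmse": rmse.rmse,
                            "n_images_scored": rmse.n_images_scored,
                            "n_images_total": rmse.n_images_total}}
        Path(f"{out_prefix}_metrics.json").write_text(json.dumps(payload, indent=2))
    return report


def crossval(config: RunConfig, dataset_dir, out_dir=None,
             verbose: bool = False) -> dict:
    """Group-wise cross-validation over a dataset directory."""
    images, points, groups = load_dataset(dataset_dir)
    out = cross_validate(images, points, groups, config, verbose=verbose)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out["folds"].to_csv(out_dir / "folds.csv", index=False)
        out["aggregate"].to_csv(out_dir / "aggregate.csv", index=False)
    return out
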