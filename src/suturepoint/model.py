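"""Model / Results objects: seeded training, prediction, evaluation, cross-validation.

:class:`SutureDetectionModel` is built from data (images plus per-image
point annotations) and a :class:`RunConfig`; ``fit()`` minimises the joint
two-stage objective with Adam (lr 0.001 by default) under a
reduce-on-plateau schedule (factor 0.1, patience 10 epochs, monitored on
the training loss — the validation split must stay unseen, so it is never
used for scheduling or model selection) and returns a
:class:`SutureDetectionResults` carrying the selected parameters, the
per-epoch log, and ``predict`` / ``evaluate`` / ``summary`` methods.
Group-wise cross-validation trains one model per fold with no group
straddling folds and aggregates fold metrics as mean +/- std.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import losses as L
from .codec import (DistributionSpec, PointSet, decode_points, encode_binary_mask,
                    encode_heatmap)
from .layers import Detector, ModelConfig, save_checkpoint
from .matching import (MetricsReport, aggregate_folds, detection_metrics,
                       match_points, radius_sweep, rmse_localisation,
                       summarise_rmse)
from .synthetic import AugmentConfig, augment_sample

__all__ = [
    "RunConfig",
    "Adam",
    "SutureDetectionModel",
    "SutureDetectionResults",
    "group_kfold",
    "cross_validate",
]


@dataclass(frozen=True)
class RunConfig:
    """Everything a training run depends on, YAML-serialisable."""

    model: ModelConfig = field(default_factory=ModelConfig)
    loss: L.LossConfig = field(default_factory=L.LossConfig)
    dist: DistributionSpec = field(default_factory=DistributionSpec)
    learning_rate: float = 0.001
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    epochs: int = 10
    batch_size: int = 8
    decode_threshold: float = 0.5
    radii: tuple[float, ...] = (6.0, 8.0, 10.0)
    folds: int = 4
    group_key: str = "group"
    seed: int = 0
    augment: AugmentConfig | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["radii"] = list(self.radii)
        if self.augment is not None:
            doc["augment"]["contrast_range"] = list(self.augment.contrast_range)
            doc["augment"]["saturation_range"] = list(self.augment.saturation_range)
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            doc = yaml.safe_load(Path(source).read_text())
        else:
            doc = yaml.safe_load(io.StringIO(str(source)))
        doc["model"] = ModelConfig(**doc.get("model", {}))
        doc["loss"] = L.LossConfig(**doc.get("loss", {}))
        doc["dist"] = DistributionSpec(**doc.get("dist", {}))
        if doc.get("augment"):
            aug = doc["augment"]
            for key in ("contrast_range", "saturation_range"):
                if key in aug:
                    aug[key] = tuple(aug[key])
            doc["augment"] = AugmentConfig(**aug)
        else:
            doc["augment"] = None
        if "radii" in doc:
            doc["radii"] = tuple(doc["radii"])
        return cls(**doc)


class Adam:
    """Adam optimiser over a list of autograd parameter tensors."""

    def __init__(self, params, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * p.grad ** 2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class _InferenceMode:
    """Temporarily detach parameters so forward passes record no graph."""

    def __init__(self, detector: Detector):
        self.params = detector.parameters()

    def __enter__(self):
        self.flags = [p.requires_grad for p in self.params]
        for p in self.params:
            p.requires_grad = False
        return self

    def __exit__(self, *exc):
        for p, flag in zip(self.params, self.flags):
            p.requires_grad = flag
        return False


def _prepare_images(images) -> np.ndarray:
    """Accept (N,H,W,3) uint8/float or (N,3,H,W) float; return (N,3,H,W) in [0,1]."""
    arr = np.asarray(images)
    if arr.ndim != 4:
        raise ValueError(f"expected a 4-D image batch, got shape {arr.shape}")
    if arr.shape[-1] == 3 and arr.shape[1] != 3:
        arr = arr.transpose(0, 3, 1, 2)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


class SutureDetectionModel:
    """A suture-point detector bound to its training data.

    Parameters
    ----------
    images : array_like
        Training images, (N, H, W, 3) uint8 or (N, 3, H, W) float in [0, 1].
    point_sets : sequence of PointSet
        Ground-truth suture points, one per image.
    config : RunConfig
        Architecture, distribution encoding, loss variant and optimisation
        settings.
    """

    def __init__(self, images, point_sets: Sequence[PointSet], config: RunConfig):
        self.images = _prepare_images(images)
        self.point_sets = list(point_sets)
        if len(self.images) != len(self.point_sets):
            raise ValueError("images and point_sets differ in length")
        if len(self.images) == 0:
            raise ValueError("training set is empty")
        cfg = config.model
        if self.images.shape[2:] != (cfg.input_height, cfg.input_width):
            raise ValueError(
                f"images are {self.images.shape[2:]} but the model expects "
                f"{(cfg.input_height, cfg.input_width)}")
        self.config = config

    @classmethod
    def from_manifest(cls, dataset_dir, config: RunConfig) -> "SutureDetectionModel":
        """Build from a directory written by :func:`suturepoint.synthetic.generate_dataset`."""
        images, points, _ = load_dataset(dataset_dir)
        return cls(images, points, config)

    # -- target encoding -----------------------------------------------------
    def _encode_targets(self, point_sets) -> tuple[np.ndarray, np.ndarray]:
        heat = np.stack([encode_heatmap(ps, self.config.dist) for ps in point_sets])
        mask = np.stack([encode_binary_mask(ps) for ps in point_sets])
        return heat[:, None], mask[:, None]

    # -- fitting -------------------------------------------------------------
    def fit(self, val_images=None, val_point_sets=None,
            verbose: bool = False) -> "SutureDetectionResults":
        """Train the detector; returns a results object with the best state.

        The checkpoint kept is the epoch with the lowest training loss (the
        validation split, when given, is only logged, never used for
        selection or scheduling).
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        detector = Detector(cfg.model, seed=cfg.seed)
        optimiser = Adam(detector.parameters(), lr=cfg.learning_rate)
        heat, mask = self._encode_targets(self.point_sets)

        val = None
        if val_images is not None:
            val_imgs = _prepare_images(val_images)
            vheat = np.stack([encode_heatmap(ps, cfg.dist) for ps in val_point_sets])
            vmask = np.stack([encode_binary_mask(ps) for ps in val_point_sets])
            val = (val_imgs, vheat[:, None], vmask[:, None])

        n = len(self.images)
        log_rows = []
        best_loss = np.inf
        best_state = detector.state_dict()
        plateau_best = np.inf
        plateau_count = 0
        for epoch in range(1, cfg.epochs + 1):
            if cfg.augment is not None:
                imgs, heat, mask = self._augmented_epoch(rng)
            else:
                imgs = self.images
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                outputs = detector.forward(imgs[idx])
                loss = L.total_loss(outputs, heat[idx], mask[idx], cfg.loss)
                value = loss.item()
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite training loss ({value}) at epoch {epoch}")
                optimiser.zero_grad()
                loss.backward()
                optimiser.step()
                epoch_loss += value * len(idx)
            epoch_loss /= n

            val_loss = np.nan
            if val is not None:
                val_loss = self._eval_loss(detector, *val)
            log_rows.append({"epoch": epoch, "train_loss": epoch_loss,
                             "val_loss": val_loss, "lr": optimiser.lr})
            if verbose:
                print(f"epoch {epoch:3d}  train_loss {epoch_loss:.5f}  "
                      f"lr {optimiser.lr:.2e}")

            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_state = detector.state_dict()
            # reduce-on-plateau, monitored on the training loss
            if epoch_loss < plateau_best - 1e-6:
                plateau_best = epoch_loss
                plateau_count = 0
            else:
                plateau_count += 1
                if plateau_count >= cfg.plateau_patience:
                    optimiser.lr *= cfg.plateau_factor
                    plateau_count = 0
        detector.load_state_dict(best_state)
        return SutureDetectionResults(detector, cfg, pd.DataFrame(log_rows),
                                      best_loss)

    def _augmented_epoch(self, rng):
        imgs, pts = [], []
        for i in range(len(self.images)):
            img, ps = augment_sample(self.images[i].transpose(1, 2, 0),
                                     self.point_sets[i], self.config.augment,
                                     rng=rng)
            imgs.append(img.transpose(2, 0, 1))
            pts.append(ps)
        heat, mask = self._encode_targets(pts)
        return np.stack(imgs), heat, mask

    def _eval_loss(self, detector, imgs, heat, mask) -> float:
        with _InferenceMode(detector):
            total, n = 0.0, len(imgs)
            for start in range(0, n, self.config.batch_size):
                sl = slice(start, start + self.config.batch_size)
                outputs = detector.forward(imgs[sl])
                total += L.total_loss(outputs, heat[sl], mask[sl],
                                      self.config.loss).item() * (len(imgs[sl]))
        return total / n


class SutureDetectionResults:
    """Fitted detector plus training log, prediction and evaluation methods."""

    def __init__(self, detector: Detector, config: RunConfig,
                 log: pd.DataFrame, best_loss: float):
        self.detector = detector
        self.config = config
        self.log = log
        self.best_loss = best_loss

    # -- inference -----------------------------------------------------------
    def predict(self, images) -> list[tuple[np.ndarray, PointSet]]:
        """Stage-2 heatmap and decoded point set for each image.

        Decoding thresholds the stage-2 map at ``config.decode_threshold``
        and takes the intensity-weighted centre of mass of each connected
        component.  Deterministic.
        """
        imgs = _prepare_images(images)
        out = []
        with _InferenceMode(self.detector):
            for start in range(0, len(imgs), self.config.batch_size):
                stage2 = self.detector.forward(
                    imgs[start:start + self.config.batch_size]).stage2.numpy()
                for hm in stage2[:, 0]:
                    out.append((hm, decode_points(hm, self.config.decode_threshold)))
        return out

    def evaluate(self, images, gts: Sequence[PointSet],
                 radii: Sequence[float] | None = None,
                 pooling: str = "pooled") -> dict:
        """Radius-swept detection metrics plus localisation RMSE."""
        radii = tuple(radii if radii is not None else self.config.radii)
        preds = [ps for _, ps in self.predict(images)]
        metrics = radius_sweep(preds, list(gts), radii, pooling=pooling)
        rmse = summarise_rmse(rmse_localisation(p, g)
                              for p, g in zip(preds, gts) if len(g))
        return {"metrics": metrics, "rmse": rmse, "predictions": preds}

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Suture point detection results",
            "=" * 46,
            f"{'U-Net depth / base filters':34s} {cfg.model.depth} / {cfg.model.base_filters}",
            f"{'input size':34s} {cfg.model.input_height}x{cfg.model.input_width}",
            f"{'parameters':34s} {self.detector.n_parameters()}",
            f"{'encoding':34s} {cfg.dist.kind} "
            + (f"(sigma1={cfg.dist.sigma1})" if cfg.dist.kind == "gaussian"
               else f"(alpha={cfg.dist.alpha})"),
            f"{'gaussian layer sigma2':34s} {cfg.model.sigma2}",
            f"{'loss variant':34s} {cfg.loss.variant}",
            f"{'epochs run':34s} {len(self.log)}",
            f"{'best training loss':34s} {self.best_loss:.5f}",
            f"{'final learning rate':34s} {self.log['lr'].iloc[-1]:.2e}"
            if len(self.log) else f"{'final learning rate':34s} -",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path, extra: dict | None = None) -> None:
        """Write the checkpoint (.npz + manifest JSON) and the training log CSV."""
        path = Path(path)
        manifest = {"seed": self.config.seed,
                    "best_train_loss": self.best_loss,
                    "run_config": yaml.safe_load(self.config.to_yaml())}
        manifest.update(extra or {})
        save_checkpoint(self.detector, path, manifest)
        stem = path.with_suffix("") if path.suffix else path
        self.log.to_csv(f"{stem}_log.csv", index=False)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def group_kfold(groups: Sequence[str], n_folds: int) -> list[tuple[list[int], list[int]]]:
    """Deterministic group-wise k-fold split.

    Unique groups (sorted) are dealt round-robin to folds; returns
    ``(train_indices, val_indices)`` per fold.  No group straddles folds.
    """
    unique = sorted(set(groups))
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(unique) < n_folds:
        raise ValueError(f"{len(unique)} groups cannot fill {n_folds} folds")
    assignment = {g: i % n_folds for i, g in enumerate(unique)}
    folds = []
    for k in range(n_folds):
        val = [i for i, g in enumerate(groups) if assignment[g] == k]
        train = [i for i, g in enumerate(groups) if assignment[g] != k]
        folds.append((train, val))
    return folds


def cross_validate(images, point_sets: Sequence[PointSet],
                   groups: Sequence[str], config: RunConfig,
                   pooling: str = "pooled", verbose: bool = False) -> dict:
    """Group-wise k-fold cross-validation at the primary matching radius.

    Each fold trains a fresh seeded model on the training groups and
    evaluates on the held-out groups (used purely as an unseen set — no
    early stopping or selection touches it).  Returns per-fold reports,
    the mean +/- std aggregation, and the per-fold results objects.
    """
    images = _prepare_images(images)
    folds = group_kfold(list(groups), config.folds)
    fold_reports: list[MetricsReport] = []
    fold_rows = []
    results_objects = []
    radius = config.radii[0]
    for k, (train_idx, val_idx) in enumerate(folds):
        fold_cfg = replace(config, seed=config.seed + k)
        model = SutureDetectionModel(images[train_idx],
                                     [point_sets[i] for i in train_idx], fold_cfg)
        res = model.fit(verbose=verbose)
        preds = [ps for _, ps in res.predict(images[val_idx])]
        gts = [point_sets[i] for i in val_idx]
        report = detection_metrics(
            [match_points(p, g, radius) for p, g in zip(preds, gts)],
            pooling=pooling)
        fold_reports.append(report)
        fold_rows.append({"fold": k, "ppv": report.ppv, "tpr": report.tpr,
                          "f1": report.f1, "n_images": report.n_images})
        results_objects.append(res)
    return {"folds": pd.DataFrame(fold_rows),
            "aggregate": aggregate_folds(fold_reports),
            "results": results_objects}


# ---------------------------------------------------------------------------
# dataset loading (manifest written by synthetic.generate_dataset)
# ---------------------------------------------------------------------------

def load_dataset(dataset_dir) -> tuple[np.ndarray, list[PointSet], list[str]]:
    """Load images, annotations and group ids from a dataset directory."""
    import json as _json

    import imageio.v3 as iio

    from .synthetic import read_labelme

    dataset_dir = Path(dataset_dir)
    doc = _json.loads((dataset_dir / "manifest.json").read_text())
    images, points, groups = [], [], []
    for entry in doc["entries"]:
        images.append(iio.imread(dataset_dir / entry["image"]))
        points.append(read_labelme(dataset_dir / entry["annotation"]))
        groups.append(entry.get("group", "group0"))
    return np.stack(images), points, groups
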