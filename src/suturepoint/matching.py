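"""Detection and localisation metrics for multi-instance point predictions.

A prediction counts as a true positive when it lies strictly within a
matching radius (default 6 px) of a ground-truth point, with a greedy
closest-first assignment: all candidate pairs inside the radius are sorted
by distance and accepted when neither member is already matched, so when
several predictions compete for one ground-truth point the closest wins and
the runner-up falls through to its second-best ground-truth point.  From
the resulting TP/FP/FN counts, PPV (precision) and TPR (recall) are reported
in percent and F1 as their harmonic mean ``2 P R / (P + R)`` on fractions.

Localisation is summarised by an RMSE over predictions: each predicted
point contributes its distance to the nearest ground-truth point (reuse
allowed), averaged per image; images without predictions cannot be scored
and are counted separately.

Also here: the radius sweep (6/8/10 px), the close-point subset analysis
(ground-truth points with a neighbour closer than 15 px versus the rest),
and mean +/- std aggregation across cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .codec import PointSet

__all__ = [
    "MatchResult",
    "MetricsReport",
    "RmseReport",
    "match_points",
    "detection_metrics",
    "rmse_localisation",
    "summarise_rmse",
    "close_gt_mask",
    "close_subset_analysis",
    "radius_sweep",
    "aggregate_folds",
]

NO_PREDICTION = None  # marker returned by rmse_localisation


@dataclass(frozen=True)
class MatchResult:
    """Accepted (prediction, ground-truth) pairs and counts at one radius."""

    pairs: tuple = field(default=())  # (pred_index, gt_index, distance)
    tp: int = 0
    fp: int = 0
    fn: int = 0
    radius: float = 6.0


@dataclass(frozen=True)
class MetricsReport:
    """PPV and TPR in percent, F1 in [0, 1], at one matching radius."""

    ppv: float
    tpr: float
    f1: float
    radius: float
    n_images: int


@dataclass(frozen=True)
class RmseReport:
    """Mean per-image localisation RMSE over the images that have predictions."""

    rmse: float
    n_images_scored: int
    n_images_total: int


def match_points(pred: PointSet, gt: PointSet, radius: float = 6.0) -> MatchResult:
    """Greedy radius-constrained matching of predictions to ground truth.

    Candidate pairs with Euclidean distance strictly below ``radius`` are
    sorted ascending by distance (ties broken by lower prediction index,
    then lower ground-truth index) and accepted when neither point is
    already matched.  Counts satisfy ``tp + fp == len(pred)`` and
    ``tp + fn == len(gt)``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n_pred, n_gt = len(pred), len(gt)
    if n_pred == 0 or n_gt == 0:
        return MatchResult((), 0, n_pred, n_gt, radius)
    d = cdist(pred.points, gt.points)
    pi, gi = np.nonzero(d < radius)
    order = np.lexsort((gi, pi, d[pi, gi]))
    used_pred = np.zeros(n_pred, dtype=bool)
    used_gt = np.zeros(n_gt, dtype=bool)
    pairs = []
    for k in order:
        p, g = int(pi[k]), int(gi[k])
        if used_pred[p] or used_gt[g]:
            continue
        used_pred[p] = used_gt[g] = True
        pairs.append((p, g, float(d[p, g])))
    tp = len(pairs)
    return MatchResult(tuple(pairs), tp, n_pred - tp, n_gt - tp, radius)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def detection_metrics(results: Sequence[MatchResult],
                      pooling: str = "pooled") -> MetricsReport:
    """PPV / TPR / F1 over a set of per-image match results.

    ``pooled`` sums TP/FP/FN over images before forming the rates;
    ``per_image`` averages per-image rates over the images where the
    denominator is defined.  Undefined rates follow the zero convention
    (no predictions -> PPV 0, no ground truth -> TPR 0, F1 0 when both
    rates vanish).
    """
    results = list(results)
    if not results:
        raise ValueError("no match results given")
    radii = {r.radius for r in results}
    if len(radii) > 1:
        raise ValueError(f"mixed matching radii: {sorted(radii)}")
    if pooling == "pooled":
        tp = sum(r.tp for r in results)
        fp = sum(r.fp for r in results)
        fn = sum(r.fn for r in results)
        ppv = _safe_div(tp, tp + fp)
        tpr = _safe_div(tp, tp + fn)
    elif pooling == "per_image":
        ppvs = [_safe_div(r.tp, r.tp + r.fp) for r in results if r.tp + r.fp > 0]
        tprs = [_safe_div(r.tp, r.tp + r.fn) for r in results if r.tp + r.fn > 0]
        ppv = float(np.mean(ppvs)) if ppvs else 0.0
        tpr = float(np.mean(tprs)) if tprs else 0.0
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    f1 = _safe_div(2.0 * ppv * tpr, ppv + tpr)
    return MetricsReport(ppv=100.0 * ppv, tpr=100.0 * tpr, f1=f1,
                         radius=radii.pop(), n_images=len(results))


def rmse_localisation(pred: PointSet, gt: PointSet) -> float | None:
    """Per-image localisation RMSE, or the no-prediction marker (None).

    Each predicted point contributes its minimum Euclidean distance to any
    ground-truth point (a ground-truth point may serve several predictions);
    the root of the mean of the squared minima is returned.  Undefined for
    an empty ground truth.
    """
    if len(gt) == 0:
        raise ValueError("rmse_localisation is undefined for empty ground truth")
    if len(pred) == 0:
        return NO_PREDICTION
    d = cdist(pred.points, gt.points)
    return float(np.sqrt(np.mean(d.min(axis=1) ** 2)))


def summarise_rmse(values: Iterable[float | None]) -> RmseReport:
    """Average per-image RMSE values, excluding no-prediction images."""
    values = list(values)
    scored = [v for v in values if v is not None]
    rmse = float(np.mean(scored)) if scored else float("nan")
    return RmseReport(rmse=rmse, n_images_scored=len(scored),
                      n_images_total=len(values))


def close_gt_mask(gt: PointSet, close_threshold: float = 15.0) -> np.ndarray:
    """Boolean mask of ground-truth points with a neighbour closer than the threshold."""
    n = len(gt)
    if n == 0:
        return np.zeros(0, dtype=bool)
    d = cdist(gt.points, gt.points)
    np.fill_diagonal(d, np.inf)
    return (d < close_threshold).any(axis=1)


def close_subset_analysis(gt: PointSet, results_a: MatchResult,
                          results_b: MatchResult,
                          close_threshold: float = 15.0) -> pd.DataFrame:
    """Matched-percentage comparison of two models on close vs non-close points.

    Ground-truth points are split into the close subset (a neighbour within
    ``close_threshold`` px) and the rest; for each model the percentage of
    each subset that was matched is reported.  Subsets with no members get
    NaN.  Both match results must refer to the same ground truth.
    """
    for res in (results_a, results_b):
        if res.tp + res.fn != len(gt):
            raise ValueError("match result does not refer to the given ground truth")
    close = close_gt_mask(gt, close_threshold)
    rows = []
    for name, res in (("a", results_a), ("b", results_b)):
        matched = np.zeros(len(gt), dtype=bool)
        for _, g, _ in res.pairs:
            matched[g] = True
        for subset, mask in (("close", close), ("non_close", ~close)):
            n = int(mask.sum())
            pct = 100.0 * matched[mask].sum() / n if n else float("nan")
            rows.append({"model": name, "subset": subset,
                         "n_points": n, "tp_percent": pct})
    return pd.DataFrame(rows)


def radius_sweep(preds: Sequence[PointSet], gts: Sequence[PointSet],
                 radii: Sequence[float] = (6.0, 8.0, 10.0),
                 pooling: str = "pooled") -> pd.DataFrame:
    """Detection metrics at each matching radius (default 6, 8, 10 px)."""
    radii = list(radii)
    if any(r <= 0 for r in radii) or sorted(radii) != radii:
        raise ValueError("radii must be positive and ascending")
    if len(preds) != len(gts):
        raise ValueError("prediction and ground-truth lists differ in length")
    rows = []
    for radius in radii:
        results = [match_points(p, g, radius) for p, g in zip(preds, gts)]
        rep = detection_metrics(results, pooling=pooling)
        rows.append({"radius": radius, "ppv": rep.ppv, "tpr": rep.tpr,
                     "f1": rep.f1, "n_images": rep.n_images})
    return pd.DataFrame(rows)


def aggregate_folds(fold_reports: Sequence[MetricsReport]) -> pd.DataFrame:
    """Mean +/- population standard deviation of each metric across folds."""
    reports = list(fold_reports)
    if len(reports) < 2:
        raise ValueError("need at least two folds to aggregate")
    radii = {r.radius for r in reports}
    if len(radii) > 1:
        raise ValueError(f"mixed matching radii: {sorted(radii)}")
    rows = []
    for metric in ("ppv", "tpr", "f1"):
        vals = np.array([getattr(r, metric) for r in reports])
        rows.append({"metric": metric, "mean": float(vals.mean()),
                     "std": float(vals.std()), "n_folds": len(reports)})
    return pd.DataFrame(rows)
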