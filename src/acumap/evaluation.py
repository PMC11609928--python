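"""Localization-quality metrics: per-point distance errors, pixel-to-physical
calibration, object keypoint similarity (OKS), precision/recall and mAP, mean
error confidence intervals, and per-axis Kolmogorov-Smirnov comparisons.

Conventions (documented package choices where the protocol is unstated
upstream): OKS scale ``s`` is the square root of the ground-truth bbox area,
falling back to the landmark bounding box; the mean-error CI is the normal
approximation (±1.96 SE); the KS p-value is the asymptotic two-sample
distribution; AP uses 101-point interpolated precision with greedy,
confidence-ordered matching at OKS thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidInputError, PairingError
from .geometry import Point, euclidean_distance
from .mapping import PredictedAcupoint

DEFAULT_OKS_K = 0.02
DEFAULT_OKS_THRESHOLDS = tuple(round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class GroundTruthAnnotation:
    """One annotated acupoint on one image."""

    image_id: object
    code: str
    position: Point
    bbox: Optional[tuple[float, float, float, float]] = None  # x, y, w, h


@dataclass(frozen=True)
class CalibrationModel:
    """Pixel-to-physical scale from a reference object of known length.

    ``cm_per_pixel`` keeps full precision; ``reported()`` truncates toward
    zero at 4 decimals, which is the figure used for mm conversions.
    """

    cm_per_pixel: float
    reference_length_cm: float
    reference_length_px: float

    def reported(self) -> float:
        return math.trunc(self.cm_per_pixel * 1e4) / 1e4


@dataclass(frozen=True)
class OKSParams:
    k: float = DEFAULT_OKS_K
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.s > 0):
            raise InvalidInputError("OKS parameters k and s must be positive")


@dataclass
class EvalReport:
    """Aggregated evaluation output (all distances in pixels unless noted)."""

    per_point_errors: dict[str, list[float]]
    mean_distance: float
    ci95: tuple[float, float]
    ks_x: tuple[float, float]
    ks_y: tuple[float, float]
    counts: dict[float, tuple[int, int, int]]  # threshold -> (TP, FP, FN)
    ap_per_category: dict[str, float]  # at the primary threshold (0.5)
    map50: float
    map50_95: float
    calibration: Optional[CalibrationModel] = None
    calibrated_errors_mm: Optional[dict[str, list[float]]] = None
    n_pairs: int = 0

    def to_dict(self) -> dict:
        out = {
            "n_pairs": self.n_pairs,
            "mean_distance_px": self.mean_distance,
            "ci95_px": list(self.ci95),
            "ks_x": {"statistic": self.ks_x[0], "p_value": self.ks_x[1]},
            "ks_y": {"statistic": self.ks_y[0], "p_value": self.ks_y[1]},
            "counts": {str(t): {"tp": c[0], "fp": c[1], "fn": c[2]}
                       for t, c in self.counts.items()},
            "ap_per_category@0.5": self.ap_per_category,
            "mAP@50": self.map50,
            "mAP@50-95": self.map50_95,
            "per_point_mean_px": {c: float(np.mean(v))
                                  for c, v in self.per_point_errors.items() if v},
        }
        if self.calibration is not None:
            out["cm_per_pixel"] = self.calibration.reported()
            out["mean_distance_mm"] = self.mean_distance * self.calibration.reported() * 10.0
        return out


# --------------------------------------------------------------- calibration

def calibrate_from_reference(length_cm: float, length_px: float) -> CalibrationModel:
    """Build a calibration model from a reference length seen in the image."""
    if not (length_cm > 0 and length_px > 0):
        raise InvalidInputError("reference lengths must be positive")
    return CalibrationModel(
        cm_per_pixel=length_cm / length_px,
        reference_length_cm=length_cm,
        reference_length_px=length_px,
    )


def pixels_to_mm(error_px: float, calib: CalibrationModel) -> float:
    """Convert a pixel error to millimeters via the truncated factor."""
    if error_px < 0:
        raise InvalidInputError("pixel error must be nonnegative")
    return error_px * calib.reported() * 10.0


# -------------------------------------------------------------------- errors

def distance_error(pred: PredictedAcupoint, gt: GroundTruthAnnotation) -> float:
    """Euclidean image-space distance between a prediction and its annotation."""
    if pred.code != gt.code:
        raise PairingError(f"code mismatch: {pred.code!r} vs {gt.code!r}")
    if pred.position is None:
        raise PairingError(f"{pred.code}: prediction has no position")
    p, g = pred.position, gt.position
    return euclidean_distance(Point(p.x, p.y), Point(g.x, g.y))


def oks(d: float, params: OKSParams) -> float:
    """exp(-d^2 / (2 s^2 k^2)) — 1 at d=0, decaying with distance."""
    if d < 0:
        raise InvalidInputError("distance must be nonnegative")
    return math.exp(-(d * d) / (2.0 * params.s * params.s * params.k * params.k))


def precision_recall(tp: int, fp: int, fn: int) -> tuple[Optional[float], Optional[float]]:
    """Percent precision and recall; ``None`` where the ratio is undefined."""
    if min(tp, fp, fn) < 0:
        raise InvalidInputError("counts must be nonnegative")
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    return precision, recall


# ------------------------------------------------------------------ matching

def _gt_scale(gt: GroundTruthAnnotation,
              fallback_bbox: Optional[tuple[float, float, float, float]]) -> float:
    bbox = gt.bbox if gt.bbox is not None else fallback_bbox
    if bbox is None:
        raise InvalidInputError(f"{gt.code}: no bbox available for the OKS scale")
    _, _, w, h = bbox
    area = w * h
    if area <= 0:
        raise InvalidInputError(f"{gt.code}: degenerate bbox for the OKS scale")
    return math.sqrt(area)


def match_by_oks(
    preds: Sequence[tuple[PredictedAcupoint, float]],
    gts: Sequence[GroundTruthAnnotation],
    threshold: float,
    k: float = DEFAULT_OKS_K,
    fallback_bbox: Optional[tuple[float, float, float, float]] = None,
) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """Greedy per-image, per-category matching.

    ``preds`` are (prediction, confidence) pairs. In descending confidence,
    each prediction takes the highest-OKS unmatched ground truth of the same
    code with OKS >= threshold (ties broken by ground-truth order). Returns
    (TP, FP, FN, matches) where matches holds (pred index, gt index, OKS).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    taken: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for pi in order:
        pred, _conf = preds[pi]
        if not pred.visible or pred.position is None:
            continue
        best: Optional[tuple[float, int]] = None
        for gi, gt in enumerate(gts):
            if gi in taken or gt.code != pred.code:
                continue
            d = distance_error(pred, gt)
            s = _gt_scale(gt, fallback_bbox)
            score = oks(d, OKSParams(k=k, s=s))
            if score >= threshold and (best is None or score > best[0]):
                best = (score, gi)
        if best is not None:
            taken.add(best[1])
            matches.append((pi, best[1], best[0]))
    tp = len(matches)
    fp = sum(1 for p, _ in preds if p.visible and p.position is not None) - tp
    fn = len(gts) - tp
    return tp, fp, fn, matches


# ------------------------------------------------------------------- AP/mAP

def _average_precision(scored: list[tuple[float, bool]], n_gt: int) -> Optional[float]:
    """101-point interpolated AP from (confidence, is-TP) pairs."""
    if n_gt == 0:
        return None
    if not scored:
        return 0.0
    scored = sorted(scored, key=lambda t: -t[0])
    tp_cum = fp_cum = 0
    precisions, recalls = [], []
    for _conf, is_tp in scored:
        if is_tp:
            tp_cum += 1
        else:
            fp_cum += 1
        precisions.append(tp_cum / (tp_cum + fp_cum))
        recalls.append(tp_cum / n_gt)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        candidates = [p for p, rec in zip(precisions, recalls) if rec >= r]
        ap += max(candidates) if candidates else 0.0
    return ap / 101.0


def ap_by_category(
    preds_by_image: dict[object, list[tuple[PredictedAcupoint, float]]],
    gts_by_image: dict[object, list[GroundTruthAnnotation]],
    threshold: float,
    k: float = DEFAULT_OKS_K,
) -> dict[str, float]:
    """Per-acupoint-code AP across all images at one OKS threshold."""
    codes = sorted(
        {g.code for gts in gts_by_image.values() for g in gts}
        | {p.code for ps in preds_by_image.values() for p, _ in ps if p.visible}
    )
    out: dict[str, float] = {}
    for code in codes:
        scored: list[tuple[float, bool]] = []
        n_gt = 0
        for image_id in sorted(set(preds_by_image) | set(gts_by_image), key=str):
            preds = [(p, c) for p, c in preds_by_image.get(image_id, [])
                     if p.code == code and p.visible and p.position is not None]
            gts = [g for g in gts_by_image.get(image_id, []) if g.code == code]
            n_gt += len(gts)
            _tp, _fp, _fn, matches = match_by_oks(preds, gts, threshold, k=k)
            matched_pi = {pi for pi, _gi, _s in matches}
            for pi, (pred, conf) in enumerate(preds):
                scored.append((conf, pi in matched_pi))
        ap = _average_precision(scored, n_gt)
        if ap is not None:
            out[code] = ap
    return out


def mean_ap(ap_per_category: dict[str, float]) -> float:
    """Arithmetic mean of per-category AP values."""
    if not ap_per_category:
        raise InvalidInputError("mean AP needs at least one category")
    return float(np.mean(list(ap_per_category.values())))


# --------------------------------------------------------------- statistics

def summarize_errors(errors: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean error with a normal-approximation 95% CI (degenerate at n=1)."""
    if len(errors) == 0:
        raise InvalidInputError("cannot summarize an empty error list")
    arr = np.asarray(errors, dtype=float)
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, (mean, mean)
    half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(arr.size)
    return mean, (mean - half, mean + half)


def ks_axis_test(pred_values: Sequence[float],
                 gt_values: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value for one axis."""
    if len(pred_values) == 0 or len(gt_values) == 0:
        raise InvalidInputError("KS test needs nonempty samples")
    with np.errstate(divide="ignore"):  # scipy's asymp path at n=1
        result = stats.ks_2samp(np.asarray(pred_values, dtype=float),
                                np.asarray(gt_values, dtype=float),
                                method="asymp")
    return float(result.statistic), float(min(1.0, result.pvalue))


# ----------------------------------------------------------------- pipeline

def evaluate(
    preds_by_image: dict[object, list[tuple[PredictedAcupoint, float]]],
    gts_by_image: dict[object, list[GroundTruthAnnotation]],
    calib: Optional[CalibrationModel] = None,
    oks_k: float = DEFAULT_OKS_K,
    thresholds: Sequence[float] = DEFAULT_OKS_THRESHOLDS,
) -> EvalReport:
    """Full evaluation: errors per code, mean+CI, KS per axis, TP/FP/FN per
    OKS threshold, AP/mAP, and optional mm-calibrated errors."""
    per_point: dict[str, list[float]] = {}
    pred_x, pred_y, gt_x, gt_y = [], [], [], []
    all_errors: list[float] = []
    for image_id, gts in gts_by_image.items():
        preds = {p.code: p for p, _ in preds_by_image.get(image_id, [])
                 if p.visible and p.position is not None}
        for gt in gts:
            pred = preds.get(gt.code)
            if pred is None:
                continue
            err = distance_error(pred, gt)
            per_point.setdefault(gt.code, []).append(err)
            all_errors.append(err)
            pred_x.append(pred.position.x)
            pred_y.append(pred.position.y)
            gt_x.append(gt.position.x)
            gt_y.append(gt.position.y)

    if not all_errors:
        counts = {
            float(t): (0, sum(len([1 for p, _ in ps if p.visible])
                              for ps in preds_by_image.values()),
                       sum(len(g) for g in gts_by_image.values()))
            for t in thresholds
        }
        return EvalReport(
            per_point_errors={}, mean_distance=float("nan"),
            ci95=(float("nan"), float("nan")),
            ks_x=(float("nan"), float("nan")), ks_y=(float("nan"), float("nan")),
            counts=counts, ap_per_category={}, map50=0.0, map50_95=0.0,
            calibration=calib, n_pairs=0,
        )

    mean, ci = summarize_errors(all_errors)
    counts: dict[float, tuple[int, int, int]] = {}
    map_values: list[float] = []
    ap_primary: dict[str, float] = {}
    for t in thresholds:
        tp = fp = fn = 0
        for image_id in sorted(set(preds_by_image) | set(gts_by_image), key=str):
            preds = preds_by_image.get(image_id, [])
            gts = gts_by_image.get(image_id, [])
            fallback = _landmark_bbox_fallback(gts)
            itp, ifp, ifn, _ = match_by_oks(preds, gts, float(t), k=oks_k,
                                            fallback_bbox=fallback)
            tp, fp, fn = tp + itp, fp + ifp, fn + ifn
        counts[float(t)] = (tp, fp, fn)
        aps = ap_by_category(preds_by_image, gts_by_image, float(t), k=oks_k)
        if abs(float(t) - 0.5) < 1e-12:
            ap_primary = aps
        map_values.append(mean_ap(aps) if aps else 0.0)

    map50 = map_values[0] if thresholds else 0.0
    map50_95 = float(np.mean(map_values)) if map_values else 0.0

    calibrated = None
    if calib is not None:
        calibrated = {c: [pixels_to_mm(e, calib) for e in v]
                      for c, v in per_point.items()}

    return EvalReport(
        per_point_errors=per_point,
        mean_distance=mean,
        ci95=ci,
        ks_x=ks_axis_test(pred_x, gt_x),
        ks_y=ks_axis_test(pred_y, gt_y),
        counts=counts,
        ap_per_category=ap_primary,
        map50=map50,
        map50_95=map50_95,
        calibration=calib,
        calibrated_errors_mm=calibrated,
        n_pairs=len(all_errors),
    )


def evaluate_files(
    preds_file,
    gts_file,
    registry,
    calib: Optional[CalibrationModel] = None,
    oks_k: float = DEFAULT_OKS_K,
    thresholds: Sequence[float] = DEFAULT_OKS_THRESHOLDS,
) -> EvalReport:
    """File-level wrapper: COCO-style results vs COCO keypoint ground truth."""
    from .fileio import read_coco_ground_truth, read_coco_results

    preds = read_coco_results(preds_file, registry)
    gts = read_coco_ground_truth(gts_file, registry)
    return evaluate(preds, gts, calib=calib, oks_k=oks_k, thresholds=thresholds)


def _landmark_bbox_fallback(
    gts: Sequence[GroundTruthAnnotation],
) -> Optional[tuple[float, float, float, float]]:
    """Bounding box of the annotated points, for annotations without a bbox."""
    if not gts:
        return None
    xs = [g.position.x for g in gts]
    ys = [g.position.y for g in gts]
    w, h = max(xs) - min(xs), max(ys) - min(ys)
    if w <= 0 or h <= 0:
        return None
    return (min(xs), min(ys), w, h)
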