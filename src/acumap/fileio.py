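"""File formats: the versioned landmark JSON schema, COCO keypoint ground
truth, COCO-style prediction results, and prediction CSV.

Numbers are written at full precision in JSON and 1-decimal fixed
precision in CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional, Union

from .errors import SchemaError
from .evaluation import GroundTruthAnnotation
from .geometry import Point
from .landmarks import SLOT_COUNTS, LandmarkSet
from .mapping import PredictedAcupoint
from .registry import Registry

LANDMARK_SCHEMA = "acumap-landmarks/1"

_REGION_CATEGORY_ID = {"hand": 1, "face": 2}


# ---------------------------------------------------------------- landmarks

def read_landmarks(path: Union[str, Path]) -> LandmarkSet:
    """Read and validate one landmark JSON file."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "$") from exc
    if not isinstance(raw, dict):
        raise SchemaError("document must be a JSON object", "$")
    if raw.get("schema") != LANDMARK_SCHEMA:
        raise SchemaError(
            f"expected schema {LANDMARK_SCHEMA!r}, got {raw.get('schema')!r}",
            "$.schema",
        )
    region = raw.get("region")
    if region not in SLOT_COUNTS:
        raise SchemaError(f"unknown region {region!r}", "$.region")
    space = raw.get("space", "pixel")
    if space not in ("pixel", "normalized"):
        raise SchemaError(f"unknown space {space!r}", "$.space")
    handedness = raw.get("handedness")
    if handedness not in (None, "left", "right"):
        raise SchemaError(f"unknown handedness {handedness!r}", "$.handedness")
    image_size = raw.get("image_size")
    if image_size is not None:
        if (not isinstance(image_size, (list, tuple)) or len(image_size) != 2
                or not all(isinstance(v, (int, float)) and v > 0 for v in image_size)):
            raise SchemaError("image_size must be [width, height] > 0", "$.image_size")
        image_size = (int(image_size[0]), int(image_size[1]))
    points_raw = raw.get("points")
    if not isinstance(points_raw, list):
        raise SchemaError("points must be a list", "$.points")
    expected = SLOT_COUNTS[region]
    if len(points_raw) != expected:
        raise SchemaError(
            f"{region} needs exactly {expected} point slots, got {len(points_raw)}",
            "$.points",
        )
    points: list[Optional[Point]] = []
    for i, entry in enumerate(points_raw):
        if entry is None:
            points.append(None)
            continue
        if not (isinstance(entry, list) and len(entry) in (2, 3)
                and all(isinstance(v, (int, float)) for v in entry)):
            raise SchemaError("point must be null or [x, y] / [x, y, z]",
                              f"$.points[{i}]")
        z = float(entry[2]) if len(entry) == 3 else 0.0
        try:
            point = Point(float(entry[0]), float(entry[1]), z)
        except Exception as exc:
            raise SchemaError(str(exc), f"$.points[{i}]") from exc
        points.append(point)
    try:
        return LandmarkSet(
            region=region, points=tuple(points), handedness=handedness,
            space=space, image_size=image_size,
        )
    except Exception as exc:
        raise SchemaError(str(exc), "$") from exc


def write_landmarks(landmarks: LandmarkSet, path: Union[str, Path]) -> None:
    doc = {
        "schema": LANDMARK_SCHEMA,
        "region": landmarks.region,
        "handedness": landmarks.handedness,
        "space": landmarks.space,
        "image_size": list(landmarks.image_size) if landmarks.image_size else None,
        "points": [
            None if p is None else [p.x, p.y, p.z] for p in landmarks.points
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ------------------------------------------------------------------- COCO GT

def build_coco_ground_truth(scene, registry: Registry) -> dict:
    """COCO keypoint document for a synthetic scene.

    One category per region whose ordered keypoint names are the acupoint
    codes; one annotation per image with (x, y, v) triplets, v=2 for
    visible points and v=0 (x=y=0) otherwise; bbox encloses the landmarks.
    """
    region = scene.spec.region
    codes = [e.code for e in registry.region_entries(region)]
    category = {
        "id": _REGION_CATEGORY_ID[region],
        "name": region,
        "supercategory": "body",
        "keypoints": codes,
        "skeleton": [],
    }
    images, annotations = [], []
    for i, (landmarks, annos) in enumerate(
            zip(scene.landmark_sets, scene.annotations)):
        image_id = i + 1
        w, h = landmarks.image_size or scene.spec.image_size
        images.append({
            "id": image_id,
            "width": int(w),
            "height": int(h),
            "file_name": f"landmarks_{i:05d}.json",
        })
        pts = landmarks.present_points()
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        bbox = [min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys)]
        by_code = {code: (pos, visible) for code, pos, visible in annos}
        keypoints: list[float] = []
        n_visible = 0
        for code in codes:
            pos, visible = by_code.get(code, (Point(0.0, 0.0), False))
            if visible:
                keypoints.extend([pos.x, pos.y, 2])
                n_visible += 1
            else:
                keypoints.extend([0.0, 0.0, 0])
        annotations.append({
            "id": image_id,
            "image_id": image_id,
            "category_id": category["id"],
            "keypoints": keypoints,
            "num_keypoints": n_visible,
            "bbox": bbox,
            "area": bbox[2] * bbox[3],
            "iscrowd": 0,
        })
    return {"images": images, "annotations": annotations,
            "categories": [category]}


def read_coco_ground_truth(
    path: Union[str, Path], registry: Registry
) -> dict[object, list[GroundTruthAnnotation]]:
    """Read a COCO keypoint file into per-image annotation lists.

    Keypoint names must resolve to registry codes; visibility-0 entries
    are skipped; the annotation bbox is preserved on every point.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "$") from exc
    if not isinstance(raw, dict) or "categories" not in raw:
        raise SchemaError("missing 'categories' block", "$.categories")
    known = set(registry.codes())
    keypoints_by_category: dict[int, list[str]] = {}
    for ci, cat in enumerate(raw["categories"]):
        names = cat.get("keypoints", [])
        unmatched = [n for n in names if n not in known]
        if unmatched:
            raise SchemaError(
                f"keypoint names not in registry: {unmatched}",
                f"$.categories[{ci}].keypoints",
            )
        keypoints_by_category[cat["id"]] = names
    out: dict[object, list[GroundTruthAnnotation]] = {}
    for ai, anno in enumerate(raw.get("annotations", [])):
        cat_id = anno.get("category_id")
        if cat_id not in keypoints_by_category:
            raise SchemaError(f"unknown category_id {cat_id!r}",
                              f"$.annotations[{ai}]")
        names = keypoints_by_category[cat_id]
        flat = anno.get("keypoints", [])
        if len(flat) != 3 * len(names):
            raise SchemaError(
                f"expected {3 * len(names)} keypoint values, got {len(flat)}",
                f"$.annotations[{ai}].keypoints",
            )
        bbox = tuple(anno["bbox"]) if "bbox" in anno else None
        image_id = anno.get("image_id")
        bucket = out.setdefault(image_id, [])
        for ki, code in enumerate(names):
            x, y, v = flat[3 * ki:3 * ki + 3]
            if v <= 0:
                continue
            bucket.append(GroundTruthAnnotation(
                image_id=image_id, code=code,
                position=Point(float(x), float(y)), bbox=bbox,
            ))
    return out


# --------------------------------------------------------------- predictions

def write_predictions_csv(
    predictions: list[PredictedAcupoint],
    path: Union[str, Path],
    image_id: Optional[object] = None,
) -> None:
    """CSV with code, x, y, posture, visible (coordinates at 1 decimal)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["code", "x", "y", "posture", "visible"]
        if image_id is not None:
            header.insert(0, "image_id")
        writer.writerow(header)
        for pred in predictions:
            x = f"{pred.position.x:.1f}" if pred.position else ""
            y = f"{pred.position.y:.1f}" if pred.position else ""
            row = [pred.code, x, y, pred.posture, int(pred.visible)]
            if image_id is not None:
                row.insert(0, image_id)
            writer.writerow(row)


def write_coco_results(
    preds_by_image: dict[object, list[tuple[PredictedAcupoint, float]]],
    registry: Registry,
    region: str,
    path: Union[str, Path],
) -> None:
    """COCO-style keypoint results, one entry per image."""
    codes = [e.code for e in registry.region_entries(region)]
    results = []
    for image_id in sorted(preds_by_image, key=str):
        preds = preds_by_image[image_id]
        by_code = {p.code: (p, conf) for p, conf in preds}
        keypoints: list[float] = []
        postures = set()
        score = 1.0
        for code in codes:
            entry = by_code.get(code)
            if entry is None or not entry[0].visible or entry[0].position is None:
                keypoints.extend([0.0, 0.0, 0])
                continue
            pred, conf = entry
            keypoints.extend([pred.position.x, pred.position.y, 2])
            postures.add(pred.posture)
            score = min(score, conf)
        results.append({
            "image_id": image_id,
            "category_id": _REGION_CATEGORY_ID[region],
            "keypoints": keypoints,
            "score": score,
            "posture": sorted(postures)[0] if postures else None,
        })
    Path(path).write_text(json.dumps(results, indent=1, sort_keys=True) + "\n")


def read_coco_results(
    path: Union[str, Path], registry: Registry
) -> dict[object, list[tuple[PredictedAcupoint, float]]]:
    """Read COCO-style results back into per-image prediction lists."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "$") from exc
    if not isinstance(raw, list):
        raise SchemaError("results document must be a JSON array", "$")
    region_by_id = {v: k for k, v in _REGION_CATEGORY_ID.items()}
    out: dict[object, list[tuple[PredictedAcupoint, float]]] = {}
    for ri, result in enumerate(raw):
        region = region_by_id.get(result.get("category_id"))
        if region is None:
            raise SchemaError(f"unknown category_id {result.get('category_id')!r}",
                              f"$[{ri}]")
        codes = [e.code for e in registry.region_entries(region)]
        flat = result.get("keypoints", [])
        if len(flat) != 3 * len(codes):
            raise SchemaError(
                f"expected {3 * len(codes)} keypoint values, got {len(flat)}",
                f"$[{ri}].keypoints",
            )
        posture = result.get("posture") or "unknown"
        score = float(result.get("score", 1.0))
        bucket = out.setdefault(result.get("image_id"), [])
        for ki, code in enumerate(codes):
            x, y, v = flat[3 * ki:3 * ki + 3]
            if v <= 0:
                bucket.append((PredictedAcupoint(
                    code=code, position=None, posture=posture, visible=False),
                    score))
            else:
                bucket.append((PredictedAcupoint(
                    code=code, position=Point(float(x), float(y)),
                    posture=posture, visible=True), score))
    return out
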