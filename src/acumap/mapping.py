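"""Evaluate declarative mapping rules against landmark sets.

Rules are authored for right hands and evaluated in pixel space; left
hands are mirrored about the vertical image midline before evaluation
and the resulting points mirrored back, so one rule table serves both
hands. z coordinates participate in posture classification only — rule
projection is 2D image-space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional

from .errors import InvalidInputError, RuleEvaluationError
from .geometry import Point, euclidean_distance, fraction_point, midpoint, point_along
from .landmarks import LandmarkSet
from .posture import classify_face_pose, classify_hand_posture
from .registry import MappingRule, Registry, RuleStep

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictedAcupoint:
    """A named predicted coordinate plus the posture that selected its rule."""

    code: str
    position: Optional[Point]
    posture: str
    visible: bool

    def __post_init__(self) -> None:
        if self.visible and self.position is None:
            raise InvalidInputError(f"{self.code}: visible prediction needs a position")


def _resolve(ref: tuple[str, int], landmarks: LandmarkSet,
             computed: list[Point], code: str) -> Point:
    kind, idx = ref
    if kind == "step":
        return computed[idx]
    point = landmarks.points[idx]
    if point is None:
        raise RuleEvaluationError(f"{code}: landmark slot {idx} is absent")
    return point


def _flat(p: Point) -> Point:
    return Point(p.x, p.y, 0.0)


def apply_rule(rule: MappingRule, landmarks: LandmarkSet, code: str = "<rule>") -> Point:
    """Run a rule's steps in order; the last step's point is the result."""
    computed: list[Point] = []
    for step in rule.steps:
        computed.append(_apply_step(step, landmarks, computed, code))
    return computed[-1]


def _apply_step(step: RuleStep, landmarks: LandmarkSet,
                computed: list[Point], code: str) -> Point:
    if step.op == "anchor":
        idx = step.get("landmark")
        point = landmarks.points[idx]  # type: ignore[index]
        if point is None:
            raise RuleEvaluationError(f"{code}: landmark slot {idx} is absent")
        return _flat(point)
    if step.op == "midpoint":
        a = _resolve(step.get("a"), landmarks, computed, code)  # type: ignore[arg-type]
        b = _resolve(step.get("b"), landmarks, computed, code)  # type: ignore[arg-type]
        return _flat(midpoint(a, b))
    if step.op == "fraction":
        a = _resolve(step.get("a"), landmarks, computed, code)  # type: ignore[arg-type]
        b = _resolve(step.get("b"), landmarks, computed, code)  # type: ignore[arg-type]
        return _flat(fraction_point(a, b, step.get("t")))  # type: ignore[arg-type]
    if step.op == "toward":
        origin = _resolve(step.get("origin"), landmarks, computed, code)  # type: ignore[arg-type]
        target = _resolve(step.get("target"), landmarks, computed, code)  # type: ignore[arg-type]
        bi, bj = step.get("base")  # type: ignore[misc]
        base = euclidean_distance(
            _flat(_resolve(("landmark", bi), landmarks, computed, code)),
            _flat(_resolve(("landmark", bj), landmarks, computed, code)),
        )
        distance = step.get("scale") * base  # type: ignore[operator]
        return point_along(_flat(origin), _flat(target), distance)
    raise RuleEvaluationError(f"{code}: unknown step op {step.op!r}")


def mirror_landmarks(landmarks: LandmarkSet) -> LandmarkSet:
    """Reflect x about the vertical image midline and flip handedness."""
    if landmarks.space == "pixel":
        if landmarks.image_size is None:
            raise InvalidInputError("mirroring pixel-space landmarks needs image_size")
        width = float(landmarks.image_size[0])
    else:
        width = 1.0
    points = tuple(
        None if p is None else Point(width - p.x, p.y, p.z)
        for p in landmarks.points
    )
    flipped = {"left": "right", "right": "left", None: None}[landmarks.handedness]
    return replace(landmarks, points=points, handedness=flipped)


def _mirror_point(p: Point, width: float) -> Point:
    return Point(width - p.x, p.y, p.z)


def map_acupoints(landmarks: LandmarkSet, registry: Registry) -> list[PredictedAcupoint]:
    """Classify posture/pose, then evaluate every registry entry for the region.

    Output follows registry order, in pixel space; entries with no rule
    for the classified posture come back with ``visible=False``.
    """
    landmarks = landmarks.to_pixel()
    if landmarks.region == "hand":
        posture = classify_hand_posture(landmarks).label
        eval_set = landmarks
        mirror_back = landmarks.handedness == "left"
        if mirror_back:
            if landmarks.image_size is None:
                raise InvalidInputError("left-hand mapping needs image_size")
            eval_set = mirror_landmarks(landmarks)
        width = float(landmarks.image_size[0]) if landmarks.image_size else 0.0
    else:
        posture = classify_face_pose(landmarks).label
        eval_set = landmarks
        mirror_back = False
        width = 0.0
    logger.debug("classified %s as %r", landmarks.region, posture)

    predictions: list[PredictedAcupoint] = []
    for entry in registry.region_entries(landmarks.region):
        rule = entry.rule_for(posture)
        if rule is None:
            predictions.append(
                PredictedAcupoint(code=entry.code, position=None,
                                  posture=posture, visible=False)
            )
            continue
        try:
            point = apply_rule(rule, eval_set, code=entry.code)
        except Exception as exc:
            raise RuleEvaluationError(f"{entry.code}: {exc}") from exc
        if mirror_back:
            point = _mirror_point(point, width)
        predictions.append(
            PredictedAcupoint(code=entry.code, position=point,
                              posture=posture, visible=True)
        )
    return predictions


def overlay_predictions(image, predictions: list[PredictedAcupoint],
                        radius: int = 3, label: bool = True):
    """Return a copy of a PIL image with a labeled dot per visible prediction.

    Out-of-bounds predictions are skipped with a warning.
    """
    from PIL import ImageDraw

    out = image.copy()
    draw = ImageDraw.Draw(out)
    for pred in predictions:
        if not pred.visible or pred.position is None:
            continue
        x, y = round(pred.position.x), round(pred.position.y)
        if not (0 <= x < out.width and 0 <= y < out.height):
            warnings.warn(f"{pred.code}: prediction ({x}, {y}) outside image bounds",
                          stacklevel=2)
            continue
        draw.ellipse([x - radius, y - radius, x + radius, y + radius],
                     fill=(255, 0, 0))
        if label:
            draw.text((x + radius + 1, y - radius - 1), pred.code, fill=(255, 0, 0))
    return out
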