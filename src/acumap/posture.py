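"""Hand-posture and face-pose classification from landmark geometry.

A hand set is assigned one of four view labels (front, back, inside,
outside) from the angle between the palm-plane normal and the optical
axis; a face set is assigned one of three labels (center, left, right)
from a signed nose-to-contour asymmetry ratio. All numeric thresholds
are package conventions (configurable), not published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGeometryError, InvalidInputError
from .geometry import Point, Vector, angle_between, cross_product, euclidean_distance
from .landmarks import INDEX_MCP, PINKY_MCP, WRIST, LandmarkSet

HAND_POSTURES = ("front", "back", "inside", "outside")
FACE_POSES = ("center", "left", "right")

# Optical axis pointing from the scene toward the viewer (screen-space z
# is negative toward the viewer); a palm facing the camera has angle ~0.
VIEW_AXIS = Vector(0.0, 0.0, -1.0)

# Face-mesh slots used by the yaw proxy: nose tip plus the two cheek
# contour points at ear level (image-left and image-right in the
# canonical front-facing template).
NOSE_TIP = 1
CONTOUR_LEFT = 234
CONTOUR_RIGHT = 454


@dataclass(frozen=True)
class PalmFrame:
    """Three distinct palm-plane slots: a reference and two secondaries."""

    reference_index: int = WRIST
    secondary_indices: tuple[int, int] = (INDEX_MCP, PINKY_MCP)

    def __post_init__(self) -> None:
        idx = (self.reference_index, *self.secondary_indices)
        if len(set(idx)) != 3:
            raise InvalidInputError("palm frame indices must be distinct")


DEFAULT_PALM_FRAME = PalmFrame()


@dataclass(frozen=True)
class HandPosture:
    label: str
    palm_angle_deg: float
    normal: Vector


@dataclass(frozen=True)
class FacePose:
    label: str
    yaw_proxy: float


def palm_normal(hand: LandmarkSet, frame: PalmFrame = DEFAULT_PALM_FRAME) -> Vector:
    """Unit normal of the palm plane, oriented so that a palm facing the
    viewer yields ~(0, 0, -1) for either handedness.

    The normal is the cross product of the vectors from the reference
    slot to the two secondary slots; for left hands the sign is flipped
    so both hands share the facing convention.
    """
    ref = hand.slot(frame.reference_index)
    a = hand.slot(frame.secondary_indices[0])
    b = hand.slot(frame.secondary_indices[1])
    n = cross_product(a - ref, b - ref)
    if n.norm() <= 1e-12:
        raise DegenerateGeometryError("palm frame landmarks are collinear")
    n = n.unit()
    if hand.handedness == "left":
        n = n.scaled(-1.0)
    return n


def classify_hand_posture(
    hand: LandmarkSet,
    handedness: str | None = None,
    frame: PalmFrame = DEFAULT_PALM_FRAME,
    front_max_deg: float = 45.0,
    back_min_deg: float = 135.0,
) -> HandPosture:
    """Classify a 21-slot hand set into front/back/inside/outside.

    front for palm angle in [0, front_max_deg), back for
    [back_min_deg, 180]; otherwise the sign of the normal's x component
    decides inside vs outside (flipped convention for left hands).
    Boundary angles fall to the lower-named side of each half-open
    interval.
    """
    if handedness is not None:
        if handedness not in ("left", "right"):
            raise InvalidInputError(f"unknown handedness {handedness!r}")
        if hand.handedness is not None and hand.handedness != handedness:
            raise InvalidInputError("handedness argument contradicts landmark set")
        if hand.handedness is None:
            from dataclasses import replace

            hand = replace(hand, handedness=handedness)
    effective = hand.handedness or "right"
    n = palm_normal(hand, frame)
    theta = math.degrees(angle_between(n, VIEW_AXIS))
    if theta < front_max_deg:
        label = "front"
    elif theta >= back_min_deg:
        label = "back"
    else:
        x = n.dx if effective == "right" else -n.dx
        label = "inside" if x < 0 else "outside"
    return HandPosture(label=label, palm_angle_deg=theta, normal=n)


def face_yaw_proxy(face: LandmarkSet) -> float:
    """Signed relative difference of nose-tip-to-contour distances.

    Positive when the image-right half is foreshortened (head turned so
    the nose approaches the image-right contour), negative for the
    mirror case, ~0 for a frontal face. Scale- and translation-invariant.
    """
    try:
        nose = face.slot(NOSE_TIP)
        left = face.slot(CONTOUR_LEFT)
        right = face.slot(CONTOUR_RIGHT)
    except InvalidInputError as exc:
        raise InvalidInputError(f"yaw proxy landmarks missing: {exc}") from exc
    # Projected (2D) distances: depth must not cancel the asymmetry.
    d_left = euclidean_distance(Point(nose.x, nose.y), Point(left.x, left.y))
    d_right = euclidean_distance(Point(nose.x, nose.y), Point(right.x, right.y))
    total = d_left + d_right
    if total <= 1e-12:
        raise DegenerateGeometryError("degenerate face contour")
    return (d_left - d_right) / total


def classify_face_pose(face: LandmarkSet, center_threshold: float = 0.2) -> FacePose:
    """Classify a face set into center/left/right by the yaw proxy.

    |yaw| < center_threshold -> center; otherwise a positive proxy
    (image-right side compressed) means the head is turned to the
    "right" label, negative to "left".
    """
    yaw = face_yaw_proxy(face)
    if abs(yaw) < center_threshold:
        label = "center"
    else:
        label = "right" if yaw > 0 else "left"
    return FacePose(label=label, yaw_proxy=yaw)
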