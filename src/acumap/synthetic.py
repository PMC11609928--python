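"""Seeded generators for hand/face landmark sets and annotated evaluation
scenes, so every other module is testable without external data.

Canonical templates are authored once in a unit box (x, y in [0, 1],
y down, z in template units, negative toward the viewer) with
anatomically plausible *relative* proportions; absolute realism is not
required because all downstream computation is relative. Posture/pose is
produced by rotating the template about the vertical axis; the requested
label is always recovered by the classifiers at jitter 0.

Randomness: one ``numpy`` generator seeded per call; jitter draws are
slot-major (dx then dy per slot, ascending slot index).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .geometry import Point
from .landmarks import FACE_SLOT_COUNT, HAND_SLOT_COUNT, LandmarkSet
from .mapping import map_acupoints, mirror_landmarks
from .posture import FACE_POSES, HAND_POSTURES
from .registry import Registry

DEFAULT_IMAGE_SIZE = (640, 480)

# Right hand, palm toward the viewer, fingers up, thumb on the image-right
# side. Slots: 0 wrist, 1-4 thumb, 5-8 index, 9-12 middle, 13-16 ring,
# 17-20 pinky (base -> tip). Small negative z on the fingertips gives the
# template a mild, realistic cupping.
_HAND_TEMPLATE: tuple[tuple[float, float, float], ...] = (
    (0.50, 0.90, 0.000),  # 0 wrist
    (0.63, 0.82, -0.005),  # 1 thumb CMC
    (0.72, 0.72, -0.010),  # 2 thumb MCP
    (0.78, 0.63, -0.015),  # 3 thumb IP
    (0.83, 0.55, -0.020),  # 4 thumb tip
    (0.62, 0.52, 0.000),  # 5 index MCP
    (0.64, 0.38, -0.008),  # 6 index PIP
    (0.65, 0.28, -0.014),  # 7 index DIP
    (0.66, 0.20, -0.020),  # 8 index tip
    (0.53, 0.50, 0.000),  # 9 middle MCP
    (0.53, 0.34, -0.008),  # 10 middle PIP
    (0.53, 0.23, -0.014),  # 11 middle DIP
    (0.53, 0.14, -0.020),  # 12 middle tip
    (0.44, 0.51, 0.000),  # 13 ring MCP
    (0.43, 0.36, -0.008),  # 14 ring PIP
    (0.42, 0.26, -0.014),  # 15 ring DIP
    (0.41, 0.18, -0.020),  # 16 ring tip
    (0.36, 0.54, 0.000),  # 17 pinky MCP
    (0.34, 0.42, -0.008),  # 18 pinky PIP
    (0.33, 0.34, -0.014),  # 19 pinky DIP
    (0.32, 0.27, -0.020),  # 20 pinky tip
)

# Rotation about the vertical axis that realizes each hand posture for the
# right-hand template (front normal starts at (0, 0, -1)). 70 degrees, not
# 90, for the side views so the 2D projection stays non-degenerate.
_POSTURE_YAW_DEG = {"front": 0.0, "inside": 70.0, "outside": -70.0, "back": 180.0}

# Face template key slots (front view; image-left side uses the low
# indices of each bilateral pair). Indices follow the common 468-slot
# face-mesh numbering for every slot a mapping rule or the classifier
# references; the remaining slots are deterministic ellipse filler.
_FACE_KEY_SLOTS: dict[int, tuple[float, float]] = {
    0: (0.50, 0.62),  # upper lip top
    1: (0.50, 0.50),  # nose tip
    2: (0.50, 0.56),  # nose base
    6: (0.50, 0.38),  # nose bridge
    10: (0.50, 0.10),  # forehead top
    17: (0.50, 0.70),  # lower lip bottom
    33: (0.30, 0.38),  # L eye outer corner
    50: (0.32, 0.55),  # L cheek
    61: (0.40, 0.66),  # L mouth corner
    64: (0.44, 0.56),  # L nose ala
    70: (0.27, 0.31),  # L brow outer
    105: (0.34, 0.29),  # L brow mid
    107: (0.42, 0.30),  # L brow inner
    133: (0.41, 0.39),  # L eye inner corner
    145: (0.35, 0.41),  # L lower eyelid
    151: (0.50, 0.22),  # mid forehead
    152: (0.50, 0.88),  # chin
    168: (0.50, 0.34),  # nasion
    172: (0.28, 0.72),  # L jaw angle
    234: (0.20, 0.48),  # L contour at ear level
    263: (0.70, 0.38),  # R eye outer corner
    280: (0.68, 0.55),  # R cheek
    291: (0.60, 0.66),  # R mouth corner
    294: (0.56, 0.56),  # R nose ala
    300: (0.73, 0.31),  # R brow outer
    334: (0.66, 0.29),  # R brow mid
    336: (0.58, 0.30),  # R brow inner
    362: (0.59, 0.39),  # R eye inner corner
    374: (0.65, 0.41),  # R lower eyelid
    397: (0.72, 0.72),  # R jaw angle
    454: (0.80, 0.48),  # R contour at ear level
}

_POSE_YAW_DEG = {"center": 0.0, "left": 25.0, "right": -25.0}

# Bilateral slot pairs (image-left slot, image-right slot) that swap roles
# when a face is mirrored: a landmark provider run on a mirrored image
# re-assigns the side-specific indices, so a faithful synthetic mirror
# must swap them too (a raw point reflection is an isometry and would
# leave every distance-based quantity unchanged).
BILATERAL_FACE_PAIRS: tuple[tuple[int, int], ...] = (
    (33, 263), (50, 280), (61, 291), (64, 294), (70, 300), (105, 334),
    (107, 336), (133, 362), (145, 374), (172, 397), (234, 454),
)


def mirror_face_landmarks(face: LandmarkSet) -> LandmarkSet:
    """Reflect a face set about the vertical image midline, swapping the
    bilateral slot indices so side semantics are preserved."""
    if face.region != "face":
        raise InvalidInputError("mirror_face_landmarks expects a face set")
    if face.space == "pixel":
        if face.image_size is None:
            raise InvalidInputError("mirroring pixel-space landmarks needs image_size")
        width = float(face.image_size[0])
    else:
        width = 1.0
    pts = [None if p is None else Point(width - p.x, p.y, p.z)
           for p in face.points]
    for a, b in BILATERAL_FACE_PAIRS:
        pts[a], pts[b] = pts[b], pts[a]
    return face.with_points(tuple(pts))


def _face_depth(x: float, y: float) -> float:
    """Ellipsoid-ish depth: central features protrude toward the viewer."""
    r2 = ((x - 0.5) / 0.32) ** 2 + ((y - 0.5) / 0.45) ** 2
    return -0.35 * max(0.0, 1.0 - r2)


def _face_template() -> list[tuple[float, float, float]]:
    pts: list[tuple[float, float, float]] = []
    for i in range(FACE_SLOT_COUNT):
        if i in _FACE_KEY_SLOTS:
            x, y = _FACE_KEY_SLOTS[i]
        else:
            # Deterministic filler on concentric ellipses.
            angle = 2.0 * math.pi * i / FACE_SLOT_COUNT
            radial = 0.25 + 0.65 * ((i * 37) % 97) / 97.0
            x = 0.5 + 0.40 * radial * math.cos(angle)
            y = 0.5 + 0.45 * radial * math.sin(angle)
        z = _face_depth(x, y)
        if i == 1:  # nose tip protrudes beyond the ellipsoid
            z -= 0.08
        pts.append((x, y, z))
    return pts


_FACE_TEMPLATE: tuple[tuple[float, float, float], ...] = tuple(_face_template())


def _rotate_yaw(pts, deg: float, cx: float = 0.5):
    """Rotate about the vertical axis through x = cx, z = 0."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return [
        (cx + (x - cx) * c + z * s, y, -(x - cx) * s + z * c)
        for x, y, z in pts
    ]


def _rotate_inplane(pts, deg: float, cx: float = 0.5, cy: float = 0.5):
    """Rotate about the optical axis through (cx, cy)."""
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return [
        (cx + (x - cx) * c - (y - cy) * s, cy + (x - cx) * s + (y - cy) * c, z)
        for x, y, z in pts
    ]


def _to_pixels(pts, scale: float, image_size: tuple[int, int],
               center: Optional[tuple[float, float]] = None):
    """Place the unit-box template into pixel space.

    ``scale`` multiplies a base extent of 0.75 * min(image dims); z shares
    the x unit.
    """
    w, h = image_size
    extent = 0.75 * min(w, h) * scale
    cx = w / 2.0 if center is None else center[0]
    cy = h / 2.0 if center is None else center[1]
    return [
        (cx + (x - 0.5) * extent, cy + (y - 0.5) * extent, z * extent)
        for x, y, z in pts
    ]


def _jitter(pts, jitter_sd: float, rng: np.random.Generator):
    """Isotropic Gaussian jitter on x and y, slot-major draw order."""
    if jitter_sd == 0:
        return list(pts)
    out = []
    for x, y, z in pts:
        dx, dy = rng.normal(0.0, jitter_sd, size=2)
        out.append((x + dx, y + dy, z))
    return out


def gen_hand_landmarks(
    posture: str,
    handedness: str = "right",
    scale: float = 1.0,
    rotation: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    center: Optional[tuple[float, float]] = None,
) -> LandmarkSet:
    """21-slot hand set whose classified posture equals ``posture`` at jitter 0.

    ``rotation`` is an extra in-plane rotation in degrees; ``scale``
    multiplies the template extent; jitter is Gaussian per x/y coordinate.
    Left hands are mirrored copies of the right-hand construction.
    """
    if posture not in HAND_POSTURES:
        raise InvalidInputError(f"unknown hand posture {posture!r}")
    if handedness not in ("left", "right"):
        raise InvalidInputError(f"unknown handedness {handedness!r}")
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    rng = np.random.default_rng(seed)
    pts = _rotate_yaw(_HAND_TEMPLATE, _POSTURE_YAW_DEG[posture])
    pts = _rotate_inplane(pts, rotation)
    pts = _to_pixels(pts, scale, image_size, center)
    pts = _jitter(pts, jitter_sd, rng)
    hand = LandmarkSet(
        region="hand",
        points=tuple(Point(x, y, z) for x, y, z in pts),
        handedness="right",
        space="pixel",
        image_size=image_size,
    )
    if handedness == "left":
        hand = mirror_landmarks(hand)
    return hand


def gen_face_landmarks(
    pose: str,
    scale: float = 1.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    rotation: float = 0.0,
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    center: Optional[tuple[float, float]] = None,
) -> LandmarkSet:
    """468-slot face set whose classified pose equals ``pose`` at jitter 0."""
    if pose not in FACE_POSES:
        raise InvalidInputError(f"unknown face pose {pose!r}")
    if scale <= 0:
        raise InvalidInputError("scale must be positive")
    rng = np.random.default_rng(seed)
    pts = _rotate_yaw(_FACE_TEMPLATE, _POSE_YAW_DEG[pose])
    pts = _rotate_inplane(pts, rotation)
    pts = _to_pixels(pts, scale, image_size, center)
    pts = _jitter(pts, jitter_sd, rng)
    return LandmarkSet(
        region="face",
        points=tuple(Point(x, y, z) for x, y, z in pts),
        space="pixel",
        image_size=image_size,
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters for one synthetic annotated evaluation scene."""

    n_images: int
    region: str = "hand"
    posture_mix: tuple[tuple[str, float], ...] = (("front", 0.5), ("back", 0.5))
    scale_range: tuple[float, float] = (0.8, 1.2)
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    jitter_sd: float = 0.0
    seed: int = 0
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE

    def __post_init__(self) -> None:
        if self.n_images < 0:
            raise InvalidInputError("n_images must be nonnegative")
        if self.region not in ("hand", "face"):
            raise InvalidInputError(f"unknown region {self.region!r}")
        if self.jitter_sd < 0:
            raise InvalidInputError("jitter_sd must be nonnegative")
        labels = HAND_POSTURES if self.region == "hand" else FACE_POSES
        total = 0.0
        for label, weight in self.posture_mix:
            if label not in labels:
                raise InvalidInputError(f"label {label!r} invalid for {self.region}")
            if weight < 0:
                raise InvalidInputError("posture weights must be nonnegative")
            total += weight
        if self.posture_mix and total <= 0:
            raise InvalidInputError("posture weights must sum to a positive value")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise InvalidInputError("invalid scale_range")

    @classmethod
    def from_dict(cls, raw: dict) -> "SceneSpec":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown scene-spec keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "posture_mix" in kwargs and isinstance(kwargs["posture_mix"], dict):
            kwargs["posture_mix"] = tuple(kwargs["posture_mix"].items())
        for key in ("scale_range", "rotation_range", "image_size"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class Scene:
    """In-memory scene: per-image landmark sets plus ground-truth annotations."""

    spec: SceneSpec
    landmark_sets: list[LandmarkSet] = field(default_factory=list)
    # image index -> list of (code, ground-truth Point, visible)
    annotations: list[list[tuple[str, Point, bool]]] = field(default_factory=list)


def gen_eval_scene(spec: SceneSpec, registry: Registry) -> Scene:
    """Generate landmark sets and rule-derived ground truth for evaluation.

    Ground truth for each image is exactly the mapping-engine output on the
    clean landmarks, perturbed by ``jitter_sd`` Gaussian noise per x/y
    coordinate (so jitter 0 closes the loop: predictions == ground truth).
    """
    rng = np.random.default_rng(spec.seed)
    labels = [label for label, _ in spec.posture_mix]
    weights = np.array([w for _, w in spec.posture_mix], dtype=float)
    weights = weights / weights.sum() if len(weights) else weights
    scene = Scene(spec=spec)
    for i in range(spec.n_images):
        label = str(rng.choice(labels, p=weights))
        scale = float(rng.uniform(*spec.scale_range))
        rotation = float(rng.uniform(*spec.rotation_range))
        child_seed = int(rng.integers(0, 2**63 - 1))
        if spec.region == "hand":
            handedness = "right" if rng.random() < 0.5 else "left"
            landmarks = gen_hand_landmarks(
                label, handedness=handedness, scale=scale, rotation=rotation,
                jitter_sd=0.0, seed=child_seed, image_size=spec.image_size,
            )
        else:
            landmarks = gen_face_landmarks(
                label, scale=scale, jitter_sd=0.0, seed=child_seed,
                rotation=rotation, image_size=spec.image_size,
            )
        predictions = map_acupoints(landmarks, registry)
        annos: list[tuple[str, Point, bool]] = []
        for pred in predictions:
            if pred.visible and pred.position is not None:
                pos = pred.position
                if spec.jitter_sd > 0:
                    dx, dy = rng.normal(0.0, spec.jitter_sd, size=2)
                    pos = Point(pos.x + dx, pos.y + dy)
                annos.append((pred.code, pos, True))
            else:
                annos.append((pred.code, Point(0.0, 0.0), False))
        scene.landmark_sets.append(landmarks)
        scene.annotations.append(annos)
    return scene


def write_scene(scene: Scene, registry: Registry, out_dir: Path) -> tuple[list[Path], Path]:
    """Write per-image landmark JSON files and one COCO keypoint GT file."""
    from .fileio import build_coco_ground_truth, write_landmarks

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    landmark_paths: list[Path] = []
    for i, landmarks in enumerate(scene.landmark_sets):
        path = out_dir / f"landmarks_{i:05d}.json"
        write_landmarks(landmarks, path)
        landmark_paths.append(path)
    coco = build_coco_ground_truth(scene, registry)
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(coco, indent=1, sort_keys=True) + "\n")
    return landmark_paths, gt_path
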