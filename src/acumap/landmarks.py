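"""Indexed landmark collections for one hand (21 slots) or face (468 slots)."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import InvalidInputError
from .geometry import Point

HAND_SLOT_COUNT = 21
FACE_SLOT_COUNT = 468

SLOT_COUNTS = {"hand": HAND_SLOT_COUNT, "face": FACE_SLOT_COUNT}

# Hand slot semantics follow the common 21-point schema: 0 wrist,
# 1-4 thumb, 5-8 index, 9-12 middle, 13-16 ring, 17-20 pinky
# (base -> tip within each finger).
WRIST = 0
THUMB_TIP = 4
INDEX_MCP = 5
INDEX_TIP = 8
MIDDLE_MCP = 9
MIDDLE_TIP = 12
RING_MCP = 13
RING_TIP = 16
PINKY_MCP = 17
PINKY_TIP = 20


@dataclass(frozen=True)
class LandmarkSet:
    """Landmarks for one region with an explicit coordinate-space tag.

    ``points`` has exactly 21 (hand) or 468 (face) entries; missing slots
    are ``None``. ``space`` is either ``"pixel"`` or ``"normalized"``;
    normalized coordinates must lie in [0, 1] and require ``image_size``
    (width, height) for conversion to pixel space.
    """

    region: str
    points: tuple[Optional[Point], ...]
    handedness: Optional[str] = None
    space: str = "pixel"
    image_size: Optional[tuple[int, int]] = None
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.region not in SLOT_COUNTS:
            raise InvalidInputError(f"unknown region {self.region!r}")
        expected = SLOT_COUNTS[self.region]
        if len(self.points) != expected:
            raise InvalidInputError(
                f"{self.region} landmark set needs {expected} slots, "
                f"got {len(self.points)}"
            )
        if self.space not in ("pixel", "normalized"):
            raise InvalidInputError(f"unknown coordinate space {self.space!r}")
        if self.handedness not in (None, "left", "right"):
            raise InvalidInputError(f"unknown handedness {self.handedness!r}")
        if self.space == "normalized":
            for i, p in enumerate(self.points):
                if p is None:
                    continue
                if not (0.0 <= p.x <= 1.0 and 0.0 <= p.y <= 1.0):
                    raise InvalidInputError(
                        f"normalized coordinate out of [0,1] at slot {i}: "
                        f"({p.x}, {p.y})"
                    )

    def slot(self, index: int) -> Point:
        p = self.points[index]
        if p is None:
            raise InvalidInputError(f"landmark slot {index} is absent")
        return p

    def present_points(self) -> list[Point]:
        return [p for p in self.points if p is not None]

    def to_pixel(self) -> "LandmarkSet":
        """Scale normalized coordinates by image width/height."""
        if self.space == "pixel":
            return self
        if self.image_size is None:
            raise InvalidInputError(
                "image_size required to convert normalized coordinates"
            )
        w, h = self.image_size
        pts = tuple(
            None if p is None else Point(p.x * w, p.y * h, p.z * w)
            for p in self.points
        )
        return replace(self, points=pts, space="pixel")

    def with_points(self, points: Sequence[Optional[Point]]) -> "LandmarkSet":
        return replace(self, points=tuple(points))
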