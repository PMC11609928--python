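"""Vector/point primitives used by every mapping rule and metric.

Coordinate convention: image pixel space with origin at the top-left
corner, x increasing rightward, y increasing downward, and z increasing
away from the viewer (so a surface facing the camera has a normal with a
negative z component). 2D points behave as z = 0 in 3D operations. All
arithmetic is double precision; comparisons use absolute tolerance 1e-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateGeometryError, InvalidInputError

ATOL = 1e-9


@dataclass(frozen=True)
class Point:
    """A 2D/3D location; ``z`` defaults to 0 for planar points."""

    x: float
    y: float
    z: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"non-finite coordinate {name}={v!r}")

    def to_tuple(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    def __sub__(self, other: "Point") -> "Vector":
        return Vector(self.x - other.x, self.y - other.y, self.z - other.z)

    def translate(self, v: "Vector") -> "Point":
        return Point(self.x + v.dx, self.y + v.dy, self.z + v.dz)


@dataclass(frozen=True)
class Vector:
    """A displacement with the same units as :class:`Point`."""

    dx: float
    dy: float
    dz: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"non-finite component {name}={v!r}")

    def norm(self) -> float:
        return math.sqrt(self.dx**2 + self.dy**2 + self.dz**2)

    def scaled(self, s: float) -> "Vector":
        return Vector(self.dx * s, self.dy * s, self.dz * s)

    def unit(self) -> "Vector":
        n = self.norm()
        if n <= ATOL:
            raise DegenerateGeometryError("cannot normalize a zero vector")
        return self.scaled(1.0 / n)

    def dot(self, other: "Vector") -> float:
        return self.dx * other.dx + self.dy * other.dy + self.dz * other.dz


def euclidean_distance(p: Point, q: Point) -> float:
    """Length of the straight segment between ``p`` and ``q``."""
    return (p - q).norm()


def angle_between(u: Vector, v: Vector) -> float:
    """Angle in radians in [0, pi] between two nonzero vectors.

    The cosine is clamped to [-1, 1] before the arccos so that rounding
    at the parallel/antiparallel limits cannot produce NaN.
    """
    nu, nv = u.norm(), v.norm()
    if nu <= ATOL or nv <= ATOL:
        raise DegenerateGeometryError("angle undefined for zero vector")
    c = u.dot(v) / (nu * nv)
    return math.acos(max(-1.0, min(1.0, c)))


def cross_product(u: Vector, v: Vector) -> Vector:
    """Right-handed cross product; parallel inputs yield the zero vector."""
    return Vector(
        u.dy * v.dz - u.dz * v.dy,
        u.dz * v.dx - u.dx * v.dz,
        u.dx * v.dy - u.dy * v.dx,
    )


def midpoint(p: Point, q: Point) -> Point:
    """Componentwise mean of the two points."""
    return Point((p.x + q.x) / 2.0, (p.y + q.y) / 2.0, (p.z + q.z) / 2.0)


def point_along(origin: Point, target: Point, distance: float) -> Point:
    """Point on the ray origin->target at ``distance`` from the origin.

    ``distance`` may exceed the origin-target separation (extrapolation
    is allowed) and may be 0 (returns the origin).
    """
    if not math.isfinite(distance):
        raise InvalidInputError(f"non-finite distance {distance!r}")
    direction = target - origin
    if direction.norm() <= ATOL:
        raise DegenerateGeometryError("origin and target coincide")
    return origin.translate(direction.unit().scaled(distance))


def fraction_point(p: Point, q: Point, t: float) -> Point:
    """Affine combination p + t*(q - p); t outside [0, 1] extrapolates."""
    if not math.isfinite(t):
        raise InvalidInputError(f"non-finite fraction {t!r}")
    return Point(
        p.x + t * (q.x - p.x),
        p.y + t * (q.y - p.y),
        p.z + t * (q.z - p.z),
    )
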