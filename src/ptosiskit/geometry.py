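"""Geometric substrate: per-eye annotation types and polygon utilities.

Coordinate convention, used repo-wide: 0-based image pixels, ``x`` increasing
rightward (columns), ``y`` increasing downward (rows). Values may be
fractional (subpixel).

An :class:`EyeAnnotation` bundles everything the measurements need: a
circular iris observation, the upper and lower lid contours (ordered from the
medial to the lateral canthus) and the two canthi. The closed eye outline is
the upper lid traversed medial→lateral followed by the lower lid
lateral→medial; it must be a simple polygon with positive area.

Angles for radial measurements live in an *eye-local* frame so that left and
right eyes are directly comparable: 0° points toward the lateral canthus and
90° toward the upper lid, i.e. counterclockwise in a y-up frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .errors import InvalidAnnotationError

__all__ = [
    "Point2D",
    "LidContour",
    "IrisObservation",
    "EyeAnnotation",
    "eye_polygon",
    "lateral_sign",
    "ray_direction",
    "ray_polygon_distance",
    "load_annotations",
    "save_annotations",
]

#: maximum distance (px) allowed between a lid endpoint and its canthus
CANTHUS_TOL = 0.5


@dataclass(frozen=True)
class Point2D:
    """A subpixel image location (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidAnnotationError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class LidContour:
    """An ordered open polyline along one lid margin, medial → lateral.

    The x-coordinates must be strictly monotone (increasing or decreasing
    depending on which side of the face the eye is on), so the curve is a
    function of the image column and can be evaluated by linear
    interpolation.
    """

    points: tuple[Point2D, ...]
    role: Literal["upper", "lower"]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise InvalidAnnotationError("lid contour needs at least 3 points")
        xs = np.array([p.x for p in self.points])
        dx = np.diff(xs)
        if not (np.all(dx > 0) or np.all(dx < 0)):
            raise InvalidAnnotationError(
                f"{self.role} lid x-coordinates are not strictly monotone"
            )
        if self.role not in ("upper", "lower"):
            raise InvalidAnnotationError(f"unknown lid role {self.role!r}")

    @classmethod
    def from_array(cls, xy: Sequence[Sequence[float]], role: str) -> "LidContour":
        return cls(tuple(Point2D(float(x), float(y)) for x, y in xy), role)  # type: ignore[arg-type]

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of the polyline vertices."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    @property
    def x_range(self) -> tuple[float, float]:
        xs = self.xy[:, 0]
        return float(xs.min()), float(xs.max())

    def y_at(self, x: float | np.ndarray) -> np.ndarray:
        """Lid height (image row) at column(s) ``x`` by linear interpolation.

        Raises if any query column lies outside the contour's span.
        """
        arr = self.xy
        xs, ys = arr[:, 0], arr[:, 1]
        if xs[0] > xs[-1]:
            xs, ys = xs[::-1], ys[::-1]
        xq = np.atleast_1d(np.asarray(x, dtype=float))
        if np.any(xq < xs[0] - 1e-9) or np.any(xq > xs[-1] + 1e-9):
            raise InvalidAnnotationError(
                f"column query outside {self.role} lid span [{xs[0]}, {xs[-1]}]"
            )
        out = np.interp(xq, xs, ys)
        return out if np.ndim(x) else out[0]

    def spans(self, x: float) -> bool:
        lo, hi = self.x_range
        return lo - 1e-9 <= x <= hi + 1e-9

    def translated(self, dx: float, dy: float) -> "LidContour":
        return LidContour(
            tuple(Point2D(p.x + dx, p.y + dy) for p in self.points), self.role
        )


@dataclass(frozen=True)
class IrisObservation:
    """Circular iris model: center and radius in pixels.

    The iris *top point* is ``(center.x, center.y - radius)``; its distance to
    the center is the scale reference r1 of the marginal reflex ratio. Using
    the radius rather than a detected top point keeps r1 well-defined when a
    drooping lid occludes the physical iris top.
    """

    center: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.radius) and self.radius > 0):
            raise InvalidAnnotationError(f"iris radius must be > 0, got {self.radius}")

    @property
    def top(self) -> Point2D:
        return Point2D(self.center.x, self.center.y - self.radius)


@dataclass(frozen=True)
class EyeAnnotation:
    """Full per-eye geometry in image pixel coordinates."""

    side: Literal["left", "right"]
    iris: IrisObservation
    upper_lid: LidContour
    lower_lid: LidContour
    medial_canthus: Point2D
    lateral_canthus: Point2D

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidAnnotationError(f"unknown eye side {self.side!r}")
        for lid in (self.upper_lid, self.lower_lid):
            first, last = lid.points[0], lid.points[-1]
            for endpoint, canthus, name in (
                (first, self.medial_canthus, "medial"),
                (last, self.lateral_canthus, "lateral"),
            ):
                d = math.hypot(endpoint.x - canthus.x, endpoint.y - canthus.y)
                if d > CANTHUS_TOL:
                    raise InvalidAnnotationError(
                        f"{lid.role} lid endpoint is {d:.2f} px from the "
                        f"{name} canthus (tolerance {CANTHUS_TOL})"
                    )
        # Validates simplicity / positive area as a side effect.
        eye_polygon(self)

    def translated(self, dx: float, dy: float) -> "EyeAnnotation":
        return EyeAnnotation(
            side=self.side,
            iris=IrisObservation(
                Point2D(self.iris.center.x + dx, self.iris.center.y + dy),
                self.iris.radius,
            ),
            upper_lid=self.upper_lid.translated(dx, dy),
            lower_lid=self.lower_lid.translated(dx, dy),
            medial_canthus=Point2D(self.medial_canthus.x + dx, self.medial_canthus.y + dy),
            lateral_canthus=Point2D(self.lateral_canthus.x + dx, self.lateral_canthus.y + dy),
        )

    def with_upper_lid(self, upper: LidContour) -> "EyeAnnotation":
        return EyeAnnotation(
            side=self.side,
            iris=self.iris,
            upper_lid=upper,
            lower_lid=self.lower_lid,
            medial_canthus=self.medial_canthus,
            lateral_canthus=self.lateral_canthus,
        )

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "iris": {
                "cx": self.iris.center.x,
                "cy": self.iris.center.y,
                "r": self.iris.radius,
            },
            "upper_lid": self.upper_lid.xy.tolist(),
            "lower_lid": self.lower_lid.xy.tolist(),
            "medial_canthus": [self.medial_canthus.x, self.medial_canthus.y],
            "lateral_canthus": [self.lateral_canthus.x, self.lateral_canthus.y],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EyeAnnotation":
        return cls(
            side=d["side"],
            iris=IrisObservation(
                Point2D(float(d["iris"]["cx"]), float(d["iris"]["cy"])),
                float(d["iris"]["r"]),
            ),
            upper_lid=LidContour.from_array(d["upper_lid"], "upper"),
            lower_lid=LidContour.from_array(d["lower_lid"], "lower"),
            medial_canthus=Point2D(*map(float, d["medial_canthus"])),
            lateral_canthus=Point2D(*map(float, d["lateral_canthus"])),
        )


def eye_polygon(eye: EyeAnnotation) -> Polygon:
    """Closed eye outline as a simple shapely polygon.

    Vertices are the upper lid medial→lateral followed by the lower lid
    lateral→medial with the shared canthus vertices not duplicated.
    """
    upper = eye.upper_lid.xy
    lower = eye.lower_lid.xy[::-1]  # lateral → medial
    # Drop lower-lid endpoints coincident with the canthi already contributed
    # by the upper lid.
    verts = np.vstack([upper, lower[1:-1]])
    poly = Polygon(verts)
    if not poly.is_valid:
        raise InvalidAnnotationError("eye outline is self-intersecting")
    if poly.area <= 0:
        raise InvalidAnnotationError("eye outline has non-positive area")
    return poly


def lateral_sign(eye: EyeAnnotation) -> float:
    """+1 if the lateral canthus lies to the right of the medial one, else -1."""
    return 1.0 if eye.lateral_canthus.x >= eye.medial_canthus.x else -1.0


def ray_direction(eye: EyeAnnotation, theta_deg: float) -> np.ndarray:
    """Unit image-frame direction for an eye-local angle.

    Eye-local frame: 0° toward the lateral canthus, 90° toward the upper lid,
    counterclockwise in a y-up frame. Image rows grow downward, hence the
    negated sine.
    """
    t = math.radians(theta_deg)
    s = lateral_sign(eye)
    return np.array([s * math.cos(t), -math.sin(t)])


def ray_polygon_distance(
    poly: Polygon, origin: Point2D, direction: np.ndarray
) -> float | None:
    """Distance from ``origin`` along ``direction`` to the nearest boundary hit.

    Returns ``None`` when the ray never meets the boundary (origin outside
    with an outward direction). Intersections at polygon vertices count once;
    for collinear overlaps the nearest point of the overlap is used.
    """
    minx, miny, maxx, maxy = poly.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny, 1.0)
    o = origin.as_array()
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ray = LineString([o, o + reach * d])
    hit = ray.intersection(poly.exterior)
    if hit.is_empty:
        return None
    pts: list[tuple[float, float]] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        else:  # collinear overlap: both ends are candidate hits
            pts.extend(geom.coords)
    dists = [float(np.hypot(px - o[0], py - o[1])) for px, py in pts]
    dists = [t for t in dists if t > 1e-9]
    return min(dists) if dists else None


def polygon_contains(poly: Polygon, p: Point2D) -> bool:
    return bool(poly.contains(Point(p.x, p.y)))


# ---------------------------------------------------------------------------
# annotation file format
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> dict[str, list[EyeAnnotation]]:
    """Read an annotation JSON file: list of {image, eyes: [...]} objects.

    Coordinates are 0-based pixel positions, y increasing downward.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):
        raw = [raw]
    out: dict[str, list[EyeAnnotation]] = {}
    for record in raw:
        out[record["image"]] = [EyeAnnotation.from_dict(e) for e in record["eyes"]]
    return out


def save_annotations(
    path: str | Path, records: dict[str, Iterable[EyeAnnotation]]
) -> None:
    payload = [
        {"image": image, "eyes": [eye.to_dict() for eye in eyes]}
        for image, eyes in records.items()
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
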