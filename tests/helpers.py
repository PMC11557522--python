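"""Shared fixture builders and independent oracles for the test suite.

The oracles here are deliberately implemented from first principles (dense
boundary sampling, shoelace formula, exact polygon clipping) so they stay
independent of the code paths they check.
"""

from __future__ import annotations

import numpy as np
import shapely

from ptosiskit.geometry import (
    EyeAnnotation,
    IrisObservation,
    LidContour,
    Point2D,
    eye_polygon,
    lateral_sign,
)


def radial_eye(
    center: tuple[float, float],
    radii: np.ndarray,
    side: str = "left",
) -> EyeAnnotation:
    """Star-shaped eye outline from per-angle radii on a uniform grid.

    ``radii[k]`` is the boundary distance at eye-local angle k*step where
    step = 360/len(radii). The grid must contain 0 and 180 (the canthi).
    Vertices are placed exactly at the grid angles, so radial distance
    queries on the same grid are exact. Radii must vary slowly enough that
    x = r(theta)*cos(theta) stays strictly monotone along each lid
    (ratio of adjacent radii below ~1.15 on a 15-degree grid).
    """
    n = len(radii)
    assert n % 2 == 0, "need vertices at both canthi (even grid)"
    step = 360.0 / n
    cx, cy = center
    s = 1.0 if side == "left" else -1.0
    thetas = np.arange(n) * step
    # image coordinates: eye-local (cos, sin) -> (s*cos, -sin)
    xs = cx + s * radii * np.cos(np.radians(thetas))
    ys = cy - radii * np.sin(np.radians(thetas))
    k = n // 2
    # upper half: angles 0..180 inclusive; order medial (180) -> lateral (0)
    ui = np.arange(k, -1, -1)
    li = np.arange(k, n + 1) % n  # 180..360(=0), already medial -> lateral
    upper = LidContour.from_array(np.column_stack([xs[ui], ys[ui]]), "upper")
    lower = LidContour.from_array(np.column_stack([xs[li], ys[li]]), "lower")
    return EyeAnnotation(
        side=side,  # type: ignore[arg-type]
        iris=IrisObservation(Point2D(cx, cy), radius=float(min(radii) / 2.0)),
        upper_lid=upper,
        lower_lid=lower,
        medial_canthus=Point2D(float(xs[k]), float(ys[k])),
        lateral_canthus=Point2D(float(xs[0]), float(ys[0])),
    )


def random_radial_eye(rng: np.random.Generator, n_pts: int = 9) -> EyeAnnotation:
    """Random irregular eye fixture with the iris center guaranteed inside.

    Lids are x-monotone polylines with jittered vertices; the outline is
    vertically simple, so the center (placed mid-aperture) is interior.
    """
    cx = float(rng.uniform(50, 150))
    cy = float(rng.uniform(50, 150))
    w = float(rng.uniform(44, 64))
    xs = np.linspace(-w / 2, w / 2, n_pts)
    xs[1:-1] += rng.uniform(-1.2, 1.2, n_pts - 2)
    arc = 1.0 - (xs / (w / 2)) ** 2
    up = -(rng.uniform(8.0, 16.0) * arc + rng.uniform(0.0, 2.0, n_pts) * arc)
    lo = rng.uniform(6.0, 12.0) * arc + rng.uniform(0.0, 2.0, n_pts) * arc
    up[[0, -1]] = 0.0
    lo[[0, -1]] = 0.0
    side = "left" if rng.uniform() < 0.5 else "right"
    order = slice(None) if side == "left" else slice(None, None, -1)
    upper = LidContour.from_array(
        np.column_stack([cx + xs, cy + up])[order], "upper"
    )
    lower = LidContour.from_array(
        np.column_stack([cx + xs, cy + lo])[order], "lower"
    )
    med = Point2D(cx + (-w / 2 if side == "left" else w / 2), cy)
    lat = Point2D(cx + (w / 2 if side == "left" else -w / 2), cy)
    return EyeAnnotation(
        side=side,  # type: ignore[arg-type]
        iris=IrisObservation(Point2D(cx, cy - rng.uniform(0.0, 3.0)),
                             radius=float(rng.uniform(0.16, 0.2) * w)),
        upper_lid=upper,
        lower_lid=lower,
        medial_canthus=med,
        lateral_canthus=lat,
    )


def boundary_sampling_mplpd(
    eye: EyeAnnotation, theta: float, n: int = 100_000
) -> float:
    """Brute-force radial distance: densely sample the outline, locate every
    place where the boundary's eye-local polar angle crosses theta, and
    return the nearest such crossing's distance."""
    poly = eye_polygon(eye)
    ext = poly.exterior
    ts = np.linspace(0.0, ext.length, n, endpoint=False)
    pts = shapely.get_coordinates(shapely.line_interpolate_point(ext, ts))
    cx, cy = eye.iris.center.x, eye.iris.center.y
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    s = lateral_sign(eye)
    ang = np.degrees(np.arctan2(-dy, s * dx))
    # signed angular offset from theta in (-180, 180]
    off = (ang - theta + 180.0) % 360.0 - 180.0
    off_next = np.roll(off, -1)
    dist = np.hypot(dx, dy)
    dist_next = np.roll(dist, -1)
    # genuine crossings of 0 (not the antipodal +-180 wrap)
    crossing = (np.sign(off) != np.sign(off_next)) & (np.abs(off) < 90) & (
        np.abs(off_next) < 90
    )
    hits = [
        d0 + abs(o0) / (abs(o0) + abs(o1)) * (d1 - d0)
        for o0, o1, d0, d1 in zip(
            off[crossing], off_next[crossing], dist[crossing], dist_next[crossing]
        )
    ]
    hits += list(dist[off == 0.0])
    return float(min(hits))


def shoelace_area(vertices: np.ndarray) -> float:
    """Independent polygon area (shoelace formula)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def mirror_positional(eye: EyeAnnotation) -> EyeAnnotation:
    """Mirror the contour about the vertical axis through the iris center,
    keeping the eye side: canthi are relabelled by position, so the lateral
    canthus stays on the same image side as before."""
    cx = eye.iris.center.x

    def refl(p: Point2D) -> Point2D:
        return Point2D(2 * cx - p.x, p.y)

    def refl_lid(lid: LidContour) -> LidContour:
        pts = tuple(refl(p) for p in reversed(lid.points))
        return LidContour(pts, lid.role)

    return EyeAnnotation(
        side=eye.side,
        iris=eye.iris,
        upper_lid=refl_lid(eye.upper_lid),
        lower_lid=refl_lid(eye.lower_lid),
        medial_canthus=refl(eye.lateral_canthus),
        lateral_canthus=refl(eye.medial_canthus),
    )


def mirror_anatomical(eye: EyeAnnotation, axis_x: float) -> EyeAnnotation:
    """Reflect the whole annotation about the vertical line x = axis_x and
    swap the side label: produces the anatomically mirrored fellow eye."""

    def refl(p: Point2D) -> Point2D:
        return Point2D(2 * axis_x - p.x, p.y)

    def refl_lid(lid: LidContour) -> LidContour:
        return LidContour(tuple(refl(p) for p in lid.points), lid.role)

    return EyeAnnotation(
        side="right" if eye.side == "left" else "left",
        iris=IrisObservation(refl(eye.iris.center), eye.iris.radius),
        upper_lid=refl_lid(eye.upper_lid),
        lower_lid=refl_lid(eye.lower_lid),
        medial_canthus=refl(eye.medial_canthus),
        lateral_canthus=refl(eye.lateral_canthus),
    )


def scale_eye(eye: EyeAnnotation, factor: float, about=(0.0, 0.0)) -> EyeAnnotation:
    """Uniformly scale an annotation about a point."""
    ax, ay = about

    def sc(p: Point2D) -> Point2D:
        return Point2D(ax + factor * (p.x - ax), ay + factor * (p.y - ay))

    def sc_lid(lid: LidContour) -> LidContour:
        return LidContour(tuple(sc(p) for p in lid.points), lid.role)

    return EyeAnnotation(
        side=eye.side,
        iris=IrisObservation(sc(eye.iris.center), eye.iris.radius * factor),
        upper_lid=sc_lid(eye.upper_lid),
        lower_lid=sc_lid(eye.lower_lid),
        medial_canthus=sc(eye.medial_canthus),
        lateral_canthus=sc(eye.lateral_canthus),
    )


def detect_lid_row(image: np.ndarray, cx: float, cy: float, threshold: float = 120.0
                   ) -> float:
    """Column-wise dark-to-skin transition detector (test-only).

    Scans upward from the iris center in column cx and returns the subpixel
    row where intensity first crosses ``threshold`` (iris is dark, skin above
    the lid is bright).
    """
    col = image[:, int(round(cx))].astype(float)
    r = int(round(cy))
    while r > 0 and col[r] < threshold:
        r -= 1
    if r == int(round(cy)):
        return float(r)  # lid at or below the center row
    lo, hi = col[r + 1], col[r]  # dark below, bright at r
    if hi == lo:
        return float(r)
    frac = (threshold - lo) / (hi - lo)
    return (r + 1) - frac
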