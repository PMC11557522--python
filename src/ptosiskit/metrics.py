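"""Pixel-based ptosis attributes: marginal reflex ratio and radial lid distances.

Two camera-scale-free quantities describe how far a drooping upper lid
encroaches on the eye:

* **MRR** (marginal reflex ratio) — ``r0 / r1`` where ``r0`` is the signed
  vertical pixel distance from the iris center up to the upper lid margin at
  the iris column and ``r1`` is the iris radius (distance from the iris
  center to the iris top point). A healthy eye sits around 0.8–1.0; values
  at or below 0 mean the lid margin has reached or passed the pupil center
  (severe ptosis), flagged ``closed_eye``.

* **MPLPD(θ)** (mid-pupil lid pixel distance) — the distance from the iris
  center along the ray at eye-local angle θ to the closed eye outline.
  Sampled on a regular grid (default every 15°) it profiles the whole
  palpebral aperture.

Being ratios and pixel distances of a single photograph, both are agnostic
to real-world calibration: no ruler or reference sticker is required.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidAnnotationError, MeasurementError
from .geometry import (
    EyeAnnotation,
    eye_polygon,
    polygon_contains,
    ray_direction,
    ray_polygon_distance,
)

__all__ = [
    "MeasurementReport",
    "compute_mrr",
    "compute_mplpd",
    "mplpd_profile",
    "measure_eye",
    "reports_to_csv",
    "reports_to_json",
]


def compute_mrr(eye: EyeAnnotation) -> tuple[float, float, float]:
    """Marginal reflex ratio of one eye.

    Returns ``(mrr, r0, r1)``. ``r0`` is signed: positive when the upper lid
    margin lies above the iris center, negative when it has dropped below it,
    so the ratio remains defined for severe ptosis instead of failing.
    """
    r1 = eye.iris.radius
    cx = eye.iris.center.x
    if not eye.upper_lid.spans(cx):
        raise MeasurementError("lid does not cover pupil column")
    lid_y = float(eye.upper_lid.y_at(cx))
    r0 = eye.iris.center.y - lid_y  # y grows downward: above center => r0 > 0
    return r0 / r1, r0, r1


def compute_mplpd(eye: EyeAnnotation, theta: float) -> float | None:
    """Distance from the iris center to the eye outline at eye-local angle theta.

    ``theta`` may be any real number (reduced mod 360). Returns ``None`` when
    the iris center lies outside (or on) the closed eye outline, which happens
    for closed or near-closed eyes.
    """
    poly = eye_polygon(eye)  # raises on degenerate outline
    if not polygon_contains(poly, eye.iris.center):
        return None
    d = ray_polygon_distance(poly, eye.iris.center, ray_direction(eye, theta % 360.0))
    if d is None:  # cannot happen for an interior origin; defensive
        raise InvalidAnnotationError("ray from interior point missed the outline")
    return d


def mplpd_profile(
    eye: EyeAnnotation, step: float = 15.0
) -> list[tuple[float, float | None]]:
    """Radial distance profile at angles 0, step, ..., 360-step.

    The grid is half-open: the 360° sample duplicates 0° and is omitted so
    means over the profile do not double-weight one direction.
    """
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ConfigurationError(f"angle step {step} does not divide 360")
    poly = eye_polygon(eye)
    if not polygon_contains(poly, eye.iris.center):
        thetas = np.arange(0.0, 360.0, step)
        return [(float(t), None) for t in thetas]
    out = []
    for t in np.arange(0.0, 360.0, step):
        d = ray_polygon_distance(poly, eye.iris.center, ray_direction(eye, float(t)))
        out.append((float(t), d))
    return out


@dataclass
class MeasurementReport:
    """Per-eye measurement results plus quality flags."""

    image: str
    side: str
    mrr: float
    r0: float
    r1: float
    mplpd: list[tuple[float, float | None]]
    flags: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "image": self.image,
            "side": self.side,
            "mrr": self.mrr,
            "r0": self.r0,
            "r1": self.r1,
            "mplpd": [[t, d] for t, d in self.mplpd],
            "flags": sorted(self.flags),
        }


def measure_eye(
    eye: EyeAnnotation, step: float = 15.0, image: str = ""
) -> MeasurementReport:
    """Full measurement report: MRR plus the radial profile plus flags.

    Flags: ``closed_eye`` when mrr <= 0; ``iris_occluded`` when the lid margin
    sits below the iris top (r0 < r1); ``center_outside_contour`` when the
    radial profile is undefined.
    """
    mrr, r0, r1 = compute_mrr(eye)
    profile = mplpd_profile(eye, step)
    flags: set[str] = set()
    if mrr <= 0:
        flags.add("closed_eye")
    if r0 < r1:
        flags.add("iris_occluded")
    if all(d is None for _, d in profile):
        flags.add("center_outside_contour")
    return MeasurementReport(image, eye.side, mrr, r0, r1, profile, flags)


def reports_to_csv(reports: Sequence[MeasurementReport], path: str | Path) -> None:
    """Write reports as CSV: image, side, mrr, r0, r1, mplpd_0..mplpd_345, flags."""
    if not reports:
        raise ValueError("no reports to write")
    thetas = [t for t, _ in reports[0].mplpd]
    header = ["image", "side", "mrr", "r0", "r1"]
    header += [f"mplpd_{int(t)}" for t in thetas]
    header += ["flags"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in reports:
            row: list = [r.image, r.side, f"{r.mrr:.6f}", f"{r.r0:.4f}", f"{r.r1:.4f}"]
            row += ["" if d is None else f"{d:.4f}" for _, d in r.mplpd]
            row += [";".join(sorted(r.flags))]
            w.writerow(row)


def reports_to_json(reports: Sequence[MeasurementReport], path: str | Path) -> None:
    Path(path).write_text(json.dumps([r.to_dict() for r in reports], indent=2))
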