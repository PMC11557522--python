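"""Mirror-symmetry evaluation of treated (or predicted) eyes.

For a unilateral case the untreated fellow eye is the natural reference: a
perfect correction makes the treated eye the mirror image of its fellow. Two
statistics quantify how close a pair gets:

* **overlap ratio** — intersection area over union area of the two eye
  outlines after translating both iris centers to the origin and
  horizontally flipping the treated outline; 1 means perfect symmetry.
* **MPLPD ratio profile** — per-angle ratio of the treated eye's radial lid
  distance to the fellow eye's, both taken in their own eye-local frames
  (which makes the mirroring implicit); values near 1 at every angle mean
  matching apertures.

Alignment is translation-only, anchored on the iris centers: rotation or
scale normalisation would hide exactly the size/shape asymmetry these
statistics are meant to capture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Polygon

from .errors import EvaluationError, InvalidAnnotationError
from .geometry import EyeAnnotation, eye_polygon
from .metrics import mplpd_profile

__all__ = [
    "AlignedEyePair",
    "SymmetryReport",
    "CohortRecord",
    "CohortSummary",
    "mirror_align",
    "overlap_ratio",
    "mplpd_ratio_profile",
    "symmetry_report",
    "evaluate_cohort",
]

logger = logging.getLogger(__name__)


@dataclass
class AlignedEyePair:
    """Two eye outlines in a shared frame: iris centers at the origin, the
    test outline horizontally flipped."""

    reference: Polygon
    test: Polygon


def _centered_polygon(eye: EyeAnnotation) -> Polygon:
    poly = eye_polygon(eye)
    return affinity.translate(poly, xoff=-eye.iris.center.x, yoff=-eye.iris.center.y)


def mirror_align(fellow: EyeAnnotation, treated: EyeAnnotation) -> AlignedEyePair:
    """Translate both outlines to iris-centered frames and flip the treated one.

    Translation-only: no rotation or scaling (deliberate — see module docs).
    """
    ref = _centered_polygon(fellow)
    test = affinity.scale(_centered_polygon(treated), xfact=-1.0, yfact=1.0, origin=(0, 0))
    return AlignedEyePair(reference=ref, test=test)


def overlap_ratio(pair: AlignedEyePair, supersample: int = 4) -> float:
    """Intersection-over-union of the aligned outlines by supersampled rasterization.

    The common grid spans the union bounding box at ``supersample`` samples
    per pixel per axis (default 4x).
    """
    bounds = np.array([pair.reference.bounds, pair.test.bounds])
    minx, miny = bounds[:, :2].min(axis=0)
    maxx, maxy = bounds[:, 2:].max(axis=0)
    if not (maxx > minx and maxy > miny):
        raise InvalidAnnotationError("zero union area")
    step = 1.0 / supersample
    xs = np.arange(minx + step / 2, maxx, step)
    ys = np.arange(miny + step / 2, maxy, step)
    xx, yy = np.meshgrid(xs, ys)
    in_ref = shapely.contains_xy(pair.reference, xx.ravel(), yy.ravel())
    in_test = shapely.contains_xy(pair.test, xx.ravel(), yy.ravel())
    union = np.count_nonzero(in_ref | in_test)
    if union == 0:
        raise InvalidAnnotationError("zero union area")
    inter = np.count_nonzero(in_ref & in_test)
    return inter / union


def mplpd_ratio_profile(
    fellow: EyeAnnotation, treated: EyeAnnotation, step: float = 15.0
) -> list[tuple[float, float | None]]:
    """Per-angle treated/fellow radial-distance ratios in eye-local frames.

    Angles where either distance is undefined are reported as missing.
    Raises when every angle is missing (typically a closed eye whose iris
    center lies outside the outline).
    """
    prof_f = mplpd_profile(fellow, step)
    prof_t = mplpd_profile(treated, step)
    out: list[tuple[float, float | None]] = []
    for (theta, df), (_, dt) in zip(prof_f, prof_t):
        if df is None or dt is None or df == 0:
            out.append((theta, None))
        else:
            out.append((theta, dt / df))
    if all(r is None for _, r in out):
        raise EvaluationError(
            "MPLPD ratio undefined at every angle (closed_eye: iris center "
            "outside at least one eye outline)"
        )
    return out


@dataclass
class SymmetryReport:
    """Overlap ratio and MPLPD-ratio profile for one eye pair."""

    overlap_ratio: float
    mplpd_ratios: list[tuple[float, float | None]]
    mean_mplpd_ratio: float
    n_angles_present: int
    flags: set[str] = field(default_factory=set)
    contour_source: str = "annotation"

    def to_dict(self) -> dict:
        return {
            "overlap_ratio": self.overlap_ratio,
            "mplpd_ratios": [[t, r] for t, r in self.mplpd_ratios],
            "mean_mplpd_ratio": self.mean_mplpd_ratio,
            "n_angles_present": self.n_angles_present,
            "flags": sorted(self.flags),
            "contour_source": self.contour_source,
        }


def symmetry_report(
    fellow: EyeAnnotation,
    treated: EyeAnnotation,
    step: float = 15.0,
    supersample: int = 4,
    contour_source: str = "annotation",
) -> SymmetryReport:
    """Compute both symmetry statistics for one fellow/treated pair."""
    pair = mirror_align(fellow, treated)
    ratios = mplpd_ratio_profile(fellow, treated, step)
    present = [r for _, r in ratios if r is not None]
    flags: set[str] = set()
    if len(present) < len(ratios):
        flags.add("missing_angles")
    return SymmetryReport(
        overlap_ratio=overlap_ratio(pair, supersample),
        mplpd_ratios=ratios,
        mean_mplpd_ratio=float(np.mean(present)),
        n_angles_present=len(present),
        flags=flags,
        contour_source=contour_source,
    )


@dataclass
class CohortRecord:
    """One unilateral case: fellow eye plus the treated eye before and
    (optionally) after prediction."""

    fellow: EyeAnnotation
    treated_before: EyeAnnotation
    treated_predicted: EyeAnnotation | None = None
    image: str = ""
    bilateral: bool = False


@dataclass
class CohortSummary:
    """Mean and standard deviation of each statistic per condition.

    SD uses the n-1 denominator. The cohort mean of the MPLPD ratio is the
    mean over per-case means (each case first averaged over its angle grid).
    """

    control: list[SymmetryReport]
    predicted: list[SymmetryReport]
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, reports in (("control", self.control), ("predicted", self.predicted)):
            if not reports:
                continue
            ov = np.array([r.overlap_ratio for r in reports])
            mp = np.array([r.mean_mplpd_ratio for r in reports])
            rows.append(
                {
                    "condition": name,
                    "n": len(reports),
                    "overlap_mean": ov.mean(),
                    "overlap_sd": ov.std(ddof=1) if len(ov) > 1 else float("nan"),
                    "mplpd_ratio_mean": mp.mean(),
                    "mplpd_ratio_sd": mp.std(ddof=1) if len(mp) > 1 else float("nan"),
                }
            )
        return pd.DataFrame(rows).set_index("condition")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self, path: str | Path) -> None:
        import json

        payload = {
            "summary": self.to_frame().reset_index().to_dict(orient="records"),
            "control": [r.to_dict() for r in self.control],
            "predicted": [r.to_dict() for r in self.predicted],
            "n_skipped": self.n_skipped,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_cohort(
    records: Sequence[CohortRecord], step: float = 15.0, supersample: int = 4
) -> CohortSummary:
    """Control vs predicted symmetry statistics over a unilateral cohort.

    The control condition compares the untouched treated eye with the fellow
    eye (symmetry of the unmodified photograph); the predicted condition
    compares the predicted treated eye. Bilateral records are skipped with a
    warning — fellow-eye symmetry is meaningless there.
    """
    control: list[SymmetryReport] = []
    predicted: list[SymmetryReport] = []
    skipped = 0
    for rec in records:
        if rec.bilateral:
            logger.warning("skipping bilateral record %s", rec.image or "<unnamed>")
            skipped += 1
            continue
        control.append(symmetry_report(rec.fellow, rec.treated_before, step, supersample))
        if rec.treated_predicted is not None:
            predicted.append(
                symmetry_report(rec.fellow, rec.treated_predicted, step, supersample)
            )
    if not control:
        raise EvaluationError("no usable unilateral records in cohort")
    return CohortSummary(control=control, predicted=predicted, n_skipped=skipped)
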