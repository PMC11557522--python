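"""Post-operative target-lid synthesis and conditioning artifacts.

Given a pre-operative eye annotation and a requested marginal reflex ratio,
this module produces the three artifacts a generative inpainting backend
consumes:

1. a deformed **target upper-lid contour** whose measured MRR equals the
   request exactly (in contour space),
2. an **edge conditioning image**: the Canny edge map of the photograph with
   the editable region wiped and replaced by the rasterized target contour
   (optionally with a supratarsal crease stroke), and
3. a **binary inpainting mask** covering the band between the original and
   target lid margins plus a safety margin, excluding still-visible iris.

Lid deformation is multiplicative vertical scaling about the canthal
baseline: every lid point's height above the line through the two canthi is
scaled by the factor that brings the height at the iris column to the target
value. This preserves the lid's shape character, keeps the anatomically
fixed canthi pinned, and is exact under linear interpolation. For
near-closed eyes (lid height at the iris column <= 1 px) the multiplicative
factor is ill-conditioned, so an additive vertical lift with cosine falloff
from the iris column to each canthus is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import feature as skfeature

from .errors import ConfigurationError, InvalidAnnotationError, MeasurementError
from .geometry import EyeAnnotation, LidContour, Point2D
from .metrics import compute_mrr

__all__ = [
    "TargetSpec",
    "BundleConfig",
    "ConditioningBundle",
    "solve_target_lid",
    "render_condition_edges",
    "build_inpaint_mask",
    "make_bundle",
]


@dataclass(frozen=True)
class TargetSpec:
    """Requested post-operative state for one treated eye.

    ``target_mrr`` is the requested marginal reflex ratio (the guidance value
    y0). ``source`` records whether it was copied from the fellow eye or given
    explicitly. ``crease_offset`` > 0 adds a parallel supratarsal-crease
    stroke that many ControlNet-style engines interpret as a double-eyelid
    fold; 0 disables it.
    """

    target_mrr: float
    source: Literal["fellow_eye", "explicit"] = "explicit"
    crease_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_mrr <= 1.2):
            raise ConfigurationError(
                f"target_mrr must lie in (0, 1.2], got {self.target_mrr}"
            )
        if self.crease_offset < 0:
            raise ConfigurationError("crease_offset must be >= 0")


@dataclass
class BundleConfig:
    """Knobs for conditioning-artifact construction.

    Canny thresholds are on the 8-bit intensity scale with the conventional
    1:3 low:high ratio as default. ``mask_margin`` is the dilation radius in
    pixels at a 256-px eye-crop scale; callers working on larger crops scale
    it proportionally.
    """

    canny_low: float = 50.0
    canny_high: float = 150.0
    mask_margin: float = 5.0
    edges_off: bool = False  # ablation: emit an empty conditioning image
    mask_off: bool = False   # ablation: mask = whole-eye bounding box + margin

    def __post_init__(self) -> None:
        if self.canny_low >= self.canny_high:
            raise ConfigurationError("canny_low must be < canny_high")
        if self.mask_margin < 0:
            raise ConfigurationError("mask_margin must be >= 0")


@dataclass
class ConditioningBundle:
    """Everything a generative backend needs for one treated eye."""

    edge_image: np.ndarray       # bool (H, W)
    mask: np.ndarray             # bool (H, W)
    target_contour: LidContour
    target_spec: TargetSpec
    source_eye: EyeAnnotation

    def save(self, out_dir: str | Path, stem: str = "bundle") -> dict:
        """Write edge/mask PNGs plus a JSON manifest; returns the manifest."""
        import json

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        edge_path = out / f"{stem}_edges.png"
        mask_path = out / f"{stem}_mask.png"
        Image.fromarray((self.edge_image.astype(np.uint8)) * 255).save(edge_path)
        Image.fromarray((self.mask.astype(np.uint8)) * 255).save(mask_path)
        manifest = {
            "edge_image": edge_path.name,
            "mask": mask_path.name,
            "target_contour": self.target_contour.xy.tolist(),
            "target_spec": {
                "target_mrr": self.target_spec.target_mrr,
                "source": self.target_spec.source,
                "crease_offset": self.target_spec.crease_offset,
            },
        }
        (out / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


# ---------------------------------------------------------------------------
# target contour solving
# ---------------------------------------------------------------------------

def _baseline_y(eye: EyeAnnotation, x: np.ndarray) -> np.ndarray:
    """Row of the canthal baseline (line through the two canthi) at column x."""
    m, l = eye.medial_canthus, eye.lateral_canthus
    if abs(l.x - m.x) < 1e-12:
        raise InvalidAnnotationError("canthi share a column; baseline undefined")
    return m.y + (l.y - m.y) * (x - m.x) / (l.x - m.x)


def solve_target_lid(eye: EyeAnnotation, spec: TargetSpec) -> LidContour:
    """Deform the upper lid so its measured MRR equals ``spec.target_mrr``.

    Anchored at both canthi; multiplicative height scaling about the canthal
    baseline, with an additive cosine-falloff lift when the current lid
    height at the iris column is <= 1 px (near-closed eye). Raises when the
    deformed lid would cross the lower lid.
    """
    _, _, r1 = compute_mrr(eye)
    cx = eye.iris.center.x
    pts = eye.upper_lid.xy
    xs, ys = pts[:, 0], pts[:, 1]
    b = _baseline_y(eye, xs)
    b_c = float(_baseline_y(eye, np.array([cx]))[0])
    lid_c = float(eye.upper_lid.y_at(cx))
    y_target = eye.iris.center.y - spec.target_mrr * r1
    h_c = b_c - lid_c          # current height above baseline at iris column
    h_target = b_c - y_target  # required height

    if h_c > 1.0:
        s = h_target / h_c
        new_ys = b - s * (b - ys)
    else:
        # near-closed fallback: vertical lift, full at the iris column,
        # cosine-decayed to zero at each canthus
        lift = lid_c - y_target
        w = np.empty_like(xs)
        for i, x in enumerate(xs):
            anchor = eye.medial_canthus.x if (
                (x - cx) * (eye.medial_canthus.x - cx) > 0
            ) else eye.lateral_canthus.x
            span = anchor - cx
            w[i] = 1.0 if abs(span) < 1e-12 else np.cos(
                0.5 * np.pi * np.clip((x - cx) / span, 0.0, 1.0)
            )
        new_ys = ys - lift * w

    target = LidContour(
        tuple(Point2D(float(x), float(y)) for x, y in zip(xs, new_ys)), "upper"
    )
    _check_fissure(eye, target)
    return target


def _check_fissure(eye: EyeAnnotation, target: LidContour) -> None:
    """Reject targets whose lid margin crosses below the lower lid."""
    lo, hi = eye.lower_lid.x_range
    xs = target.xy[:, 0]
    inside = (xs > lo + 1e-6) & (xs < hi - 1e-6)
    if not inside.any():
        return
    upper_y = target.xy[inside, 1]
    lower_y = np.asarray(eye.lower_lid.y_at(xs[inside]))
    # interior points only: canthi legitimately touch
    margin = (xs[inside] - lo) * (hi - xs[inside])
    interior = margin > 1e-6 * (hi - lo) ** 2
    if np.any(upper_y[interior] > lower_y[interior] + 1e-9):
        raise MeasurementError("target collapses palpebral fissure")


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _raster_polyline(
    points: np.ndarray, shape: tuple[int, int], dy: float = 0.0
) -> np.ndarray:
    """1-px stroke of a polyline: anti-aliased lines thresholded at 0.5."""
    acc = np.zeros(shape, dtype=float)
    pts = points.copy()
    pts[:, 1] += dy
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        rr, cc, val = skdraw.line_aa(
            int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1))
        )
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        np.maximum.at(acc, (rr[ok], cc[ok]), val[ok])
    return acc >= 0.5


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def render_condition_edges(
    image: np.ndarray,
    eye: EyeAnnotation,
    target: LidContour,
    mask: np.ndarray,
    canny_low: float = 50.0,
    canny_high: float = 150.0,
    crease_offset: float = 0.0,
) -> np.ndarray:
    """Edge conditioning image: Canny edges with the edit region re-drawn.

    Edge pixels inside ``mask`` are erased and replaced by the rasterized
    target contour (plus an optional crease stroke ``crease_offset`` px above
    it). Thresholds are on the 8-bit scale; the underlying detector works in
    [0, 1] so they are rescaled internally.
    """
    if canny_low >= canny_high:
        raise ConfigurationError("canny_low must be < canny_high")
    gray = _to_gray(image)
    if gray.shape != mask.shape:
        raise ConfigurationError("image and mask dimensions differ")
    edges = skfeature.canny(
        gray / 255.0,
        sigma=1.0,
        low_threshold=canny_low / 255.0,
        high_threshold=canny_high / 255.0,
    )
    edges[mask] = False
    stroke = _raster_polyline(target.xy, gray.shape)
    if crease_offset > 0:
        stroke |= _raster_polyline(target.xy, gray.shape, dy=-crease_offset)
    return edges | stroke


def build_inpaint_mask(
    eye: EyeAnnotation,
    target: LidContour,
    margin: float,
    shape: tuple[int, int],
    crease_offset: float = 0.0,
) -> np.ndarray:
    """Binary editing mask for the inpainting backend.

    Union of (a) the band between the original and target upper-lid curves,
    (b) the original lid stroke and the target stroke (and crease stroke when
    enabled), dilated by ``margin``; minus still-visible iris pixels below the
    lower envelope of both lid curves. A single connected component is
    returned (the largest, should the exclusion split the region).
    """
    if margin < 0:
        raise ConfigurationError("margin must be >= 0")
    H, W = shape
    mask = _raster_polyline(eye.upper_lid.xy, shape)
    mask |= _raster_polyline(target.xy, shape)
    if crease_offset > 0:
        mask |= _raster_polyline(target.xy, shape, dy=-crease_offset)

    # column-wise fill of the band between the two curves
    lo = max(eye.upper_lid.x_range[0], target.x_range[0])
    hi = min(eye.upper_lid.x_range[1], target.x_range[1])
    for col in range(int(np.ceil(lo)), int(np.floor(hi)) + 1):
        if not (0 <= col < W):
            continue
        y0 = float(eye.upper_lid.y_at(col))
        y1 = float(target.y_at(col))
        r0 = int(np.clip(round(min(y0, y1)), 0, H - 1))
        r1 = int(np.clip(round(max(y0, y1)), 0, H - 1))
        mask[r0 : r1 + 1, col] = True

    if margin > 0:
        mask = ndimage.binary_dilation(mask, structure=_disk(margin))

    # keep visible iris (below the lower envelope of both lid curves) intact
    cx, cy, r = eye.iris.center.x, eye.iris.center.y, eye.iris.radius
    yy, xx = np.mgrid[0:H, 0:W]
    iris = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    cols = np.arange(W, dtype=float)
    span = (cols >= lo) & (cols <= hi)
    envelope = np.full(W, -np.inf)
    if span.any():
        envelope[span] = np.maximum(
            np.asarray(eye.upper_lid.y_at(cols[span])),
            np.asarray(target.y_at(cols[span])),
        )
    below_env = yy > envelope[None, :] + 0.5
    mask &= ~(iris & below_env)

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _disk(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx**2 + yy**2) <= radius**2


def make_bundle(
    image: np.ndarray,
    eye: EyeAnnotation,
    spec: TargetSpec,
    config: BundleConfig | None = None,
) -> ConditioningBundle:
    """Compose target solving, edge rendering and mask building.

    Enforces the bundle invariant that every lit pixel of the rendered target
    contour lies inside the mask.
    """
    cfg = config or BundleConfig()
    target = solve_target_lid(eye, spec)
    shape = _to_gray(image).shape

    if cfg.mask_off:
        mask = _bbox_mask(eye, target, cfg.mask_margin, shape)
    else:
        mask = build_inpaint_mask(
            eye, target, cfg.mask_margin, shape, crease_offset=spec.crease_offset
        )

    if cfg.edges_off:
        edges = np.zeros(shape, dtype=bool)
    else:
        edges = render_condition_edges(
            image, eye, target, mask, cfg.canny_low, cfg.canny_high,
            crease_offset=spec.crease_offset,
        )

    if not cfg.edges_off:
        stroke = _raster_polyline(target.xy, shape)
        if spec.crease_offset > 0:
            stroke |= _raster_polyline(target.xy, shape, dy=-spec.crease_offset)
        if np.any(stroke & ~mask):
            raise InvalidAnnotationError(
                "conditioning invariant violated: target stroke escapes mask"
            )
    return ConditioningBundle(edges, mask, target, spec, eye)


def _bbox_mask(
    eye: EyeAnnotation, target: LidContour, margin: float, shape: tuple[int, int]
) -> np.ndarray:
    """Ablation mask: whole-eye bounding box plus margin."""
    pts = np.vstack([eye.upper_lid.xy, eye.lower_lid.xy, target.xy])
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    H, W = shape
    mask = np.zeros(shape, dtype=bool)
    mask[
        int(np.clip(np.floor(y0), 0, H - 1)) : int(np.clip(np.ceil(y1), 0, H - 1)) + 1,
        int(np.clip(np.floor(x0), 0, W - 1)) : int(np.clip(np.ceil(x1), 0, W - 1)) + 1,
    ] = True
    return mask
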