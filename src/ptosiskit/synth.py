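"""Parametric periorbital scene generator with exact ground-truth annotations.

Renders schematic two-eye face crops — flat-shaded skin, sclera, iris disc
and parabolic lid arcs plus Gaussian noise — with full control over each
eye's intrinsic marginal reflex ratio. The upper-lid arc height at the iris
column is set analytically from the requested MRR, so the stored annotation
measures back to the requested value exactly; re-detecting the lid from
image intensities recovers it to within a pixel of rasterization error.

The rendering is deliberately schematic: sufficient contrast for Canny edge
detection and exact geometry for every measurement, but no photorealistic
skin texture, pose variation or illumination. It stands in for clinical
photographs wherever the pipeline needs a test substrate, and doubles as the
repository's landmark-provider fixture (the 468-point face-mesh interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import ConfigurationError
from .geometry import EyeAnnotation, IrisObservation, LidContour, Point2D

__all__ = [
    "EyeParams",
    "SceneParams",
    "SyntheticScene",
    "render_scene",
    "sample_unilateral_cohort",
    "ground_truth_landmark_provider",
    "N_MESH_POINTS",
]

#: size of the face-mesh landmark set the provider interface emits
N_MESH_POINTS = 468
#: lid polyline sampling density
POINTS_PER_LID = 17
#: canthal baseline offset below the iris center, in iris radii
CANTHUS_DROP = 0.3


@dataclass(frozen=True)
class EyeParams:
    """Parametric description of one rendered eye."""

    center: tuple[float, float]          # iris center (x, y), px
    palpebral_width: float = 88.0        # canthus-to-canthus distance, px
    iris_radius: float = 18.0            # px
    mrr: float = 0.85                    # intrinsic marginal reflex ratio
    lid_arc_height: float = 12.0         # lower-lid sag below the canthal line, px
    crease: bool = False                 # render a supratarsal crease line

    def __post_init__(self) -> None:
        if not (-0.3 <= self.mrr <= 1.1):
            raise ConfigurationError(f"intrinsic MRR {self.mrr} outside [-0.3, 1.1]")
        if not (0 < self.iris_radius < self.palpebral_width / 2):
            raise ConfigurationError(
                "iris radius must satisfy 0 < r < palpebral_width / 2"
            )
        if self.lid_arc_height <= 0:
            raise ConfigurationError("lid_arc_height must be > 0")


@dataclass(frozen=True)
class SceneParams:
    """Full scene description: two eyes plus rendering parameters."""

    width: int = 384
    height: int = 192
    right_eye: EyeParams = field(default_factory=lambda: EyeParams(center=(96.0, 96.0)))
    left_eye: EyeParams = field(default_factory=lambda: EyeParams(center=(288.0, 96.0)))
    skin: int = 180
    sclera: int = 235
    iris_intensity: int = 60
    noise_sigma: float = 3.0
    seed: int = 0
    ptosis_side: Literal["left", "right", None] = None

    def __post_init__(self) -> None:
        levels = (self.skin, self.sclera, self.iris_intensity)
        for i, a in enumerate(levels):
            for b in levels[i + 1 :]:
                if abs(a - b) < 30:
                    raise ConfigurationError(
                        "skin/sclera/iris intensities must differ by >= 30 levels"
                    )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    def eye(self, side: str) -> EyeParams:
        return self.left_eye if side == "left" else self.right_eye


@dataclass
class SyntheticScene:
    """Rendered image plus exact ground-truth annotations and parameters."""

    image: np.ndarray                       # uint8 (H, W)
    annotations: dict[str, EyeAnnotation]   # keyed by eye side
    landmarks: np.ndarray                   # (468, 3) face-mesh-style points
    params: SceneParams

    def save(self, out_dir: str | Path, stem: str) -> dict:
        import dataclasses
        import json

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        img_path = out / f"{stem}.png"
        ann_path = out / f"{stem}_annotations.json"
        par_path = out / f"{stem}_params.json"
        Image.fromarray(self.image).save(img_path)
        ann_path.write_text(
            json.dumps(
                [{"image": img_path.name,
                  "eyes": [self.annotations[s].to_dict() for s in ("right", "left")]}],
                indent=2,
            )
        )
        par_path.write_text(json.dumps(dataclasses.asdict(self.params), indent=2))
        return {
            "image": img_path.name,
            "annotations": ann_path.name,
            "params": par_path.name,
            "ptosis_side": self.params.ptosis_side,
        }


def _lid_curves(eye: EyeParams):
    """Analytic lid parabolas: returns (y_upper(x), y_lower(x), canthal y, half-width)."""
    cx, cy = eye.center
    r = eye.iris_radius
    half = eye.palpebral_width / 2.0
    y_c = cy + CANTHUS_DROP * r
    h_u = (CANTHUS_DROP + eye.mrr) * r   # height so the apex row is cy - mrr*r

    def q(x):
        u = (np.asarray(x, dtype=float) - cx) / half
        return 1.0 - u**2

    return (lambda x: y_c - h_u * q(x)), (lambda x: y_c + eye.lid_arc_height * q(x)), y_c, half


def _annotate_eye(side: str, eye: EyeParams) -> EyeAnnotation:
    cx, cy = eye.center
    y_u, y_l, y_c, half = _lid_curves(eye)
    # medial canthus is toward the nose: image-right for the subject's right
    # eye (which appears on the image's left), image-left for the left eye
    if side == "right":
        x_med, x_lat = cx + half, cx - half
    else:
        x_med, x_lat = cx - half, cx + half
    xs = np.linspace(x_med, x_lat, POINTS_PER_LID)
    upper = LidContour.from_array(np.column_stack([xs, y_u(xs)]), "upper")
    lower = LidContour.from_array(np.column_stack([xs, y_l(xs)]), "lower")
    return EyeAnnotation(
        side=side,
        iris=IrisObservation(Point2D(cx, cy), eye.iris_radius),
        upper_lid=upper,
        lower_lid=lower,
        medial_canthus=Point2D(x_med, y_c),
        lateral_canthus=Point2D(x_lat, y_c),
    )


def _canonical_template(n: int, width: int, height: int) -> np.ndarray:
    """Fixed grid filling the non-periocular portion of the 468-point mesh."""
    side = int(np.ceil(np.sqrt(n)))
    u, v = np.meshgrid(np.linspace(0.1, 0.9, side), np.linspace(0.1, 0.9, side))
    pts = np.column_stack([u.ravel()[:n] * width, v.ravel()[:n] * height,
                           np.zeros(n)])
    return pts


def render_scene(params: SceneParams) -> SyntheticScene:
    """Render one scene deterministically under its seed."""
    H, W = params.height, params.width
    img = np.full((H, W), float(params.skin))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    annotations: dict[str, EyeAnnotation] = {}
    for side in ("right", "left"):
        eye = params.eye(side)
        cx, cy = eye.center
        y_u, y_l, _, half = _lid_curves(eye)
        inside_cols = np.abs(xx - cx) < half
        aperture = inside_cols & (yy > y_u(xx)) & (yy < y_l(xx))
        img[aperture] = params.sclera
        iris = aperture & ((xx - cx) ** 2 + (yy - cy) ** 2 <= eye.iris_radius**2)
        img[iris] = params.iris_intensity
        if eye.crease:
            crease_y = y_u(xx) - 0.35 * eye.iris_radius
            on_crease = inside_cols & (np.abs(yy - crease_y) < 0.7) & (
                np.abs(xx - cx) < 0.9 * half
            )
            img[on_crease] = max(0, params.skin - 45)
        annotations[side] = _annotate_eye(side, eye)

    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    peri = []
    for side in ("right", "left"):
        ann = annotations[side]
        peri.append(np.column_stack([ann.upper_lid.xy, np.zeros(POINTS_PER_LID)]))
        peri.append(np.column_stack([ann.lower_lid.xy, np.zeros(POINTS_PER_LID)]))
        c = ann.iris.center
        peri.append(np.array([[c.x, c.y, 0.0]]))
    peri_arr = np.vstack(peri)
    template = _canonical_template(N_MESH_POINTS - len(peri_arr), W, H)
    landmarks = np.vstack([peri_arr, template])

    return SyntheticScene(image=image, annotations=annotations,
                          landmarks=landmarks, params=params)


def ground_truth_landmark_provider(
    scene: SyntheticScene,
) -> tuple[np.ndarray, dict[str, EyeAnnotation]]:
    """Landmark provider backed by the scene's stored ground truth.

    Returns the 468-point mesh array and the exact per-eye annotations,
    satisfying the same interface an optional real face-mesh adapter would
    implement for photographs.
    """
    return scene.landmarks, scene.annotations


def sample_unilateral_cohort(
    n: int,
    severity: tuple[float, float] = (0.05, 0.55),
    seed: int = 0,
    base: SceneParams | None = None,
) -> list[SyntheticScene]:
    """Sample ``n`` unilateral-ptosis scenes, fully reproducible under seed.

    The fellow eye's MRR is drawn from the healthy band [0.75, 0.95]; the
    ptotic eye's from ``severity``. The affected side alternates draw by
    draw so both sides are represented, as in unilateral clinical cohorts.
    """
    if n < 1:
        raise ConfigurationError("cohort size must be >= 1")
    lo, hi = severity
    if lo > hi:
        raise ConfigurationError(f"empty severity range ({lo}, {hi})")
    if lo < -0.3 or hi > 1.1:
        raise ConfigurationError("severity range must lie within [-0.3, 1.1]")
    base = base or SceneParams()
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        side: Literal["left", "right"] = "left" if i % 2 == 0 else "right"
        fellow_mrr = float(rng.uniform(0.75, 0.95))
        ptotic_mrr = float(rng.uniform(lo, hi))
        eyes = {
            side: replace(base.eye(side), mrr=ptotic_mrr),
            ("right" if side == "left" else "left"): replace(
                base.eye("right" if side == "left" else "left"), mrr=fellow_mrr
            ),
        }
        params = replace(
            base,
            left_eye=eyes["left"],
            right_eye=eyes["right"],
            seed=int(rng.integers(2**31)),
            ptosis_side=side,
        )
        scenes.append(render_scene(params))
    return scenes
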