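import numpy as np
import pytest

from ptosiskit.geometry import EyeAnnotation, IrisObservation, LidContour, Point2D
from ptosiskit.synth import EyeParams, SceneParams, render_scene

from helpers import radial_eye


@pytest.fixture
def circle_eye() -> EyeAnnotation:
    """Eye whose outline has radius exactly 20 at every 15-degree grid angle."""
    eye = radial_eye((100.0, 100.0), np.full(24, 20.0))
    return eye


@pytest.fixture
def ellipse_eye() -> EyeAnnotation:
    """Outline on an ellipse with semi-axes 30 (horizontal) and 12 (vertical),
    vertices at the 15-degree grid angles."""
    a, b = 30.0, 12.0
    thetas = np.radians(np.arange(24) * 15.0)
    radii = a * b / np.sqrt((b * np.cos(thetas)) ** 2 + (a * np.sin(thetas)) ** 2)
    return radial_eye((100.0, 100.0), radii)


@pytest.fixture
def dodecagon_eye() -> EyeAnnotation:
    """Irregular 12-gon fixture (fixed radii) for oracle comparisons."""
    radii = np.array(
        [22.0, 21.0, 23.5, 22.5, 21.5, 23.0, 22.0, 21.2, 23.3, 22.8, 21.7, 22.4]
    )
    return radial_eye((100.0, 100.0), radii)


@pytest.fixture
def parabolic_eye() -> EyeAnnotation:
    """Realistic parabolic-lid annotation from the scene generator."""
    scene = render_scene(SceneParams(noise_sigma=0.0))
    return scene.annotations["left"]


@pytest.fixture
def default_scene():
    return render_scene(SceneParams(seed=7))


@pytest.fixture
def closed_eye_scene():
    """Severe-ptosis fixture: left eye's lid margin below the pupil center."""
    params = SceneParams(
        left_eye=EyeParams(center=(288.0, 96.0), mrr=-0.1),
        right_eye=EyeParams(center=(96.0, 96.0), mrr=0.85),
        seed=3,
        ptosis_side="left",
    )
    return render_scene(params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
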