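import numpy as np
import pytest

from ptosiskit.errors import ConfigurationError, InvalidAnnotationError, MeasurementError
from ptosiskit.geometry import EyeAnnotation, IrisObservation, LidContour, Point2D
from ptosiskit.metrics import compute_mrr
from ptosiskit.synth import EyeParams, SceneParams, render_scene
from ptosiskit.targets import (
    BundleConfig,
    TargetSpec,
    _raster_polyline,
    build_inpaint_mask,
    make_bundle,
    render_condition_edges,
    solve_target_lid,
)

from helpers import random_radial_eye, scale_eye


class TestTargetSpec:
    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.3])
    def test_mrr_range(self, bad):
        with pytest.raises(ConfigurationError):
            TargetSpec(bad)


class TestSolveTargetLid:
    def test_identity_when_target_equals_current(self, parabolic_eye):
        current, _, _ = compute_mrr(parabolic_eye)
        solved = solve_target_lid(parabolic_eye, TargetSpec(current))
        np.testing.assert_allclose(solved.xy, parabolic_eye.upper_lid.xy, atol=1e-9)

    def test_target_one_passes_through_iris_top(self, parabolic_eye):
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.0))
        top = parabolic_eye.iris.top
        assert float(solved.y_at(top.x)) == pytest.approx(top.y, abs=1e-9)

    def test_round_trip_parabolic(self, parabolic_eye):
        solved = solve_target_lid(parabolic_eye, TargetSpec(0.9))
        mrr, _, _ = compute_mrr(parabolic_eye.with_upper_lid(solved))
        assert mrr == pytest.approx(0.9, abs=1e-6)

    def test_round_trip_random(self, rng):
        for _ in range(100):
            eye = random_radial_eye(rng)
            target = float(rng.uniform(0.3, 1.1))
            solved = solve_target_lid(eye, TargetSpec(target))
            mrr, _, _ = compute_mrr(eye.with_upper_lid(solved))
            assert mrr == pytest.approx(target, abs=1e-6)

    def test_canthi_unmoved(self, parabolic_eye):
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.05))
        np.testing.assert_allclose(solved.xy[0], parabolic_eye.upper_lid.xy[0], atol=1e-9)
        np.testing.assert_allclose(solved.xy[-1], parabolic_eye.upper_lid.xy[-1], atol=1e-9)

    def test_monotone_in_target(self, parabolic_eye):
        lids = [
            solve_target_lid(parabolic_eye, TargetSpec(t)).xy[:, 1]
            for t in (0.4, 0.7, 0.95, 1.1)
        ]
        for lower_t, higher_t in zip(lids, lids[1:]):
            # larger target raises the lid everywhere (smaller image row)
            assert np.all(higher_t <= lower_t + 1e-12)

    def test_closed_eye_additive_fallback(self):
        scene = render_scene(
            SceneParams(left_eye=EyeParams(center=(288.0, 96.0), mrr=-0.1), seed=0)
        )
        eye = scene.annotations["left"]
        solved = solve_target_lid(eye, TargetSpec(0.85))
        assert float(solved.y_at(eye.iris.center.x)) == pytest.approx(
            eye.iris.center.y - 0.85 * eye.iris.radius, abs=1e-9
        )
        # full round trip through measurement
        mrr, _, _ = compute_mrr(eye.with_upper_lid(solved))
        assert mrr == pytest.approx(0.85, abs=1e-6)

    def test_fissure_collapse_rejected(self):
        # iris center sits below the lower lid: small targets pull the upper
        # lid through it
        upper = LidContour.from_array([[80, 100], [100, 90], [120, 100]], "upper")
        lower = LidContour.from_array([[80, 100], [100, 103], [120, 100]], "lower")
        eye = EyeAnnotation(
            side="left",
            iris=IrisObservation(Point2D(100.0, 110.0), 10.0),
            upper_lid=upper,
            lower_lid=lower,
            medial_canthus=Point2D(80, 100),
            lateral_canthus=Point2D(120, 100),
        )
        with pytest.raises(MeasurementError, match="palpebral fissure"):
            solve_target_lid(eye, TargetSpec(0.5))


class TestRasterRoundTrip:
    def test_rasterized_mrr_within_tolerance(self, rng):
        """Solved contours survive rasterization to a 256-px-wide eye crop."""
        for _ in range(30):
            raw = random_radial_eye(rng)
            width = abs(raw.lateral_canthus.x - raw.medial_canthus.x)
            eye = scale_eye(raw, 256.0 / width)
            target = float(rng.uniform(0.3, 1.1))
            solved = solve_target_lid(eye, TargetSpec(target))
            shape = (
                int(eye.iris.center.y + 300),
                int(eye.iris.center.x + 300),
            )
            stroke = _raster_polyline(solved.xy, shape)
            col = int(round(eye.iris.center.x))
            rows = np.flatnonzero(stroke[:, col])
            assert rows.size > 0
            r0 = eye.iris.center.y - float(rows.mean())
            assert r0 / eye.iris.radius == pytest.approx(target, abs=0.02)


class TestConditionEdges:
    def test_uniform_image_gives_contour_only(self, parabolic_eye):
        img = np.full((192, 384), 128, dtype=np.uint8)
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.0))
        mask = build_inpaint_mask(parabolic_eye, solved, 5.0, img.shape)
        edges = render_condition_edges(img, parabolic_eye, solved, mask)
        stroke = _raster_polyline(solved.xy, img.shape)
        assert np.array_equal(edges, stroke)

    def test_crease_disabled_by_default(self, parabolic_eye):
        img = np.full((192, 384), 128, dtype=np.uint8)
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.0))
        mask = build_inpaint_mask(parabolic_eye, solved, 5.0, img.shape)
        plain = render_condition_edges(img, parabolic_eye, solved, mask)
        with_crease = render_condition_edges(
            img, parabolic_eye, solved, mask, crease_offset=6.0
        )
        assert with_crease.sum() > plain.sum()

    def test_identity_target_edges_near_original_lid(self, default_scene):
        from scipy import ndimage

        eye = default_scene.annotations["left"]
        current, _, _ = compute_mrr(eye)
        solved = solve_target_lid(eye, TargetSpec(current))
        mask = build_inpaint_mask(eye, solved, 5.0, default_scene.image.shape)
        edges = render_condition_edges(default_scene.image, eye, solved, mask)
        lid_stroke = _raster_polyline(eye.upper_lid.xy, default_scene.image.shape)
        dist = ndimage.distance_transform_edt(~lid_stroke)
        lit_in_mask = edges & mask
        assert lit_in_mask.any()
        assert dist[lit_in_mask].max() <= 1.0

    def test_bad_thresholds(self, parabolic_eye):
        img = np.zeros((192, 384), dtype=np.uint8)
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.0))
        mask = np.ones(img.shape, dtype=bool)
        with pytest.raises(ConfigurationError):
            render_condition_edges(img, parabolic_eye, solved, mask,
                                   canny_low=150, canny_high=50)


def _flat_lid_eye():
    """Horizontal upper lid spanning 40 columns at row 100."""
    upper = LidContour.from_array(
        [[80, 100], [90, 100], [100, 100], [110, 100], [120, 100]], "upper"
    )
    lower = LidContour.from_array([[80, 100], [100, 112], [120, 100]], "lower")
    return EyeAnnotation(
        side="left",
        iris=IrisObservation(Point2D(100.0, 130.0), 5.0),  # disc clear of the band
        upper_lid=upper,
        lower_lid=lower,
        medial_canthus=Point2D(80, 100),
        lateral_canthus=Point2D(120, 100),
    )


class TestInpaintMask:
    def test_identity_target_margin_zero_is_stroke(self, parabolic_eye):
        solved = solve_target_lid(
            parabolic_eye, TargetSpec(compute_mrr(parabolic_eye)[0])
        )
        mask = build_inpaint_mask(parabolic_eye, solved, 0.0, (192, 384))
        stroke = _raster_polyline(parabolic_eye.upper_lid.xy, (192, 384))
        assert np.all(stroke[mask.sum(axis=1) > 0].sum(axis=1) > 0)
        assert np.all(mask[stroke])  # stroke fully covered
        # nothing beyond one pixel of the stroke
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(~stroke)
        assert dist[mask].max() <= 1.5

    def test_band_area_matches_pixel_count_oracle(self):
        eye = _flat_lid_eye()
        target = LidContour.from_array(
            [[80, 95], [90, 95], [100, 95], [110, 95], [120, 95]], "upper"
        )
        mask = build_inpaint_mask(eye, target, 0.0, (200, 200))
        # independent pixel-count oracle: integer columns 80..120, rows 95..100
        expected = 0
        for col in range(80, 121):
            expected += 100 - 95 + 1
        assert mask.sum() == expected

    def test_dilation_monotone(self, parabolic_eye, rng):
        solved = solve_target_lid(parabolic_eye, TargetSpec(1.0))
        m0 = build_inpaint_mask(parabolic_eye, solved, 0.0, (192, 384))
        for margin in (2.0, 5.0, 9.0):
            m = build_inpaint_mask(parabolic_eye, solved, margin, (192, 384))
            assert np.all(m[m0])

    def test_single_connected_component(self, default_scene):
        from scipy import ndimage

        eye = default_scene.annotations["right"]
        solved = solve_target_lid(eye, TargetSpec(1.0))
        mask = build_inpaint_mask(eye, solved, 5.0, default_scene.image.shape)
        _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        assert n == 1

    def test_visible_iris_excluded(self, default_scene):
        eye = default_scene.annotations["left"]
        solved = solve_target_lid(eye, TargetSpec(1.1))
        mask = build_inpaint_mask(eye, solved, 5.0, default_scene.image.shape)
        c, r = eye.iris.center, eye.iris.radius
        # a probe point well inside the iris, below both lid curves
        probe = (int(c.y + 0.6 * r), int(c.x))
        assert not mask[probe]


class TestMakeBundle:
    def test_bundle_invariants(self, default_scene):
        eye = default_scene.annotations["left"]
        bundle = make_bundle(default_scene.image, eye, TargetSpec(1.0))
        stroke = _raster_polyline(bundle.target_contour.xy, default_scene.image.shape)
        assert np.all(bundle.mask[stroke])
        assert bundle.edge_image.dtype == bool and bundle.mask.dtype == bool

    def test_edges_off_ablation(self, default_scene):
        eye = default_scene.annotations["left"]
        bundle = make_bundle(
            default_scene.image, eye, TargetSpec(1.0), BundleConfig(edges_off=True)
        )
        assert bundle.edge_image.sum() == 0

    def test_mask_off_ablation(self, default_scene):
        eye = default_scene.annotations["left"]
        full = make_bundle(default_scene.image, eye, TargetSpec(1.0))
        loose = make_bundle(
            default_scene.image, eye, TargetSpec(1.0), BundleConfig(mask_off=True)
        )
        assert loose.mask.sum() > full.mask.sum()
        # bounding-box mask covers the whole eye outline
        pts = np.vstack([eye.upper_lid.xy, eye.lower_lid.xy]).astype(int)
        assert np.all(loose.mask[pts[:, 1], pts[:, 0]])

    def test_save_artifacts(self, tmp_path, default_scene):
        eye = default_scene.annotations["left"]
        bundle = make_bundle(default_scene.image, eye, TargetSpec(1.0))
        manifest = bundle.save(tmp_path, "case")
        assert (tmp_path / manifest["edge_image"]).exists()
        assert (tmp_path / manifest["mask"]).exists()
        assert (tmp_path / "case_manifest.json").exists()
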