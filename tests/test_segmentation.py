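"""Registration, vocal-tract localization, tissue classification, outlines."""

import numpy as np
import pytest

from vtmod import segmentation as seg, synthetic as syn
from vtmod.core import (
    EstimationError,
    ExtractionError,
    ImageFrame,
    ImageSeries,
    PixelMask,
    RigidTransform,
    VTOutline,
)


class TestRigidTransformType:
    def test_inverse_composes_to_identity(self):
        t = RigidTransform(7.3, (4.2, -3.1))
        rt = t.compose(t.inverse())
        assert abs(rt.rotation_deg) < 1e-9
        assert np.allclose(rt.translation_mm, 0.0, atol=1e-9)

    def test_point_roundtrip(self):
        t = RigidTransform(-5.0, (2.0, 9.0))
        pts = np.array([[0.0, 0.0], [10.0, -4.0], [3.3, 7.7]])
        back = t.inverse().apply_points(t.apply_points(pts, pivot=(5, 5)), pivot=(5, 5))
        assert np.allclose(back, pts, atol=1e-9)


class TestApplyTransform:
    def test_identity_returns_input(self, reference_frame):
        out = seg.apply_transform(reference_frame, RigidTransform())
        assert np.allclose(out.intensities, reference_frame.intensities, atol=1e-9)

    def test_roundtrip_error_small(self, reference_frame):
        t = RigidTransform(4.0, (3.0, -2.0))
        moved = seg.apply_transform(reference_frame, t)
        back = seg.apply_transform(moved, t.inverse())
        interior = np.zeros(reference_frame.shape, bool)
        interior[10:-10, 10:-10] = True
        err = np.abs(back.intensities - reference_frame.intensities)[interior].mean()
        rng_intensity = np.ptp(reference_frame.intensities)
        assert err < 0.01 * rng_intensity

    def test_integer_pixel_translation_moves_impulse(self):
        img = np.zeros((21, 21))
        img[10, 10] = 100.0
        frame = ImageFrame(img, 2.5)
        out = seg.apply_transform(frame, RigidTransform(0.0, (2.5, 0.0)))
        assert out.intensities[10, 11] == pytest.approx(100.0)
        assert out.intensities[10, 10] == pytest.approx(0.0)


class TestEstimateRigid:
    def test_identity_for_identical_frames(self, reference_frame, static_mask):
        t = seg.estimate_rigid_transform(reference_frame, reference_frame, static_mask)
        assert abs(t.rotation_deg) < 0.1
        assert np.allclose(t.translation_mm, 0.0, atol=0.1)

    def test_planted_motion_recovered(self, template_outline, reference_frame, static_mask):
        motion = RigidTransform(3.0, (2.0, -1.0))
        frame = syn.render_frame(template_outline, rigid=motion, noise_sd=5.0, seed=1)
        est = seg.estimate_rigid_transform(frame, reference_frame, static_mask)
        truth = motion.inverse()
        assert est.rotation_deg == pytest.approx(truth.rotation_deg, abs=0.5)
        assert np.allclose(est.translation_mm, truth.translation_mm, atol=0.5)

    def test_labile_displacement_does_not_bias(self, reference_frame, static_mask):
        # same head motion, but the larynx additionally displaced ~10 mm
        motion = RigidTransform(3.0, (2.0, -1.0))
        displaced = syn.make_vocal_tract_contour(syn.ShapeParams(larynx_height=-0.7))
        frame = syn.render_frame(displaced, rigid=motion, noise_sd=5.0, seed=2)
        est = seg.estimate_rigid_transform(frame, reference_frame, static_mask)
        truth = motion.inverse()
        assert est.rotation_deg == pytest.approx(truth.rotation_deg, abs=0.5)
        assert np.allclose(est.translation_mm, truth.translation_mm, atol=0.5)

    def test_rotation_equivariance(self, template_outline, reference_frame, static_mask):
        base = RigidTransform(2.0, (1.0, 0.0))
        extra = 3.0
        f1 = syn.render_frame(template_outline, rigid=base)
        f2 = syn.render_frame(
            template_outline, rigid=RigidTransform(base.rotation_deg + extra, base.translation_mm)
        )
        t1 = seg.estimate_rigid_transform(f1, reference_frame, static_mask)
        t2 = seg.estimate_rigid_transform(f2, reference_frame, static_mask)
        assert (t1.rotation_deg - t2.rotation_deg) == pytest.approx(extra, abs=0.5)

    def test_flat_region_raises(self, reference_frame):
        flat = PixelMask(np.zeros(reference_frame.shape, bool))
        flat.mask[:5, :5] = True
        uniform = ImageFrame(np.full(reference_frame.shape, 7.0), 2.5)
        with pytest.raises(EstimationError):
            seg.estimate_rigid_transform(uniform, uniform, flat)


class TestHighVarianceMask:
    def test_constant_series_empty(self):
        frames = [ImageFrame(np.full((30, 30), 9.0), 2.5) for _ in range(5)]
        mask = seg.high_variance_mask(ImageSeries(frames))
        assert mask.count() == 0

    def test_quantile_monotonicity(self, cohort_session):
        series, _, result = cohort_session
        m90 = seg.high_variance_mask(result.registered, 0.90)
        m99 = seg.high_variance_mask(result.registered, 0.99)
        assert m99.count() <= m90.count()

    def test_covers_labile_pixels(self, cohort_session):
        series, gt, result = cohort_session
        airs = np.stack(
            [syn.rasterize_air_mask(gt.outlines[f.frame_index]) for f in series]
        )
        labile = airs.any(axis=0) & ~airs.all(axis=0)
        cand = seg.refine_candidates(seg.high_variance_mask(result.registered))
        assert (cand.mask & labile).sum() / labile.sum() >= 0.95

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            seg.high_variance_mask(ImageSeries([ImageFrame(np.zeros((5, 5)), 2.5)]))


class TestClassifyTissue:
    def test_noiseless_exact(self, template_outline):
        from scipy import ndimage

        frame = syn.render_frame(template_outline)
        gt_air = syn.rasterize_air_mask(template_outline)
        cand = PixelMask(ndimage.binary_dilation(gt_air, iterations=2))
        tissue = seg.classify_tissue(frame, cand)
        pred_air = cand.mask & ~tissue.mask
        core = ndimage.binary_erosion(gt_air)
        assert np.all(pred_air[core])
        assert not tissue.low_contrast

    def test_noise_accuracy(self, template_outline):
        from scipy import ndimage

        gt_air = syn.rasterize_air_mask(template_outline)
        cand = PixelMask(ndimage.binary_dilation(gt_air, iterations=2))
        accs = []
        for s in range(20):
            frame = syn.render_frame(template_outline, noise_sd=10.0, seed=s)
            tissue = seg.classify_tissue(frame, cand)
            pred_air = cand.mask & ~tissue.mask
            accs.append((pred_air == (gt_air & cand.mask))[cand.mask].mean())
        assert np.mean(accs) >= 0.98

    def test_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((30, 30)) > 0.5, 200.0, 10.0)
        img += rng.normal(0, 3, img.shape)
        frame = ImageFrame(img, 2.5)
        cand = PixelMask(np.ones((30, 30), bool))
        tissue = seg.classify_tissue(frame, cand)
        inv = seg.classify_tissue(ImageFrame(-img, 2.5), cand)
        # inverted intensities with swapped labels give the identical boundary
        assert np.array_equal(tissue.mask, cand.mask & ~inv.mask)

    def test_low_contrast_flag(self):
        rng = np.random.default_rng(1)
        frame = ImageFrame(rng.normal(100, 1.0, (30, 30)), 2.5)
        tissue = seg.classify_tissue(frame, PixelMask(np.ones((30, 30), bool)))
        assert tissue.low_contrast


class TestExtractOutline:
    def test_disk_perimeter(self):
        Y, X = np.mgrid[0:40, 0:40]
        disk = (X - 20) ** 2 + (Y - 20) ** 2 <= 100
        o = seg.extract_outline(
            PixelMask(~disk, "tissue"), PixelMask(np.ones((40, 40), bool)), 0, 2.5
        )
        assert o.closed and o.is_simple()
        assert o.perimeter() == pytest.approx(2 * np.pi * 10 * 2.5, rel=0.02)

    def test_artifact_ignored(self):
        Y, X = np.mgrid[0:40, 0:40]
        disk = (X - 15) ** 2 + (Y - 20) ** 2 <= 64
        artifact = (X - 35) ** 2 + (Y - 35) ** 2 <= 4  # < 10 px
        air = disk | artifact
        o = seg.extract_outline(
            PixelMask(~air, "tissue"), PixelMask(np.ones((40, 40), bool)), 0, 2.5
        )
        centroid = o.points.mean(axis=0)
        assert np.allclose(centroid, [15 * 2.5, 20 * 2.5], atol=2.5)

    def test_no_air_raises(self):
        with pytest.raises(ExtractionError):
            seg.extract_outline(
                PixelMask(np.ones((20, 20), bool), "tissue"),
                PixelMask(np.ones((20, 20), bool)),
            )

    def test_session_outlines_close_to_truth(self, cohort_session):
        series, gt, result = cohort_session
        hds = [
            seg.outline_hausdorff_mm(result.outlines[k], gt.outlines[f.frame_index])
            for k, f in enumerate(series)
        ]
        assert np.mean(hds) <= 2.5  # one pixel

    def test_session_dice(self, cohort_session):
        series, gt, result = cohort_session
        dices = [
            seg.dice_coefficient(
                result.air_masks[k], syn.rasterize_air_mask(gt.outlines[f.frame_index])
            )
            for k, f in enumerate(series)
        ]
        assert np.mean(dices) >= 0.95


class TestCorrectOutline:
    def test_empty_edits_identity(self, template_outline):
        out = seg.correct_outline(template_outline, [])
        assert np.array_equal(out.points, template_outline.points)

    def test_replace_with_same_value_identity(self, template_outline):
        pt = tuple(template_outline.points[5])
        out = seg.correct_outline(template_outline, [(5, pt)])
        assert np.array_equal(out.points, template_outline.points)

    def test_spike_correction_reduces_hausdorff(self, template_outline):
        spiked_pts = template_outline.points.copy()
        truth_pt = spiked_pts[40].copy()
        normal = spiked_pts[40] - spiked_pts[39]
        spiked_pts[40] += np.array([0.0, -5.0])  # 5 mm outlier spike
        spiked = VTOutline(spiked_pts, closed=True)
        before = seg.outline_hausdorff_mm(spiked, template_outline)
        fixed = seg.correct_outline(spiked, [(40, tuple(truth_pt))])
        after = seg.outline_hausdorff_mm(fixed, template_outline)
        assert after < before

    def test_self_intersection_rejected(self):
        square = VTOutline(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]), closed=True
        )
        with pytest.raises(ValueError, match="self-intersect"):
            seg.correct_outline(square, [(0, (15.0, 5.0))])

    def test_bad_index(self, template_outline):
        with pytest.raises(IndexError):
            seg.correct_outline(template_outline, [(10_000, (0.0, 0.0))])


class TestTranslationInvariance:
    def test_outline_area_invariant_to_series_translation(self, template_outline, reference_frame, static_mask):
        """Registration absorbs a constant shift of the input series."""
        from shapely.geometry import Polygon

        rng = np.random.default_rng(0)
        shapes = [
            (h, 0.45 * (-1) ** k, float(rng.normal(0, 1.5)), float(rng.normal(0, 1.5)))
            for k, h in enumerate(np.linspace(-0.5, 0.5, 8))
        ]

        def segment_with_shift(shift):
            frames = []
            for k, (h, tp, sway, velum) in enumerate(shapes):
                o = syn.make_vocal_tract_contour(
                    syn.ShapeParams(larynx_height=h, tongue_position=tp),
                    pharynx_sway_mm=sway,
                    velum_mm=velum,
                )
                f = syn.render_frame(o, rigid=RigidTransform(0.0, shift), noise_sd=0.0, seed=k)
                f.frame_index = k
                frames.append(f)
            series = ImageSeries(frames)
            res = seg.segment_series(series, reference_frame, static_mask)
            return [Polygon(o.points).area for o in res.outlines]

        a0 = segment_with_shift((0.0, 0.0))
        a1 = segment_with_shift((5.0, -5.0))
        assert np.allclose(a0, a1, rtol=0.02)
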