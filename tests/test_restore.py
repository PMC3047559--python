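"""Focus metric, multifocus fusion, usable-FOV and distortion correction."""

import numpy as np
import pytest
from scipy import ndimage

from pocketscope import restore, synth
from pocketscope.restore import (
    ImageStack,
    RadialDistortionModel,
    fit_pincushion,
    fuse_multifocus,
    sml_map,
    undistort,
    usable_fov,
)


class TestSmlMap:
    def test_constant_image_all_zero(self):
        assert not sml_map(np.full((32, 32), 7.0)).any()

    def test_single_bright_pixel(self):
        img = np.zeros((15, 15))
        img[7, 7] = 3.0
        ml = sml_map(img, step=1, window=1)
        assert ml[7, 7] == pytest.approx(4 * 3.0)

    def test_blur_lowers_mean_sml(self, grating_texture):
        blurred = ndimage.gaussian_filter(grating_texture, 2.0)
        assert sml_map(blurred).mean() < sml_map(grating_texture).mean()

    @pytest.mark.parametrize("window", [0, 2])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            sml_map(np.zeros((8, 8)), window=window)

    def test_window_larger_than_image(self):
        with pytest.raises(ValueError):
            sml_map(np.zeros((4, 4)), window=5)


class TestFusion:
    @pytest.mark.parametrize("transform", ["wavelet", "laplacian"])
    def test_identical_frames_idempotent(self, grating_texture, transform):
        fused, _ = fuse_multifocus(
            ImageStack([grating_texture, grating_texture.copy()]),
            transform=transform,
        )
        np.testing.assert_allclose(fused, grating_texture, atol=1e-8)

    def test_sharp_plus_blur_recovers_sharp(self, grating_texture):
        blurred = ndimage.gaussian_filter(grating_texture, 2.0)
        fused, dm = fuse_multifocus(ImageStack([grating_texture, blurred]))
        rng_span = grating_texture.max() - grating_texture.min()
        assert np.abs(fused - grating_texture).mean() < 0.01 * rng_span
        assert dm.pixel.max() < 2 and dm.pixel.min() >= 0

    def test_split_field_fusion_sharp_everywhere(self, grating_texture):
        """Each frame sharp on one half: the fusion must carry >= 95% of
        the per-region best SML on both halves."""
        blurred = ndimage.gaussian_filter(grating_texture, 2.0)
        left_sharp = grating_texture.copy()
        left_sharp[:, 256:] = blurred[:, 256:]
        right_sharp = blurred.copy()
        right_sharp[:, 256:] = grating_texture[:, 256:]
        fused, _ = fuse_multifocus(ImageStack([left_sharp, right_sharp]))
        s_fused = sml_map(fused)
        s_ref = sml_map(grating_texture)
        margin = 16
        left = np.s_[margin:-margin, margin : 256 - margin]
        right = np.s_[margin:-margin, 256 + margin : -margin]
        assert s_fused[left].mean() >= 0.95 * s_ref[left].mean()
        assert s_fused[right].mean() >= 0.95 * s_ref[right].mean()

    def test_permutation_invariance(self, grating_texture):
        blurred = ndimage.gaussian_filter(grating_texture, 2.0)
        a = grating_texture.copy()
        a[:, 256:] = blurred[:, 256:]
        b = blurred.copy()
        b[:, 256:] = grating_texture[:, 256:]
        f1, _ = fuse_multifocus(ImageStack([a, b]))
        f2, _ = fuse_multifocus(ImageStack([b, a]))
        span = grating_texture.max() - grating_texture.min()
        assert np.abs(f1 - f2).mean() < 0.005 * span

    def test_envelope_bounded(self, grating_texture):
        blurred = ndimage.gaussian_filter(grating_texture, 2.0)
        fused, _ = fuse_multifocus(ImageStack([grating_texture, blurred]))
        lo = min(grating_texture.min(), blurred.min())
        hi = max(grating_texture.max(), blurred.max())
        span = hi - lo
        assert fused.min() >= lo - 0.02 * span
        assert fused.max() <= hi + 0.02 * span

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            ImageStack([np.zeros((8, 8)), np.zeros((9, 8))])

    def test_single_frame_fusion_rejected(self):
        with pytest.raises(ValueError):
            fuse_multifocus(ImageStack([np.zeros((8, 8))]))

    def test_rgb_fusion_shape_and_chroma(self, grating_texture):
        rgb = np.stack(
            [grating_texture, 0.5 * grating_texture, 0.25 * grating_texture],
            axis=-1,
        )
        blurred = ndimage.gaussian_filter(rgb, (2.0, 2.0, 0))
        fused, _ = fuse_multifocus(ImageStack([rgb, blurred]))
        assert fused.shape == rgb.shape
        assert np.abs(fused - rgb).mean() < 0.02


class TestUsableFov:
    def test_uniformly_sharp_full_frame(self, grating_texture):
        out = usable_fov(grating_texture)
        assert out["side_px"] == 512

    def test_field_curvature_shrinks_and_threshold_monotone(self, curvature_stack):
        frame = curvature_stack.frames[0]
        sides = [
            usable_fov(frame, thr)["side_px"] for thr in (0.8, 0.5, 0.2)
        ]
        assert sides[0] < 512
        assert sides[0] <= sides[1] <= sides[2]

    def test_fusion_doubles_usable_area(self, curvature_stack):
        fused, _ = fuse_multifocus(
            ImageStack(curvature_stack.frames, curvature_stack.focal_offsets_um)
        )
        best_single = max(
            usable_fov(f)["side_px"] for f in curvature_stack.frames
        )
        fused_side = usable_fov(fused)["side_px"]
        assert fused_side / best_single >= 1.4  # area factor ~2

    def test_bad_threshold_rejected(self, grating_texture):
        with pytest.raises(ValueError):
            usable_fov(grating_texture, 1.5)


class TestDistortion:
    def _correspondences(self, k1, k2=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        ideal = rng.uniform(20.0, 492.0, (n, 2))
        model = RadialDistortionModel(np.array([256.0, 256.0]), k1, k2, 256.0)
        return model.distort_points(ideal), ideal

    def test_zero_distortion_fit(self):
        obs, ideal = self._correspondences(0.0)
        model, rms = fit_pincushion(obs, ideal, norm_radius=256.0)
        assert abs(model.k1) < 1e-6 and abs(model.k2) < 1e-6
        assert rms < 1e-6

    def test_k1_recovery_within_5pct(self):
        obs, ideal = self._correspondences(0.08)
        model, rms = fit_pincushion(obs, ideal, norm_radius=256.0)
        assert model.k1 == pytest.approx(0.08, rel=0.05)
        assert rms < 0.05

    @pytest.mark.parametrize("k1, sign", [(0.06, 1), (-0.06, -1)])
    def test_sign_convention(self, k1, sign):
        obs, ideal = self._correspondences(k1)
        model, _ = fit_pincushion(obs, ideal, norm_radius=256.0)
        assert np.sign(model.k1) == sign

    def test_degenerate_points_rejected(self):
        ideal = np.stack([np.linspace(0, 100, 15), np.linspace(0, 100, 15)], axis=1)
        with pytest.raises(ValueError):
            fit_pincushion(ideal, ideal)

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 100, (5, 2))
        with pytest.raises(ValueError):
            fit_pincushion(pts, pts)

    def test_roundtrip_points(self):
        model = RadialDistortionModel(np.array([128.0, 128.0]), 0.08, 0.01, 128.0)
        pts = np.random.default_rng(1).uniform(0, 256, (200, 2))
        back = model.undistort_points(model.distort_points(pts))
        assert np.abs(back - pts).max() < 0.05

    def test_identity_model_leaves_image(self, grating_texture):
        model = RadialDistortionModel(np.array([256.0, 256.0]), 0.0, 0.0, 256.0)
        out = undistort(grating_texture, model)
        assert np.abs(out - grating_texture).max() < 1e-9

    def test_image_roundtrip_smooth_scene(self):
        scene = ndimage.gaussian_filter(
            np.random.default_rng(2).standard_normal((256, 256)), 4.0
        )
        scene = (scene - scene.min()) / (scene.max() - scene.min())
        model = RadialDistortionModel(np.array([128.0, 128.0]), 0.06, 0.0, 128.0)
        rec = undistort(restore.distort_image(scene, model), model)
        inner = np.s_[8:-8, 8:-8]
        assert np.abs(rec - scene)[inner].mean() < 0.01

    def test_ronchi_lines_straight_after_undistort(self):
        """Warp a 20 lp/mm ruling with pincushion, undistort, and check the
        recovered bar edges are straight to < 0.5 px."""
        img = synth.make_ronchi(20.0, 5.0, (256, 256))
        model = RadialDistortionModel(np.array([128.0, 128.0]), 0.06, 0.0, 128.0)
        rec = undistort(restore.distort_image(img, model), model)
        # subpixel edge positions per row for a few dark->bright transitions
        devs = []
        for x0 in range(20, 236, 30):
            cols = []
            for row in range(40, 216):
                seg = rec[row, x0 - 4 : x0 + 5]
                d = np.diff(seg)
                j = int(np.argmax(np.abs(d)))
                if abs(d[j]) < 0.2:
                    continue
                frac = (0.5 - seg[j]) / d[j] if d[j] != 0 else 0.0
                cols.append(x0 - 4 + j + np.clip(frac, -1, 2))
            if len(cols) > 50:
                cols = np.asarray(cols)
                devs.append(np.abs(cols - np.median(cols)))
        assert devs, "no edges recovered"
        assert np.median(np.concatenate(devs)) < 0.5

    def test_scale_free_normalised_convention(self):
        obs, ideal = self._correspondences(0.08)
        model1, _ = fit_pincushion(obs, ideal, norm_radius=256.0)
        model2, _ = fit_pincushion(obs * 2.0, ideal * 2.0, norm_radius=512.0)
        assert model2.k1 == pytest.approx(model1.k1, rel=1e-6)
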