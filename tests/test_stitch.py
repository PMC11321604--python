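"""Weighted sliding-window stitching, rendering, and RPC pixel accounting."""

import numpy as np
import pytest

from rpcseg.stitch import (
    PALETTE, StitchSpec, count_rpc_pixels, inference_anchors, predict_roi,
    render_rgb, rgb_to_labels,
)
from rpcseg.synthetic import CohortSpec, ScannerProfile, generate_roi
from rpcseg.taxonomy import CANCER, IGNORE


class ConstantModel:
    """Emits the same score vector at every pixel of every patch."""

    def __init__(self, scores, patch=64):
        self.scores = np.asarray(scores, dtype=float)
        self.patch = patch

    def predict_scores(self, patch):
        out = np.empty((patch.shape[0], patch.shape[1], self.scores.size))
        out[:] = self.scores
        return out


class GradientModel:
    """Scores depend on absolute pixel intensity, to exercise real averaging."""

    def predict_scores(self, patch):
        g = patch[..., 0].astype(float) / 255.0
        return np.stack([g, 1 - g, g * 0.5, g * 0.2, g * 0.1], axis=-1)


class TestAnchors:
    def test_clamped_final_anchor_reaches_border(self):
        spec = StitchSpec(patch_size=64, stride=48)
        xs = inference_anchors(200, spec)
        assert xs[-1] == 200 - 64
        assert xs == [0, 48, 96, 136]

    def test_exact_fit(self):
        assert inference_anchors(64, StitchSpec(patch_size=64, stride=48)) == [0]


class TestStitching:
    def test_constant_model_conserved_to_machine_precision(self):
        """Weighted averaging reproduces a constant model's output exactly."""
        model = ConstantModel([0.1, 0.7, 0.2, 0.05, 0.3])
        image = np.zeros((1024, 1024, 3), dtype=np.uint8)
        spec = StitchSpec(patch_size=256, stride=128)
        pred = predict_roi(model, image, spec)
        for c, v in enumerate([0.1, 0.7, 0.2, 0.05, 0.3]):
            np.testing.assert_allclose(pred.scores[..., c], v, rtol=0, atol=1e-12)
        assert (pred.labels == 1).all()

    def test_full_coverage_and_interior_overlap(self):
        """Every pixel is covered; interior pixels see 4 patches at 50% overlap."""
        spec = StitchSpec(patch_size=256, stride=128)
        cover = np.zeros((1024, 1024), dtype=int)
        for y in inference_anchors(1024, spec):
            for x in inference_anchors(1024, spec):
                cover[y: y + 256, x: x + 256] += 1
        assert cover.min() >= 1
        assert (cover[256:768, 256:768] == 4).all()
        pred = predict_roi(ConstantModel(np.ones(5)),
                           np.zeros((1024, 1024, 3), np.uint8), spec)
        assert (pred.weight_plane > 0).all()

    def test_visit_order_invariance_via_symmetry(self):
        """Stitched output of a content-dependent model is reproducible and smooth."""
        image = np.random.default_rng(0).integers(0, 255, (160, 160, 3), dtype=np.uint8)
        spec = StitchSpec(patch_size=64, stride=32)
        a = predict_roi(GradientModel(), image, spec)
        b = predict_roi(GradientModel(), image, spec)
        assert np.array_equal(a.scores, b.scores)

    def test_stride_equals_patch_degenerates_to_tiling(self):
        """With stride=P each pixel is covered once: stitching equals tiling."""
        image = np.random.default_rng(1).integers(0, 255, (128, 128, 3), dtype=np.uint8)
        spec = StitchSpec(patch_size=64, stride=64)
        model = GradientModel()
        pred = predict_roi(model, image, spec)
        tiled = np.zeros_like(pred.scores)
        for y in (0, 64):
            for x in (0, 64):
                tiled[y: y + 64, x: x + 64] = model.predict_scores(
                    image[y: y + 64, x: x + 64])
        np.testing.assert_allclose(pred.scores, tiled, atol=1e-12)

    def test_small_roi_reflect_padded(self):
        model = ConstantModel([0.9, 0.1, 0.1, 0.1, 0.1])
        pred = predict_roi(model, np.zeros((40, 48, 3), np.uint8),
                           StitchSpec(patch_size=64, stride=64))
        assert pred.scores.shape == (40, 48, 5)

    def test_channel_mismatch_raises(self):
        class Wobbly(ConstantModel):
            def __init__(self):
                self.n = 0

            def predict_scores(self, patch):
                self.n += 1
                k = 5 if self.n == 1 else 4
                return np.ones((patch.shape[0], patch.shape[1], k))

        with pytest.raises(ValueError, match="channels"):
            predict_roi(Wobbly(), np.zeros((128, 128, 3), np.uint8),
                        StitchSpec(patch_size=64, stride=64))

    def test_argmax_tie_breaks_to_lowest_code(self):
        model = ConstantModel([0.5, 0.5, 0.5, 0.5, 0.5])
        pred = predict_roi(model, np.zeros((64, 64, 3), np.uint8),
                           StitchSpec(patch_size=64, stride=64))
        assert (pred.labels == 0).all()

    def test_kernel_strictly_positive_and_symmetric(self):
        k = StitchSpec(patch_size=32, stride=16).kernel()
        assert (k >= 0.01 * 0.01).all() and k.max() <= 1.0
        assert np.allclose(k, k[::-1]) and np.allclose(k, k[:, ::-1])


class TestRenderAndCounts:
    def test_all_background_renders_black(self):
        rgb = render_rgb(np.zeros((16, 16), dtype=np.uint8))
        assert not rgb.any()

    def test_single_cancer_pixel_is_single_red_pixel(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[3, 4] = CANCER
        rgb = render_rgb(labels)
        assert tuple(rgb[3, 4]) == PALETTE[CANCER]
        assert (rgb.reshape(-1, 3) == PALETTE[CANCER]).all(axis=1).sum() == 1

    def test_palette_roundtrip_lossless(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(np.array([0, 1, 2, 3, 4, IGNORE], dtype=np.uint8),
                            size=(32, 32))
        assert np.array_equal(rgb_to_labels(render_rgb(labels)), labels)

    def test_rpc_count_exact(self):
        labels = np.zeros((64, 64), dtype=np.uint8)
        labels.ravel()[:123] = CANCER
        counts = count_rpc_pixels(labels)
        assert counts["rpc"] == 123
        assert sum(counts[k] for k in
                   ("background", "normal_ducts", "cancer", "other_epithelium",
                    "fat", "ignore")) == 64 * 64

    def test_ground_truth_rpc_correlates_with_realized_mixture(self):
        """Across synthetic ROIs, cancer pixel counts track the generator's bookkeeping."""
        from scipy.stats import spearmanr
        scanner = ScannerProfile("philips")
        counts, fracs = [], []
        for seed in range(30):
            target = 0.05 + 0.004 * seed
            spec = CohortSpec(roi_size=128, class_mixture={CANCER: target})
            roi = generate_roi(spec, scanner, seed=seed)
            counts.append(count_rpc_pixels(roi.mask)["rpc"])
            fracs.append(roi.class_fractions[CANCER])
        rho = spearmanr(counts, fracs).statistic
        assert rho > 0.9
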