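"""Mask generation (Methods 1 and 2), mask ops and the end-to-end pipeline."""

import math

import numpy as np
import pytest

from ingseg.attnet import FeatureMaps
from ingseg.seg_metrics import EvaluationInstance, image_metrics
from ingseg.segmentation import (
    DegenerateInputError,
    MaskSet,
    Method1Params,
    Method2Params,
    binarize_map,
    blue_background_composite,
    blue_region,
    channel_scores,
    correlation_groups,
    extract_segments,
    filter_channels,
    method1_generate_masks,
    method2_generate_masks,
    pairwise_channel_correlation,
    segment_image,
    upscale_masks,
)


def fmaps(values):
    values = np.asarray(values, dtype=np.float32)
    return FeatureMaps(values=values, source_image_size=(values.shape[0] * 8,
                                                         values.shape[1] * 8))


class TestMethod1Filter:
    def test_constant_zero_channel_dropped(self):
        f = fmaps(np.zeros((4, 4, 1)))
        assert channel_scores(f)[0] == pytest.approx(0.5)
        assert filter_channels(f).size == 0  # sigma(0) = 0.5 is not > 0.5

    def test_mean_one_channel_retained(self):
        f = fmaps(np.ones((4, 4, 1)))
        # sigma(1) ~ 0.731
        assert channel_scores(f)[0] == pytest.approx(1 / (1 + math.exp(-1)))
        assert list(filter_channels(f)) == [0]

    def test_filter_decision_iff_positive_mean(self, rng):
        vals = rng.standard_normal((6, 6, 32)).astype(np.float32)
        f = fmaps(vals)
        kept = set(filter_channels(f).tolist())
        expected = {c for c in range(32) if vals[:, :, c].mean() > 0}
        assert kept == expected


class TestMethod1Correlation:
    def test_proportional_channels_correlation_one(self, rng):
        a = rng.random((5, 5)).astype(np.float32) + 0.1
        stack = np.stack([a, 2 * a])
        r = pairwise_channel_correlation(stack)
        assert r[0, 1] == pytest.approx(1.0)

    def test_orthogonal_patterns_correlation_zero(self):
        # means 2 > 0 so both would pass the filter, but r = 0 exactly
        c1 = np.array([[3, 1], [3, 1]], dtype=np.float32)
        c2 = np.array([[3, 3], [1, 1]], dtype=np.float32)
        r = pairwise_channel_correlation(np.stack([c1, c2]))
        assert r[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_channel_correlates_zero(self, rng):
        stack = np.stack([np.full((3, 3), 2.0), rng.random((3, 3))])
        r = pairwise_channel_correlation(stack)
        assert r[0, 1] == 0.0

    def test_hand_computed_merge_decision(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]], dtype=np.float32)
        vals = np.stack([a, 2 * a, np.array([[3, 3], [1, 1]], dtype=np.float32)],
                        axis=2)
        masks = method1_generate_masks(fmaps(vals))
        # channels 0 and 1 merge (r = 1); channel 2 stays alone (r <= 0)
        sources = sorted(tuple(p["channels"]) for p in masks.provenance)
        assert sources == [(0, 1), (2,)]

    def test_transitive_groups(self):
        r = np.array([[1.0, 0.5, 0.0],
                      [0.5, 1.0, 0.5],
                      [0.0, 0.5, 1.0]])
        assert correlation_groups(r) == [[0, 1, 2]]

    def test_merging_is_permutation_invariant(self, rng):
        vals = rng.standard_normal((6, 6, 10)).astype(np.float32) + 0.3
        f = fmaps(vals)
        base = method1_generate_masks(f)
        perm = rng.permutation(10)
        fp = fmaps(vals[:, :, perm])
        permuted = method1_generate_masks(fp)
        key = lambda ms: sorted(m.tobytes() for m in ms.masks)
        assert key(base) == key(permuted)


class TestBinarization:
    def test_minmax_threshold(self):
        m = np.array([[0.0, 1.0], [0.2, 0.8]])
        mask = binarize_map(m)
        assert mask.tolist() == [[False, True], [False, True]]

    def test_constant_map_gives_empty_mask(self):
        assert not binarize_map(np.full((3, 3), 5.0)).any()

    def test_masks_always_have_foreground_or_are_discarded(self, rng):
        vals = rng.standard_normal((5, 5, 20)).astype(np.float32)
        masks = method1_generate_masks(fmaps(vals))
        for m in masks.masks:
            assert m.dtype == bool
            assert m.any()

    def test_otsu_policy(self, rng):
        m = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(5, 0.1, 50)])
        mask = binarize_map(m.reshape(10, 10), policy="otsu")
        # otsu separates the two modes up to histogram binning slack
        assert 45 <= mask.sum() <= 55

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="policy"):
            binarize_map(np.arange(4.0).reshape(2, 2), policy="median")


class TestMethod1EndToEnd:
    def test_all_filtered_out_gives_empty_set(self):
        f = fmaps(np.full((4, 4, 3), -5.0))
        masks = method1_generate_masks(f)
        assert len(masks) == 0

    def test_provenance_tracks_original_channel_ids(self, rng):
        vals = np.full((4, 4, 5), -5.0, dtype=np.float32)
        vals[:, :, 3] = rng.random((4, 4)) + 0.5
        masks = method1_generate_masks(fmaps(vals))
        assert len(masks) == 1
        assert masks.provenance[0]["channels"] == [3]


class TestMethod2:
    def test_k1_no_background_single_full_mask(self, rng):
        f = fmaps(rng.random((4, 4, 3)))
        masks = method2_generate_masks(f, Method2Params(k=1))
        assert len(masks) == 1
        assert masks.masks[0].all()

    def test_separable_halves_recovered(self):
        u, v = np.array([5.0, 0.0]), np.array([0.0, 5.0])
        vals = np.zeros((4, 6, 2), dtype=np.float32)
        vals[:, :3] = u
        vals[:, 3:] = v
        masks = method2_generate_masks(fmaps(vals), Method2Params(k=2, seed=0))
        left = np.zeros((4, 6), dtype=bool)
        left[:, :3] = True
        found = {m.tobytes() for m in masks.masks}
        assert found == {left.tobytes(), (~left).tobytes()}

    def test_partition_before_background_removal(self, rng):
        f = fmaps(rng.random((6, 6, 4)))
        masks = method2_generate_masks(f, Method2Params(k=3, seed=1))
        assert len(masks) == 3
        total = np.zeros((6, 6), dtype=int)
        for m in masks.masks:
            total += m
        assert np.all(total == 1)  # disjoint and exhaustive

    def test_background_cluster_dropped(self):
        # two planted foreground values + uniform third region marked blue
        vals = np.zeros((6, 6, 3), dtype=np.float32)
        vals[:2] = [4.0, 0.0, 0.0]
        vals[2:4] = [0.0, 4.0, 0.0]
        vals[4:] = [0.0, 0.0, 4.0]
        bg_region = np.zeros((48, 48), dtype=bool)
        bg_region[32:] = True  # maps onto the bottom third
        masks = method2_generate_masks(
            fmaps(vals), Method2Params(k=2, background_present=True, seed=0),
            background_region=bg_region,
        )
        assert len(masks) == 2
        union = masks.masks[0] | masks.masks[1]
        assert not union[4:].any()
        assert union[:4].all()

    def test_background_without_region_errors(self, rng):
        f = fmaps(rng.random((4, 4, 2)))
        with pytest.raises(ValueError, match="background_region"):
            method2_generate_masks(f, Method2Params(k=1, background_present=True))

    def test_degenerate_input_named(self):
        f = fmaps(np.ones((4, 4, 3)))
        with pytest.raises(DegenerateInputError, match="identical"):
            method2_generate_masks(f, Method2Params(k=2))

    def test_too_many_clusters(self):
        f = fmaps(np.arange(8, dtype=np.float32).reshape(2, 2, 2))
        with pytest.raises(ValueError, match="exceed"):
            method2_generate_masks(f, Method2Params(k=5))

    def test_stable_across_restart_counts_on_separable_input(self):
        vals = np.zeros((4, 4, 2), dtype=np.float32)
        vals[:2] = [3.0, 0.0]
        vals[2:] = [0.0, 3.0]
        a = method2_generate_masks(fmaps(vals), Method2Params(k=2, restarts=1))
        b = method2_generate_masks(fmaps(vals), Method2Params(k=2, restarts=8))
        assert {m.tobytes() for m in a.masks} == {m.tobytes() for m in b.masks}

    def test_params_validation(self):
        with pytest.raises(ValueError):
            Method2Params(k=0)
        with pytest.raises(ValueError):
            Method2Params(k=1, restarts=0)


class TestUpscale:
    def test_2x2_block_expansion(self):
        m = np.array([[True, False], [False, True]])
        up = upscale_masks(MaskSet(masks=[m], method="test"), (4, 4))
        expected = np.kron(m, np.ones((2, 2), dtype=bool))
        assert np.array_equal(up.masks[0], expected)

    def test_all_ones_stays_all_ones(self):
        m = np.ones((3, 3), dtype=bool)
        up = upscale_masks(MaskSet(masks=[m], method="test"), (10, 7))
        assert up.masks[0].all()
        assert up.masks[0].shape == (10, 7)

    def test_foreground_fraction_preserved(self, rng):
        for _ in range(10):
            m = rng.random((8, 8)) > 0.5
            up = upscale_masks(MaskSet(masks=[m], method="test"), (32, 32))
            frac_before = m.mean()
            frac_after = up.masks[0].mean()
            # +/- one row/column of quantization slack
            assert abs(frac_before - frac_after) <= 2 / 8

    def test_bad_target(self):
        with pytest.raises(ValueError):
            upscale_masks(MaskSet(masks=[], method="test"), (0, 4))


class TestExtractSegments:
    def test_all_ones_identity(self, rng):
        img = rng.integers(0, 255, size=(6, 6, 3)).astype(np.uint8)
        seg = extract_segments(img, MaskSet(masks=[np.ones((6, 6), dtype=bool)],
                                            method="t"))[0]
        assert np.array_equal(seg, img)

    def test_all_zeros_black(self, rng):
        img = rng.integers(1, 255, size=(6, 6, 3)).astype(np.uint8)
        seg = extract_segments(img, MaskSet(masks=[np.zeros((6, 6), dtype=bool)],
                                            method="t"))[0]
        assert not seg.any()

    def test_per_pixel_agreement(self, rng):
        img = rng.integers(1, 255, size=(6, 6, 3)).astype(np.uint8)
        mask = rng.random((6, 6)) > 0.5
        seg = extract_segments(img, MaskSet(masks=[mask], method="t"))[0]
        assert np.array_equal(seg[mask], img[mask])
        assert not seg[~mask].any()

    def test_shape_mismatch(self, rng):
        img = rng.integers(0, 255, size=(6, 6, 3)).astype(np.uint8)
        with pytest.raises(ValueError, match="match"):
            extract_segments(img, MaskSet(masks=[np.ones((3, 3), dtype=bool)],
                                          method="t"))


class TestBlueBackground:
    def test_background_pixels_exactly_blue(self, rng):
        img = rng.integers(0, 255, size=(10, 10, 3)).astype(np.uint8)
        label_map = (rng.random((10, 10)) > 0.4).astype(np.uint8)  # ~40% bg
        out = blue_background_composite(img, label_map)
        bg = label_map == 0
        assert np.all(out[bg] == (0, 0, 255))
        assert np.array_equal(out[~bg], img[~bg])

    def test_no_background_unchanged(self, rng):
        img = rng.integers(0, 255, size=(5, 5, 3)).astype(np.uint8)
        out = blue_background_composite(img, np.ones((5, 5), dtype=np.uint8))
        assert np.array_equal(out, img)

    def test_all_background_uniform_blue(self, rng):
        img = rng.integers(0, 255, size=(5, 5, 3)).astype(np.uint8)
        out = blue_background_composite(img, np.zeros((5, 5), dtype=np.uint8))
        assert np.all(out == (0, 0, 255))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            blue_background_composite(np.zeros((4, 4, 3), dtype=np.uint8),
                                      np.zeros((3, 3), dtype=np.uint8))

    def test_blue_region_detects_composite(self, rng):
        img = rng.integers(60, 200, size=(8, 8, 3)).astype(np.uint8)
        label_map = np.ones((8, 8), dtype=np.uint8)
        label_map[:3] = 0
        out = blue_background_composite(img, label_map)
        assert np.array_equal(blue_region(out), label_map == 0)


class TestSegmentImagePipeline:
    @pytest.fixture(scope="class")
    def scene(self, class_specs8):
        from ingseg.synthetic import SceneSpec, compose_multi_ingredient_scene

        return compose_multi_ingredient_scene(
            SceneSpec(k=2, class_ids=(0, 3), size=64, seed=5), class_specs8
        )

    def test_masks_cover_foreground(self, trained_slm, scene):
        masks, segments = segment_image(
            trained_slm.model, scene.blue_image, "2",
            Method2Params(k=2, background_present=True, seed=0),
        )
        assert len(masks) == 2
        assert len(segments) == 2
        union = masks.masks[0] | masks.masks[1]
        fg = scene.label_map > 0
        # union covers most of the non-background pixels
        assert np.count_nonzero(union & fg) / np.count_nonzero(fg) > 0.7

    def test_deterministic(self, trained_slm, scene):
        params = Method2Params(k=2, background_present=True, seed=0)
        m1, _ = segment_image(trained_slm.model, scene.blue_image, "2", params)
        m2, _ = segment_image(trained_slm.model, scene.blue_image, "2", params)
        assert all(np.array_equal(a, b) for a, b in zip(m1.masks, m2.masks))

    def test_trained_model_beats_iou_floor(self, trained_slm, scene):
        masks, _ = segment_image(
            trained_slm.model, scene.blue_image, "2",
            Method2Params(k=2, background_present=True, seed=0),
        )
        gts = [scene.label_map == r for r in (1, 2)]
        rec = image_metrics(EvaluationInstance(
            gts=gts, segments=[m for m in masks.masks if m.any()]))
        assert rec.m_iou > 0.5

    def test_method1_route(self, trained_slm, scene):
        masks, segments = segment_image(trained_slm.model, scene.blue_image,
                                        "1", Method1Params())
        assert len(masks) == len(segments)
        for m in masks.masks:
            assert m.shape == scene.blue_image.shape[:2]

    def test_unknown_method(self, trained_slm, scene):
        with pytest.raises(ValueError, match="method"):
            segment_image(trained_slm.model, scene.blue_image, "7",
                          Method1Params())

    def test_wrong_params_type(self, trained_slm, scene):
        with pytest.raises(TypeError):
            segment_image(trained_slm.model, scene.blue_image, "2",
                          Method1Params())


def test_maskset_rejects_nonbinary():
    with pytest.raises(ValueError, match="binary"):
        MaskSet(masks=[np.zeros((2, 2), dtype=np.uint8)], method="t")


def test_maskset_rejects_mixed_shapes():
    with pytest.raises(ValueError, match="shape"):
        MaskSet(masks=[np.zeros((2, 2), dtype=bool),
                       np.zeros((3, 3), dtype=bool)], method="t")
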