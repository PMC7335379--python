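import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import microtissue as mt
from microtissue.segmentation import (
    FLAG_DEGENERATE,
    FLAG_IMPLAUSIBLE,
    FLAG_NO_TISSUE,
    DegenerateThresholdError,
    EmptyMaskError,
    ImageFrame,
    SegConfig,
    binarize,
    largest_component_fill,
    pixels_to_area,
    segment_frame,
    segment_strategy_a,
    segment_strategy_b,
)

from conftest import frame_at
from oracles import largest_component_fill_oracle, otsu_oracle


# ---------------------------------------------------------------- binarize
def test_fixed_threshold_selects_dark_pixels():
    rng = np.random.default_rng(0)
    img = np.where(rng.random((40, 40)) < 0.3, 10.0, 200.0)
    mask, thr = binarize(img, threshold=100.0)
    assert thr == 100.0
    assert np.array_equal(mask, img == 10.0)


def test_inverted_frame_with_flipped_side_gives_same_mask():
    rng = np.random.default_rng(1)
    img = np.where(rng.random((40, 40)) < 0.3, 10.0, 200.0)
    mask_dark, _ = binarize(img, threshold=100.0, tissue_dark=True)
    mask_bright, _ = binarize(210.0 - img, threshold=110.0, tissue_dark=False)
    assert np.array_equal(mask_dark, mask_bright)


def test_auto_threshold_on_two_gaussian_histogram_matches_oracle():
    rng = np.random.default_rng(7)
    img = np.concatenate(
        [rng.normal(50, 10, 6000), rng.normal(180, 10, 6000)]
    ).reshape(120, 100)
    _, thr = binarize(img, "auto")
    assert 80.0 <= thr <= 150.0
    assert thr == pytest.approx(otsu_oracle(img), abs=3.0)


def test_constant_frame_is_degenerate():
    with pytest.raises(DegenerateThresholdError):
        binarize(np.full((10, 10), 5.0), "auto")


def test_out_of_range_fixed_threshold_rejected():
    with pytest.raises(ValueError):
        binarize(np.zeros((5, 5)) + 10.0, threshold=99.0)


# --------------------------------------------- largest_component_fill
def test_keeps_larger_of_two_squares():
    mask = np.zeros((40, 40), bool)
    mask[2:12, 2:12] = True      # 10x10
    mask[20:25, 20:25] = True    # 5x5
    out = largest_component_fill(mask)
    expected = np.zeros_like(mask)
    expected[2:12, 2:12] = True
    assert np.array_equal(out, expected)


def test_ring_fills_to_solid_square():
    mask = np.zeros((15, 15), bool)
    mask[3:12, 3:12] = True
    mask[4:11, 4:11] = False     # 1-px ring, outer size 9x9
    out = largest_component_fill(mask)
    assert out.sum() == 81
    assert out[7, 7]


def test_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        largest_component_fill(np.zeros((5, 5), bool))


def test_tie_break_smallest_first_index():
    mask = np.zeros((10, 10), bool)
    mask[6:9, 6:9] = True
    mask[0:3, 0:3] = True        # same size, earlier row-major index
    out = largest_component_fill(mask)
    assert out[0, 0] and not out[6, 6]


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((24, 24)) < 0.45
    if not mask.any():
        return
    assert np.array_equal(largest_component_fill(mask),
                          largest_component_fill_oracle(mask))


# ----------------------------------------------------- strategy A
def test_strategy_a_recovers_noise_free_area(clean_scene):
    scene, r = clean_scene
    for i in (0, 20, 48):
        res = segment_strategy_a(frame_at(scene, r, i))
        assert res.strategy_used == "A"
        assert not res.quality_flags
        assert abs(res.area - r.areas[i]) / r.areas[i] <= 0.02


def test_strategy_a_flags_featureless_frame():
    rng = np.random.default_rng(0)
    frame = ImageFrame(rng.normal(0.7, 0.01, (120, 120)), 8.0)
    res = segment_strategy_a(frame)
    assert FLAG_NO_TISSUE in res.quality_flags


def test_strategy_a_flags_implausibly_large_mask():
    rng = np.random.default_rng(1)
    img = np.full((100, 100), 0.2) + rng.normal(0, 0.005, (100, 100))
    img[:3] = 0.9                      # 97% of pixels on the dark side
    res = segment_strategy_a(ImageFrame(img, 8.0))
    assert FLAG_IMPLAUSIBLE in res.quality_flags


def test_strategy_a_oracle_equivalence_on_binary_frame(clean_scene):
    """On a noise-free two-level frame the strategy-A mask equals the
    rendered ground-truth silhouette exactly (posts are interior)."""
    scene, r = clean_scene
    soft = r.masks[0].astype(float)
    img = 0.78 - 0.40 * soft
    res = segment_strategy_a(ImageFrame(img, scene.pixel_size))
    assert np.array_equal(res.mask, r.masks[0])


# ----------------------------------------------------- strategy B
def test_strategy_b_handles_illumination_gradient(gradient_scene):
    scene, r = gradient_scene
    for i in (0, 24, 48):
        res = segment_strategy_b(frame_at(scene, r, i))
        assert not res.quality_flags
        assert abs(res.area - r.areas[i]) / r.areas[i] <= 0.05


def test_strategy_b_degenerate_on_constant_frame():
    res = segment_strategy_b(ImageFrame(np.full((50, 50), 0.5), 8.0))
    assert FLAG_DEGENERATE in res.quality_flags


def test_strategies_agree_on_clean_high_contrast_frame(clean_scene):
    scene, r = clean_scene
    frame = frame_at(scene, r, 0)
    a = segment_strategy_a(frame)
    b = segment_strategy_b(frame)
    assert abs(a.area - b.area) / a.area <= 0.03


# ----------------------------------------------------- segment_frame
def test_fallback_clean_uses_a(clean_scene):
    scene, r = clean_scene
    res = segment_frame(frame_at(scene, r, 10))
    assert res.strategy_used == "A"
    assert not res.quality_flags


def test_fallback_gradient_uses_b(gradient_scene):
    scene, r = gradient_scene
    res = segment_frame(frame_at(scene, r, 10))
    assert res.strategy_used == "B"
    assert res.fallback_from_a
    assert not res.quality_flags


def test_fallback_constant_frame_fails_both():
    res = segment_frame(ImageFrame(np.full((50, 50), 0.5), 8.0))
    assert res.failed
    assert res.fallback_from_a


def test_segment_frame_deterministic(default_scene):
    scene, r = default_scene
    f = frame_at(scene, r, 5)
    r1, r2 = segment_frame(f), segment_frame(f)
    assert np.array_equal(r1.mask, r2.mask)
    assert r1.pixel_count == r2.pixel_count


def test_auto_threshold_invariant_to_affine_rescaling(clean_scene):
    scene, r = clean_scene
    img = r.stack[5].astype(float)
    base = segment_frame(ImageFrame(img, scene.pixel_size))
    scaled = segment_frame(ImageFrame(0.013 * img + 7.5, scene.pixel_size))
    assert scaled.strategy_used == base.strategy_used == "A"
    assert scaled.pixel_count == base.pixel_count


def test_result_mask_is_single_filled_component(default_scene):
    from scipy import ndimage

    scene, r = default_scene
    res = segment_frame(frame_at(scene, r, 30))
    _, n = ndimage.label(res.mask, structure=np.ones((3, 3)))
    assert n == 1
    assert np.array_equal(ndimage.binary_fill_holes(res.mask), res.mask)
    assert res.pixel_count == int(res.mask.sum())
    assert res.area == pixels_to_area(res.pixel_count, scene.pixel_size)


# ----------------------------------------------------- pixels_to_area
@pytest.mark.parametrize(
    "count,size,expected",
    [(100, 10.0, 0.01), (0, 5.0, 0.0), (1, 1.0, 1e-6)],
)
def test_pixel_area_conversion(count, size, expected):
    assert pixels_to_area(count, size) == pytest.approx(expected)


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        pixels_to_area(-1, 10.0)


@given(st.integers(0, 10**6), st.floats(0.1, 100.0))
@settings(max_examples=50, deadline=None)
def test_area_scales_quadratically_with_pixel_size(count, size):
    assert pixels_to_area(count, 2 * size) == pytest.approx(
        4 * pixels_to_area(count, size), rel=1e-12
    )
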