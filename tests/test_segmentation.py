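"""Shoot segmentation: index arithmetic, thresholding, branch dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import teaprof as tp
from teaprof.segmentation import Lighting

from conftest import brute_force_otsu


# -- average gray and lighting classification --------------------------------


def test_average_gray_constant_and_symmetry():
    img = np.full((10, 10, 3), 100, dtype=np.uint8)
    assert tp.average_gray(img) == pytest.approx(100.0)
    img2 = np.zeros((2, 10, 3), dtype=np.uint8)
    img2[0] = 200
    assert tp.average_gray(img2) == pytest.approx(100.0)


@given(hnp.arrays(np.uint8, (16, 16, 3)))
@settings(max_examples=50, deadline=None)
def test_average_gray_matches_per_pixel_luminance(img):
    expect = np.mean(
        0.299 * img[..., 0].astype(float)
        + 0.587 * img[..., 1].astype(float)
        + 0.114 * img[..., 2].astype(float)
    )
    assert abs(tp.average_gray(img) - expect) <= 0.5


@pytest.mark.parametrize(
    "ag,label",
    [
        (124.0, Lighting.LOW_LIGHT),   # overcast field frame
        (166.0, Lighting.HIGH_LIGHT),  # sunny field frame
        (90.0, Lighting.LOW_LIGHT),
        (140.0, Lighting.HIGH_LIGHT),  # 140 belongs to the high band
        (220.0, Lighting.HIGH_LIGHT),
        (89.9, Lighting.OUT_OF_RANGE),
        (220.1, Lighting.OUT_OF_RANGE),
    ],
)
def test_classify_lighting_boundaries(ag, label):
    assert tp.classify_lighting(ag).label is label


# -- super-green index -------------------------------------------------------


@pytest.mark.parametrize(
    "rgb,expect",
    [
        ((100, 100, 100), 50),   # 200 - 50 - 100
        ((0, 255, 0), 255),      # clamp ceiling
        ((255, 0, 255), 0),      # clamp floor
        ((101, 100, 0), 150),    # R/2 is exact halving: 200 - 50.5 = 149.5 -> 150
    ],
)
def test_supergreen_hand_values(rgb, expect):
    img = np.array([[rgb]], dtype=np.uint8)
    assert tp.supergreen(img)[0, 0] == expect


@given(hnp.arrays(np.uint8, (8, 8, 3)))
@settings(max_examples=50, deadline=None)
def test_supergreen_range_and_green_dominance(img):
    sg = tp.supergreen(img)
    assert sg.dtype == np.uint8
    g = img[..., 1].astype(int)
    dominant = (g >= img[..., 0]) & (g >= img[..., 2]) & (g > 0)
    # 2G - R/2 - B >= 2G - G/2 - G = G/2 when G dominates
    assert np.all(sg[dominant] >= np.floor(g[dominant] / 2.0))


# -- CLAHE -------------------------------------------------------------------


def test_clahe_constant_stays_constant():
    img = np.full((64, 64, 3), 120, dtype=np.uint8)
    out = tp.clahe_enhance(img)
    assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1


def test_clahe_output_in_range_and_shape(low_frame):
    _, frame, _ = low_frame
    out = tp.clahe_enhance(frame.rgb)
    assert out.shape == frame.rgb.shape and out.dtype == np.uint8


def test_clahe_increases_mode_separation():
    """A low-contrast bimodal frame becomes more separated after CLAHE."""
    rng = np.random.default_rng(0)
    gray = np.where(rng.random((64, 64)) < 0.5, 110, 130).astype(np.uint8)
    img = np.stack([gray] * 3, axis=-1)
    out = tp.clahe_enhance(img)
    out_gray = out.mean(axis=2)
    before = 130 - 110
    after = out_gray[gray == 130].mean() - out_gray[gray == 110].mean()
    assert after > before


def test_clahe_rejects_too_small_images():
    img = np.full((4, 4, 3), 50, dtype=np.uint8)
    with pytest.raises(tp.ParameterError):
        tp.clahe_enhance(img)


# -- specular mask -----------------------------------------------------------


def test_specular_rule_min_channel():
    img = np.array([[[255, 255, 255], [250, 250, 200]]], dtype=np.uint8)
    mask = tp.specular_mask(img)
    assert mask[0, 0] and not mask[0, 1]


# -- Otsu --------------------------------------------------------------------


def test_otsu_bimodal_matches_brute_force():
    gray = np.array([10] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
    t = tp.otsu_threshold(gray)
    assert t == brute_force_otsu(gray)
    assert 10 <= t < 200


def test_otsu_zero_exclusion_matches_zero_free_image():
    rng = np.random.default_rng(1)
    content = np.where(rng.random(400) < 0.5,
                       rng.integers(30, 60, 400),
                       rng.integers(150, 200, 400)).astype(np.uint8)
    padded = np.concatenate([np.zeros(200, np.uint8), content])
    assert tp.otsu_threshold(padded, exclude_zero=True) == tp.otsu_threshold(content)


def test_otsu_degenerate_histogram():
    with pytest.raises(tp.DegenerateHistogramError):
        tp.otsu_threshold(np.full((5, 5), 77, dtype=np.uint8))
    with pytest.raises(tp.DegenerateHistogramError):
        # zeros plus one nonzero level is degenerate once zero is excluded
        tp.otsu_threshold(np.array([0, 0, 9, 9], dtype=np.uint8), exclude_zero=True)


@given(
    hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 255)),
    st.booleans(),
)
@settings(max_examples=60, deadline=None)
def test_otsu_equals_exhaustive_maximizer(gray, exclude_zero):
    vals = np.unique(gray)
    if exclude_zero:
        vals = vals[vals != 0]
    if len(vals) < 2:
        return
    assert tp.otsu_threshold(gray, exclude_zero) == brute_force_otsu(gray, exclude_zero)


# -- erosion -----------------------------------------------------------------


def test_erosion_removes_isolated_pixel_and_shrinks_rectangle():
    mask = np.zeros((9, 9), dtype=bool)
    mask[4, 4] = True
    assert not tp.morphological_erode(mask).any()

    rect = np.zeros((12, 15), dtype=bool)
    rect[2:9, 3:12] = True  # 7 x 9 rectangle
    out = tp.morphological_erode(rect)
    expect = np.zeros_like(rect)
    expect[3:8, 4:11] = True  # 5 x 7, shrunk by 1 on every side
    assert np.array_equal(out, expect)

    empty = np.zeros((6, 6), dtype=bool)
    assert not tp.morphological_erode(empty).any()


def test_erosion_output_subset_of_input(low_frame):
    _, frame, _ = low_frame
    mask = tp.segment_shoots(frame.rgb)
    eroded = tp.morphological_erode(mask.pixels)
    assert not (eroded & ~mask.pixels).any()


# -- full pipeline -----------------------------------------------------------


def test_segment_low_light_precision_recall(low_frame):
    _, frame, truth = low_frame
    mask = tp.segment_shoots(frame.rgb)
    assert mask.source_lighting.label is Lighting.LOW_LIGHT
    score = tp.detection_score(tp.score_mask(mask.pixels, truth.shoot_mask))
    assert score.precision >= 0.90
    assert score.recall >= 0.90


def test_segment_high_light_excludes_specular(high_frame):
    _, frame, _ = high_frame
    mask = tp.segment_shoots(frame.rgb)
    assert mask.source_lighting.label is Lighting.HIGH_LIGHT
    spec = tp.specular_mask(frame.rgb)
    assert not (mask.pixels & spec).any()


def test_segment_negative_control_no_shoots():
    frame, _ = tp.generate_frame(tp.SceneParams(shoot_density=0.0, seed=21))
    mask = tp.segment_shoots(frame.rgb)
    assert mask.pixels.mean() <= 0.01


def test_segment_deterministic(low_frame):
    _, frame, _ = low_frame
    m1 = tp.segment_shoots(frame.rgb)
    m2 = tp.segment_shoots(frame.rgb)
    assert np.array_equal(m1.pixels, m2.pixels)


def test_lighting_dispatch_switches_with_illumination():
    """Scaling a frame from the low band into the high band flips the branch."""
    low, _ = tp.generate_frame(tp.SceneParams(illumination="low", seed=4))
    high, _ = tp.generate_frame(tp.SceneParams(illumination="high", seed=4))
    assert tp.segment_shoots(low.rgb).source_lighting.label is Lighting.LOW_LIGHT
    assert tp.segment_shoots(high.rgb).source_lighting.label is Lighting.HIGH_LIGHT


def test_out_of_range_frame_rejected_unless_forced():
    dark = np.full((64, 64, 3), 20, dtype=np.uint8)
    dark[::2, ::2] = (10, 60, 5)
    with pytest.raises(tp.LightingOutOfRangeError):
        tp.segment_shoots(dark)
    mask = tp.segment_shoots(dark, force_class=Lighting.LOW_LIGHT)
    assert mask.pixels.shape == (64, 64)
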