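"""Mode computation, binarization, mask merging, Scores and Growth rate."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fascore
from fascore.photometric import CorrectedImage, flatten_background
from fascore.registration import AffineParams
from fascore.scoring import (
    ScoreConfig,
    ScoreReport,
    ScoringError,
    binarize,
    compute_mode,
    growth_rate,
    merge_masks,
    score_image,
    score_pair,
)
from fascore.segmentation import RegionMask
from fascore.synthetic import lesion_region_mask, make_pair, random_scene, render_scene

from conftest import nested_mottle_scene


def _mask(arr):
    return RegionMask(arr.astype(np.uint8), source="synthetic_truth")


# --- mode ------------------------------------------------------------------

def test_mode_of_constant_image_is_its_value():
    assert compute_mode(np.full((50, 50), 1.0)) == 1.0


def test_mode_finds_dominant_bin():
    vals = np.concatenate([np.full(900, 1.0), np.full(100, 1.5)])
    rng = np.random.default_rng(0)
    rng.shuffle(vals)
    mode = compute_mode(vals.reshape(20, 50))
    # exhaustive check: the most populated of 256 uniform bins contains 1.0
    width = 0.5 / 256
    assert abs(mode - 1.0) <= width


def test_mode_tie_breaks_to_lower_bin():
    vals = np.concatenate([np.zeros(500), np.ones(500)]).reshape(20, 50)
    mode = compute_mode(vals)
    assert mode < 0.5  # centre of the lowest bin, not the highest


def test_mode_requires_valid_pixels():
    with pytest.raises(ScoringError):
        compute_mode(np.ones((10, 10)), valid=np.zeros((10, 10), bool))


def test_mode_respects_validity_mask():
    arr = np.ones((10, 10))
    arr[:5] = 7.0
    valid = np.zeros((10, 10), bool)
    valid[:5] = True
    assert compute_mode(arr, valid=valid) == 7.0


# --- binarization ----------------------------------------------------------

def test_constant_image_binarizes_to_zero():
    out = binarize(np.full((50, 50), 1.0))
    assert out.count == 0
    assert out.threshold_value == pytest.approx(1.2)


def test_zero_multiplier_keeps_all_positive_pixels():
    rng = np.random.default_rng(1)
    arr = rng.uniform(0.5, 1.5, (50, 50))
    out = binarize(arr, multiplier=0.0)
    assert out.count == arr.size


def test_invalid_pixels_forced_to_zero():
    arr = np.full((20, 20), 5.0)
    arr[0, 0] = 1.0  # make the mode 5.0's bin distinct
    valid = np.zeros((20, 20), bool)
    valid[:10] = True
    out = binarize(arr, multiplier=0.0, valid=valid)
    assert not out.pixels[~valid].any()


def test_threshold_boundary_is_strict_by_default():
    arr = np.array([[1.0, 1.2, 1.2001]] * 3)
    out = binarize(arr, multiplier=1.2, mode_valid=None)
    # mode bin centre is slightly above 1.0 here; check against the actual cut
    assert not (arr <= out.threshold_value)[out.pixels.astype(bool)].any()
    inclusive = binarize(arr, multiplier=1.2, inclusive=True)
    assert inclusive.count >= out.count


def test_high_contrast_scene_binarizes_to_mottle_and_vessels(scene):
    corrected = flatten_background(render_scene(scene))
    out = binarize(corrected)
    truth = (scene.mottle_map | scene.vessel_map).astype(bool)
    lesion = scene.lesion_mask.astype(bool)
    mismatch = (out.pixels.astype(bool) ^ truth)[lesion].sum()
    assert mismatch <= 0.01 * lesion.sum()


# --- mask merging ----------------------------------------------------------

def test_merge_disjoint_masks_adds_areas():
    a = np.zeros((496, 496), np.uint8)
    b = np.zeros((496, 496), np.uint8)
    a[:10, :10] = 1  # 100 px
    b[100:105, :10] = 1  # 50 px
    assert merge_masks(_mask(a), _mask(b)).area == 150


def test_merge_identical_masks_is_idempotent(lesion_mask):
    merged = merge_masks(lesion_mask, lesion_mask)
    assert np.array_equal(merged.pixels, lesion_mask.pixels)


@given(seed=st.integers(0, 10_000))
def test_merge_obeys_inclusion_exclusion(seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((496, 496)) < 0.2).astype(np.uint8)
    b = (rng.random((496, 496)) < 0.2).astype(np.uint8)
    merged = merge_masks(_mask(a), _mask(b))
    assert merged.area == int(a.sum() + b.sum() - (a & b).sum())


# --- growth rate -----------------------------------------------------------

def test_growth_rate_formula():
    assert growth_rate(100, 120) == pytest.approx(0.20)
    assert growth_rate(100, 100) == 0.0
    assert math.isnan(growth_rate(0, 50))


def test_published_style_score_pair_rounds_to_minus_011():
    g = growth_rate(26984, 24026)
    assert round(g, 2) == -0.11


# --- full pair pipeline ----------------------------------------------------

def test_self_pair_growth_is_exactly_zero(rendered, lesion_mask):
    cfg = ScoreConfig(transform=AffineParams.identity())
    report = score_pair(rendered, rendered, lesion_mask, lesion_mask, cfg)
    assert report.growth_rate == 0.0
    assert report.reference_score == report.test_score


def test_twenty_percent_more_mottle_gives_growth_point_two():
    s1 = nested_mottle_scene(31, coverage=0.20)
    s2 = nested_mottle_scene(31, coverage=0.24)  # same field, 20% more speckle
    ref = render_scene(s1)
    tst = render_scene(s2)
    mask = lesion_region_mask(s1)
    cfg = ScoreConfig(transform=AffineParams.identity())
    report = score_pair(ref, tst, mask, mask, cfg)
    assert report.growth_rate == pytest.approx(0.20, abs=0.03)


def test_swap_symmetry_on_identity_pairs():
    s1 = nested_mottle_scene(32, coverage=0.20)
    s2 = nested_mottle_scene(32, coverage=0.26)
    ref, tst = render_scene(s1), render_scene(s2)
    mask = lesion_region_mask(s1)
    cfg = ScoreConfig(transform=AffineParams.identity())
    g = score_pair(ref, tst, mask, mask, cfg).growth_rate
    g_swapped = score_pair(tst, ref, mask, mask, cfg).growth_rate
    # approximate: histogram matching always remaps the test side, so the two
    # orientations are not bit-symmetric
    assert g_swapped == pytest.approx(1.0 / (1.0 + g) - 1.0, abs=0.05)
    # the exactly symmetric case: identical frames swap to identical growth
    g_self = score_pair(ref, ref, mask, mask, cfg).growth_rate
    assert g_self == 0.0


def test_score_monotone_in_mask_area(scene, rendered):
    corrected = flatten_background(rendered)
    small = lesion_region_mask(scene)
    from scipy.ndimage import binary_dilation

    big = _mask(binary_dilation(scene.lesion_mask, iterations=15))
    s_small, _ = score_image(corrected, small)
    s_big, _ = score_image(corrected, big)
    assert s_big >= s_small


def test_zero_reference_score_reports_undefined_growth():
    flat = fascore.FAImage(np.full((496, 496), 100, np.uint8))
    mask = np.zeros((496, 496), np.uint8)
    mask[200:300, 200:300] = 1
    cfg = ScoreConfig(transform=AffineParams.identity())
    report = score_pair(flat, flat, _mask(mask), _mask(mask), cfg)
    assert report.reference_score == 0
    assert not report.growth_rate_defined


def test_registration_failure_names_csv_fallback():
    flat = fascore.FAImage(np.full((496, 496), 100, np.uint8))
    mask = _mask(np.ones((496, 496), np.uint8))
    with pytest.raises(ScoringError, match="correspondences"):
        score_pair(flat, flat, mask, mask)


def test_score_report_validates_and_serializes():
    report = ScoreReport(reference_score=10, test_score=12, merged_mask_area=20,
                         growth_rate=0.2)
    d = report.to_dict()
    assert d["growth_rate"] == pytest.approx(0.2)
    assert "10" in report.to_csv_row()
    with pytest.raises(ScoringError):
        ScoreReport(reference_score=30, test_score=1, merged_mask_area=20,
                    growth_rate=0.0)


def test_mode_within_mask_flag_changes_only_the_mode_region(rendered, lesion_mask):
    cfg_a = ScoreConfig(transform=AffineParams.identity(), mode_within_mask=False)
    cfg_b = ScoreConfig(transform=AffineParams.identity(), mode_within_mask=True)
    ra = score_pair(rendered, rendered, lesion_mask, lesion_mask, cfg_a)
    rb = score_pair(rendered, rendered, lesion_mask, lesion_mask, cfg_b)
    assert ra.merged_mask_area == rb.merged_mask_area
    assert ra.growth_rate == rb.growth_rate == 0.0
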