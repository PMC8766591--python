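"""Keypoint matching, RANSAC affine estimation and warping."""

import numpy as np
import pytest
from skimage.measure import ransac as sk_ransac
from skimage.transform import AffineTransform

import fascore
from fascore.registration import (
    AffineParams,
    CorrespondenceFallback,
    CorrespondenceSet,
    RegistrationError,
    detect_correspondences,
    estimate_affine,
    fit_affine_lstsq,
    warp,
)
from fascore.segmentation import RegionMask
from fascore.synthetic import make_pair, random_scene, render_scene


def _known_affine():
    return AffineParams(np.array([[1.04, 0.03, 12.0], [-0.02, 0.98, -6.0]]))


def _correspondences_from(params, n=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    aln = rng.uniform(30, 460, size=(n, 2))
    ref = params.apply(aln) + rng.normal(0, noise, size=(n, 2))
    return CorrespondenceSet(ref_points=ref, aligned_points=aln)


def _grid_error(est, true):
    gy, gx = np.mgrid[40:456:10j, 40:456:10j]
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return np.linalg.norm(est.apply(pts) - true.apply(pts), axis=1).mean()


# --- correspondence detection ---------------------------------------------

def test_self_match_has_zero_displacement(rendered):
    corr = detect_correspondences(rendered, rendered)
    assert len(corr) >= 3
    assert np.allclose(corr.ref_points, corr.aligned_points)


def test_known_translation_recovered_in_matches():
    scene = random_scene(11)
    t = AffineParams(np.array([[1.0, 0.0, 10.0], [0.0, 1.0, -7.0]]))
    ref, aln, _ = make_pair(scene, t)
    corr = detect_correspondences(ref, aln)
    # a point at aligned coord q corresponds to ref coord q + (10, -7)
    disp = np.median(corr.ref_points - corr.aligned_points, axis=0)
    assert np.abs(disp - np.array([10.0, -7.0])).max() <= 1.0


def test_constant_image_raises_fallback():
    flat = np.full((496, 496), 50, dtype=np.uint8)
    with pytest.raises(CorrespondenceFallback, match="CSV"):
        detect_correspondences(flat, flat)


# --- affine estimation -----------------------------------------------------

def test_exact_correspondences_recover_matrix():
    true = _known_affine()
    corr = _correspondences_from(true, noise=0.0)
    est = estimate_affine(corr, seed=0)
    assert np.abs(est.matrix - true.matrix).max() < 1e-6


def test_identity_correspondences_give_identity():
    corr = _correspondences_from(AffineParams.identity(), noise=0.0)
    est = estimate_affine(corr, seed=0)
    assert np.abs(est.matrix - AffineParams.identity().matrix).max() < 1e-9


def test_thirty_percent_outliers_tolerated():
    true = _known_affine()
    rng = np.random.default_rng(5)
    corr = _correspondences_from(true, n=60, noise=0.2, seed=5)
    n_out = 18
    corr.ref_points[:n_out] = rng.uniform(0, 496, size=(n_out, 2))
    est = estimate_affine(corr, seed=1)
    assert _grid_error(est, true) <= 0.5


def test_ransac_is_seed_deterministic():
    true = _known_affine()
    corr = _correspondences_from(true, n=50, noise=0.5, seed=2)
    corr.ref_points[:10] += 40.0
    a = estimate_affine(corr, seed=3)
    b = estimate_affine(corr, seed=3)
    assert np.array_equal(a.matrix, b.matrix)
    assert a.inlier_count == b.inlier_count


def test_collinear_points_rejected():
    aln = np.column_stack([np.arange(10.0), np.arange(10.0)])
    corr = CorrespondenceSet(ref_points=aln + 1.0, aligned_points=aln)
    with pytest.raises(RegistrationError):
        estimate_affine(corr, seed=0)


def test_too_few_pairs_rejected():
    corr = CorrespondenceSet(ref_points=[[0, 0], [1, 1]], aligned_points=[[0, 0], [1, 1]])
    with pytest.raises(RegistrationError, match=">= 3"):
        estimate_affine(corr, seed=0)


def test_agrees_with_skimage_ransac_cross_check():
    """Independent robust estimator (skimage.measure.ransac) finds the same model."""
    true = _known_affine()
    corr = _correspondences_from(true, n=80, noise=0.3, seed=8)
    corr.ref_points[:24] = np.random.default_rng(8).uniform(0, 496, size=(24, 2))
    ours = estimate_affine(corr, seed=0)
    model, _ = sk_ransac(
        (corr.aligned_points, corr.ref_points), AffineTransform,
        min_samples=3, residual_threshold=3.0, max_trials=2000, rng=0,
    )
    theirs = AffineParams.from_transform(model)
    assert _grid_error(ours, theirs) < 0.2


def test_degenerate_determinant_rejected():
    with pytest.raises(RegistrationError, match="determinant"):
        AffineParams(np.array([[0.1, 0.0, 0.0], [0.0, 0.1, 0.0]]))


def test_end_to_end_recovery_on_rendered_pairs():
    """Full FAST/BRIEF/RANSAC chain on synthetic pairs within the stated envelope
    (|rotation| <= 10 deg, scale 0.9-1.1, |translation| <= 30 px)."""
    hits = 0
    seeds = range(6)
    attempted = 0
    for seed in seeds:
        scene = random_scene(seed)
        r = np.random.default_rng(seed + 500)
        tf = AffineTransform(
            rotation=np.deg2rad(r.uniform(-10, 10)),
            scale=r.uniform(0.9, 1.1),
            translation=r.uniform(-30, 30, 2),
        )
        true = AffineParams.from_transform(tf)
        try:
            ref, aln, _ = make_pair(scene, true, gain=r.uniform(0.9, 1.1),
                                    offset=r.uniform(-5, 5))
        except Exception:
            continue  # a draw may eject the lesion; skip, don't fail
        attempted += 1
        corr = detect_correspondences(ref, aln)
        est = estimate_affine(corr, seed=0)
        hits += _grid_error(est, true) <= 1.0
    assert attempted >= 4
    assert hits >= int(np.ceil(0.9 * attempted))


# --- warping ---------------------------------------------------------------

def test_warp_identity_is_noop(rendered):
    out, valid = warp(rendered, AffineParams.identity())
    assert np.array_equal(out.pixels, rendered.pixels)
    assert valid.all()


def test_warp_roundtrip_error_small(rendered):
    # bilinear interpolation round-trip on a smooth image stays within ~2 levels
    from scipy.ndimage import gaussian_filter

    import fascore

    smooth = fascore.FAImage(
        np.clip(np.rint(gaussian_filter(rendered.pixels.astype(float), 4.0)),
                0, 255).astype(np.uint8)
    )
    params = _known_affine()
    fwd, v1 = warp(smooth, params)
    back, v2 = warp(fwd, params.inverse())
    interior = v1 & v2
    interior[:20] = interior[-20:] = False
    interior[:, :20] = interior[:, -20:] = False
    err = np.abs(back.pixels.astype(float) - smooth.pixels.astype(float))[interior]
    assert err.mean() <= 2.0


def test_mask_warp_stays_binary(scene):
    mask = RegionMask(scene.lesion_mask.copy(), source="synthetic_truth")
    out, valid = warp(mask, _known_affine())
    assert set(np.unique(out.pixels)) <= {0, 1}
    assert not out.pixels[~valid].any()


# --- persistence -----------------------------------------------------------

def test_correspondence_csv_roundtrip(tmp_path):
    corr = _correspondences_from(_known_affine(), n=12)
    path = tmp_path / "points.csv"
    corr.to_csv(path)
    loaded = CorrespondenceSet.from_csv(path)
    assert loaded.source == "csv_file"
    assert np.allclose(loaded.ref_points, corr.ref_points)
    assert np.allclose(loaded.aligned_points, corr.aligned_points)


def test_affine_csv_roundtrip(tmp_path):
    params = _known_affine()
    path = tmp_path / "affine.csv"
    params.save_csv(path)
    assert np.allclose(AffineParams.load_csv(path).matrix, params.matrix)


def test_lstsq_fit_is_exact_on_three_points():
    true = _known_affine()
    src = np.array([[10.0, 20.0], [400.0, 50.0], [200.0, 450.0]])
    m = fit_affine_lstsq(src, true.apply(src))
    assert np.abs(m - true.matrix).max() < 1e-9
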