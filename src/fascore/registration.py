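"""Affine registration of an FA image pair.

The second ("Aligned") frame of a pair is mapped onto the first ("Reference
alignment") frame by a 6-parameter affine transform covering translation,
scale, rotation and skew.  Correspondences come from FAST corners (vessel
branch points are strong corners) described with BRIEF binary descriptors and
matched by Hamming distance with cross-checking; the transform is estimated
robustly with RANSAC.  When automatic detection fails — featureless or badly
degraded frames — a CSV file of manually picked corresponding points can be
substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from skimage.feature import BRIEF, corner_fast, corner_peaks, match_descriptors
from skimage.transform import AffineTransform, warp as _sk_warp

from .imaging import FAImage
from .segmentation import RegionMask

#: CSV column order for manually supplied correspondence files.
CSV_COLUMNS = ("x_ref", "y_ref", "x_aln", "y_aln")

#: Sanity bounds on the determinant of the linear part of an estimated affine;
#: fundus follow-up pairs never halve or double in scale.
DET_BOUNDS = (0.5, 2.0)


class RegistrationError(RuntimeError):
    """Estimation failed (degenerate geometry, too few inliers)."""


class CorrespondenceFallback(RegistrationError):
    """Automatic matching found < 3 points; supply a correspondence CSV."""


@dataclass
class AffineParams:
    """A 2x3 affine matrix ``[a b tx; c d ty]`` mapping aligned-image (x, y)
    coordinates to reference-image coordinates, with RANSAC bookkeeping."""

    matrix: np.ndarray
    inlier_count: int = 0
    n_candidates: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (2, 3):
            raise RegistrationError(f"affine matrix must be 2x3, got {self.matrix.shape}")
        det = abs(np.linalg.det(self.matrix[:, :2]))
        if not (DET_BOUNDS[0] <= det <= DET_BOUNDS[1]):
            raise RegistrationError(
                f"affine determinant {det:.4f} outside sanity bounds {DET_BOUNDS}"
            )

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_transform(cls, tform: AffineTransform, **kw) -> "AffineParams":
        return cls(np.asarray(tform.params)[:2, :], **kw)

    def to_transform(self) -> AffineTransform:
        m = np.eye(3)
        m[:2, :] = self.matrix
        return AffineTransform(matrix=m)

    def inverse(self) -> "AffineParams":
        m = np.eye(3)
        m[:2, :] = self.matrix
        return AffineParams(np.linalg.inv(m)[:2, :])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(N, 2)`` aligned-frame (x, y) points into the reference frame."""
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def save_csv(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.matrix, delimiter=",", fmt="%.10g")

    @classmethod
    def load_csv(cls, path: str | Path) -> "AffineParams":
        return cls(np.loadtxt(Path(path), delimiter=",").reshape(2, 3))


@dataclass
class CorrespondenceSet:
    """Matched point pairs between the reference and aligned frames.

    ``ref_points`` and ``aligned_points`` are ``(N, 2)`` arrays of (x, y)
    pixel coordinates (0-based, origin top-left).  May contain outliers.
    """

    ref_points: np.ndarray
    aligned_points: np.ndarray
    source: str = "automatic"  # "automatic" | "csv_file"

    def __post_init__(self) -> None:
        self.ref_points = np.atleast_2d(np.asarray(self.ref_points, dtype=np.float64))
        self.aligned_points = np.atleast_2d(np.asarray(self.aligned_points, dtype=np.float64))
        if self.ref_points.shape != self.aligned_points.shape or self.ref_points.shape[1] != 2:
            raise RegistrationError("correspondence point arrays must both be (N, 2)")

    def __len__(self) -> int:
        return self.ref_points.shape[0]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrespondenceSet":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise RegistrationError(f"correspondence CSV {path} lacks columns {missing}")
        return cls(
            df[["x_ref", "y_ref"]].to_numpy(float),
            df[["x_aln", "y_aln"]].to_numpy(float),
            source="csv_file",
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            np.hstack([self.ref_points, self.aligned_points]), columns=list(CSV_COLUMNS)
        ).to_csv(path, index=False)


def _keypoints_and_descriptors(
    img: np.ndarray, extractor: BRIEF, fast_n: int, fast_threshold: float, min_distance: int
):
    corners = corner_peaks(
        corner_fast(img, n=fast_n, threshold=fast_threshold), min_distance=min_distance
    )
    extractor.extract(img, corners)
    return corners[extractor.mask], extractor.descriptors


def detect_correspondences(
    reference: Union[FAImage, np.ndarray],
    aligned: Union[FAImage, np.ndarray],
    fast_n: int = 9,
    fast_threshold: float = 0.10,
    min_distance: int = 7,
    descriptor_size: int = 256,
    patch_size: int = 49,
) -> CorrespondenceSet:
    """FAST corners + BRIEF descriptors + Hamming matching with cross-check.

    Raises :class:`CorrespondenceFallback` when fewer than 3 matches are found
    (the caller should fall back to a manually prepared correspondence CSV).
    """
    ref = _as_float(reference)
    aln = _as_float(aligned)
    extractor = BRIEF(descriptor_size=descriptor_size, patch_size=patch_size, sigma=1, rng=1)
    kp_r, d_r = _keypoints_and_descriptors(ref, extractor, fast_n, fast_threshold, min_distance)
    kp_a, d_a = _keypoints_and_descriptors(aln, extractor, fast_n, fast_threshold, min_distance)
    if len(kp_r) < 3 or len(kp_a) < 3:
        raise CorrespondenceFallback(
            f"too few FAST/BRIEF keypoints ({len(kp_r)} ref, {len(kp_a)} aligned); "
            "provide a correspondence CSV (x_ref,y_ref,x_aln,y_aln)"
        )
    matches = match_descriptors(d_r, d_a, metric="hamming", cross_check=True)
    if matches.shape[0] < 3:
        raise CorrespondenceFallback(
            f"only {matches.shape[0]} cross-checked matches; "
            "provide a correspondence CSV (x_ref,y_ref,x_aln,y_aln)"
        )
    # corner arrays are (row, col); correspondence points are (x, y)
    return CorrespondenceSet(
        ref_points=kp_r[matches[:, 0]][:, ::-1],
        aligned_points=kp_a[matches[:, 1]][:, ::-1],
        source="automatic",
    )


def fit_affine_lstsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Closed-form least-squares affine fit mapping ``src`` to ``dst`` (2x3)."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return coef.T  # rows: [a b tx], [c d ty]


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    a, b, c = pts[0], pts[1], pts[2]
    u, v = b - a, c - a
    return abs(u[0] * v[1] - u[1] * v[0]) <= tol  # 2-D cross product


def estimate_affine(
    corr: CorrespondenceSet,
    residual_threshold: float = 3.0,
    max_iter: int = 2000,
    seed: int = 0,
) -> AffineParams:
    """RANSAC estimate of the aligned -> reference affine transform.

    Minimal samples of 3 point pairs are fitted exactly; the consensus is the
    set of pairs whose reprojection residual is below ``residual_threshold``
    pixels; the best consensus set is refitted by least squares.  Deterministic
    for a fixed seed.
    """
    n = len(corr)
    if n < 3:
        raise RegistrationError(f"affine estimation needs >= 3 point pairs, got {n}")
    src = corr.aligned_points
    dst = corr.ref_points
    rng = np.random.default_rng(seed)

    best_inliers: Optional[np.ndarray] = None
    best_count = 0
    for _ in range(max_iter):
        idx = rng.choice(n, size=3, replace=False)
        if _collinear(src[idx]) or _collinear(dst[idx]):
            continue
        try:
            m = fit_affine_lstsq(src[idx], dst[idx])
        except np.linalg.LinAlgError:
            continue
        resid = np.linalg.norm(src @ m[:, :2].T + m[:, 2] - dst, axis=1)
        inliers = resid < residual_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_inliers = inliers
            if count == n:
                break
    if best_inliers is None or best_count < 3:
        raise RegistrationError(
            "RANSAC found no affine model with >= 3 inliers; "
            "check the images or provide a correspondence CSV"
        )
    if _collinear_set(src[best_inliers]):
        raise RegistrationError("all RANSAC inliers are collinear; affine is underdetermined")
    m = fit_affine_lstsq(src[best_inliers], dst[best_inliers])
    resid = np.linalg.norm(src @ m[:, :2].T + m[:, 2] - dst, axis=1)
    return AffineParams(m, inlier_count=int((resid < residual_threshold).sum()), n_candidates=n)


def _collinear_set(pts: np.ndarray, tol: float = 1e-6) -> bool:
    centered = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(centered, tol=tol) < 2


def warp(
    image_or_mask: Union[FAImage, RegionMask, np.ndarray],
    params: AffineParams,
    interpolation: Optional[str] = None,
) -> Tuple[Union[FAImage, RegionMask, np.ndarray], np.ndarray]:
    """Warp an aligned-frame image or mask into the reference frame.

    FA images use linear interpolation; region masks use nearest-neighbour so
    they stay binary.  Returns ``(warped, valid)`` where ``valid`` is True for
    pixels whose preimage lies inside the source frame; out-of-frame pixels
    are filled with 0 and must be excluded from downstream scoring.
    """
    tform = params.to_transform()
    inv = tform.inverse  # maps reference (output) coords to aligned (input) coords

    def _do(arr: np.ndarray, order: int) -> np.ndarray:
        return _sk_warp(
            arr.astype(np.float64), inv, order=order, cval=0.0, preserve_range=True
        )

    if isinstance(image_or_mask, FAImage):
        order = {"nearest": 0, "linear": 1, None: 1}[interpolation]
        out = np.clip(np.rint(_do(image_or_mask.pixels, order)), 0, 255).astype(np.uint8)
        valid = _validity_mask(image_or_mask.pixels.shape, inv)
        return FAImage(out, source_path=image_or_mask.source_path), valid
    if isinstance(image_or_mask, RegionMask):
        order = {"nearest": 0, None: 0}.get(interpolation, 0)
        out = (_do(image_or_mask.pixels, order) > 0.5).astype(np.uint8)
        valid = _validity_mask(image_or_mask.pixels.shape, inv)
        return RegionMask(out, source=image_or_mask.source), valid
    arr = np.asarray(image_or_mask, dtype=np.float64)
    order = {"nearest": 0, "linear": 1, None: 1}[interpolation]
    return _do(arr, order), _validity_mask(arr.shape, inv)


def _validity_mask(shape: Tuple[int, int], inverse_map) -> np.ndarray:
    ones = np.ones(shape, dtype=np.float64)
    return _sk_warp(ones, inverse_map, order=0, cval=0.0, preserve_range=True) > 0.5


def _as_float(img: Union[FAImage, np.ndarray]) -> np.ndarray:
    arr = img.pixels if isinstance(img, FAImage) else np.asarray(img)
    arr = arr.astype(np.float64)
    return arr / 255.0 if arr.max() > 1.5 else arr
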