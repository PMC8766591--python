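"""Mode-threshold binarization and Score / Growth-rate computation.

After alignment and brightness correction, each frame is binarized at 1.2x
the mode of its pixel values; the abnormal-region masks of the two frames are
merged (pixelwise OR) and applied to both binarized frames; the Score of a
frame is the number of hyperfluorescent pixels (value 1) inside the merged
mask.  The Growth rate between two visits is

    (Test score - Reference score) / Reference score.

Subtracting the Reference score cancels structures present in both frames
(retinal vessels inside the mask), so the Growth rate tracks change in the
mottled hyperfluorescent area rather than static anatomy.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .imaging import CANONICAL_SIZE, FAImage
from .photometric import CorrectedImage, DEFAULT_SIGMA, flatten_background, match_histogram
from .registration import (
    AffineParams,
    CorrespondenceSet,
    RegistrationError,
    detect_correspondences,
    estimate_affine,
    warp,
)
from .segmentation import RegionMask

#: Binarization threshold as a multiple of the mode pixel value.
DEFAULT_MULTIPLIER = 1.2

#: Number of uniform bins used to locate the mode of a ratio image.
MODE_BINS = 256


class ScoringError(RuntimeError):
    pass


@dataclass
class BinarizedImage:
    """Result of thresholding a corrected frame at ``multiplier x mode``."""

    pixels: np.ndarray
    threshold_value: float
    mode_value: float
    multiplier: float = DEFAULT_MULTIPLIER

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(np.uint8)
        if not np.isin(np.unique(self.pixels), (0, 1)).all():
            raise ScoringError("BinarizedImage values must be 0/1")

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class ScoreReport:
    """Scores and Growth rate for one reference/test pair."""

    reference_score: int
    test_score: int
    merged_mask_area: int
    growth_rate: float  # NaN when the reference score is 0 (undefined)
    mask_sources: Tuple[str, str] = ("annotation_file", "annotation_file")
    reference_path: str = "<memory>"
    test_path: str = "<memory>"

    def __post_init__(self) -> None:
        total = CANONICAL_SIZE * CANONICAL_SIZE
        for name, score in (("reference", self.reference_score), ("test", self.test_score)):
            if not 0 <= score <= self.merged_mask_area <= total:
                raise ScoringError(
                    f"{name} score {score} inconsistent with merged mask area "
                    f"{self.merged_mask_area}"
                )

    @property
    def growth_rate_defined(self) -> bool:
        return not math.isnan(self.growth_rate)

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["growth_rate"] = None if math.isnan(self.growth_rate) else self.growth_rate
        d["mask_sources"] = list(self.mask_sources)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv_row(self) -> str:
        g = "" if math.isnan(self.growth_rate) else f"{self.growth_rate:.6f}"
        return (
            f"{self.reference_path},{self.test_path},{self.reference_score},"
            f"{self.test_score},{self.merged_mask_area},{g}"
        )


@dataclass
class ScoreConfig:
    """Tunable constants of the scoring pipeline (defaults are the method's)."""

    sigma_px: float = DEFAULT_SIGMA
    multiplier: float = DEFAULT_MULTIPLIER
    mode_within_mask: bool = False
    match_direction: str = "test_to_reference"  # or "reference_to_test"
    # Histogram matching equalises exposure on the raw aligned frames before
    # background division ("raw", default).  Matching the corrected ratio
    # images instead ("corrected") forces the matched frame's global intensity
    # distribution - and with it the count above any fixed threshold - onto
    # the reference's, which cancels the very growth signal the Score
    # measures; it is kept selectable for comparison only.
    match_stage: str = "raw"
    residual_threshold: float = 3.0
    ransac_max_iter: int = 2000
    ransac_seed: int = 0
    inclusive_threshold: bool = False  # use >= instead of strict > at the cut
    transform: Optional[AffineParams] = None
    correspondences: Optional[CorrespondenceSet] = None


def growth_rate(reference_score: float, test_score: float) -> float:
    """(Test score - Reference score) / Reference score; NaN when undefined."""
    if reference_score == 0:
        return float("nan")
    return (test_score - reference_score) / reference_score


def compute_mode(
    corrected: Union[CorrectedImage, np.ndarray],
    valid: Optional[np.ndarray] = None,
    bins: int = MODE_BINS,
) -> float:
    """Mode of the valid pixel values via a uniform histogram.

    Valid pixels are quantized into ``bins`` uniform bins spanning their
    observed range; the mode is the centre of the most populated bin, with
    ties broken toward the lower bin.  A constant image returns its value.
    """
    arr = corrected.pixels if isinstance(corrected, CorrectedImage) else np.asarray(corrected)
    vals = arr.ravel() if valid is None else arr[np.asarray(valid, bool)]
    if vals.size == 0:
        raise ScoringError("compute_mode: no valid pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    return float(0.5 * (edges[i] + edges[i + 1]))


def binarize(
    corrected: Union[CorrectedImage, np.ndarray],
    multiplier: float = DEFAULT_MULTIPLIER,
    valid: Optional[np.ndarray] = None,
    mode_valid: Optional[np.ndarray] = None,
    inclusive: bool = False,
) -> BinarizedImage:
    """Threshold a corrected frame at ``multiplier x mode``.

    The comparison is strict (``>``) by default; pixels outside ``valid`` are
    forced to 0.  ``mode_valid`` optionally restricts the mode computation to
    a sub-region (e.g. inside the merged mask) independently of ``valid``.
    """
    arr = corrected.pixels if isinstance(corrected, CorrectedImage) else np.asarray(corrected)
    mode = compute_mode(arr, valid if mode_valid is None else mode_valid)
    threshold = multiplier * mode
    binary = (arr >= threshold) if inclusive else (arr > threshold)
    if valid is not None:
        binary = binary & np.asarray(valid, bool)
    return BinarizedImage(binary.astype(np.uint8), threshold_value=float(threshold),
                          mode_value=mode, multiplier=multiplier)


def merge_masks(mask_ref: RegionMask, mask_aln_warped: RegionMask) -> RegionMask:
    """Summative mask: pixelwise OR of the two aligned abnormal-region masks."""
    if mask_ref.pixels.shape != mask_aln_warped.pixels.shape:
        raise ScoringError("mask shape mismatch")
    merged = (mask_ref.pixels | mask_aln_warped.pixels).astype(np.uint8)
    source = mask_ref.source if mask_ref.source == mask_aln_warped.source else "annotation_file"
    return RegionMask(merged, source=source)


def score_image(
    corrected: CorrectedImage,
    merged_mask: RegionMask,
    valid: Optional[np.ndarray] = None,
    multiplier: float = DEFAULT_MULTIPLIER,
    mode_within_mask: bool = False,
    inclusive: bool = False,
) -> Tuple[int, BinarizedImage]:
    """Binarize one corrected frame and count hyperfluorescent pixels in the mask."""
    if valid is None:
        valid = np.ones(corrected.pixels.shape, bool)
    mode_valid = valid & merged_mask.astype_bool() if mode_within_mask else valid
    if not mode_valid.any():
        raise ScoringError("no valid pixels available for mode computation")
    binary = binarize(corrected, multiplier=multiplier, valid=valid,
                      mode_valid=mode_valid, inclusive=inclusive)
    score = int((binary.pixels.astype(bool) & merged_mask.astype_bool() & valid).sum())
    return score, binary


def _match_raw(test: FAImage, reference: FAImage, valid: np.ndarray) -> FAImage:
    """Histogram-match the raw 8-bit test frame onto the reference frame.

    Equalises global brightness/contrast (the gain/offset differences between
    visits) before background division.  Computed over valid pixels only;
    invalid pixels stay 0.
    """
    from .photometric import CorrectedImage as _CI

    matched = match_histogram(
        _CI(test.pixels.astype(np.float64)),
        _CI(reference.pixels.astype(np.float64)),
        test_valid=valid,
        ref_valid=valid,
    ).pixels
    out = np.clip(np.rint(matched), 0, 255).astype(np.uint8)
    out[~valid] = 0
    return FAImage(out, source_path=test.source_path)


def score_pair(
    ref: FAImage,
    aln: FAImage,
    mask_ref: RegionMask,
    mask_aln: RegionMask,
    config: Optional[ScoreConfig] = None,
    return_artifacts: bool = False,
):
    """Run the full pair pipeline and return a :class:`ScoreReport`.

    Stages: estimate (or accept) the aligned->reference affine; warp the test
    frame and its mask; histogram-match the raw test frame to the reference
    (exposure equalisation); background-divide both frames; merge the masks;
    binarize each frame at ``multiplier x mode``; count hyperfluorescent
    pixels inside the merged mask.  Out-of-frame pixels introduced by warping
    are excluded from the mode, the binarization and both Scores
    symmetrically.
    """
    config = config or ScoreConfig()

    # --- registration ------------------------------------------------------
    if config.transform is not None:
        params = config.transform
    else:
        try:
            corr = config.correspondences or detect_correspondences(ref, aln)
            params = estimate_affine(
                corr,
                residual_threshold=config.residual_threshold,
                max_iter=config.ransac_max_iter,
                seed=config.ransac_seed,
            )
        except RegistrationError as exc:
            raise ScoringError(
                f"registration failed ({exc}); supply manually picked corresponding "
                "points via a CSV file (--correspondences)"
            ) from exc

    warped_aln, valid = warp(aln, params)
    warped_mask_aln, _ = warp(mask_aln, params)

    # --- photometric correction -------------------------------------------
    if config.match_direction not in ("test_to_reference", "reference_to_test"):
        raise ScoringError(f"unknown match_direction {config.match_direction!r}")
    ref_img, aln_img = ref, warped_aln
    if config.match_stage == "raw":
        if config.match_direction == "test_to_reference":
            aln_img = _match_raw(aln_img, ref_img, valid)
        else:
            ref_img = _match_raw(ref_img, aln_img, valid)
    elif config.match_stage != "corrected":
        raise ScoringError(f"unknown match_stage {config.match_stage!r}")
    corrected_ref = flatten_background(ref_img, sigma_px=config.sigma_px)
    corrected_aln = flatten_background(aln_img, sigma_px=config.sigma_px)
    if config.match_stage == "corrected":
        if config.match_direction == "test_to_reference":
            corrected_aln = match_histogram(corrected_aln, corrected_ref,
                                            test_valid=valid, ref_valid=valid)
        else:
            corrected_ref = match_histogram(corrected_ref, corrected_aln,
                                            test_valid=valid, ref_valid=valid)

    # --- masking and scoring ----------------------------------------------
    merged = merge_masks(mask_ref, warped_mask_aln)
    ref_score, ref_binary = score_image(
        corrected_ref, merged, valid, config.multiplier,
        config.mode_within_mask, config.inclusive_threshold,
    )
    test_score, test_binary = score_image(
        corrected_aln, merged, valid, config.multiplier,
        config.mode_within_mask, config.inclusive_threshold,
    )

    report = ScoreReport(
        reference_score=ref_score,
        test_score=test_score,
        merged_mask_area=int((merged.astype_bool() & valid).sum()),
        growth_rate=growth_rate(ref_score, test_score),
        mask_sources=(mask_ref.source, mask_aln.source),
        reference_path=ref.source_path,
        test_path=aln.source_path,
    )
    if not return_artifacts:
        return report
    artifacts = {
        "params": params,
        "valid": valid,
        "warped_aln": aln_img,
        "warped_mask_aln": warped_mask_aln,
        "corrected_ref": corrected_ref,
        "corrected_aln": corrected_aln,
        "merged_mask": merged,
        "binary_ref": ref_binary,
        "binary_test": test_binary,
    }
    return report, artifacts
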