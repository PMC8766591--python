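"""End-to-end orchestration: load frames, obtain masks, register, correct,
score, and write reviewable artifacts.

A run is reproducible from its :class:`RunConfig` (every constant and seed is
recorded in the emitted report) and writes its intermediates as ordinary
image files so a clinician can audit each stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .imaging import FAImage, load_and_preprocess, write_float_image, write_image
from .registration import CorrespondenceSet
from .scoring import ScoreConfig, ScoreReport, score_pair
from .segmentation import RegionMask, UnetSegmenter, load_mask, predict_mask, save_mask

logger = logging.getLogger("fascore")


@dataclass
class RunConfig:
    """All tunables of one pipeline run; serialises losslessly to JSON."""

    sigma_px: float = 70.0
    binarize_multiplier: float = 1.2
    prob_threshold: float = 0.5
    mode_within_mask: bool = False
    match_direction: str = "test_to_reference"
    match_stage: str = "raw"
    residual_threshold: float = 3.0
    ransac_max_iter: int = 2000
    seed: int = 0
    mask_source: str = "model"  # "model" | "annotation_file" | "synthetic_truth"
    model_path: Optional[str] = None
    correspondences_path: Optional[str] = None
    output_dir: str = "fascore_out"
    write_intermediates: bool = True

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def score_config(self) -> ScoreConfig:
        corr = (
            CorrespondenceSet.from_csv(self.correspondences_path)
            if self.correspondences_path
            else None
        )
        return ScoreConfig(
            sigma_px=self.sigma_px,
            multiplier=self.binarize_multiplier,
            mode_within_mask=self.mode_within_mask,
            match_direction=self.match_direction,
            match_stage=self.match_stage,
            residual_threshold=self.residual_threshold,
            ransac_max_iter=self.ransac_max_iter,
            ransac_seed=self.seed,
            correspondences=corr,
        )


def _obtain_mask(
    image: FAImage, config: RunConfig, mask_path: Optional[str], model: Optional[UnetSegmenter]
) -> RegionMask:
    if mask_path is not None:
        return load_mask(mask_path)
    if config.mask_source == "model":
        if model is None:
            raise ValueError("mask_source='model' requires model_path")
        return predict_mask(model, image, prob_threshold=config.prob_threshold)
    if hasattr(image, "scene"):
        return RegionMask(image.scene.lesion_mask.copy(), source="synthetic_truth")
    raise ValueError(
        "no mask available: supply --mask files, a trained model, or synthetic scenes"
    )


def _overlay_png(image: FAImage, merged: RegionMask, binary: np.ndarray) -> np.ndarray:
    """Review overlay: mask outline in yellow, hyperfluorescent pixels in green."""
    from scipy.ndimage import binary_dilation

    rgb = np.stack([image.pixels] * 3, axis=-1).astype(np.uint8)
    hyper = binary.astype(bool) & merged.astype_bool()
    rgb[hyper] = (0, 200, 0)
    outline = binary_dilation(merged.astype_bool(), iterations=2) & ~merged.astype_bool()
    rgb[outline] = (255, 230, 0)
    return rgb


def run_pair(
    reference_path: str | Path,
    test_path: str | Path,
    config: Optional[RunConfig] = None,
    reference: Optional[FAImage] = None,
    test: Optional[FAImage] = None,
    mask_ref_path: Optional[str] = None,
    mask_test_path: Optional[str] = None,
    outdir: Optional[Path] = None,
) -> ScoreReport:
    """Score one reference/test pair and write report + intermediates.

    Frames may be passed in-memory (``reference``/``test``) for synthetic
    runs; otherwise they are loaded and preprocessed from the given paths.
    """
    config = config or RunConfig()
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref = reference if reference is not None else load_and_preprocess(reference_path)
    tst = test if test is not None else load_and_preprocess(test_path)

    model = UnetSegmenter.load(config.model_path) if (
        config.mask_source == "model" and config.model_path
    ) else None
    mask_ref = _obtain_mask(ref, config, mask_ref_path, model)
    mask_tst = _obtain_mask(tst, config, mask_test_path, model)

    logger.info("[register] %s -> %s", test_path, reference_path)
    report, artifacts = score_pair(
        ref, tst, mask_ref, mask_tst, config.score_config(), return_artifacts=True
    )
    report.reference_path = str(reference_path)
    report.test_path = str(test_path)

    payload = report.to_dict()
    payload["config"] = asdict(config)
    payload["config_hash"] = config.config_hash()
    payload["affine_matrix"] = artifacts["params"].matrix.tolist()
    payload["ransac_inliers"] = artifacts["params"].inlier_count
    (outdir / "score_report.json").write_text(json.dumps(payload, indent=2))
    header = "reference_path,test_path,reference_score,test_score,merged_mask_area,growth_rate"
    (outdir / "score_report.csv").write_text(header + "\n" + report.to_csv_row() + "\n")

    if config.write_intermediates:
        logger.info("[artifacts] writing intermediates to %s", outdir)
        write_image(outdir / "warped_test.png", artifacts["warped_aln"].pixels)
        write_float_image(outdir / "corrected_reference.tif", artifacts["corrected_ref"].pixels)
        write_float_image(outdir / "corrected_test.tif", artifacts["corrected_aln"].pixels)
        save_mask(outdir / "merged_mask.png", artifacts["merged_mask"])
        write_image(outdir / "binary_reference.png", artifacts["binary_ref"].pixels * 255)
        write_image(outdir / "binary_test.png", artifacts["binary_test"].pixels * 255)
        write_image(
            outdir / "overlay_reference.png",
            _overlay_png(ref, artifacts["merged_mask"], artifacts["binary_ref"].pixels),
        )
        write_image(
            outdir / "overlay_test.png",
            _overlay_png(
                artifacts["warped_aln"], artifacts["merged_mask"], artifacts["binary_test"].pixels
            ),
        )
        artifacts["params"].save_csv(outdir / "affine.csv")
    return report


def run_series(
    image_paths: Sequence[str | Path],
    config: Optional[RunConfig] = None,
    images: Optional[Sequence[FAImage]] = None,
    mask_paths: Optional[Sequence[Optional[str]]] = None,
    baseline: str = "first",
) -> Tuple[List[Optional[ScoreReport]], "pd.DataFrame"]:
    """Score a date-ordered series against its earliest frame.

    Every later visit is paired with the baseline (default: the first image,
    day 0); ``baseline="previous"`` compares consecutive visits instead.  The
    trajectory table carries per-visit Growth rate and merged-mask area, plus
    a ``discrepancy`` flag raised when the mask area grows while the Growth
    rate falls — the signature of new blocking (e.g. hemorrhage) inside an
    expanding lesion, which hyperfluorescence alone under-reports.
    """
    import pandas as pd

    config = config or RunConfig()
    if len(image_paths) < 2:
        raise ValueError("a series needs at least 2 images")
    if baseline not in ("first", "previous"):
        raise ValueError("baseline must be 'first' or 'previous'")
    mask_paths = list(mask_paths) if mask_paths is not None else [None] * len(image_paths)

    outroot = Path(config.output_dir)
    reports: List[Optional[ScoreReport]] = []
    rows = []
    prev_growth: Optional[float] = None
    prev_mask: Optional[int] = None
    for i in range(1, len(image_paths)):
        ref_i = 0 if baseline == "first" else i - 1
        try:
            report = run_pair(
                image_paths[ref_i],
                image_paths[i],
                config,
                reference=images[ref_i] if images else None,
                test=images[i] if images else None,
                mask_ref_path=mask_paths[ref_i],
                mask_test_path=mask_paths[i],
                outdir=outroot / f"visit_{i:02d}",
            )
        except Exception as exc:  # one failed pair must not abort the series
            logger.error("[series] pair %d failed: %s", i, exc)
            reports.append(None)
            rows.append({"visit": i, "reference_visit": ref_i, "growth_rate": math.nan,
                         "merged_mask_area": math.nan, "discrepancy": False,
                         "error": str(exc)})
            continue
        reports.append(report)
        discrepancy = (
            prev_growth is not None
            and prev_mask is not None
            and report.merged_mask_area > prev_mask
            and report.growth_rate_defined
            and report.growth_rate < prev_growth
        )
        rows.append({
            "visit": i,
            "reference_visit": ref_i,
            "growth_rate": report.growth_rate,
            "merged_mask_area": report.merged_mask_area,
            "discrepancy": bool(discrepancy),
            "error": "",
        })
        prev_growth = report.growth_rate
        prev_mask = report.merged_mask_area
    table = pd.DataFrame(rows)
    outroot.mkdir(parents=True, exist_ok=True)
    table.to_csv(outroot / "trajectory.csv", index=False)
    return reports, table
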