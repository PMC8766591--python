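"""Synthetic FA-like scenes with known ground truth.

Real early-phase FA frames show a dark fundus background, a branching bright
vessel tree, one or more lesions filled with speckled ("mottled")
hyperfluorescence with unclear boundaries, and a smooth low-frequency
luminance slope; follow-up frames are related by an affine transform plus
brightness/contrast shifts.  The generator reproduces exactly these
properties — and nothing subtler — so that every downstream stage (masking,
registration, brightness correction, scoring) can be exercised against exact
ground truth without patient data.

Rendering is a pure function of the scene fields and its seed: identical
scenes give bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as _disk, polygon as _polygon

from .imaging import CANONICAL_SIZE, FAImage
from .registration import AffineParams, warp as _warp
from .segmentation import RegionMask


class SceneError(ValueError):
    pass


@dataclass
class SyntheticScene:
    """Ground-truth decomposition of one synthetic FA frame.

    ``mottle_map`` is the true hyperfluorescent speckle and is constrained to
    lie inside ``lesion_mask | vessel_map``; ``illumination`` is a strictly
    positive low-frequency multiplicative field.
    """

    width: int
    height: int
    vessel_map: np.ndarray
    lesion_mask: np.ndarray
    mottle_map: np.ndarray
    illumination: np.ndarray
    base_intensity: float = 100.0
    rng_seed: int = 0
    vessel_gain: float = 60.0
    mottle_gain: float = 50.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        shape = (self.height, self.width)
        for name in ("vessel_map", "lesion_mask", "mottle_map"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise SceneError(f"{name} has shape {arr.shape}, scene is {shape}")
            setattr(self, name, (arr > 0).astype(np.uint8))
        self.illumination = np.asarray(self.illumination, dtype=np.float64)
        if self.illumination.shape != shape:
            raise SceneError(
                f"illumination has shape {self.illumination.shape}, scene is {shape}"
            )
        if (self.illumination <= 0).any():
            raise SceneError("illumination must be strictly positive everywhere")
        stray = self.mottle_map & ~(self.lesion_mask | self.vessel_map)
        if stray.any():
            raise SceneError(
                f"{int(stray.sum())} mottle pixels fall outside lesion_mask | vessel_map"
            )


def render_scene(scene: SyntheticScene) -> FAImage:
    """Render a scene to an 8-bit FA frame.

    ``clip((base + vessel_gain*vessel + mottle_gain*mottle + noise) x
    illumination)`` quantized to uint8.  Mottle takes precedence over vessels
    where they overlap.  The rendered image carries the scene as the
    ``scene`` attribute for ground-truth access.
    """
    signal = np.full((scene.height, scene.width), float(scene.base_intensity))
    signal += scene.vessel_gain * (scene.vessel_map & ~scene.mottle_map)
    signal += scene.mottle_gain * scene.mottle_map
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.rng_seed)
        signal += rng.normal(0.0, scene.noise_sd, size=signal.shape)
    img = np.clip(np.rint(signal * scene.illumination), 0, 255).astype(np.uint8)
    fa = FAImage(img, source_path=f"<synthetic:{scene.rng_seed}>")
    fa.scene = scene
    return fa


def make_pair(
    scene: SyntheticScene,
    transform: Optional[AffineParams] = None,
    gain: float = 1.0,
    offset: float = 0.0,
) -> Tuple[FAImage, FAImage, AffineParams]:
    """Render a (reference, aligned) pair related by a known affine transform.

    ``transform`` maps aligned-image coordinates to reference coordinates (the
    quantity the registration stage estimates) and must keep at least 80% of
    the lesion pixels inside the frame.  ``gain``/``offset`` apply a
    brightness/contrast shift to the aligned frame; shifts that saturate more
    than 1% of pixels are rejected, since histogram matching cannot undo
    saturation.
    """
    transform = transform or AffineParams.identity()
    reference = render_scene(scene)

    # Lesion retention: lesion pixel p (reference frame) lands at T^-1(p).
    ys, xs = np.nonzero(scene.lesion_mask)
    if len(xs):
        moved = transform.inverse().apply(np.column_stack([xs, ys]).astype(float))
        inside = (
            (moved[:, 0] >= 0)
            & (moved[:, 0] <= scene.width - 1)
            & (moved[:, 1] >= 0)
            & (moved[:, 1] <= scene.height - 1)
        )
        retained = inside.mean()
        if retained < 0.8:
            raise SceneError(
                f"transform keeps only {retained:.0%} of lesion pixels in frame (< 80%)"
            )

    warped, valid = _warp(reference, transform.inverse())  # aligned(x) = reference(T(x))
    shifted = gain * warped.pixels.astype(np.float64) + offset
    saturated = ((shifted > 255) | (shifted < 0))[valid].mean()
    if saturated > 0.01:
        raise SceneError(
            f"photometric shift saturates {saturated:.1%} of in-frame pixels (> 1%)"
        )
    shifted[~valid] = 0.0  # out-of-frame padding stays 0
    aligned = FAImage(
        np.clip(np.rint(shifted), 0, 255).astype(np.uint8),
        source_path=f"<synthetic:{scene.rng_seed}:aligned>",
    )
    aligned.scene = scene
    return reference, aligned, transform


def ground_truth_score(
    scene: SyntheticScene,
    mask: Optional[np.ndarray] = None,
    multiplier: float = 1.2,
) -> int:
    """Brute-force oracle Score of a rendered scene.

    Removes the *true* illumination field from the rendered frame, finds the
    mode by direct histogram scan (256 uniform bins over the observed range),
    and counts pixels strictly above ``multiplier x mode`` inside ``mask``
    (default: the ground-truth lesion mask).  Shares no code with the scoring
    module.
    """
    rendered = render_scene(scene).pixels.astype(np.float64)
    corrected = rendered / (scene.illumination * float(scene.base_intensity))
    vals = corrected.ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        mode = lo
    else:
        edges = np.linspace(lo, hi, 257)
        best_bin, best_count = 0, -1
        for i in range(256):
            upper = vals <= edges[i + 1] if i == 255 else vals < edges[i + 1]
            count = int(((vals >= edges[i]) & upper).sum())
            if count > best_count:
                best_bin, best_count = i, count
        mode = 0.5 * (edges[best_bin] + edges[best_bin + 1])
    region = scene.lesion_mask.astype(bool) if mask is None else np.asarray(mask, bool)
    return int(((corrected > multiplier * mode) & region).sum())


def lesion_region_mask(scene: SyntheticScene) -> RegionMask:
    """The scene's ground-truth lesion mask as a pipeline RegionMask."""
    return RegionMask(scene.lesion_mask.copy(), source="synthetic_truth")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _draw_vessel_tree(shape: Tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Branching random-walk vessel tree with width tapering along branches.

    Branch points are sharp bright corners, which is what FAST keys on in
    real FA frames.
    """
    h, w = shape
    canvas = np.zeros(shape, dtype=np.uint8)
    n_trunks = rng.integers(2, 4)
    stack = []
    for _ in range(n_trunks):
        side = rng.integers(0, 4)
        if side == 0:
            pos, ang = np.array([0.0, rng.uniform(0.2, 0.8) * w]), rng.uniform(0.2, 0.8) * np.pi
        elif side == 1:
            pos, ang = np.array([h - 1.0, rng.uniform(0.2, 0.8) * w]), -rng.uniform(0.2, 0.8) * np.pi
        elif side == 2:
            pos, ang = np.array([rng.uniform(0.2, 0.8) * h, 0.0]), rng.uniform(-0.3, 0.3) * np.pi
        else:
            pos, ang = np.array([rng.uniform(0.2, 0.8) * h, w - 1.0]), np.pi + rng.uniform(-0.3, 0.3) * np.pi
        stack.append((pos, ang, 4.0, int(0.55 * max(h, w))))
    while stack:
        pos, ang, width, steps = stack.pop()
        for _ in range(steps):
            if width < 0.6:
                break
            pos = pos + 3.0 * np.array([np.sin(ang), np.cos(ang)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            ang += rng.normal(0.0, 0.12)
            rr, cc = _disk((pos[0], pos[1]), max(width / 2.0, 0.8), shape=shape)
            canvas[rr, cc] = 1
            if width > 1.0 and rng.random() < 0.03:
                split = rng.uniform(0.35, 0.7)
                stack.append((pos.copy(), ang + split, width * 0.7, steps))
                ang -= split * 0.6
                width *= 0.85
            width *= 0.997
    return canvas


def _draw_lesion(shape: Tuple[int, int], rng: np.random.Generator,
                 n_blobs: int) -> np.ndarray:
    """Union of smooth wobbly-radius blobs placed centrally."""
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        cy = rng.uniform(0.3, 0.7) * h
        cx = rng.uniform(0.3, 0.7) * w
        r0 = rng.uniform(0.10, 0.18) * min(h, w)
        theta = np.linspace(0.0, 2.0 * np.pi, 80, endpoint=False)
        wobble = np.ones_like(theta)
        for k in (2, 3, 5):
            wobble += rng.uniform(0.0, 0.12) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
        radius = r0 * wobble
        rr, cc = _polygon(cy + radius * np.sin(theta), cx + radius * np.cos(theta), shape=shape)
        mask[rr, cc] = 1
    return mask


def _draw_mottle(lesion: np.ndarray, rng: np.random.Generator,
                 coverage: float) -> np.ndarray:
    """Thresholded band-pass noise inside the lesion (speckled texture)."""
    noise = rng.normal(size=lesion.shape)
    band = gaussian_filter(noise, 2.0) - gaussian_filter(noise, 6.0)
    inside = band[lesion.astype(bool)]
    if inside.size == 0:
        return np.zeros_like(lesion)
    cut = np.quantile(inside, 1.0 - coverage)
    return ((band > cut) & lesion.astype(bool)).astype(np.uint8)


def illumination_field(
    shape: Tuple[int, int],
    amplitude: float = 0.25,
    kind: str = "bump",
    center: Optional[Tuple[float, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Smooth positive multiplicative field with relative amplitude <= 30%.

    ``bump`` is a broad Gaussian hill (scale ~ 60% of the frame); ``ramp`` is
    a planar slope.  Both have mean ~1 and spatial power far below the
    sigma = 70 px background-division cutoff, which is the structure that
    stage must remove.
    """
    if not 0 <= amplitude <= 0.3:
        raise SceneError("illumination amplitude must be within +/-30%")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    rng = rng or np.random.default_rng(0)
    if kind == "bump":
        cy, cx = center if center is not None else (rng.uniform(0.2, 0.8) * h,
                                                    rng.uniform(0.2, 0.8) * w)
        s = 0.6 * max(h, w)
        bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * s * s)))
        bump = (bump - bump.mean()) / max(np.abs(bump - bump.mean()).max(), 1e-12)
        return 1.0 + amplitude * bump
    if kind == "ramp":
        ang = rng.uniform(0.0, 2.0 * np.pi)
        ramp = (yy - h / 2.0) * np.sin(ang) + (xx - w / 2.0) * np.cos(ang)
        ramp /= max(np.abs(ramp).max(), 1e-12)
        return 1.0 + amplitude * ramp
    if kind == "flat":
        return np.ones(shape)
    raise SceneError(f"unknown illumination kind {kind!r}")


def random_scene(
    seed: int,
    width: int = CANONICAL_SIZE,
    height: int = CANONICAL_SIZE,
    n_lesions: Optional[int] = None,
    mottle_coverage: float = 0.25,
    illumination_amplitude: float = 0.25,
    illumination_kind: str = "bump",
    base_intensity: float = 100.0,
    vessel_gain: float = 60.0,
    mottle_gain: float = 50.0,
    noise_sd: float = 1.0,
) -> SyntheticScene:
    """Draw a random but fully reproducible synthetic scene.

    Defaults emulate the study conditions: lesions covering a few percent to
    ~10% of the frame, speckle occupying ~25% of the lesion at 1.5x the
    background level, vessels slightly brighter still, and a smooth +/-25%
    luminance slope.
    """
    rng = np.random.default_rng(seed)
    shape = (height, width)
    vessels = _draw_vessel_tree(shape, rng)
    lesion = _draw_lesion(shape, rng, n_lesions if n_lesions is not None else rng.integers(1, 4))
    mottle = _draw_mottle(lesion, rng, mottle_coverage)
    illum = illumination_field(shape, illumination_amplitude, illumination_kind, rng=rng)
    return SyntheticScene(
        width=width,
        height=height,
        vessel_map=vessels,
        lesion_mask=lesion,
        mottle_map=mottle,
        illumination=illum,
        base_intensity=base_intensity,
        rng_seed=seed,
        vessel_gain=vessel_gain,
        mottle_gain=mottle_gain,
        noise_sd=noise_sd,
    )


def scene_params_to_json(path: str | Path, **params) -> None:
    """Persist generator parameters as a flat JSON config."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True))


def scene_from_json(path: str | Path) -> SyntheticScene:
    params = json.loads(Path(path).read_text())
    return random_scene(**params)
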