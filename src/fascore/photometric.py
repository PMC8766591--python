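"""Brightness correction for aligned FA pairs.

FA frames carry a smooth multiplicative luminance slope (vignetting, uneven
illumination) that differs between visits.  It is removed by background
division: the frame is divided by its own heavily Gaussian-blurred copy
(sigma = 70 px by default), leaving a ratio image whose local background sits
near 1.0.  The pair is then equalised by histogram matching: the Aligned
(test) frame's intensity distribution is remapped onto the Reference frame's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .imaging import FAImage

#: Default Gaussian background scale in pixels.
DEFAULT_SIGMA = 70.0


@dataclass
class CorrectedImage:
    """Background-normalised frame in ratio units (~1.0 = local background)."""

    pixels: np.ndarray
    parent: Optional[FAImage] = None
    sigma_px: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("CorrectedImage requires a 2-D grid")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise ValueError("CorrectedImage values must be finite and non-negative")


def flatten_background(
    image: Union[FAImage, np.ndarray], sigma_px: float = DEFAULT_SIGMA
) -> CorrectedImage:
    """Divide a frame by its Gaussian-blurred background (reflect boundary).

    The output is ``image / max(G_sigma(image), eps)`` with eps guarding zero
    division.  An all-zero frame yields an all-zero output with a warning
    rather than an exception.
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    parent = image if isinstance(image, FAImage) else None
    arr = (image.pixels if isinstance(image, FAImage) else np.asarray(image)).astype(np.float64)
    if arr.max() <= 0:
        warnings.warn("flatten_background: all-zero image; returning zeros", stacklevel=2)
        return CorrectedImage(np.zeros_like(arr), parent=parent, sigma_px=sigma_px)
    background = gaussian_filter(arr, sigma=sigma_px, mode="reflect")
    eps = 1e-6 * arr.max()
    ratio = arr / np.maximum(background, eps)
    return CorrectedImage(ratio, parent=parent, sigma_px=sigma_px)


def match_histogram(
    test: CorrectedImage,
    reference: CorrectedImage,
    test_valid: Optional[np.ndarray] = None,
    ref_valid: Optional[np.ndarray] = None,
) -> CorrectedImage:
    """Remap the test frame so its empirical CDF matches the reference's.

    Standard histogram specification via exact quantile mapping: equal input
    values map to equal outputs and pixel ranks are preserved (monotone
    remap).  The reference is never modified.  Optional validity masks
    restrict both the estimated CDFs and the remapped pixels, so out-of-frame
    regions introduced by warping do not distort the match; pixels outside
    ``test_valid`` are left unchanged.
    """
    tv = np.ones(test.pixels.shape, bool) if test_valid is None else np.asarray(test_valid, bool)
    rv = (
        np.ones(reference.pixels.shape, bool)
        if ref_valid is None
        else np.asarray(ref_valid, bool)
    )
    t_pix = test.pixels[tv]
    r_pix = reference.pixels[rv]
    if t_pix.size == 0 or r_pix.size == 0:
        raise ValueError("histogram matching requires at least one valid pixel on each side")

    out = test.pixels.copy()
    if np.ptp(r_pix) == 0:
        warnings.warn("match_histogram: constant reference; test mapped to that constant",
                      stacklevel=2)
        out[tv] = r_pix[0]
        return CorrectedImage(out, parent=test.parent, sigma_px=test.sigma_px)

    t_vals, t_inv, t_counts = np.unique(t_pix, return_inverse=True, return_counts=True)
    t_quant = np.cumsum(t_counts) / t_pix.size
    r_vals, r_counts = np.unique(r_pix, return_counts=True)
    r_quant = np.cumsum(r_counts) / r_pix.size
    mapped_vals = np.interp(t_quant, r_quant, r_vals)
    out[tv] = mapped_vals[t_inv]
    return CorrectedImage(out, parent=test.parent, sigma_px=test.sigma_px)
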