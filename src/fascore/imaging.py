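"""Image I/O and preprocessing for fundus fluorescein-angiography (FA) frames.

Every image entering the pipeline is normalised to a single canonical form: a
496 x 496, 8-bit, single-channel raster.  Rescaling is order-0
(nearest-neighbour, no anti-aliasing) so that binary annotation masks survive
preprocessing without acquiring intermediate grey levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

#: Canonical side length of a preprocessed FA frame, in pixels.
CANONICAL_SIZE = 496


class ImagingError(ValueError):
    """Raised for undecodable files, empty crops and malformed rasters."""


@dataclass
class FAImage:
    """A preprocessed fundus FA frame.

    Attributes
    ----------
    pixels
        ``(496, 496)`` array of ``uint8`` intensities.  Row-major, origin at
        the top-left corner, 0-based indices, pixel centres at integer
        coordinates.
    source_path
        Where the frame came from ("<synthetic>" for generated scenes).
    capture_phase_seconds
        Seconds after fluorescein injection, when known.  Early-phase frames
        (< 60 s) are the intended input; the value is metadata only.
    banner_crop
        ``(x, y, w, h)`` rectangle removed before rescaling, if any
        (instrument banners with burned-in acquisition data).
    """

    pixels: np.ndarray
    source_path: str = "<memory>"
    capture_phase_seconds: Optional[float] = None
    banner_crop: Optional[Tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
            raise ImagingError(
                f"FAImage requires a {CANONICAL_SIZE}x{CANONICAL_SIZE} grid, "
                f"got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ImagingError(f"FAImage requires uint8 pixels, got {self.pixels.dtype}")


def _collapse_channels(raw: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A)-encoded greyscale export to one channel (luma average)."""
    if raw.ndim == 2:
        return raw
    if raw.ndim == 3 and raw.shape[-1] in (3, 4):
        return raw[..., :3].mean(axis=-1)
    raise ImagingError(f"cannot interpret raster of shape {raw.shape} as a 2-D image")


def _to_uint8(img: np.ndarray) -> np.ndarray:
    """Map intensities to 8 bits.  Integer dtypes scale by their full range."""
    if img.dtype == np.uint8:
        return img
    img = np.asarray(img, dtype=np.float64)
    if img.size and img.max() > 255:
        # 16-bit (or wider) export: scale the nominal range, not the observed one,
        # so a pair of frames keeps its relative exposure.
        img = img * (255.0 / 65535.0)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def nearest_resample(img: np.ndarray, out_shape: Tuple[int, int]) -> np.ndarray:
    """Order-0 resample with the half-pixel-centre convention.

    Output pixel (i, j) samples input pixel ``floor((i + 0.5) * H_in / H_out)``
    (clamped), the standard nearest-neighbour mapping without anti-aliasing
    with halfway points resolved upward.  Binary inputs stay binary; the
    indexing is exact (no float boundary ambiguity).
    """
    h_in, w_in = img.shape
    h_out, w_out = out_shape
    rows = np.minimum((np.arange(h_out) * 2 + 1) * h_in // (2 * h_out), h_in - 1)
    cols = np.minimum((np.arange(w_out) * 2 + 1) * w_in // (2 * w_out), w_in - 1)
    return img[np.ix_(rows, cols)]


def preprocess_array(
    raw: np.ndarray,
    crop: Optional[Tuple[int, int, int, int]] = None,
    source_path: str = "<memory>",
) -> FAImage:
    """Apply the preprocessing contract to an in-memory raster.

    The optional ``crop`` rectangle ``(x, y, w, h)`` is removed first (used to
    trim burned-in banners), then the raster is resampled anisotropically to
    496 x 496 with order-0 interpolation and mapped to 8 bits.
    """
    img = _collapse_channels(np.asarray(raw))
    if crop is not None:
        x, y, w, h = crop
        if w <= 0 or h <= 0:
            raise ImagingError(f"zero-area crop rectangle {crop}")
        if x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
            raise ImagingError(f"crop rectangle {crop} exceeds image bounds {img.shape}")
        img = img[y : y + h, x : x + w]
    img = _to_uint8(img)
    if img.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
        img = nearest_resample(img, (CANONICAL_SIZE, CANONICAL_SIZE))
    return FAImage(pixels=img, source_path=source_path, banner_crop=crop)


def load_and_preprocess(
    path: str | Path, crop: Optional[Tuple[int, int, int, int]] = None
) -> FAImage:
    """Read an image file (TIFF/PNG) and normalise it to the canonical form."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImagingError(f"cannot decode image file {path}: {exc}") from exc
    return preprocess_array(raw, crop=crop, source_path=str(path))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit greyscale image; TIFF via tifffile, PNG via imageio."""
    path = Path(path)
    arr = np.ascontiguousarray(pixels)
    if arr.dtype != np.uint8:
        arr = _to_uint8(arr)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_float_image(path: str | Path, pixels: np.ndarray) -> None:
    """Persist a corrected (ratio-unit) image as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(pixels, dtype=np.float32))
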