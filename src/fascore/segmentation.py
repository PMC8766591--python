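"""Abnormal-region masking for FA images.

The pipeline filters scoring to an "Abnormal region" mask: 1 where the frame
is predicted (or annotated) to contain pathological fluorescence change, 0
elsewhere.  Three interchangeable mask sources are supported so the scoring
pipeline never depends on a trained network being available:

* ``model`` — a small U-net segmenter trained on annotated frames,
* ``annotation_file`` — a clinician-drawn binary mask loaded from disk,
* ``synthetic_truth`` — the ground-truth lesion mask of a generated scene.

The segmenter follows the scikit-learn estimator protocol (``fit`` /
``predict`` / ``predict_proba``, fitted attributes with a trailing
underscore) and trains on CPU in minutes at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.transform import resize
from sklearn.base import BaseEstimator

from . import _unet
from .imaging import CANONICAL_SIZE, FAImage

MASK_SOURCES = ("model", "annotation_file", "synthetic_truth")


class SegmentationError(ValueError):
    pass


@dataclass
class RegionMask:
    """Binary abnormal-region mask on the canonical 496x496 grid (1 = abnormal)."""

    pixels: np.ndarray
    source: str = "annotation_file"
    prob_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
            raise SegmentationError(
                f"RegionMask requires a {CANONICAL_SIZE}x{CANONICAL_SIZE} grid, "
                f"got {self.pixels.shape}"
            )
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise SegmentationError(f"RegionMask values must be 0/1, found {vals[:8]}")
        self.pixels = self.pixels.astype(np.uint8)
        if self.source not in MASK_SOURCES:
            raise SegmentationError(f"unknown mask source {self.source!r}")

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


def load_mask(path: str | Path) -> RegionMask:
    """Read a 0/1 (or 0/255) mask image as an annotation-file RegionMask."""
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return RegionMask((raw > 0).astype(np.uint8), source="annotation_file")


def save_mask(path: str | Path, mask: RegionMask) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8))


def _image_stack(images: Sequence[Union[FAImage, np.ndarray]]) -> np.ndarray:
    arrs = []
    for im in images:
        arr = im.pixels if isinstance(im, FAImage) else np.asarray(im)
        if arr.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
            raise SegmentationError(f"expected {CANONICAL_SIZE}x{CANONICAL_SIZE} images, got {arr.shape}")
        arrs.append(arr.astype(np.float64) / 255.0)
    return np.stack(arrs)


def _mask_stack(masks: Sequence[Union[RegionMask, np.ndarray]]) -> np.ndarray:
    arrs = []
    for m in masks:
        arr = m.pixels if isinstance(m, RegionMask) else np.asarray(m)
        if arr.shape != (CANONICAL_SIZE, CANONICAL_SIZE):
            raise SegmentationError(f"expected {CANONICAL_SIZE}x{CANONICAL_SIZE} masks, got {arr.shape}")
        arrs.append((arr > 0).astype(np.float64))
    return np.stack(arrs)


class UnetSegmenter(BaseEstimator):
    """U-net abnormal-region segmenter trained and run on CPU.

    Frames are resampled to ``train_size`` x ``train_size`` for the network;
    predicted probabilities are resampled back to the 496 grid before
    thresholding.  Training minimises pixelwise binary cross-entropy (or soft
    Dice) with Adam and is deterministic for a fixed ``random_state``.

    Parameters
    ----------
    n_levels : resolution levels including the bottleneck (channel widths
        double per level from ``base_channels``).
    train_size : working resolution; must be divisible by 2**(n_levels-1).
    loss : ``"bce"`` or ``"dice"``.
    prob_threshold : probability cut for ``predict`` (pixel = 1 iff
        probability >= threshold).
    """

    def __init__(
        self,
        n_levels: int = 3,
        base_channels: int = 8,
        train_size: int = 128,
        epochs: int = 30,
        batch_size: int = 5,
        learning_rate: float = 2e-3,
        loss: str = "bce",
        prob_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.n_levels = n_levels
        self.base_channels = base_channels
        self.train_size = train_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.prob_threshold = prob_threshold
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------
    def _downsample(self, stack: np.ndarray, order: int) -> np.ndarray:
        s = self.train_size
        out = np.empty((stack.shape[0], s, s))
        for i, img in enumerate(stack):
            out[i] = resize(img, (s, s), order=order, anti_aliasing=(order > 0),
                            preserve_range=True)
        return out

    def _loss_fn(self):
        try:
            return {"bce": _unet.bce_with_logits, "dice": _unet.dice_with_logits}[self.loss]
        except KeyError:
            raise SegmentationError(f"unknown loss {self.loss!r}; use 'bce' or 'dice'")

    # -- estimator API ------------------------------------------------------
    def fit(self, X: Sequence, y: Sequence) -> "UnetSegmenter":
        """Train on paired frames ``X`` and binary truth masks ``y``."""
        imgs = _image_stack(X)
        masks = _mask_stack(y)
        if imgs.shape[0] != masks.shape[0]:
            raise SegmentationError(
                f"{imgs.shape[0]} images vs {masks.shape[0]} masks: training pairs must match"
            )
        if imgs.shape[0] < 2:
            raise SegmentationError("need at least 2 training pairs")
        if self.train_size % 2 ** (self.n_levels - 1):
            raise SegmentationError("train_size must be divisible by 2**(n_levels-1)")
        loss_fn = self._loss_fn()

        xs = self._downsample(imgs, order=1)[:, None]   # (N,1,s,s)
        ys = self._downsample(masks, order=0)[:, None]

        net = _unet.UNet(self.n_levels, self.base_channels, seed=self.random_state)
        opt = _unet.Adam(net.parameters(), lr=self.learning_rate)
        shuffler = np.random.default_rng(self.random_state + 1)

        n = xs.shape[0]
        history: List[float] = []
        for _ in range(self.epochs):
            order = shuffler.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                z = net.forward(xs[sel])
                loss, dz = loss_fn(z, ys[sel])
                net.backward(dz)
                opt.step(net.gradients())
                losses.append(loss)
            history.append(float(np.mean(losses)))

        self.net_ = net
        self.loss_history_ = history
        self.n_train_ = n
        return self

    def predict_proba(self, X: Sequence) -> np.ndarray:
        """Per-pixel abnormality probabilities on the 496 grid, shape (n, 496, 496)."""
        if not hasattr(self, "net_"):
            raise SegmentationError("segmenter is not fitted")
        imgs = _image_stack(X)
        xs = self._downsample(imgs, order=1)[:, None]
        probs_small = _unet.sigmoid(self.net_.forward(xs))[:, 0]
        out = np.empty((imgs.shape[0], CANONICAL_SIZE, CANONICAL_SIZE))
        for i, p in enumerate(probs_small):
            out[i] = resize(p, (CANONICAL_SIZE, CANONICAL_SIZE), order=1,
                            anti_aliasing=False, preserve_range=True)
        return out

    def predict(self, X: Sequence, prob_threshold: Optional[float] = None) -> np.ndarray:
        thr = self.prob_threshold if prob_threshold is None else prob_threshold
        return (self.predict_proba(X) >= thr).astype(np.uint8)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if not hasattr(self, "net_"):
            raise SegmentationError("segmenter is not fitted")
        meta = json.dumps(self.get_params())
        np.savez(Path(path), __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 __loss_history__=np.asarray(self.loss_history_), **self.net_.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "UnetSegmenter":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            est = cls(**meta)
            net = _unet.UNet(est.n_levels, est.base_channels, seed=est.random_state)
            net.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
            est.net_ = net
            est.loss_history_ = list(data["__loss_history__"])
        est.n_train_ = -1
        return est


def train_segmenter(
    images: Sequence[Union[FAImage, np.ndarray]],
    truth_masks: Sequence[Union[RegionMask, np.ndarray]],
    config: Optional[dict] = None,
) -> UnetSegmenter:
    """Train a :class:`UnetSegmenter`; ``config`` overrides constructor defaults."""
    est = UnetSegmenter(**(config or {}))
    return est.fit(images, truth_masks)


def predict_mask(
    model: UnetSegmenter,
    image: Union[FAImage, np.ndarray],
    prob_threshold: Optional[float] = None,
) -> RegionMask:
    """Predict the abnormal-region mask for one frame."""
    thr = model.prob_threshold if prob_threshold is None else prob_threshold
    pred = model.predict([image], prob_threshold=thr)[0]
    return RegionMask(pred, source="model", prob_threshold=thr)


def sensitivity_specificity(
    pred: Union[RegionMask, np.ndarray], truth: Union[RegionMask, np.ndarray]
) -> Tuple[float, float]:
    """Pixelwise sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    A denominator of zero (no abnormal or no normal pixels in the truth)
    yields NaN for that statistic rather than a silent 0.
    """
    p = (pred.pixels if isinstance(pred, RegionMask) else np.asarray(pred)) > 0
    t = (truth.pixels if isinstance(truth, RegionMask) else np.asarray(truth)) > 0
    if p.shape != t.shape:
        raise SegmentationError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int((p & t).sum())
    fn = int((~p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def dice_coefficient(
    pred: Union[RegionMask, np.ndarray], truth: Union[RegionMask, np.ndarray]
) -> float:
    p = (pred.pixels if isinstance(pred, RegionMask) else np.asarray(pred)) > 0
    t = (truth.pixels if isinstance(truth, RegionMask) else np.asarray(truth)) > 0
    denom = p.sum() + t.sum()
    return 2.0 * (p & t).sum() / denom if denom else float("nan")
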