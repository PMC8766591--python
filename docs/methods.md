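# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations behind `fascore`. It documents design
decisions; every empirical number it refers to is computed by the test suite
or by `scripts/acceptance.py`, not asserted here.

## Pipeline model

The quantity of interest is the area of mottled early-phase hyperfluorescence
inside a clinician-meaningful "abnormal region". The pipeline factorises an
FA frame as

```
I(x) ≈ L(x) · S(x) + noise
```

where `L` is a smooth multiplicative luminance field (vignetting, uneven
illumination; spatial scale ≫ 70 px) and `S` is the scene signal (background
fundus, vessels, speckled lesion texture). Dividing the frame by its own
Gaussian blur with σ = 70 px estimates and removes `L`:

```
R = I / max(G_σ(I), ε),    ε = 1e-6 · max(I)
```

with reflect boundary handling. `R` is a ratio image whose local background
sits near 1.0; an all-zero frame returns zeros with a warning instead of
raising. σ = 70 px is the method's fixed constant; it must sit well above
the speckle grain (a few px) and below the illumination scale (hundreds of
px), and is exposed as `sigma_px` for other image geometries.

Binarization uses a threshold of 1.2 × the **mode** of the ratio image.
The mode is computed from a 256-bin uniform histogram over the observed range
of valid pixels; the most populated bin's centre wins and ties break toward
the lower bin (a deterministic, documented rule — the underlying data are
continuous ratios, so some binning convention is unavoidable). A constant
image returns its value. The comparison at the threshold is strict (`>`) by
default with an `inclusive` switch; a constant frame therefore binarizes to
all zeros. The mode is taken over the whole valid frame by default;
`mode_within_mask=True` restricts it to the merged mask.

Scores count binarized pixels inside the merged (OR) mask, and

```
growth = (score_test − score_ref) / score_ref
```

is reported as NaN (JSON `null`) when the reference score is 0, never as an
infinity. Swapping the roles of the two frames maps a growth of `g` to
approximately `1/(1+g) − 1`; the relation is approximate rather than exact
because histogram matching always remaps the test side.

## Registration

Correspondences come from FAST corners (`n=9`, threshold 0.10, peaks
separated by ≥ 7 px) described with 256-bit BRIEF descriptors (patch 49,
fixed sampling seed) and matched by Hamming distance with cross-checking.
None of these constants is canonical; they are conventional values exposed in
the API. Vessel branch points are dense corner sources, which is why the
synthetic vessel generator is a branching walk.

The affine transform (aligned → reference coordinates, 2×3 matrix in (x, y)
convention) is estimated by RANSAC: exact fits to random 3-point samples,
consensus at a 3 px residual, up to 2000 iterations, least-squares refit on
the best consensus set, all driven by an explicit integer seed so runs are
reproducible. Estimates whose linear part has |det| outside [0.5, 2] are
rejected as degenerate — follow-up fundus pairs never halve or double in
scale. Fewer than 3 automatic matches raises a fallback error naming the
manual-correspondence CSV format (`x_ref,y_ref,x_aln,y_aln`, 0-based pixel
coordinates).

Images are warped with bilinear interpolation, masks with nearest-neighbour
(so they stay binary). Out-of-frame pixels are filled with 0 and recorded in
a validity mask; they are excluded from the mode, the binarization, the
histogram matching and both Scores symmetrically — asymmetric exclusion
would bias the growth rate.

## Photometric equalisation and the matching stage

Histogram matching is exact empirical-quantile specification (monotone,
rank-preserving, reference never modified), computed over valid pixels only.
The implementation is mask-aware because warped frames carry invalid borders
that must not distort the mapping; on unmasked input it agrees with the
standard scikit-image implementation (asserted by a test).

**Stage.** Matching is applied to the raw warped 8-bit test frame *before*
background division (`match_stage="raw"`, default), equalising gain/offset
differences between visits. Matching the corrected ratio images instead
(`match_stage="corrected"`, selectable) has a provable defect: quantile
specification forces the matched frame's global intensity distribution onto
the reference's, so the count of pixels above any fixed threshold — the
Score — is forced toward the reference's count and the growth signal is
largely cancelled. The raw-stage default is the only ordering under which
the pipeline can report the nonzero growth it is designed to measure. The
direction of matching (test onto reference) follows from the reference frame
being the fixed standard of the pair; `match_direction` swaps it.

**Residual nuisance error.** Subpixel registration residuals resample the
speckle (bilinear smoothing), and full-frame quantile matching then slightly
stretches the smoothed distribution back; together these contribute a
nuisance error of a few percent of the Score on speckle-dominated synthetic
pairs (zero for identity geometry). This is the same order as the intrinsic
repeat variability any such pipeline shows on serial captures and is the
reason pair-level fixtures assert growth bounds of ~±0.1 rather than ±0.01.

## Segmentation

The abnormal-region segmenter is a U-net implemented directly in numpy
(im2col convolutions over BLAS, explicit backprop, Adam) so that training is
CPU-only and fully deterministic for a fixed seed. Defaults: 3 resolution
levels, base 8 channels doubling per level, two 3×3 conv+ReLU per block,
nearest-neighbour upsampling with skip concatenation, sigmoid head, pixelwise
binary cross-entropy (soft Dice available), learning rate 2e-3, batch 5,
30 epochs. Frames are resampled to 128 × 128 for the network and predicted
probabilities resampled back to 496 × 496 before thresholding at
`prob_threshold` (default 0.5; `predict` uses `probability ≥ threshold`, so
0 yields all-ones and anything above 1 yields all-zeros). A deeper/wider
variant is configurable, but at pure-numpy desk scale the small default
reaches the target pixel sensitivity/specificity in minutes, which is the
design point. The segmenter follows the scikit-learn estimator protocol and
is one of three interchangeable mask sources — annotation files and
synthetic ground truth exercise the full pipeline without any trained model.

Pixel sensitivity TP/(TP+FN) and specificity TN/(TN+FP) report NaN when a
denominator is zero rather than a silent 0.

## Trend test

The Jonckheere–Terpstra statistic sums Mann–Whitney counts over ordered group
pairs with ½-weight for ties. The one-sided p-value (increasing alternative
by default, matching the hypothesis that growth rises with clinical severity
rank) is computed:

* **exactly** for pooled n ≤ 10: for untied data via the Terpstra
  decomposition (JT is the sum of independent Mann–Whitney statistics
  U(n₁+…+n_{j−1}, n_j), so the null pmf is a convolution of count
  distributions); with ties by explicit enumeration of assignments (capped at
  3·10⁵ arrangements). The null distribution is cached on (group sizes, tie
  pattern).
* by a **tie-corrected normal approximation** otherwise, continuity
  correction off by default (`continuity_correction=True` subtracts 0.5 and
  markedly improves small-n agreement with the exact null).

Degenerate inputs: a single group or an empty group raises; all-identical
observations give JT equal to its null mean and p = 1.

## Synthetic scenes

The generator emulates exactly the properties the pipeline must cope with
and no more: a dark background (base level 100), a branching random-walk
vessel tree with tapering width (+60 grey levels — sharp corners at branch
points for FAST), one to three wobbly-radius lesion blobs covering roughly
3–12% of the frame, speckled mottle inside the lesion (thresholded band-pass
noise, ~25% coverage, +50 levels ⇒ 1.5 × background, comfortably above the
1.2 threshold and below vessel brightness), a smooth ±25% luminance field
(broad Gaussian bump or planar ramp — all spatial power far below the σ = 70
cutoff), and mild sensor noise (σ = 1 grey level). Pairs are built by
warping the rendered reference with a known affine (which must keep ≥ 80% of
lesion pixels in frame) plus a gain/offset shift (rejected if it would
saturate > 1% of in-frame pixels, since matching cannot undo saturation).
Rendering is a pure function of the scene fields and seed.

What the scenes do **not** model: choroidal texture, late-phase leakage
dynamics, halos, hemorrhage blocking (only approximated in tests by shrinking
mottle inside an enlarged lesion), media opacity, or realistic FA noise
statistics — the generator's parameters were chosen once for testability of
each pipeline contract, not for photorealism. Passing tests therefore show
the pipeline implements its stated operations correctly and robustly under
the modelled nuisances; they do not certify clinical accuracy on real FA
images, whose metrics require clinical data.

The ground-truth Score oracle removes the *true* illumination field from a
render, finds the mode by direct pixel scan and counts pixels above 1.2 ×
mode inside the mask; it shares no code with the scoring module.

## Preprocessing conventions

Canonical form is 496 × 496 unsigned 8-bit, row-major, origin top-left,
0-based indices. Rescaling is order-0 with half-pixel centres (output pixel
(i, j) samples input pixel `floor((i+0.5)·H_in/H_out)`, computed in integer
arithmetic so halfway cases are deterministic); binary images acquire no new
grey levels, and preprocessing is idempotent. RGB-encoded greyscale collapses
by channel average; 16-bit inputs scale by the nominal range (so paired
frames keep relative exposure); non-square inputs rescale anisotropically
(no letterboxing). An optional crop rectangle removes instrument banners
before rescaling.

## Problem sizes

Default verification sizes — 20 scenes for the scoring oracle, 50 sampled
affines (30% outliers) for registration recovery, 50 jittered pairs for
stability, every group configuration with pooled n ≤ 9 plus a 2000-rep null
simulation for the trend test, and 50 training / 10 held-out scenes with 30
epochs for the segmenter — were chosen as the smallest sets that make each
property statistically meaningful on a single CPU; all are parameters of the
respective functions.

## Known limitations

* Growth based on hyperfluorescence under-reports lesions that turn
  hypofluorescent (hemorrhage, lipid blocking); the series mode flags the
  mask-up/growth-down discrepancy but cannot correct it.
* The binarization is exposure-sensitive at the margins; frames with halos
  or heavy artefacts should be excluded upstream.
* Histogram matching interacts with interpolation smoothing (see above);
  pairs are comparable, but absolute Scores across instruments are not.
* The shipped U-net defaults are desk-scale; clinical-grade segmentation
  would need real annotated data and a larger model.
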