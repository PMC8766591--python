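# fascore

Quantification of retinal-pigment-epithelium (RPE) disease area change from
early-phase fluorescein-angiography (FA) image pairs.

## The problem

Loss of RPE produces early-phase hyperfluorescence on FA ("window defects"):
choroidal background light shows through wherever the pigment layer is gone.
Tracking how this diseased area changes between visits matters both for
monitoring atrophic/neovascular AMD and for judging RPE-transplantation
outcomes — but the hyperfluorescent area is speckled with unclear boundaries,
frames carry a smooth luminance slope, and follow-up images are shifted,
rotated, scaled and differently exposed, so manual quantification is slow and
subjective. This package implements an automated two-step pipeline for
ophthalmic-imaging researchers:

1. **Abnormal-region masking** — a small U-net (or a clinician annotation
   file, or a synthetic ground-truth mask) marks the overall abnormal region
   so that scoring ignores healthy retina and stray bright structures.
2. **Scoring** — the image pair is affinely registered (FAST corners, BRIEF
   descriptors, Hamming matching, RANSAC), exposure-equalised by histogram
   matching, and each frame is divided by its own Gaussian-blurred background
   (σ = 70 px) to remove the luminance slope. The corrected frame is
   binarized at **1.2 × the mode** of its pixel values, the two masks are
   merged (pixelwise OR), and the **Score** of a frame is the number of
   hyperfluorescent pixels inside the merged mask.

Between a reference visit and a test visit,

```
Growth rate = (Test score − Reference score) / Reference score
```

Stable structures inside the mask (retinal vessels) contribute equally to
both Scores, so the Growth rate tracks change in the mottled
hyperfluorescent area. A Jonckheere–Terpstra trend test (exact permutation
null for small samples, tie-corrected normal approximation otherwise) checks
that Growth rates rise across ordered clinician severity ranks.

All frames are preprocessed to the canonical 496 × 496 8-bit form with
order-0 (nearest-neighbour) rescaling so binary masks survive unchanged.

Because clinical FA images cannot be redistributed, the package ships a
synthetic-scene generator (`fascore.synthetic`) producing FA-like frames with
a branching vessel tree, speckled lesions, a smooth luminance slope and
known affine/photometric ground truth; every stage is validated against it.

## Worked example

```python
import numpy as np
import fascore
from fascore.registration import AffineParams
from fascore.scoring import score_pair
from fascore.synthetic import lesion_region_mask

scene = fascore.random_scene(7)
transform = AffineParams(np.array([[1.02, 0.01, 8.0], [-0.01, 0.99, -5.0]]))
reference, test, true = fascore.make_pair(scene, transform, gain=1.05, offset=3.0)
mask = lesion_region_mask(scene)
print(score_pair(reference, test, mask, mask).to_json(indent=2))
```

prints

```json
{
  "reference_score": 7170,
  "test_score": 7368,
  "merged_mask_area": 28425,
  "growth_rate": 0.027615062761506277,
  "mask_sources": ["synthetic_truth", "synthetic_truth"],
  "reference_path": "<synthetic:7>",
  "test_path": "<synthetic:7:aligned>"
}
```

The two frames show the same scene through an affine transform plus a
brightness shift, so the ~7,200-pixel hyperfluorescent area is recovered on
both sides and the growth rate is near zero (+0.028 here; resampling of
speckle and histogram matching contribute a few percent of nuisance error,
the same order as the method's intrinsic repeat variability). A genuinely
enlarged speckle area raises `test_score` and the growth rate accordingly;
`growth_rate` is `null` in the JSON when the reference score is 0.

The same pipeline is available from the shell:

```
fascore pair ref.tif test.tif --mask-ref ref_mask.png --mask-test test_mask.png --out results/
fascore series day0.tif day400.tif day800.tif --masks m0.png,m1.png,m2.png
fascore train --images-dir frames/ --masks-dir masks/ --out segmenter.npz
fascore simulate --seed 0 --n 5 --pair --out synthetic/
fascore jt-test ranks.csv --plot ranks.png
```

`fascore series` scores every visit against day 0 and flags visits where the
mask area grows while the growth rate falls — the signature of new blocking
(e.g. hemorrhage) inside an expanding lesion.

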