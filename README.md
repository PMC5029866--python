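# tvseg

Segmentation of individual cell nuclei in H&E-stained breast-cancer
histopathology crops, built for images where classical pipelines struggle:
enlarged, irregularly shaped cancer nuclei with coarse peripheral chromatin,
frequently touching or overlapping, alongside stain artifacts.

It is a library plus a small CLI, aimed at digital-pathology researchers who
need per-nucleus masks and contours (e.g. as input to nuclear-pleomorphism
features) and a reproducible way to score them against labeled ground truth.

## Method

Two image cues drive everything: nuclei are dark after hematoxylin staining,
and their boundaries carry a sharp, roughly convex intensity gradient.

1. **PCA grayscale** `A`: each RGB image is projected on the first principal
   component of its own channel covariance, sign-fixed so nuclei are dark,
   rescaled to [0, 1].
2. **Sobel gradients**: magnitude `G` and orientation `α = atan2(G_V, G_H)`.
3. **Stick tensor voting**: every strong-gradient pixel casts votes that
   decay along the osculating arc to each receiver,

   `DF(s, k, σ) = exp(−(s² + c·k²)/σ²) · G·(1−A)`,  `c = 16(σ−1)/π²`,

   with arc length `s = αl/sin α` and curvature `k = 2 sin α / l`. Sticks
   parallel to the gradient build a *center* saliency map; sticks
   perpendicular to it build a *boundary* map. Their difference
   (perpendicular − parallel, rescaled) is the combined map: boundaries
   bright, interiors dark.
4. **Seeds**: suppressed regional maxima of the smoothed parallel map.
5. **Boundary per seed**: a 30×30 window is resampled along 32 radial
   spokes; each spoke chooses a boundary radius by minimizing

   `E = Σᵢ E_data(i, lᵢ) + Σ_{⟨i,j⟩} E_smooth(lᵢ, lⱼ)`

   on the cyclic spoke graph — data cost is the negative combined saliency
   at the candidate radius, smoothness cost is `λ|lᵢ−lⱼ|` with a hard 5 px
   bound — decoded with min-sum loopy belief propagation (an exact
   cycle-DP oracle backs it in the tests).
6. **Post-filter**: segments whose mean interior intensity exceeds 0.6 (ink
   stains, glare) are discarded. Scoring reports precision, recall, and the
   Dice coefficient `2|M∩N|/(|M|+|N|)` at image level and per matched pair.

No clinical images ship with the package; a synthetic H&E-like scene
generator with exact ground truth (dark elliptical nuclei with darker rims,
overlapping pairs, pink background, bright artifacts) supports development,
testing and the quantitative claims below.

## Worked example

```sh
$ tvseg synth --seed 1 --out scene          # 512x512, 30 nuclei, 2 artifacts
scene with 30 nuclei -> scene

$ tvseg segment scene/scene.png --out run
30 nuclei segmented -> run (segment means: 0.16, 0.16, 0.16, 0.15, ...)

$ tvseg evaluate run/labeled_mask.png scene/gt_mask.png
precision=1.0000 recall=1.0000 image_dice=0.9438 mean_pair_dice=0.9397 (TP=30 FP=0 FN=0)
```

All 30 nuclei of the generated scene are found (no false positives, both
bright artifacts rejected by the mean-intensity filter at 0.6 — the reported
segment means sit near 0.16, far below it). The image-level Dice of 0.944
says the union of predicted masks overlaps the union of true masks almost
completely; the mean pair Dice of 0.940 says each individual nucleus mask is
also accurate. `run/` contains the 16-bit labeled mask, contour CSV/JSON,
per-segment statistics and a JSON manifest echoing every parameter;
`segment --debug` additionally writes the PCA grayscale and all three
saliency maps as float TIFFs.

The same pipeline is available as a library:

```python
from tvseg import SceneConfig, generate_scene, segment_image, evaluate_segmentation
scene = generate_scene(SceneConfig(rng_seed=1))
segments, intermediates = segment_image(scene.rgb)
print(evaluate_segmentation(segments, scene.gt))
```

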