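# tvseg: methods

## Problem and model

`tvseg` segments individual cell nuclei in crops of H&E-stained breast-cancer
histopathology (typically 1024x1280 at x40 magnification). Cancer nuclei are
hard targets for classical thresholding/watershed pipelines: they vary from
round to highly irregular, their chromatin is coarse and marginalized to the
periphery, and they frequently touch or overlap. The method leans on two weak
but robust cues — nuclei are *dark* (hematoxylin) and roughly *convex* with a
sharp intensity gradient at their boundary — and turns them into a seed-then-
delineate pipeline:

1. **Grayscale reduction.** Each RGB image is projected onto the first
   principal component of its own 3x3 channel covariance, sign-normalized so
   nuclei are dark, and min-max rescaled to [0, 1]. Per-image PCA adapts to
   staining variation without a calibrated deconvolution matrix.
2. **Gradients.** 3x3 Sobel responses `G_H` (d/dcol) and `G_V` (d/drow), with
   edge-replicated borders; magnitude `G = sqrt(G_H^2 + G_V^2)` and
   orientation `alpha = atan2(G_V, G_H)`. The two-argument arctangent is
   essential: a tangent ratio would lose the quadrant needed to orient votes.
3. **Stick tensor voting.** Every pixel with `G` above a floor casts decaying
   votes to its neighborhood. A vote to a receiver at chord length `l` and
   acute chord/stick angle `a` follows the osculating circular arc, with arc
   length `s = a l / sin a` and curvature `k = 2 sin a / l`, and weight

       G (1 - A) exp(-(s^2 + c k^2) / sigma^2),
       c = -16 log10(0.1) (sigma - 1) / pi^2 = 16 (sigma - 1) / pi^2.

   Sticks aligned with the gradient (*parallel* voting) reinforce nucleus
   centers; sticks rotated 90 degrees (*perpendicular* voting) reinforce
   boundaries. The *combined* map (perpendicular minus parallel, rescaled to
   [0, 1]) shows boundaries bright and interiors dark.
4. **Seeds.** Regional maxima of the parallel map, smoothed at the voting
   scale, above 10% of the global maximum, greedily thinned to a 10 px
   minimum spacing, then refined to the centroid of the near-maximal plateau
   (see "Numerical choices").
5. **Boundary extraction.** A 30x30 window around each seed is resampled
   along 32 spokes at radii 1..15 (bilinear). Each spoke picks a boundary
   radius; the energy is the sum of per-spoke data costs (negative
   window-normalized combined saliency — the bright boundary ridge is cheap)
   and pairwise costs `lambda |l_i - l_j|` for cyclically adjacent spokes,
   infinite when the deviation reaches 5 px. The cycle makes the MRF loopy;
   it is decoded by synchronous min-sum loopy belief propagation (messages
   initialized to 0, normalized by their minimum each round, damped 0.5, up
   to 50 rounds, tolerance 1e-6), beliefs decoded by argmin with ties toward
   the smaller radius. An exact conditioning-plus-chain-DP solver ships
   alongside as the inference oracle used in tests; on random cyclic
   instances (6-10 spokes, 6-10 labels) LBP decodes the exact optimum in
   97-100% of cases and, by construction, never reports an energy below it.
6. **Post-filtering.** Each contour is rasterized (pixel centers inside the
   polygon) and its mean grayscale intensity computed; segments with mean
   above 0.6 are discarded as stain artifacts/false alarms. Survivors are
   relabeled densely. An optional deduplication pass (off by default) merges
   detections whose masks overlap with Dice > 0.8.

Evaluation matches detections to ground-truth nuclei greedily by mask Dice
(threshold 0.2, one-to-one) and reports precision `TP/(TP+FP)`, recall
`TP/(TP+FN)`, image-level Dice (union vs union) and mean matched-pair Dice.
Image-level and per-pair Dice answer different questions (area agreement vs
per-nucleus segmentation quality), so both are reported.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `sigma` | 5 | px | stick scale; suited to 5-12 px nucleus radii at x40 |
| `support_radius` | 3 sigma | px | standard stick-field truncation |
| `angular_aperture` | pi/4 | rad | classical 45-degree stick cone, both lobes |
| `gradient_floor` | 5% of max G | — | skip near-flat background voters (large speedup) |
| `window` | 30 | px | boundary search window; must enclose one nucleus |
| `n_profiles` | 32 | — | ~3 px arc spacing at the 15 px max radius |
| `smoothness_limit` | 5 | px | hard bound on adjacent-spoke radius deviation |
| `smoothness_weight` | 0.5 | per px | linear penalty inside the bound |
| LBP schedule | 50 iters, tol 1e-6, damping 0.5 | — | synchronous min-sum |
| `seed_min_distance` | 10 | px | minimum seed spacing |
| `seed_min_height_fraction` | 0.1 | — | reject weak maxima |
| `seed_smooth_sigma` | 5 (= sigma) | px | see below |
| `mean_threshold` | 0.6 | — | artifact filter on the [0,1] PCA grayscale |

**Seed smoothing at the voting scale.** Inside a nucleus larger than the
stick scale, parallel votes do not pile up at the center — the arc-length
decay confines each voter's influence to ~2 sigma, so the interior field is a
ridge *ring* at roughly `radius - sigma`. Smoothing below that scale leaves
several regional maxima per large nucleus (duplicate seeds, precision loss);
smoothing at the voting scale merges the ring into one central peak while
still separating touching nuclei whose centers sit ~1.5 radii apart. Stronger
smoothing was measured to merge clustered pairs and cost recall.

## Synthetic scenes

No clinical dataset ships with the package, so all quantitative statements
are made on generated scenes with exact ground truth. The default scene is a
512x512 crop with 30 elliptical nuclei (semi-major 5-12 px, eccentricity up
to 0.5), 30% of them placed as touching/overlapping pairs (center distance
80-100% of the summed radii, overlap capped at 40% of the smaller footprint),
dark hematoxylin-hued interiors with a cosine roll-off into a darker rim
(peripheral chromatin), mild smoothed interior texture, two bright stain
artifacts, an eosin-pink background and Gaussian sensor noise (sigma 0.02).
All randomness flows from one integer seed; scenes are bitwise reproducible.

What the generator does *not* emulate — and hence what passing tests do not
show: true H&E colorimetry and stain variation between slides, stromal and
tubule structure, nucleoli, out-of-focus blur, dense clusters of more than
two nuclei, and nuclei larger than the 30 px search window. Results on
clinical material will be worse than the synthetic numbers; the synthetic
regime establishes correctness of each stage and the detection behavior the
design targets, not clinical performance.

`single_nucleus_fixture` renders one clean nucleus (no texture, minimal
noise) with known center and radius for seed-localization and
boundary-recovery measurements.

## Numerical choices

- **Degenerate inputs.** Constant-color images have a degenerate channel
  covariance; the grayscale falls back to the channel mean with a warning.
  Constant saliency maps yield no seeds; a constant combined difference
  rescales to all zeros (checked with a relative 1e-12 tolerance so float
  dust does not explode under min-max rescaling). Sobel responses below
  1e-12 are zeroed so constant regions are exactly flat.
- **Vote geometry.** The field is symmetric about the stick axis and across
  its two lobes, so only the acute chord/stick angle (folded into [0, pi/2])
  enters; the straight-line limit `a -> 0` returns `s = l, k = 0`.
- **Infinite costs.** Off-image radii get infinite data cost; inside message
  arithmetic infinities are clamped to 1e9 to keep min-sum updates NaN-free,
  and decoded energies are recomputed from the true (infinite) costs, so an
  infeasible decoding is recognized and the nucleus rejected.
- **Tie-breaks.** Belief argmin takes the smallest radius; seed ordering is
  by descending score then row-major position.
- **Seed refinement.** The argmax of a heavily smoothed field is unstable on
  the flat annular top left by the largest nuclei (observed ~3.5 px
  off-center at radius ~12). Accepted peaks move to the intensity-weighted
  centroid of the >= 98% - of - peak plateau within 0.8 x min_distance; for a
  sharp peak this is the peak itself, and minimum spacing is re-checked after
  the move.
- **Rasterization.** Pixel centers inside or on the polygon (even-odd rule);
  a degenerate polygon yields an empty mask with a warning and the segment is
  dropped.
- **Combined-map direction.** The combined map is perpendicular minus
  parallel (boundaries bright); a `flip_sign` flag provides the opposite
  convention.

## Design choices that were genuinely open

- **Data cost.** The boundary likelihood is the negative normalized combined
  saliency at the candidate radius. An interior-homogeneity term (penalizing
  intensity spread inside the contour) is a documented alternative; the
  saliency-ridge form is simpler, matches the bright-boundary construction of
  the combined map, and recovers clean boundaries to sub-pixel mean radial
  error, so it is the default and only implementation.
- **Pairwise cost inside the 5 px bound.** A linear `lambda |dl|` with
  `lambda = 0.5`; the hard bound alone leaves the contour free to zigzag
  within 4 px, and the linear term regularizes without fighting genuine
  ellipticity.
- **Number of spokes.** 32, giving ~3 px arcs at the window edge; fewer
  spokes undersample irregular boundaries, more add cost without measurable
  accuracy gain at a 15 px max radius.
- **Per-image PCA** (rather than a fixed reference basis): adapts to stain
  level; the cost is that the grayscale convention is only anchored when
  dark nuclei are actually present (a nuclei-free image anchors "dark" to
  background noise — see limitations).

## Known limitations

- Dense clusters (3+ mutually touching nuclei) and pairs whose centers are
  closer than the 10 px seed spacing are detected as one nucleus.
- Nuclei with radius above ~13 px do not fit the 30 px window; the contour
  clips at the window edge.
- The mean-intensity filter assumes the image contains nuclei; on an image
  with none, per-image rescaling makes background "dark" and spurious
  detections can pass the filter.
- LBP is approximate on cycles: on ~1-3% of random instances it decodes a
  labeling above the exact minimum (never below). On real boundary problems,
  whose data costs are strongly peaked, no mismatch was observed.
- Whole-slide images are out of scope; the pipeline operates on crops.

## Problem sizes used in tests and the acceptance script

Inference equivalence uses 200 random cyclic MRFs (6-10 spokes, 6-10
labels). Seed localization uses 20 single-nucleus scenes (radii 5-12 px,
64x64). Boundary recovery uses 7 circular radii in [6, 12] and a 3x3 grid of
eccentricities {0.3, 0.45, 0.6} x radii {8, 10, 12}. End-to-end metrics
average 3 default 512x512 scenes (90 nuclei, 6 artifacts); determinism is
checked by re-running one 256x256 scene. The full acceptance run completes
in well under a minute on one core.
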