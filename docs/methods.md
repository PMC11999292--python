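# Methods

## Overview

`gwoscreen` implements a three-stage automated glaucoma screen for retinal
fundus photographs:

1. a **UNet++** encoder–decoder segments the optic disc (OD) and optic cup
   (OC), with its hyperparameters tunable by a **Grey Wolf Optimization**
   (GWO) search driven by segmentation quality (or, unsupervised, by a
   texture-differentiation score);
2. the disc region is **cropped** around the predicted disc mask and
   resized to 64×64;
3. a **capsule network** with dynamic routing classifies the crop as
   glaucoma or normal.

A seeded synthetic fundus generator supplies images with exact ground
truth, so the whole chain is trainable and verifiable on one CPU in
minutes.

## Grey Wolf Optimization

The pack of `k ≥ 3` wolves searches a bounded box in `R^d`. After every
evaluation round the three best wolves become the leaders α, β, γ. Every
wolf `i` then moves to the clipped arithmetic mean of three leader-relative
candidates

    E_L  = | y ∘ GW_L − GW_i |          (elementwise)
    cand = GW_L − x ∘ E_L,              L ∈ {α, β, γ}

with fresh coefficient draws per leader. Two coefficient rules are
provided:

* `variant="standard"` (canonical): `a(t) = 2(1 − t/T)`,
  `x = 2a·v1 − a ∈ [−a, a]`, `y = 2·v2`;
* `variant="paper"`: `a(t) = (1 − t/T)/2`, `x = 2a·(v1 + v2) − a ∈ [−a, 3a]`,
  `y = 2·v2`;

`v1, v2 ~ U[0,1]^d` i.i.d. Both rules collapse to pure leader attraction at
`a = 0`, so late iterations exploit while early ones explore. The decay is
deterministic; a stochastic decay would not be a schedule. The prey
location inside `E_L` is identified with the moving wolf's own position —
the only reading that yields a working black-box optimizer, and the one
canonical GWO uses. Out-of-bounds moves are hard-clipped; NaN objective
values become `+inf` sentinels (a diverged training run should lose, not
abort the search); leader ties break by index for determinism.

One unresolved ambiguity is documented rather than decided: the encircling
distance is stated elsewhere without the absolute value; the unsigned
(absolute) form is implemented, matching the pouncing equations.

## Texture-differentiation fitness

Per 8×8 non-overlapping patch, three classical descriptors: intensity
variance, 8-bin entropy, and mean gradient magnitude. The image is
standardized to zero mean / unit variance first, making every downstream
score invariant to affine intensity rescaling. Global resolution-band
energies `rho_high` / `rho_low` are the mean-square of the finest Laplacian
band and the coarsest level of a 3-level pyramid. The pack-allocation
score is

    F(d, P) = [ mean(extf) − (fc / fct) · (rho_high + rho_low)^(−1) ] + P − 1

where `fc` is the within-image 2-means misfit of the patch descriptors
(deterministic farthest-pair initialization, fixed Lloyd iterations — bit
reproducible), `fct` is the descriptor count (a deterministic "time"
proxy), and `P` the pack count. The score is strictly increasing in `P`
and strictly decreasing in `fc`. The per-patch variation flag ω is 1 iff
the z-scored descriptor vector lies more than 2 median absolute deviations
from the patch-population median; the printed probability expression this
flag stands in for is not numerically evaluable as published, so the
implemented gate preserves its documented role (variation vs. no-variation)
without inventing an untestable formula.

Segmentation fitness: supervised mode is `1 − Dice(pred, ref)` (0 best,
1 worst, empty prediction = 1 by contract). Unsupervised mode is the
negative norm of the difference between inside-mask and outside-mask mean
descriptors (patch coverage weighted): a mask isolating a texturally
distinct region — such as the bright disc — scores lower (better) than the
overwhelming majority of random same-area masks.

## UNet++ segmenter

Nested-skip topology: node `X(i,j)` consumes `X(i,0..j−1)` plus the
upsampled `X(i+1,j−1)`; every node is two same-padded 3×3 convolutions
with ReLU. Downsampling is 2×2 max pooling, upsampling nearest-neighbour.
Head: 1×1 convolution, two sigmoid channels (disc, cup). At depth 1 this
degenerates to a plain U-Net. The input side must be divisible by
`2^depth`.

Training: Adam on binary cross-entropy (computed from logits in the stable
log-sum-exp form) plus `1 − softDice` (smoothing 1), early stopping on a
validation holdout (patience 10, best weights restored). Two choices
matter for robustness at desk scale and are deliberate:

* inputs are centered (`2x − 1`) before the first convolution;
* the head bias starts at −2, the approximate background log-odds for a
  10–15 % foreground. Without it, some initializations start in the
  "everything is disc" basin and take many epochs to escape.

Predicted cup masks are intersected with the disc mask: anatomically
OC ⊂ OD.

The GWO search box for hyperparameter tuning is 4-D:
`log10(lr) ∈ [−5, −2]`, dropout `∈ [0, 0.5]`, base filters `∈ [8, 32]`
(rounded), binarization threshold `∈ [0.2, 0.8]`. Each candidate is
short-trained from a fixed seed and scored by `1 − mean validation Dice`,
so the search minimizes a noisy but reproducible objective.

## Capsule network

Default architecture (the printed one): 64×64×3 input → 9×9 valid
convolution, stride 1, 256 filters → 56×56×256 → 9×9 convolution, stride 2,
to 256 channels grouped as 32 capsule types × 8 dimensions on a 24×24 grid
(18 432 primary capsules) → squash → learned votes into two 16-D class
capsules → routing by agreement (3 iterations) → class scores = capsule
norms. These strides/paddings are the only integer solution to the printed
shape chain 64→56→24 with 9×9 kernels.

Squash: `v ↦ (‖v‖²/(1+‖v‖²)) · v/‖v‖`, epsilon-guarded at zero; output
norm strictly inside (0, 1), direction preserved. Routing: logits start at
zero, couplings are a softmax over classes (they sum to 1 for every input
capsule at every iteration), outputs are squashed weighted sums, and
agreement `û·v` increments the logits. Loss is the capsule margin loss
(`m+ = 0.9`, `m− = 0.1`, `λ = 0.5`); there is no reconstruction decoder.
Training batches receive random dihedral augmentation (90° rotations and
flips) — orientation carries no class information in a fundus crop, and at
60-image training sets the augmentation is what separates memorization
from generalization.

Desk profile: tests and the example pipeline shrink `conv_filters` (32)
and `primary_caps_types` (4) for speed; the full printed spec remains the
default and its shape invariants are always validated at build time.

## Synthetic fundus generator

Each sample is drawn from a seeded generator: a reddish mottled
background, a bright elliptical disc (radius 15–25 % of the side,
eccentricity 0.9–1.1), a brighter concentric cup whose diameter ratio
(CDR) defines the class — normal CDR ∈ [0.2, 0.4], glaucoma
CDR ∈ [0.6, 0.85], disjoint by construction — dark quadratic Bézier vessel
strokes, then the acquisition aberrations reported for public screening
sets: Gaussian blur (σ 0.3–1.2), multiplicative brightness jitter
(0.85–1.15), additive sensor noise (σ 0.02). Masks are rasterized from the
analytic ellipses *before* degradation, so ground truth is exact, and the
mask-measured CDR agrees with the drawn CDR within 2 % (rasterization).

What the generator does **not** emulate: peripapillary atrophy, vessel
bends at the cup rim (a cue real graders use), illumination gradients,
camera vignetting, and inter-eye anatomical variation. Passing tests
therefore demonstrate that the machinery — optimization, segmentation,
routing, the full pipeline — works end to end on separable data; they are
not evidence of clinical-grade accuracy on real fundus photographs.

## Pipeline and metrics

Stages run with per-stage seeds derived from one master seed
(`SeedSequence`), so a run is exactly reproducible: manifests, masks and
search traces are byte-identical across re-runs. The disc crop is centered
on the predicted-mask centroid with side twice the mask bounding box
(center-crop fallback with a warning if the mask is empty), resized to
64×64 and contrast-stretched to [0, 1] — the stretch removes the
brightness jitter that otherwise dominates the class cue. Glaucoma is the
positive class everywhere. Reported metrics: accuracy, precision,
recall (= sensitivity), specificity, as percentages; a zero-denominator
ratio is reported as NaN with a warning, never silently as 0.
Segmentation (Dice/IoU) and classification metric blocks are always
reported separately, never merged into one number.

Desk-scale problem sizes used by the tests and the example config: 20
images at 64 px for segmentation learning; 5 wolves × 5 iterations × 3
budget epochs on 32 px fixtures for tuning; 30+30 training and 10+10 test
images for the end-to-end screen. Full-scale defaults mirror the
documented training recipe (Adam 1e-4, batch 32, 100 epochs with early
stopping); fixture-scale runs use Adam 1e-3.

## Numerical choices

* float32 throughout the networks; float64 in the optimizer and texture
  code.
* Dice/IoU are exact ratios with a both-empty → 1.0 convention; the ε
  smoothing lives only inside the soft-Dice training loss.
* Leader ranking uses a stable sort (lower index wins ties).
* The networks run on a compact tape-based reverse-mode autodiff
  (`gwoscreen.autograd`): broadcast arithmetic, batched matmul, valid/same
  2-D convolution via sliding windows, 2×2 max pooling, nearest upsampling,
  channel concatenation, and a stable BCE-with-logits op with the exact
  `(σ(l) − y)/n` gradient.

## Known limitations

* The synthetic generator's class cue (CDR) is cleaner than real public
  screening datasets; real-data performance is out of scope here.
* The capsule classifier has exactly two class capsules; multi-stage
  grading would need a wider head.
* Binary/discrete and multi-objective GWO variants are out of scope, as
  are attention/transformer segmentation hybrids.
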