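# Methods

`madet` detects microaneurysms (MAs) — the earliest visible lesion of
diabetic retinopathy — in colour fundus photographs.  MAs are dark/red,
roughly circular, under ~125 µm across (a few pixels at typical fundus
resolution), and vastly outnumbered by background: the central modelling
problem is extreme class imbalance combined with confusable vessel
structure.  The package implements a two-stage patch-CNN cascade with
lesion-level free-response ROC (FROC) evaluation, plus a synthetic scene
generator that makes the whole pipeline testable without clinical data.

## Pipeline

1. **Shade correction.**  Retinal images are non-uniformly illuminated.
   The background is estimated per channel with a 30×30-pixel median
   filter and subtracted; a constant offset (default: the per-channel
   mean of the original image) keeps the result representable, and values
   are clipped to the recorded range.  An even-sided median window has no
   canonical centre: the anchor is `floor(side/2)` and, for an even
   sample count, the upper-middle order statistic is used (the
   `scipy.ndimage.median_filter` convention).  Borders are reflected
   symmetrically everywhere in the package — filters, patch windows, and
   smoothing alike — because reflection preserves local intensity
   statistics where zero padding would create artificial edges.

2. **Patch sampling.**  Training examples are square windows labeled by
   their central pixel (MA iff that pixel is a lesion pixel; with
   centroid-only annotation, iff the centre is within a closed ball of
   `lesion_radius` = 3 px of a centroid).  The raw pool takes every
   lesion pixel as a positive and draws background centres uniformly
   over the field of view (FOV), 9 per positive by default — the order
   of imbalance such pools show in practice.  Patch side defaults to
   101 px; the scaled test regime uses 25 px.  Dihedral augmentation
   (4 rotations × optional mirror, no interpolation) is available and
   label-exact.

3. **Stage 1 — screening net.**  A small CNN (three conv+maxpool stages
   with 16 filters of side 7, 5, 3; fully connected 200/100/2; softmax)
   is trained on an *exactly balanced* subsample of the pool.  Balanced
   training removes the imbalance but, having seen only a sliver of the
   background, the net over-fires on hard structures — which is exactly
   what stage 2 exploits.

4. **Hard-example selection.**  The screening net is scanned over each
   training image to give a per-pixel MA probability map.  Pixels with
   probability strictly above T = 0.6 become stage-2 training centres;
   all ground-truth lesion pixels are appended (deduplicated) so stage 2
   always sees the full positive class.  The selection shrinks the
   negative class to its informative fraction, so the stage-2 set is far
   less imbalanced than the pool — this reduction is the pipeline's
   imbalance mechanism and is asserted by the test suite.

5. **Stage 2 — final net.**  A deeper CNN (five conv+maxpool stages,
   kernel sides 7, 5, 3, 2, 2, 16 filters each; fully connected 100/2)
   is trained on the selected hard negatives plus all positives, with no
   class weighting (the selection itself is the remedy).

6. **Cascade inference.**  On a test image the screening net runs
   everywhere; the final net is evaluated *only* at pixels the screening
   map puts above T, and the detector map is 0 elsewhere.  This mirrors
   how the stage-2 training set was selected: scanning the final net over
   all pixels would feed it easy background it never saw during training
   (the classic hard-mining pitfall) and empirically floods the candidate
   list with confident false positives.  It also makes whole-image
   inference roughly an order of magnitude cheaper.

7. **Post-processing.**  The detector map is noisy; it is convolved with
   a normalised 5-pixel-radius disk kernel (the lesion scale), so that
   each detection becomes a smooth bump.  Candidates are the local maxima
   over a square neighbourhood of half-width `min_distance` (default =
   the disk radius), with the smoothed value as confidence.  Plateau ties
   go to the lexicographically smallest coordinate, which makes the
   candidate list deterministic and testable.

8. **Evaluation.**  A candidate is a true positive when a ground-truth
   centroid lies within 5 px (closed ball, Euclidean); matching is
   one-to-one, greedy in descending confidence, nearest lesion first.
   Sensitivity TP/(TP+FN) is pooled over all lesions of the set.  The
   FROC curve sweeps thresholds over the candidate confidences and plots
   sensitivity against mean false positives per image (FPI).  Summaries:
   CPM (mean sensitivity at FPI = 1/8 … 8) and the partial area under
   sensitivity vs log₂(FPI) over [1/8, 8], normalised by the interval
   width 6.  Between operating points the curve is interpolated linearly
   on the log₂ axis and extended flat beyond its ends; an operating point
   with zero FPI is pinned just below the lower integration limit, where
   only its flat extension matters.

## Network engine

No deep-learning framework is used: the networks are declared as
`NetworkSpec` layer lists and compiled to a compact numpy engine
(channels-last im2col convolution, 2×2/stride-2 max pooling, leaky
rectifier `f(x) = x if x ≥ 0 else 0.01·x`, inverted dropout, softmax
with fused cross-entropy gradient, explicit backprop).  The engine was
verified against numerical gradients.  Channel-pairwise maxout is
available as an alternative activation but off by default; the leaky
rectifier is the one given in closed form with its slope.

Published layer tables for this family of patch networks are not
internally consistent about intermediate spatial sizes.  The load-bearing
content — kernel sizes, filter counts, pooling and layer order — is
implemented exactly; spatial sizes follow from valid convolution
(`s−k+1`), same-padding for the first convolution of the final net
(which preserves the input side), and floor-division pooling.  For small
inputs a convolution that would exhaust the spatial extent switches to
same-padding and a pooling step on a 1-pixel map is skipped, so the same
stage structure compiles at any patch side ≥ 9.  The resulting shape
chains are frozen in the test suite, as is the basic net's parameter
count at side 101 (290,806).

**Training.**  Stochastic gradient descent with classical momentum
(defaults: learning rate 0.005, momentum 0.95, batch 64).  Plain SGD at
small learning rates fails to move off chance within the few-epoch
budgets used at desk scale, while larger rates destabilise training;
momentum SGD converges reliably across the regimes exercised here.
Dropout (p = 0.25) sits after all three pools and the first hidden FC
layer of the basic net, and after pools 1 and 3 of the final net.
Inputs are scaled to [−0.5, 0.5].  Training is bit-deterministic given
the seed; dropout is disabled at inference.

## Synthetic scenes

The generator renders what the detector must cope with and nothing more:
a circular FOV with a smooth multiplicative illumination field (tilted
plane + off-centre vignette, ±12.5% by default), dark curvilinear
vessels (smooth random walks, Gaussian profile, width 2–5 px, 50%
intensity dip), and small circular lesions (Gaussian profile, radius
2–5 px — the sub-125 µm scale at typical resolution — 35% dip, strongest
in the green channel as for reddish lesions on an RGB sensor), plus
additive Gaussian noise (σ = 3 grey levels).  Lesion centres are
rejection-sampled at least `2·r_max` apart, inside an eroded FOV so the
full profile fits, and off-vessel by default; a `hard_mode` flag places
half of them against vessels to exercise that known failure mode.
Scenes are byte-deterministic given their seed (renders are frozen to
8-bit), and a matched filter at the lesion scale recovers ≥95% of
planted centroids on noiseless scenes — the floor guaranteeing the
pipeline has signal to learn.

What the generator does *not* model: optic disc, exudates and
haemorrhages, vascular branching, texture, JPEG artefacts, camera
variation.  Passing the synthetic study therefore shows that the
mechanism works (imbalance reduction, cascade detection, scoring), not
that the trained weights transfer to clinical images — training on real
annotated datasets is required for that.

## Scaled-down study conditions

The reference end-to-end experiment uses 20 training and 10 held-out
scenes of 256×256 px with 8 lesions each, 25×25 patches, 5 epochs per
stage, and inference stride 2 (skipped positions take the nearest
evaluated value; the 5-px disk smoothing makes the detector insensitive
to this half-resolution scan).  These sizes keep a full run to a few
minutes on one CPU core while the task remains non-trivial.  Under these
conditions the hard-example selection cuts the non-MA:MA ratio from 9:1
to roughly 2:1, and held-out per-lesion sensitivity at 8 FPI is well
above 0.9.

## Numerical and design choices

- Strict inequality for selection (`p > T`), closed balls for all radii.
- Greedy confidence-descending matching (ties: smaller coordinate
  first); the assignment discipline is not dictated by the evaluation
  protocol itself, and greedy matches common FROC tooling; a brute-force
  oracle bounds it on test instances.
- Candidate confidence equals the smoothed map value; the threshold
  sweep happens in the evaluator, so `find_candidates` defaults to a
  zero confidence floor (pipelines that produce mostly-zero cascade maps
  pass a tiny floor to skip the background plateau).
- Cross-entropy probabilities are clipped to (1e−7, 1−1e−7).
- Cross-validation splitting is by image, seeded, default k = 5.
- Probability maps persist as 16-bit PNG (`round(p·65535)`) with a JSON
  sidecar; networks as `.npz` weights with a YAML/JSON sidecar.

## Known limitations

- The engine is CPU-bound and single-threaded; full-scale 101-px
  training at clinical dataset sizes is out of its intended range.
- Stage-2 class composition depends on the screening net's quality: a
  barely-trained screening net can select either nothing (leaving stage
  2 without negatives, which raises an error) or nearly everything.
- The FROC's FPI axis uses the number of evaluated images as the
  denominator; sets with no lesions at all are rejected rather than
  scored.
- `fov_mask` is required for tight candidate maps; without one the whole
  frame is treated as retina.
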