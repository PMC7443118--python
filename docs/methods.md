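# Methods

`whatwhere` simulates covert visual search as an accuracy-seeking
policy with two trainable pathways, and reproduces that architecture's
behavioral signatures on synthetic cluttered displays.

## The task and the generative model

A trial is a 128x128 grayscale display: isotropic band-pass clutter, a
single 28x28 target of known class embedded at a hidden position, and a
circular mask of radius 64 px.  The agent starts fixating the center
and must name the target's class, optionally after one or more
saccades.

Clutter is band-pass filtered white noise.  The radial amplitude
envelope is log-normal in frequency with a 1/f prefactor,

    A(f) = (sf0/f) * exp( - log^2(f/sf0) / (2 (b_sf ln 2)^2) ),

so `sf0` (default 0.1 cyc/px, matched to the targets' stroke scale) is
the *median* of the ring-averaged amplitude spectrum and `b_sf`
(default 1 octave; the reference protocol prints no value) is its log
bandwidth.  The texture is min-max rescaled to fill [0, 1] at full
display size.  The target is clamped to [0, 1], scaled by a contrast in
[0.3, 0.7] drawn per trial, and merged opaquely (per-pixel max;
a transparent 50/50 mean blend is available).  Positions are drawn
isotropically; a position is admissible when the whole 28x28 footprint
lies inside the mask, bounding the eccentricity at every azimuth by
64 - 14*sqrt(2) ~ 44.2 px.

Coordinates are 0-based (row, col); the display center is pixel
(64, 64); a target position is the displacement of its center pixel
(footprint index 14) from the display center.

## Retinal encoding

The peripheral observation is `T @ whiten(image)` with `T` a fixed bank
of log-Gabor filters on a log-polar grid: 10 eccentricity rings (2 ..
51.3 px) x 24 azimuths x 6 orientations x 2 phases (even/odd) = 2,880
coefficients from 16,384 pixels (~83% compression).  Filter peak
frequency scales as 1/eccentricity at constant octave bandwidth, so
spatial extent grows proportionally to eccentricity.  Whitening is the
isotropic ramp `f * exp(-(f/0.4)^4)`; each filter row is normalized so
its composition with the whitening filter has unit L2 norm, which
balances coefficient magnitudes across rings (measured spread < 10%
on white noise; plain unit-norm rows leave a ~7x imbalance).

Reconstructions for diagnostics use a truncated-SVD pseudo-inverse.
The bank's singular spectrum decays continuously with no gap, so the
cutoff trades stability against the Moore-Penrose identity error; the
default relative cutoff 1e-7 keeps `T T+ T = T` to ~1e-7 while the
reconstruction remains usable.

Gaze shifts are integer-pixel translations (saccade targets are decoded
to integer pixels); out-of-frame content is zero-padded.

## The What pathway (critic)

A small convolutional classifier reads the 28x28 foveal crop: three
conv layers (8/16/32 channels, kernels 5-3-3) each followed by 2x2 max
pooling (28 -> 14 -> 7 -> 3), then fully connected 288 -> 128 -> 10
with sigmoid outputs trained by per-class binary cross-entropy against
one-hot labels.  The pooling cascade provides the partial shift
tolerance the whole architecture relies on.  The maximum of the 10
likelihoods is the *foveal accuracy* — the critic signal.

Training is staged: first clean centered targets, then a curriculum of
freshly generated cluttered patches whose Gaussian shift std grows
stepwise (reference schedule: +1 every 5 epochs to a cap of 15, shifts
clipped at +-27 px, 75 epochs x 60,000 samples) with contrast uniform
in [0.3, 0.7].  Curriculum patches are generated directly at 28x28
(clutter cropped from a full-size normalized texture, shifted target
clipped at the patch border) — statistically equivalent to cropping a
full display and ~20x cheaper.

After training, accuracy is measured on a grid of target shifts within
+-27 px (1,000 cluttered samples per shift at full scale) to give the
55x55 shift-dependent accuracy map: the critic's empirical transfer
curve, peaked at the center and decaying to the 10% chance level by
~20 px.

## The collicular map and the Where pathway (actor)

The action space is a 240-cell motor map on the same log-polar grid.
Pixel-space accuracy maps are projected onto cells by Gaussian kernels
in (log r, azimuth) coordinates — radial width half the local log ring
spacing, angular width half the azimuth step, both unprinted in the
reference and config-exposed — each normalized to sum to one, so a
cell's value is a spatial average and a constant map projects to that
constant exactly.  Cells are independent Bernoulli accuracies, not a
distribution over cells.

Ground-truth maps exploit the independence of classification accuracy
from position: center the measured shift map at the target's retinal
offset, pad elsewhere with the map's border mean (~ chance), project to
cells.  Beyond the measured +-27 px support the accuracy has saturated
at chance, which the padding reproduces.

The Where network is fully connected, 2,880 -> 1,000 -> 1,000 -> 240,
ReLU hidden layers with batch normalization, sigmoid output, trained
with per-cell binary cross-entropy (averaged over cells) against
ground-truth maps of freshly generated displays, target positions
uniform over admissible locations (an eccentricity-Gaussian option is
config-switchable).  The output bias is initialized at logit(0.1) so
training does not spend its first epochs learning the chance base rate.
The Bernoulli entropy of the targets is the irreducible loss floor and
is reported alongside the training loss.

## The decision policy

At each fixation the agent compares the foveal accuracy with the
maximum of the predicted collicular map: answer if the fovea wins (ties
answer, which excludes saccade loops), else saccade to the argmax cell
(ties broken toward the lowest eccentricity, then lowest azimuth index,
favoring short saccades), with gaze clipped to the display and a forced
foveal answer after `max_saccades` (default 3).  Each saccade's benefit
is summarized by the information gain log p(y|x') - log p(y|x) at the
true label, likelihoods floored at 1e-6; it is negative when a saccade
worsens the view, and near zero for already-centered targets.

## Run profiles and problem sizes

Two profiles share every algorithmic switch and differ only in scale.
The `paper` profile uses the full reference protocol (20 centered +
75 curriculum epochs of 60,000; 55x55 shift map at 1,000/shift; Where
60 x 60,000 at batch 256, lr 1e-4; 1,000 trials/condition) and is meant
for full-scale runs with a real handwritten-digit bank (an IDX reader
is provided; nothing downloads data).  The `ci` profile completes the
whole pipeline in minutes on one CPU core: 3 centered epochs of 3,000;
14 curriculum epochs of 6,000 with the shift std ramping +1 every 2
epochs (cap 6); shift map measured every 5 px and bilinearly
interpolated to the 55x55 support at 100 samples/shift; Where trained
45 epochs on 8,000 cached pairs at batch 128, lr 1e-3 (the higher rate
and smaller batch compensate for the ~50x fewer optimizer steps; the
cached set replaces per-epoch regeneration because display generation
dominates at this scale); 200 trials/condition.

## The glyph fixture

Tests never download data.  The packaged target bank renders ten bold
geometric glyph classes (ring, bars, plus, X, disk, square, triangle,
double bar, diagonal) on 28x28 with random affine jitter (rotation
+-12 deg, scale 0.9-1.1, translation +-1.5 px).  The bank is
deliberately *easier* than handwriting — thick 4 px strokes,
near-footprint shapes, perfectly separable classes — so that
reduced-scale training retains headroom under the fixed clutter
conditions.  Glyph runs therefore demonstrate the architecture's
orderings (e.g. postsaccadic > presaccadic accuracy at mid periphery),
not the reference study's absolute numbers; matching those requires the
full-scale profile on the real digit set.  What the fixture does not
emulate: within-class style variability of handwriting, stroke
thickness variation, and class confusability — all of which make the
real task harder and the reference accuracies lower than glyph runs at
equal training scale.

## Numerical choices and degenerate inputs

- Exact tie in the answer/saccade comparison: answer.
- Collicular argmax ties: lowest ring, then lowest azimuth.
- A constant texture draw (zero variance) yields an all-zero display
  rather than dividing by zero; whitening maps constants to zero.
- Pixels at radius 0 get zero weight in every collicular kernel (log r
  undefined); the innermost ring (2 px) sets the minimum saccade.
- Batches of size < 2 are skipped during Where training (batch norm
  needs two samples).
- float32 for all network arithmetic and the filter bank; float64 for
  the pseudo-inverse and projection algebra.

## Known limitations

- At reduced scale the critic saturates well below the full-scale
  reference (cluttered central accuracy ~50-60% at 70% contrast vs.
  ~90% reported at full scale), so Where-map contrast and hence
  localization are correspondingly weaker; orderings are preserved, not
  magnitudes.
- The dense 2,880 x 16,384 bank costs ~190 MB; sparse storage would
  help much larger displays.
- No inhibition-of-return memory: repeated false detections can revisit
  the same location within a trial's saccade budget.  Combined with the
  miscalibration of the two confidence signals at reduced scale, extra
  corrective saccades are not guaranteed to help and can lower accuracy
  (the acceptance script reports the measured multi-saccade gain).
- Single target per display by construction; multi-target scenes are
  out of scope.
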