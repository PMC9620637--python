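# Methods

## Problem and pipeline

Atrial septal defect (ASD) closure planning from transthoracic
echocardiography (TTE) hinges on a handful of absolute lengths: the defect
diameter in each of three standard views — parasternal short-axis of the
aorta (PSSAX), subxiphoid long-axis of the two atria (SXLAX) and apical
four-chamber (A4C) — and the tissue rims between the defect and the
surrounding structures (aortic wall, superior and inferior vena cava, atrial
roof, mitral annulus), plus the atrial septum length.  A self-expanding
double-disc occluder can be placed by catheter only if the rims are
sufficient, the septum is long enough to seat the device, and a device of
the required waist diameter exists; otherwise the defect is closed
surgically.

The package implements this as *deep keypoint stadiometry*: a neural
localizer predicts 11 anatomical keypoints (3 in PSSAX, 4 each in SXLAX and
A4C), pixel distances between keypoints are converted to millimetres with
the per-image scale, and an explicit Boolean rule engine turns the
measurements into a closure plan and an occluder size.  Everything after
the localizer is deterministic and auditable: every decision carries a
per-condition trace.

## Keypoint localization

**Heatmap targets.**  Each keypoint is encoded as an unnormalized Gaussian
response map with peak 1 (grid value `exp(-((c-x)^2 + (r-y)^2) / 2σ²)`).
The encoder's default σ is 2 px at full resolution; targets at scale *s*
use coordinates scaled by *s* and σ scaled proportionally with a floor of
0.5 px.  For *training* we widen the targets to σ = 4 px at full resolution
(2 px on the finest supervised grid), which is the conventional width for
hourglass heatmap regression relative to its output grids; sharp σ = 2
targets destabilize optimization at the problem sizes this package trains
at (near-delta targets on the 1/8-scale grid).

**MSHNet.**  The localizer is a cascade of hourglass modules (3 pooling
levels, so the bottleneck sits at 1/8 of the input; residual blocks
throughout; the input size must be divisible by 8).  Multiscale supervision
taps the decoder feature maps at 1/8, 1/4 and 1/2 of the input resolution,
each projected to one heatmap channel per keypoint by a 1×1 convolution.
The multiscale loss is the sum over scales (and stacks) of the per-grid
mean squared error against the downscaled targets.  With multiscale
supervision disabled, only the finest (1/2) scale is supervised and the
model reduces to a vanilla stacked hourglass — that configuration is the
ablation baseline.

**Anatomical-aware supervision (AAS).**  To inject the structural prior
that certain keypoints co-occur in rigid spatial relations, auxiliary heads
at the finest supervised scale regress *pairwise* and *triplet*
co-occurrence maps: the target for a pair (triplet) is the element-wise
maximum of the constituent single-point Gaussians, which keeps values in
[0, 1] and is invariant to permutation within the tuple.  A view with K
keypoints has C(K,2) pair maps and C(K,3) triplet maps (PSSAX: 3 + 1,
SXLAX/A4C: 6 + 4).  Because the max-combination is a nonlinear function of
the single-point maps, the AAS heads use a hidden 3×3 convolution before
the 1×1 projection; a bare linear readout of a narrow trunk cannot
represent the targets.  The pair and triplet MSE terms are averaged over
maps and weighted 0.5 and 0.25 by default (w_ms = w_reg = 1.0); setting
both AAS weights to zero reproduces the no-AAS ablation.

**RegNet.**  A small fully convolutional refiner upsamples the last stack's
heatmaps from all supervised scales to full resolution
(nearest-neighbour), concatenates them along channels and fuses them
through a 3×3 + 1×1 convolution pair into the final full-resolution
heatmaps, trained with MSE against full-resolution targets.  The final
prediction decodes from this fused output.

**Decoding.**  Per channel: argmax (ties to the smaller row, then column)
plus the standard quarter-pixel offset toward the higher of the two axis
neighbours.  For an ideal Gaussian this bounds the per-axis error by
0.25 px + the peak-assignment error, i.e. ≤ 0.5 px Euclidean for interior
points; the test suite sweeps a 32×32 grid exhaustively.  A flat channel
decodes to the grid centre with a low-confidence flag rather than raising.

**Optimization.**  Adam, learning rate 4e-3, batch size 8, global-norm
gradient clipping at 1.0, 30 epochs by default.  Output heads (the 1×1
heatmap projections, AAS heads and RegNet's final conv) are initialized at
0.1× the He scale so the untrained network emits near-zero maps; without
this, a substantial fraction of seeds collapse early for *every*
architecture at small problem sizes.  The learning rate and clipping were
selected by validation-PCK tuning, applied identically to the full model
and the ablations.  Model selection retains the parameters of the epoch
with the highest validation PCK.  Training is a pure function of the seed
on one thread.  A replicate helper repeats train/evaluate over several
seeds and reports mean ± sample standard deviation.

**Black-box baseline.**  A deliberately non-interpretable reference:
shared-weight VGG-style towers over the three views, global average
pooling, the three mm-per-pixel scalars concatenated to the flattened
feature vector, then two fully connected layers ending in a sigmoid
P(transcatheter), thresholded at 0.5.

All networks run on a small in-repo numpy reverse-mode autodiff framework
(`dks.nnet`: same-padding convolution via im2col, 2×2 max pooling,
nearest-neighbour upsampling, affine layers, Adam); every operator's
gradient is verified against central finite differences in the test suite.
CPU-only; float32 for training, dtype-generic for gradient checks.

## Stadiometry

Measurements are Euclidean pixel distances × mm-per-pixel:

* defect diameter per view: distance between the two defect endpoints;
* SXLAX rims: superior endpoint → SVC landmark, inferior endpoint → IVC
  landmark; A4C rims: roof endpoint → roof landmark, mitral endpoint →
  mitral landmark (endpoint-specific pairing via the fixed schema order);
* PSSAX wall rim: wall landmark → the *nearer* defect endpoint (one wall
  landmark serves two endpoints);
* septum length: roof landmark → mitral landmark.  For collinear geometry
  this equals roof rim + defect + mitral rim; the synthetic generator uses
  exactly that construction, so the two candidate definitions coincide.

The maximum defect diameter is taken over the three views.  Measurements
are invariant under rigid motions of the keypoints and reproduce the
generating geometry to ~1e-14 mm on noise-free synthetic cases.

## Decision rules and sizing

The rule set is an expression tree: leaves compare a named measurement to a
threshold (mm) with one of <, ≤, >, ≥, =; internal nodes are AND, OR, NOT.
The shipped default requires all five rims ≥ 5 mm (the conventional
sufficient-rim criterion; the exact consensus thresholds are configurable,
not hard-coded) and the septum length to exceed the suggested device size.
The suggested size is the maximum defect diameter plus a 4 mm margin,
rounded up to the smallest available catalogue waist diameter (default
catalogue: every integer 8–32 mm).  A leaf threshold may name
`suggested_size_mm`, which the decision step resolves dynamically; when no
catalogue device is large enough the plan falls back to surgical (and such
references resolve to +inf so the trace stays complete).  Transcatheter is
suggested iff every condition holds *and* a device fits.  Evaluation does
not short-circuit, so the trace always covers every leaf.

## Synthetic data generator

The generator emulates what the method needs from a TTE frame, not
ultrasound physics: a sector-shaped field of view on a dark background, a
bright septum band interrupted by the defect gap, Gaussian landmark blobs
at the rim anchor structures (brighter) and defect endpoints (dimmer),
optional saturating Doppler-style jet across the gap, multiplicative
Rayleigh speckle (mean 1), Gaussian blur, and 8-bit quantization.
Keypoints lie on a line through the frame centre at a uniform ±30° angle;
all lengths are laid out in millimetres and converted through a randomized
scale, so the ground-truth keypoint geometry is exact by construction.

Sampling is stratified by the decision rules: a Bernoulli draw with the
requested class mix selects transcatheter-eligible geometry (all rims
5.5–12 mm, defect base 5–24 mm — margins clear of the 5 mm rim threshold
and the catalogue bound, so float noise cannot flip a label) or ineligible
geometry (one deficient rim 0.5–4.5 mm with probability 0.7, else an
oversize 30.5–33.5 mm defect that no device fits).  The A4C septum length
is exactly roof rim + defect + mitral rim.  Labels are produced by running
the actual decision module on the ground-truth measurements, so
label consistency of the deterministic back half is exact.

Scale: mm-per-pixel is uniform in [0.08, 0.30] for 256-px frames, rescaled
by 256/size for other frame sizes and clamped from below so the geometry
(plus a 4 mm blob margin) fits within 30 % of the frame half-size; the
scale bar is 40 mm (a typical TTE depth-scale extent).  Rendering raises an
error if a keypoint would leave the frame or the sector.  All generation is
a pure function of the seeds.

What the generator does **not** emulate — real speckle statistics,
anatomy-dependent septum curvature, shadowing, probe-angle variation,
inter-vendor appearance — bounds what passing tests show: they validate the
pipeline's mechanics and the localizer's trainability, not clinical
performance.

## Evaluation metrics

* **PCK**: fraction of keypoints whose pixel error is ≤ α × the scale-bar
  pixel length of that frame (inclusive), α = 0.1 by default; reported
  numbers state α.
* **Plan classification**: accuracy, F1 = 2PR/(P+R), sensitivity,
  specificity with transcatheter as the positive class; zero-denominator
  ratios are NaN with a warning.
* **Occluder size**: MAE in mm, and quadratic weighted kappa over the
  catalogue's ordinal levels, κ = 1 − Σw·O / Σw·E with w_ij =
  (i−j)²/(K−1)² and E the outer product of the marginals of O; κ is
  undefined (NaN + warning) for a degenerate expected matrix.

## Problem sizes and numerical choices

Tests and the acceptance script run at reduced scale, chosen as the
smallest sizes at which every qualitative property of the method is
exercised: 64-px frames, 1-stack networks with 8 base channels, 50–100
training cases, 30 epochs, 3 seeds for replicate comparisons.  At this
scale the full model (multiscale + AAS + RegNet) reaches validation PCK@0.1
≈ 1.0 and the vanilla hourglass ≈ 0.93 on average, reproducing the
direction of the ablation ordering.  End-to-end closure accuracy on
synthetic test cases is limited by rim measurements that sit near the 5 mm
threshold: at ~1 mm/px a 1–2 px localization error is a 1–2 mm measurement
error, so borderline cases flip; this is an intrinsic property of
rule-based decisions under localization noise, not of the rule engine
(which is exact given the measurements).

Degenerate inputs are handled without exceptions where a pipeline must
continue (flat heatmap → centre fallback + flag; no fitting device →
surgical) and with exceptions where configuration is wrong (unknown
measurement names, malformed rule trees, geometry that cannot fit the
frame).

## Known limitations

* Synthetic imagery is far simpler than clinical TTE; reported accuracies
  do not transfer.
* The septum is rendered straight; curved-septum arc length is out of
  scope.
* The exact consensus rim thresholds and the vendor catalogue are
  placeholders to be edited in the rule/catalogue configs.
* The autodiff framework is minimal by design (stride-1 convolutions,
  2× pooling/upsampling only) and CPU-bound; it is sized for the package's
  problem scales, not for 256-px clinical-scale training.
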