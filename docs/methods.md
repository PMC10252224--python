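# Methods

## Problem and model

`facemark3d` predicts the positions of 32 named facial soft-tissue landmarks
(endocanthion, pronasale, gonion, ...) directly from a 3D facial surface
point cloud, as used in orthodontic and orthognathic assessment.  The method
is coarse-to-fine:

1. **Voxelization.**  A cloud of K points (K varies between scans) is
   normalized into [-1, 1]^3 by an isotropic similarity — translation to the
   bounding-box midpoint, division by the scaling multiplier S = half the
   largest bounding-box edge (mm per normalized unit) — and rasterized onto
   an M^3 binary occupancy grid.  This converts the unordered, variable-size
   point set into a fixed-size tensor; the per-axis quantization error is
   bounded by the cell width, 2S/M mm.
2. **Organ detection (coarse).**  A volumetric convolutional network maps
   the M^3 grid to six axis-aligned boxes, one per face region (eyes, nose,
   lips, chin, right face, left face), each encoded as a 6-vector
   [x, y, z, xl, yl, zl]: center plus per-axis half-extents in the
   normalized frame, 36 outputs in total.  Blocks are conv(3^3, stride 1,
   pad 1) -> maxpool(2^3) -> batchnorm -> sigmoid; the head is fully
   connected with a linear 36-unit output.  Centers are decoded through
   tanh onto (-1, 1) and half-extents through softplus with a 1e-3 floor,
   so every decodable box is geometrically valid.
3. **Landmark regression (fine).**  Each organ's points are cropped with a
   configurable margin (default 1.1) around its box, re-normalized into the
   organ frame by an isotropic transform taken from the inflated box (origin
   at the box center, scale = largest inflated half-extent), and
   re-voxelized.  A per-organ network — the same conv/pool/norm/sigmoid
   cycles, deepened by eight two-convolution pre-activation volumetric
   residual blocks (the 18-layer residual layout), then a fully connected
   head — regresses the 3N organ-frame coordinates (N = 8/7/7/4/3/3).
   Composing the inverse organ and face transforms returns mm coordinates.

Taking the organ frame from the box (rather than from the bounding box of
the cropped points) makes the frame identical whether the crop came from a
ground-truth box during training or a predicted box at inference, up to the
box error itself.

### Losses

Detection: mean over the six organs of
`lambda1 * ||c - c_hat||^2 + lambda2 * ||h - h_hat||^2`
(c = center, h = half-extents; lambda1 + lambda2 = 1, default 0.5/0.5).
A variant replacing the size term with |h^2 - h_hat^2| summed per axis is
available (`size_term="diff_of_squares_abs"`); it is not the default because
a sign-indefinite difference of squares is not a distance.

Prediction: per organ, with squared per-landmark distances d_i^2,
`L = lambda1 * mean_i d_i^2 + lambda2 * max_i d_i^2` (default 0.5/0.5):
the mean term drives the average error down, the max term the worst
landmark.  For any lambda the combined loss lies between the mean and max
losses.

### Error metric

Reported errors are Euclidean distances in mm.  Since networks operate in
the normalized frame, a normalized-frame distance is converted by the
recorded scaling multiplier: `L = S * sqrt((x-x_hat)^2 + (y-y_hat)^2 +
(z-z_hat)^2)`.  Summaries report per-landmark mean ± sd across faces
(sample sd, ddof = 1), the overall mean ± sd over all face × landmark rows,
the fraction of the 32 landmarks whose per-landmark mean error is within
2.5 mm and 3.0 mm (coverage over landmark means is primary; row-level
coverage is also emitted), and per-organ Tukey box-plot statistics
(median, quartiles, 1.5·IQR whiskers).

## Synthetic data

Clinical facial scans with 32-landmark annotations are not publicly
distributable, so the package ships a parametric generator whose ground
truth is exact by construction.  A face is a height field z(x, y) over an
elliptical outline: a half-ellipsoid head (half-axes a, b, c ≈ 70, 90,
80 mm) plus Gaussian bumps — a vertically elongated nose ridge, two eye
bulges, a two-lobed mouth, a chin boss.  The 32 landmarks are images of
fixed parametric positions under the exact surface function (e.g.
pronasale at the ridge apex, cheilion at the mouth half-width, gonion on
the jaw line at a position set by the jaw angle), so they lie on the
surface to machine precision.  The cloud is sampled area-weighted uniformly
(rejection sampling on the metric area element), then warped by a smooth
lateral asymmetry factor, rotated by small pose angles, and perturbed by
isotropic Gaussian noise (default sd 0.3 mm, the order of
stereophotogrammetric system error).  Landmarks receive the warp and
rotation but not the noise.  Populations draw each parameter uniformly
from configurable ranges (defaults span mild adult variation, e.g. head
half-width 62–78 mm, pose ±5°, asymmetry ≤ 0.06) and split
train : test : val = 7 : 2 : 1 (floor-based, remainder to train).

Ground-truth organ boxes are derived from the landmarks: each organ's
normalized-frame landmark bounding box, inflated on every axis by 0.25 of
the box diagonal, with half-extents floored at 0.05.  Detection quality
metrics are therefore relative to this construction.

What the generator does *not* emulate: real craniofacial shape statistics,
skin texture, scanning occlusions and holes, or annotator variability.
Passing tests on synthetic faces demonstrate that the pipeline's geometry,
training and bookkeeping are correct and that the networks can learn the
mapping; they do not certify clinical accuracy.

## Numerical choices

- The networks run on a compact numpy/BLAS engine (im2col + matmul
  convolutions, float32 parameters and activations) with explicit
  reverse-mode gradients, validated layer-by-layer against central finite
  differences.  Optimization is Adam (lr 1e-3, beta 0.9/0.999), mini-batch
  size 12, shuffled each epoch from the run seed; everything is
  deterministic given the seed on one device.
- Voxel index mapping is `clamp(floor((c+1)/2 * M), 0, M-1)` — half-open
  binning with the c = +1 boundary assigned to the last cell.  The inverse
  (`voxel_center`) returns cell centers; round-tripping preserves indices.
- Normalization is isotropic (a single S): the mm error metric multiplies
  by one scalar, which requires one scale per model.
- Residual blocks are pre-activation (bn -> relu -> conv, twice, added to
  the input); the second convolution is initialized near zero so each block
  starts near identity.
- Degenerate inputs are rejected with specific errors: clouds with < 4
  points or non-finite values, all-identical clouds (S = 0), organ boxes
  containing no points (the empty-crop error names the organ so the caller
  can enlarge the margin), over-pooled network configurations.
- The statistical outlier filter (k-nearest-neighbor mean distance,
  mean + 2 sd threshold) stands in for manual occlusion cleaning; it never
  removes more than 20% of a cloud.

## Operating points

The reference configuration is M = 200 (grid accuracy 2S/M < 1 mm for
S ≈ 90 mm), 600 detection epochs and 500 prediction epochs.  The package's
desk-scale configuration — used by the test suite and the acceptance
script — is M = 32, ~6000 points per face, 80 faces (60 train / 20 test),
40 detection epochs, 25 prediction epochs per organ, channel widths
(8, 16, 32) for detection and (4, 8, 16) for prediction.  At this scale a
full experiment trains in a few CPU-minutes and typically reaches mean box
IoU ≈ 0.7 and end-to-end mean error of a few mm — far below the ~25 mm
box-center baseline but, by design of the scale, not a clinical-accuracy
claim.  At M = 32 voxel quantization alone contributes up to
2S/M ≈ 6 mm per axis, so desk-scale end-to-end error is dominated by grid
resolution, not by the learning machinery.

## Known limitations

- Training the M = 200 configuration is computationally heavy on CPU; the
  engine is single-device and unaccelerated by design.
- The residual stage is randomly initialized; no pretrained features are
  used anywhere.
- Whether prediction networks should train on ground-truth or predicted
  boxes is an open design point; the default is ground-truth boxes for
  training and predicted boxes at inference (the box-based organ frame
  keeps the two consistent).
- Detection is direct 36-value regression; there are no anchors, proposals
  or non-maximum suppression, and exactly one instance of each organ is
  assumed.
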