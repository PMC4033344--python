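# Methods

## Pipeline

The package implements a template-based gait recognizer in four stages:
silhouette preprocessing, motion-template construction, 2DPCA feature
extraction, and gallery/probe evaluation.

### Silhouette preprocessing

Raw grayscale frames are segmented by per-pixel Gaussian background
subtraction: the background model stores the element-wise mean and
standard deviation of a set of background frames, each incoming frame is
Gaussian-blurred (`blur_sigma`, default 1 px), and a pixel is foreground
when `|blurred − mean| > threshold_k · max(spread, spread_floor)`
(`threshold_k` default 2.5, `spread_floor` default 1 intensity unit; the
floor guards pixels whose background never varied). The largest
8-connected component is kept. Users with pre-segmented masks (the common
case for public gait datasets) bypass this stage entirely.

Each mask is then cropped to its bounding box, rescaled by bicubic
interpolation so the box height equals `target_height` (default 200 px on
a 240×320 canvas, matching common gait-video geometry) with aspect ratio
preserved, re-binarized at 0.5, and translated so its centroid sits on
the canvas center pixel. Aligning every frame to the canvas center makes
any two frames mutually aligned, which reduces frame differencing to a
per-pixel comparison. Placement rounds to the nearest pixel with ties
toward negative infinity — an arbitrary but fixed rule so outputs are
bit-reproducible across platforms. Coordinates are image-style: x =
column, y = row, 0-based, top-left origin.

### Templates

The differential image of adjacent frames is their per-pixel XOR; the
AGDI is the mean of the N−1 differential images and the GEI the mean of
the N silhouettes. Both are real-valued images in [0, 1] on the source
canvas. Templates are built over a caller-chosen frame window (whole
sequence by default) and record the window length in `n_frames_used`;
no gait-cycle detector is required, though an autocorrelation estimator
over the silhouette-width signal is provided as a convenience (note the
width signal peaks twice per gait cycle, so the estimator may return the
half period for symmetric gaits). Templates persist as 16-bit PNG
(value × 65535) with a JSON sidecar carrying kind and provenance; the
quantized values round-trip exactly.

### 2DPCA features

The image covariance over M training templates is
`C_t = Σ_i (G_i − Ḡ)ᵀ(G_i − Ḡ)`, computed as the unnormalized sum:
dividing by M rescales eigenvalues only, leaving eigenvectors,
projections and all distances unchanged, so the reported eigenvalues are
on the sum scale. Templates are projected raw (not mean-centered); the
centering term is common to every projection and cancels in distances.
The symmetric eigensolver (`numpy.linalg.eigh` on the symmetrized matrix)
supplies the spectrum; axes are ordered by descending eigenvalue and each
eigenvector's largest-magnitude component is made positive, a
sign convention that serializes deterministically and affects neither
distances nor reconstructions. Default `d = 20` components. The
projection basis serializes to a portable container — magic line, JSON
header with shapes, then flat little-endian float64 arrays — with a
bit-exact round-trip.

`VectorizedPCA` implements the classical baseline by eigendecomposing the
full `mn×mn` covariance of flattened templates. This is deliberately the
textbook construction (not an SVD or Gram-trick shortcut) because its
cost relative to the `n×n` image-covariance eigenproblem is part of what
the package measures; it refuses `d` beyond the covariance rank
(at most M−1).

### Recognition

Identification is nearest neighbour under
`d(Y, Y') = Σ_k ‖Y_k − Y'_k‖` with ties broken by gallery insertion
order; the full ranking yields the CMC. Verification z-norms the
similarities `Sim = −d` of a probe against the whole gallery (sample
standard deviation, divisor M−1; a probe whose similarities are all equal
is rejected as degenerate). Each probe contributes its same-subject score
as a genuine trial and all others as impostor trials — the standard
open-set verification reading. FAR(t) is the fraction of impostor scores
≥ t and FRR(t) the fraction of genuine scores < t over the union of
observed scores padded at both ends; the EER interpolates linearly
between the two thresholds bracketing FAR = FRR. Because z-norming is a
strictly increasing per-probe transform, it never changes the top-ranked
identity.

The `leave-one-out` protocol refits the projection basis per probe with
the same-subject gallery sequence excluded from basis training, while the
gallery still contains every subject at scoring time; `plain` fits one
basis on all gallery templates.

## Synthetic walker

The generator renders a stylized side-view walker: circle head, ellipse
torso, two-segment legs and arms as thick capped segments, joint angles
sinusoidal in `frame / cycle_length`. Left and right limbs move in
antiphase, arms oppose the legs, knees flex on the forward swing, and a
small vertical bob (proportional to stride amplitude) runs at twice the
stride frequency. Limbs attach slightly apart laterally — legs clear of
each other, arms at the torso edges — so the silhouette area varies
smoothly (< 10 % frame-to-frame at cycle lengths ≥ 20) instead of limbs
vanishing into the body at the stride crossing.

Subjects are drawn once per population from fixed uniform ranges: torso
height 0.28–0.36 and width 0.12–0.20 of figure height, head radius
0.055–0.085, leg length 0.44–0.52, arm length 0.30–0.40, stride
amplitude 14–40°, arm swing 8–34°, and cycle length 12–20 frames —
bracketing the ≈13 frames per cycle of 25 fps walking video. Sequences of
the same subject share all parameters and differ by a whole-frame shift
of the cycle plus fresh pixel noise: a walker with an integer frame
period only ever exhibits its `cycle_length` discrete poses, so two
recordings of the same subject sample the same pose set at a different
starting point. Frames are height-normalized and centroid-aligned on a
120×96 canvas (target height 100 px — small enough that a full
population renders in seconds), then salt-and-pepper noise flips each
pixel with probability 0.002 by default, a residual-segmentation-speckle
level. Under these defaults the mean between-subject AGDI distance
exceeds roughly four times the mean within-subject distance and
within-subject distance is smaller than between-subject distance in every
measured triplet, which is what the recognition tests rely on.

What the generator does *not* emulate: clothing and carrying conditions,
shadows, view-angle change, perspective, occlusion ordering, structured
segmentation artifacts, or speed variation within a sequence. Passing
tests on this data demonstrate the correctness and internal consistency
of the pipeline, not field performance on real video.

One consequence of the crisp procedural rendering: raw walker AGDIs
carry genuine high-rank structure (thin XOR bands along limb edges), so
their covariance spectrum decays more slowly than that of smooth
real-video templates — about 13 % of total scatter lies beyond the 20th
axis, versus well under 5 % for spatially smooth correlated templates.
Recognition is unaffected (the leading axes still dominate matching),
but spectral-decay properties are asserted on smooth correlated fields.

## Numerical choices

- Covariance matrices are explicitly symmetrized before `eigh`; PSD is
  enforced only to a 1e−9 relative tolerance in tests (eigenvalues may be
  tiny negatives in floating point).
- Orthonormality and unit-vector checks use 1e−6 absolute tolerance.
- Re-binarization threshold after bicubic rescale: 0.5.
- Distance ties in ranking use a stable sort, so insertion order wins.
- Degenerate inputs are errors, not silent results: empty masks, empty
  foregrounds, sequences shorter than 2 frames, non-unit candidate axes,
  zero-variance similarity vectors, and `d` beyond the available rank all
  raise with specific messages. A probe subject absent from the gallery
  is counted as a forced identification error and reported.

## Problem sizes

Test and reproduction runs use a 10-subject × 2-sequence × 40-frame
population on the 120×96 canvas with d = 20, ten seeded replicates for
the probe-length comparison, 10 000 scores per class for EER calibration,
and 96×72 templates for the 2DPCA-versus-PCA cost measurement — sizes at
which every experiment reruns from scratch in a few minutes on one core
while exercising the same code paths as full-scale data.

## Known limitations

- The cycle-length estimator assumes a roughly symmetric gait and may
  return half the true period.
- `VectorizedPCA` materializes the `mn×mn` covariance; it is a baseline
  for comparison, not a practical extractor at video resolution (that
  asymmetry is the point of 2DPCA).
- The leave-one-out protocol refits a basis per probe and scales
  accordingly.
- View angle is metadata only; no cross-view matching model is included.
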