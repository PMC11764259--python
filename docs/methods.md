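# Methods

## Problem and model

`cyclereg` performs unsupervised deformable registration between pairs of
brain images.  The target geometry is the common two-grid acquisition:
a structural volume (high resolution) and a functional BOLD series on a
grid three times coarser.  Registration is driven by the structural
images; the estimated structural deformation, downsampled to the
functional grid, transports the functional series.

Two networks are trained jointly on each pair (A, B):

* G_A(A, B) → φ_AB, the forward displacement field, and
* G_B(B, A) → φ_BA, the reverse field.

A field is a dense per-voxel displacement u in voxel units;
φ(p) = p + u(p).  Warping is differentiable trilinear resampling
(a spatial-transformer module); sampling positions outside the volume
are clamped to the border.  Label maps are warped with nearest-neighbour
sampling.

The training objective combines four groups:

    L = L_mri + α·L_fmri + β·L_cycle + γ·L_identity

* **L_mri** — MSE(B, A∘φ_AB) + λ·‖∇u_AB‖² plus the mirrored direction.
  All spatial sums are means over the voxel domain so the weights are
  resolution independent.
* **L_fmri** — 4D MSE on the functional grid through the 1/3-downsampled
  fields, plus the local functional connectivity (LFC) distance described
  below; both directions.
* **L_cycle** — after the first pass produces B′ = T(A, φ_AB) and
  A′ = T(B, φ_BA), the deformed images re-enter the networks against the
  opposite original: φ′_BA = G_B(B′, A), φ′_AB = G_A(A′, B).  The cycle
  term is the mean L1 error of T(B′, φ′_BA) vs A and T(A′, φ′_AB) vs B.
  (The second-pass fixed image is chosen as the image the chain must
  return to — the pairing under which cycle consistency is well posed.)
* **L_identity** — each network also sees an identical pair and is
  penalised (MSE) for warping it: G_A(B, B) and G_B(A, A) in the default
  "crossed" pairing; a "matched" pairing (G_A(A, A) / G_B(B, B)) is
  selectable by flag.

Default weights: α = 0.2, β = 0.1, γ = 0.5, λ = 0.02; Adam, learning
rate 1e-4, batch size 1, 500 iterations maximum.  Both networks are
updated by one joint optimizer step per pair (no alternation).  Two
optimisation safeguards are on by default: global gradient-norm
clipping (1.0) and a warmup + cosine learning-rate schedule (linear
warmup over the first 10% of iterations, cosine decay to 10% of the
base rate), the conventional recipe for window-attention encoders; both
can be disabled in the configuration.

**Intensity standardisation.**  The published loss weights — in
particular the smoothness weight λ — presume intensity-normalised MRI of
roughly unit contrast.  The pipeline therefore standardises each volume
(and each functional series) to zero mean and unit variance before it
enters the networks and losses; warped outputs are always resampled from
the original intensities.  Disable with `standardize: false`.  Without
this step, low-contrast inputs make the regulariser dominate the data
term and the optimisation stalls.

## Local functional connectivity features

The time course at voxel p is I(p).  For each voxel, the Pearson
correlations C(p, q) with all voxels q of its cubic neighbourhood
(half-width `lfc_radius`, default 1 → 26 neighbours, centre excluded)
form its LFC pattern.  The raw set depends on an arbitrary neighbour
enumeration, so it is summarised as a probability density: a Gaussian
kernel density estimate evaluated at `kde_points` (default 64) sample
points spread uniformly over [−1, 1],

    f_n = (1/N) Σ_q (2πh²)^{−1/2} exp(−(n − C(p,q))²/(2h²)),

with N the actual (border-clipped) neighbour count and bandwidth
h = 0.1 by default.  The KDE is exactly invariant to neighbour order.
Zero-variance time courses get C = 0 so background stays finite.  The
LFC loss is the mean Euclidean distance between the feature vectors of
the warped and the fixed series over voxels with nonzero temporal
variance in the fixed series; features of the warped series are
recomputed after warping, not warped as maps.

## Registration network

A U-Net-like network on the 2-channel stack of (moving, fixed):

* patch embedding: 2×2×2 space-to-depth + linear projection to
  `embed_dim` channels (default 24; the "tiny" preset uses 6);
* four encoder stages of window-attention block pairs with depths
  {2, 2, 4, 2}: each pair is LN → W-MSA → residual → LN → MLP → residual,
  then the same with the shifted-window SW-MSA — the two variants
  strictly alternate;
* window size {6, 6, 6}; attention is
  softmax(QKᵀ/√d + B)V per head with a learnable relative-position bias
  table of (2M_x−1)(2M_y−1)(2M_z−1) entries per head (heads per stage
  2, 4, 8, 8; head dim = stage dim / heads).  The shifted variant
  displaces the partition by ⌊M/2⌋ per axis, implemented as a cyclic
  shift plus an additive attention mask separating pre-shift regions;
  `count_shifted_windows` reproduces the region count independently of
  that trick.  On feature maps smaller than the window, the window is
  clamped to the grid and the bias table is sub-gathered, so parameters
  are shared across scales;
* patch merging between stages: 8-neighbour concatenation + linear
  projection (2× downsampling, channel doubling); odd extents replicate
  their border slice;
* a convolutional decoder: per level, trilinear resize to the skip
  resolution, channel concatenation with the skip, 3×3×3 convolution
  (edge-padded, leaky ReLU); finally resize to full resolution and a
  fusion convolution (≥16 channels) with the raw 2-channel input;
* a multi-scale field head: a 1×1×1 coarse head at the patch-embedding
  resolution captures the smooth bulk of the deformation (its output is
  upsampled and rescaled to fine-voxel units) and a full-resolution
  1×1×1 head refines it.  Both heads are initialised at sd 1e-5 so the
  untrained network emits a near-identity deformation.  The summed field
  is bounded by u = c·tanh(u/c) with c a quarter of the smallest grid
  extent: displacements beyond a fraction of the field of view are
  meaningless, and an unbounded head can park the sampler in the clamped
  border region where image gradients vanish and optimisation cannot
  recover.

Edge padding (convolutions) and border replication (merging) keep a
spatially constant input mapped to a spatially constant field — a cheap
sanity invariant that zero padding would break.

All tensor mathematics, including the attention blocks, warping and the
loss terms, runs on a small reverse-mode automatic-differentiation
engine over numpy arrays (`cyclereg._autodiff`); gradients of every
primitive are unit-tested against central finite differences, and the
trilinear warp is additionally tested against
`scipy.ndimage.map_coordinates` and a brute-force 8-corner oracle.

## Synthetic data

The generator emulates affinely pre-aligned pairs with known truth:

* anatomy: nested ellipsoidal shells (default 4 structures on a 24³
  grid), one label per shell, per-structure intensity levels in
  [0.3, 0.9], lightly blurred; plus smooth intratissue texture
  (Gaussian-filtered noise, sd 0.12, correlation length 2 voxels) so the
  deformation is observable everywhere inside the head — real structural
  MRI is not piecewise constant; plus white observation noise (sd 0.02);
  intensities clipped to [0, 1];
* ground-truth field: per-component Gaussian-smoothed white noise
  (smoothing length 4 voxels), rescaled to a peak magnitude of 2 voxels
  by default.  Peak amplitudes at or below half the smoothing length
  yield fold-free fields (checked exhaustively at 24³);
* the moving member is the fixed member warped by the truth field
  (trilinear; labels nearest-neighbour), so the true forward field for
  (A = fixed, B = moving) is known exactly;
* functional series: per-structure latent time courses (unit sd) plus
  voxel noise with sd 1/snr (default snr 2, T = 40); background voxels
  are pure noise.  The functional grid is the structural grid
  downsampled 3× (block centres); a "toy" equal-resolution mode
  (factor 1) exists for unit tests.

What the generator does **not** emulate: real brain anatomy, bias
fields, hemodynamics, scanner noise spectra, or inter-subject anatomical
variability (the pair differs by a known smooth warp, not by anatomy).
Passing the desk-scale tests therefore demonstrates that the estimator
recovers known smooth deformations from textured images — not
performance on clinical data.

## Desk-scale evaluation protocol

The headline published results for this family of methods come from
hundreds of subjects at 192³/64³ resolution with GPU training; the
package's own experiments are scaled to a single CPU:

* one 24³ pair (tiny preset, functional path off), truth amplitude 2
  voxels, 300 Adam iterations at base learning rate 5e-3 with the
  default warmup/cosine schedule (the config default 1e-4 is calibrated
  for full-size volumes and long schedules; small single-pair problems
  support a larger step).
* reported: mean endpoint error ‖u_est − u_truth‖ over the head
  foreground (labels > 0, where the deformation is observable — the
  same non-background convention the folding metric uses) relative to
  the zero-field baseline; mean label Dice before vs after; and the
  percentage of non-positive Jacobian determinants of the trained field.

Evaluation statistics: Dice is 2|A∩B|/(|A|+|B|) per structure
(structures absent from both maps are excluded as undefined); folding
is the percentage of voxels with det(I + ∇u) ≤ 0, with ∇u by central
differences (one-sided at borders); group functional consistency uses
voxelwise one-sample t-maps (n−1 sd; zero-sd voxels flagged undefined),
summarised by the peak t and the count of voxels strictly above
t = 5.01.  The benchmark tables in `cyclereg.evaluation` carry published
peak-t and suprathreshold-count values for six registration approaches
on four canonical resting-state networks; `mean_relative_improvement`
and `mean_count` reproduce the summary statistics usually quoted from
them.

## Numerical choices and edge cases

* Displacements are stored in voxel units of their own grid; field
  downsampling samples coarse-voxel block centres
  (fine coord = 3c + 1 for factor 3) and divides by the factor so
  physical millimetres are conserved.
* Out-of-bounds sampling clamps to the border rather than zero-filling,
  avoiding dark halos that destabilise MSE.
* Pearson correlation of a zero-variance series is defined as 0.
* The KDE normaliser counts actual in-bounds neighbours.
* Softmax subtracts the row maximum; LayerNorm uses ε = 1e-5; the LFC
  distance adds 1e-12 inside the square root to keep its gradient finite
  at exact feature equality.
* One-sample t-maps report NaN (not ±inf) where the sd is zero.
* All randomness flows from explicit seeds; training twice with the same
  seed and data gives bitwise-identical loss sequences.

## Known limitations

* No diffeomorphic parameterisation (no scaling-and-squaring, no
  inverse-consistency by construction); fold-freeness is encouraged by
  the smoothness, cycle and identity terms, not guaranteed.
* The numpy autodiff engine is single-threaded; full-size (192³) volumes
  are out of reach on CPU, which is why the package's own experiments are
  desk-scale.
* Group-ICA extraction of functional networks is out of scope; the
  t-map statistics consume user-supplied per-subject component maps.
* The t = 5.01 significance threshold is treated as a given constant,
  not derived from a null model.
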