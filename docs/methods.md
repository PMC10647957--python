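# Methods

## Registration model

The package registers a moving image *M* onto a fixed image *F* with a
2D affine transform T<sub>μ</sub>, μ ∈ ℝ⁶, predicted either by a
localization CNN in one shot or by direct per-pair optimization. The
training signal is purely image-driven: the negated mutual information
of the fixed and warped intensities, optionally plus a field-space
regularizer. No ground-truth transforms, landmarks, or segmentations
enter training; landmarks and masks are used only for evaluation.

Coordinates are 0-based, pixel-centered, ordered (row, col). The linear
part of every affine acts about the geometric image center, so rotations
and scalings do not translate content off-frame; translations are in
pixels. Displacement fields are arrays of shape (H, W, 2), components
ordered (row, col), and are produced from μ by the affine-to-field layer
φ<sub>μ</sub>(x) = A(x − c) + c + t − x. The resampler *pulls*:
warped(x) = M(x + φ(x)), with bilinear interpolation and a constant fill
(default: the moving image's minimum, i.e. background) outside the
frame. Landmark mapping uses the same convention: the recovered affine
forward-maps fixed-space points into moving space, where they are
compared with the annotated moving points; TRE aggregates per-landmark
Euclidean distances by their mean. Physical units enter exactly once:
transforms act in pixels, metrics are reported in mm via the image
spacing.

Dimensionality is 2D throughout. The reference parameter totals
(49,894 / 44,982) are arithmetically consistent only with 2D 3×3
convolutions and a 6-parameter affine, so the 2D slice-based mode is the
one implemented and tested.

## Differentiable mutual information

MI = Σ p(f,m) log₂[p(f,m)/(p(f)p(m))] is estimated from a joint
histogram (64 bins by default) made differentiable by triangular
(linear B-spline) Parzen kernels: each pixel's intensity, mapped to bin
units over an epsilon-widened per-image min/max range, spreads its unit
mass over the bins within the kernel half-width (``bandwidth``, default
1 bin). Per-pixel weights are normalized to sum to one, with a
nearest-bin fallback for pixels outside every kernel's support (possible
only for bandwidth < 1). Consequences that the tests rely on:

* at bandwidth 1 the kernels already form a partition of unity, so the
  normalization is inert on the default path;
* as the bandwidth shrinks the assignment becomes one-hot and the table
  converges to the hard nearest-bin-center histogram — in particular,
  at bandwidth ≤ 0.5 MI(F, F) = H(F) holds exactly for any image;
* a constant image maps onto bin 0 with probability 1 rather than
  splitting between the two middle bins.

Logs are base 2 (MI in bits), configurable. The loss is plain −MI as
the objective formula states; a normalized-MI variant
(2·MI/(H(F)+H(M))) sits behind a flag since the narrative text mentions
both and prints a formula only for the plain form. Bin ranges are
recomputed each forward pass from the current warped image because the
emulated acquisition setting (heterogeneous scanners) makes fixed global
ranges fragile; the range computation is treated as non-differentiable
(standard for Parzen MI).

Intensity normalization is (x − mean)/std. Training pools the statistics
per modality over the whole corpus (the "all pixel intensities" reading);
inference on a lone pair uses per-image statistics, which is the only
option when no corpus exists.

## Localization network

Five stride-2 "same"-padded 3×3 convolutions (filters [32]×5 proposed,
[16, 32, 32, 32, 32] baseline), Leaky-ReLU slope 0.2, He-normal
initialization, no pooling, no dropout; flatten; one dense layer to 6
outputs. "Same" striding maps 256 → 128 → 64 → 32 → 16 → 8, giving the
2048-long flatten and the printed parameter totals exactly; the kernel
size 3 is adopted as normative because it is the unique standard choice
reproducing those totals. The trailing "6" of the reference architecture
list is the dense output layer, not a sixth convolution — required for
the totals to match.

The dense head predicts a residual from the identity and its weights and
bias are zero-initialized, so an untrained network implements exactly
the identity warp and the initial loss equals −MI(F, M). This is the
standard spatial-transformer stabilization; a He-normal output layer
would start from a random large transform from which an MI signal rarely
recovers. He-normal is kept everywhere else.

Training uses Adam (lr 10⁻⁴ default, 500 epochs default, batch 4 —
batch size is not printed anywhere and 4 is a conventional full-image
choice), full images (no patches), no augmentation. One integer seed
controls weight initialization, data order, and synthetic generation.
No early stopping; the per-epoch history (train/val loss, wall-clock) is
recorded so users can add their own.

### Compute engine

No deep-learning framework is used: `mireg.autodiff` is a small
reverse-mode automatic-differentiation engine over numpy arrays
(elementwise ops, matmul, reductions, slicing, the strided convolution,
and the bilinear grid sampler). Every backward rule is verified against
central finite differences in the test suite, and the end-to-end
warp-gradient check (analytic vs numeric, relative error < 10⁻³) runs as
an acceptance test.

## Regularization

Two field regularizers are implemented: mean squared displacement
("l2") and bending energy ("bending": mean of d²ᵣᵣ + 2d²ᵣ𝒸 + d²𝒸𝒸 of the
second finite differences, summed over components). The reference
description never names its regularizer term; bending energy is the
default here (λ = 0.01) because its null space is exactly the affine
family — it cannot bias any legitimate affine, only pathologies of the
decoding path — which makes the open question harmless. Fields are in
pixel units; the null-space property that motivates the choice is
unit-invariant, and pixel units keep λ's scale interpretation identical
between both regularizer kinds. The l2 option exists for experiments
that do want to shrink transforms toward the identity (e.g. the
regularizer-dominance test).

## Direct single-pair optimization

`optimize_single_pair` maximizes MI over μ without any network; it is
both a practical registration path and the independent check on the
loss/transform stack. The schedule is deterministic: a coarse sweep at
half resolution (translation grid ±12 px step 2, then a joint
rotation ±18° step 2° × per-axis scale {0.92, 1.0, 1.08} grid, then a
±2 px fine translation grid), followed by three Adam stages on
Gaussian-smoothed images (σ 1.5 at half resolution, σ 0.5 and σ 0 at
full resolution) with decaying step sizes. The joint rotation-scale
sweep exists because the two couple strongly through the elliptical
skull outline: sweeping rotation alone can lock onto a wrong angle with
a compensating shear. The residual is optimized in a scaled
parametrization (linear entries scaled by 0.02 relative to translations)
so that Adam's per-parameter step sizes are commensurate. Bending energy
is identically zero on this path (the field is affine by construction)
and is skipped.

## Synthetic phantom generator

The generator stands in for the private clinical dataset the method was
developed for (slice pairs, with and without tumor, annotated with 12
landmarks and whole-brain/tumor segmentations). One label raster —
skull ring (ellipse, semi-axes 0.42/0.36 of the frame), brain interior,
two ventricles, a falx midline segment, an optional tumor ellipse — is
rendered through two label→intensity maps whose orderings disagree
(skull brightest in the CT-like map, near-darkest in the MR-like map;
soft tissue the reverse), plus Gaussian smoothing (σ 1 px) and additive
noise (σ 0.02, ~2% of the intensity range, a mild scanner-noise level).
Because the orderings disagree, the cross-modality intensity relation is
non-monotone and a pixelwise linear fit leaves >20% of the variance
unexplained: correlation-type losses fail and MI is the informative
similarity, which is the premise of the whole method.

Two departures from a strictly piecewise-constant ellipse phantom are
deliberate defaults:

* a low-amplitude (15%) deterministic sinusoidal "gyral" modulation of
  the intra-brain intensity, rendered identically by both modalities
  (it is anatomy, not noise);
* a 15% left/right ventricle size asymmetry.

Both emulate properties real slices have (interior structure;
no exact mirror symmetry) and both are needed for the misalignment's
linear part to be identifiable at all: on featureless ellipses, rotation
is nearly degenerate with shear, and a registration benchmark on such a
phantom would test luck rather than the method.

The moving image is the MR-like rendering resampled through the
*inverse* of the drawn affine, so the drawn parameters are exactly what
registration should recover and the moving-space landmarks are the
forward-mapped fixed-space ones (exact, no interpolation involved).
Landmarks follow the radiologist schema geometrically: skull extremes
(up/dp/lp/rp), falx centroid (midd), image center (cntr), inner-skull
extremes (B0/B4/B9), tumor extremes (tmr1–tmr4) and tumor centroid
(ctmr — the "1 mm circle at the tumor center" reduced to its center
point, since a point metric needs a point). Misalignment draws default
to |t| ≤ 10 px per axis, rotation ≤ 15°, per-axis scale 0.9–1.1, shear
≤ 0.05. Corpora are pure functions of one master seed; the
train/val/test split mirrors a 60/20/30-of-110 cohort split via
floor-plus-remainder fractions 6/11, 2/11, 3/11.

What the phantom does **not** emulate: real anatomical variability,
MR field distortion, CT beam hardening, multi-scanner intensity
heterogeneity beyond per-modality noise, or non-affine (deformable)
misalignment. Passing benchmarks on it therefore demonstrate that the
loss, transform model, optimizer and metrics are correct and that the
affine recovery problem the generator poses is solved to sub-pixel
accuracy — not that clinical-grade accuracy on patient data is matched.

## Evaluation metrics

TRE: per-landmark Euclidean distance in mm between corresponding points,
mean over shared names; reported per-landmark, per-pair, and as cohort
mean ± std by tumor/healthy stratum. Dice 2|A∩B|/(|A|+|B|) and Jaccard
|A∩B|/|A∪B| on binary masks (two empty masks score 1, with a warning —
reachable on tumor-free strata). Hausdorff is the symmetric max-min
distance between 8-connected mask boundaries, scaled by spacing, via
`scipy.spatial.distance.directed_hausdorff`. The identity
J = D/(2 − D) and an O(n²) brute-force Hausdorff oracle serve as
cross-checks in the tests.

## Benchmark problem sizes

The recovery benchmarks use 20 pairs at 128×128 (the generator also
supports 256×256 to mirror the reference input size); network training
for the benchmark runs on 2× downsampled (64×64) pairs with a reduced
filter stack (8, 16, 16, 16, 16), 32 MI bins, Adam lr 3·10⁻⁴, 500
epochs, batch 4 — sizes chosen so a complete run is CPU-minutes while
leaving the method, loss and parameter conventions identical to the
full-size configuration. Affine parameters transfer across resolution:
the linear part is scale-free and translations are converted through the
grid spacing at the metric boundary.

## Known limitations

* 2D affine only; no 3D mode, no deformable refinement, no
  inverse-consistency machinery.
* The MI estimator's bin ranges are per-image; pairs whose intensity
  supports change drastically under warping (large fill fractions) can
  shift bin edges between iterations.
* The numpy engine is single-threaded BLAS-bound; it is sized for
  128–256 px slices, not volumes.
* `optimize_single_pair`'s capture range is set by its sweep bounds
  (±12 px, ±18°); misalignments far outside the generator's draw ranges
  need wider sweeps.
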