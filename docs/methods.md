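# Methods

## Problem and scope

High-yield brassica crops are phenotyped by counting siliques (seed
pods) on 3-D reconstructions of single plants. The package implements
the two halves of that workflow on point clouds carried as `P x 6`
arrays (XYZ + RGB):

1. **Semantic segmentation** of each point into stem vs. silique with a
   PointNet++-style encoder/decoder whose per-group feature extractor is
   rebuilt around Kolmogorov-Arnold (KAN) convolutions, a global-local
   feature-modulation block (GLFN), and ContraNorm.
2. **Instance counting** of the silique-class points by statistical
   outlier removal (SOR) followed by DBSCAN, with a grid search for the
   clustering parameters.

Everything is exercised end-to-end on synthetic plants; no real scans
ship with the package.

## Segmentation model

**KAN convolutions.** A KAN convolution replaces every scalar kernel
weight with a learnable univariate edge function

    phi(x) = w_b * SiLU(x) + w_s * spline(x),

and an output pixel is the sum of phi_{a,b,d} over input channels d and
kernel offsets (a, b). The spline term is a linear combination of
Gaussian radial basis bumps `exp(-(x-c_g)^2 / 2 sigma^2)` on a fixed
grid (8 centers uniform on [-2, 2], sigma equal to the grid spacing) --
the FastKAN construction, which avoids B-spline grid refitting. The
`vanilla` and `fastkan` variants share this basis behind a common
interface; their learnable-parameter counts are identical at equal grid
size, which is the property that matters for the parameter-cost
comparisons. The grid range is chosen to cover activations arriving from
the preceding normalization layers; no extra input standardization is
applied.

**Reverse-bottleneck KAN convolution.** The parameter cost of a dense
KAN convolution is `c_out * c_in * k^2 * (G + 1)`. The
reverse-bottleneck variant removes the dense k x k spline: a 1x1
convolution expands to `e * c_in` channels (default e = 2), each
expanded channel gets its own edge function (a base weight on SiLU plus
G RBF coefficients), and a second 1x1 convolution projects to `c_out`.
The SiLU base term keeps its spatial extent as a standard k x k
convolution applied to SiLU(x) -- algebraically this *is* the summed
`w_b * b(.)` base term of the edge-function convolution, with the conv
weights playing the per-edge base weights, which is why the base branch
is implemented as conv(SiLU(x)) rather than SiLU(conv(x)). Costs drop to
`e*c_in*(c_in + c_out + G + 2) + c_in*c_out*k^2 + c_out`; at
c_in = c_out = 64, k = 3, G = 8 that is 54.6k vs. 331.8k scalars.

**GLFN.** The feature map is split channel-wise into halves. The global
branch scores each spatial position with a 1x1 projection, softmaxes
over positions, takes the weighted channel sum as a permutation-
invariant context vector, maps it through a two-layer MLP (ReLU + layer
norm) and adds it back. The local branch computes a sigmoid gate from a
cascade of 1x1 convolutions around a 3x3 depthwise convolution (with a
4x channel bottleneck, an order the source architecture leaves open) and
outputs `gate * F + F`. Halves are concatenated and fused 1x1, then a
partial-convolution feed-forward (PCFN) normalizes, expands 2x with
GELU, applies a 3x3 convolution to half of the hidden channels, and
projects back with a residual connection (included by transformer-FFN
convention; flag-controlled). All three residual branches are
initialized as identities (zero-init output projections, near-closed
gate): without this the modulation blocks dominate early training and
the full model converges more slowly than its own ablations at
desk-scale step counts.

**ContraNorm.** After each SA- and FP-level output, features are
normalized by `H_t = LN(H_b - (s/tau) softmax(H_b H_b^T) H_b)` with
defaults s = 0.1, tau = 1.0, applied per sample across the sampled
points (where N is already reduced, keeping the O(N^2) similarity
affordable); similarities use raw, not L2-normalized, features. With
s = 0 this is plain layer normalization. In the baseline model the same
position holds batch normalization; inner convolutions keep batch norm
in both. ContraNorm's only weights are the LN affine, so swapping it in
leaves the parameter count unchanged.

**Assembly.** SA levels use farthest-point sampling (deterministic,
start index 0) and ball-query grouping with neighbors sorted by
ascending distance, deficits filled by repeating the nearest neighbor.
Grouped features are relative XYZ + the point features (RGB + XYZ at the
input level). The per-group network applies the configured convolution
variant at each layer -- the full model uses the reverse-bottleneck KAN
convolution at layer 1 only, with kernel 3 x 3 over the K x N grouped
grid under 'same' padding. Because a 3 x 3 kernel mixes adjacent
neighbor columns (and adjacent sampled points), exact
neighbor-permutation invariance is deliberately traded away; the
distance-sorted neighbor axis makes the kernel well-defined, and with
kernel size 1 the blocks are permutation-invariant as in the original
design. GLFN runs on the K x N grid before max-pooling over K. FP levels
interpolate with inverse-distance 3-NN weights (coincident queries copy
exactly) and concatenate skip features.

Exact layer widths of the originally reported models are not public, so
printed parameter totals are treated as *ordering* constraints (the
package asserts baseline < +GLFN < +GLFN+RB-KAN, and reverse-bottleneck
< fastkan = vanilla at equal dims), not as numerical targets. Two sizes
are built in: a `tiny` preset (2 SA levels, npoints 256/64, K = 16,
widths 16..64, 1024 input points) used by every desk-scale experiment,
and a 4-level reference layout (npoints 1024/256/64/16, K = 32, widths
32..512, 4096 points) matching common semantic-segmentation practice.

## Training protocol

AdamW (weight decay 0.01), per-point cross-entropy (class weighting
available, off by default), cosine learning-rate annealing stepped per
epoch, per-cloud random subsampling to a fixed point budget each epoch,
best checkpoint by validation mIoU. The full-scale protocol is 250
epochs, batch 16, 4096 points, lr 1e-4 -> 1e-5. The desk-scale `tiny`
protocol keeps the optimizer and schedule shape but uses 20 epochs,
batch 4, 1024 points and lr 3e-3 -> 3e-4: it takes two orders of
magnitude fewer optimizer steps, so the learning rate scales up
accordingly. Problem sizes in the shipped experiments (30 plants of
~4.5k points, 21/3/6 split) were chosen so a full two-model comparison
runs in minutes on one CPU core.

The network, its layers and the optimizer run on a small reverse-mode
autodiff core written for this package (`kanglnet.autodiff`): a
numpy-backed tape with broadcast arithmetic, matmul, gather, reductions,
activations and a stride-1 grouped 2-D convolution implemented as a sum
of batched matmuls over kernel offsets. Every layer is gradient-checked
against central finite differences in the test suite.

## Counting workflow

Silique-class points -> SOR (k = 16, std_ratio = 2.0; a point is dropped
when its mean distance to its k nearest neighbors exceeds the population
mean by 2 standard deviations) -> DBSCAN (eps = 0.10, min_samples = 5,
scikit-learn implementation held to a brute-force density-reachability
oracle in the tests) -> the number of clusters, noise excluded. eps is
interpreted in the coordinate frame of the preprocessed (not
unit-normalized) cloud; a `--normalize` flag documents the alternative.
SOR defaults were chosen as common point-cloud-library values since only
the filter itself is specified upstream. The grid search evaluates mean
absolute count error over eps in [0.05, 0.20] x min_samples in [1, 15],
breaking ties toward larger min_samples (more noise suppression) and
then smaller eps (better separation); SOR does not depend on the grid,
so it runs once per cloud.

## Synthetic plants: what they emulate and how they are calibrated

The generator produces a branching stem skeleton (noisy vertical main
stem, arcing branches scaled with the silique count) carrying tapered
prolate capsules on short pedicels, colored green (stem) and
yellow-brown (silique) with per-plant illumination shift, per-point
noise (sigma 0.08) and 8% palette bleed emulating reconstruction color
noise at organ boundaries. Plants land in the 20k-30k point working
regime with counts spanning 50-300.

The geometry is parametric, not botanically simulated, and is calibrated
once to the observable statistics the downstream methods depend on:

- **Separability:** non-twin capsule pairs keep a surface gap of at
  least `0.30 - 0.40 * overlap_level` (0.14 at the default crowding of
  0.4), so the default clustering radius resolves neighbors.
- **Merge sensitivity:** a quarter of capsules are "twin" pods placed at
  gaps of 0.135-0.175, which merge once eps grows past ~0.13.
- **Fragmentation sensitivity:** per-capsule surface density is drawn
  log-uniformly from 900-1300 points/unit^2 and each capsule has a
  sparser waist at mid-length (the replum constriction), so eps below
  ~0.08 fragments the sparser capsules.
- **Neighbor-threshold sensitivity:** ~5% of capsules are immature pods
  carrying exactly 8 points; an isolated n-point blob survives DBSCAN
  iff min_samples <= n, so the pods pin the largest usable threshold.
- **Noise:** a fraction (default 1%) of points are silique-labeled
  outliers in four flavors -- 5-8 point mislabeled clumps hovering off
  the lower main stem (the false clusters that break counting without
  SOR), sparse bounding-box strays, 2-4 point floater specks, and
  two-point "ghost pairs" just beyond clustering range of a capsule
  surface, which survive SOR but cluster only at min_samples <= 2. All
  noise components except the ghost pairs are rejection-sampled to stay
  clear of the plant surface: they model sparse acquisition and
  segmentation residue, which is exactly what makes them statistically
  removable.

The segmentation training set uses a separate regime (fewer but larger,
well-sampled capsules, ~60/40 silique/stem point split, no noise) so
each organ stays recognizable after subsampling to ~1k points.

What passing tests on these plants do **not** show: robustness to real
reconstruction artifacts (non-Gaussian floaters, pose drift, holes),
real color statistics, occlusion from dense field growth, or
annotation noise in human labels. The synthetic experiments demonstrate
that the implementations are correct and that the methods behave in the
qualitatively expected way (model ordering, SOR necessity, parameter
basin), not that the quantitative accuracies transfer to field data.

## Numerical choices and degenerate inputs

- All randomness flows from explicit seeds; no global RNG state. Same
  seed, same platform -> bit-identical plants, forward passes and
  training runs.
- Layer norm / batch norm epsilon 1e-5; softmaxes are max-shifted.
- Ball query with an empty ball degenerates to the nearest point (the
  center itself when the center is a cloud point). FP interpolation
  copies features exactly at coincident points.
- Empty silique sets count as zero instances, not an error; a
  normalization of identical points sets scale 1 instead of dividing by
  zero.
- Cluster ids are renumbered by first occurrence so results are
  independent of library label order; counts are invariant to point
  permutation.
- Uniform downsampling keeps every s-th point, s = ceil(N / target_max),
  preserving order.
- Dropout augmentation removes floor(f * N) points with f drawn
  uniformly in [0, dropout_max]; "10-fold augmentation" produces ten
  augmented copies replacing each original, and splitting always happens
  before augmentation. Augmentation of validation/test sets is off by
  default (flag available).

## Known limitations

- CPU-only; the tiny preset trains in minutes, the reference preset is
  hours-scale and untested at full 250-epoch length.
- The 3 x 3 kernel over the grouped grid couples adjacent sampled
  points, an acknowledged departure from strict set-function semantics.
- ContraNorm is O(N^2) in the number of sampled points per level.
- The synthetic calibration targets the default SOR/DBSCAN parameters;
  plants generated far outside the shipped ranges (e.g. very low
  capsule density) are not guaranteed to satisfy the separability
  invariants.
- PLY support covers ascii and binary-little-endian vertex clouds only.
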