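# Methods

This note documents the models and procedures implemented in `fluoro4d`, the
choices made where the design was genuinely open, and what the bundled
synthetic phantom does and does not establish about behaviour on real data.

## Problem setting

Live multi-channel fluorescence microscopy of developing tissue yields 5D
datasets (X, Y, Z, T, channel), but hardware and fluorophore constraints cap
the number of proteins that can be imaged at once. `fluoro4d` implements
cross-channel protein localization prediction: a conditional GAN learns the
joint structure of two protein channels from dual-channel recordings, then
predicts the second channel from the first in recordings where only one was
imaged. Because localization correlates with activation state, an accurate
predictor also supports *in-silico* perturbations: edit the input channel
(erase, boost, freeze, redraw) and read the predicted channel's response.

## The 4D-reslicing generator

A 4D single-channel block can be viewed two ways: as a time series of
z-stacks (XYZ-T view) or as a z-series of 2D+time movies (XYT-Z view).
"Reslicing" between views is a pure index permutation — `fluoro4d.reslicing`
implements all view changes as exact, invertible permutations with mandatory
view tags checked at every boundary, because the two views are
shape-compatible for many block sizes and a silent axis swap is the method's
biggest implementation hazard.

The generator encodes the input block twice:

* the **XYZ path** applies a 3D convolutional encoder to the z-stack of each
  time point;
* the **XYT path** applies a second, independently parameterized encoder to
  the 2D+time movie of each z-slice.

Per-frame encodings are assembled into 5D feature stacks; the XYT-path stack
is resliced into XYZ-T view, after which the two stacks agree
voxel-for-voxel in space and time; and a shared decoder consumes the
concatenated feature pair of each time point, reconstructing the output
z-stack by z-stack. Encoders downsample X and Y only (factor 2 per level,
`depth` levels); Z and T are convolved with stride 1 and same padding. This
is the one simple scheme under which the resliced stacks match exactly, and
it makes the network fully convolutional in Z and T: the parameter count
depends only on `base_channels` and `depth`, never on the block size.

Layer choices follow the Pix2Pix family: 3x3x3 kernels, instance
normalization, leaky rectifiers (slope 0.2), nearest-neighbour upsampling +
convolution in the decoder, U-Net skip connections from the XYZ encoder,
tanh output. Weights are initialized with a fan-in-scaled truncated normal
(sigma = 1.4/sqrt(fan_in), truncated at 2 sigma, seeded) rather than the
fixed sigma 0.02 of the 2D tradition: with a fixed tiny sigma the
un-normalized stem and skip paths start an order of magnitude under-scaled
relative to the normalized trunk, and the L1 objective's sign gradients make
Adam spend hundreds of steps just growing the weights (measured: fan-in
scaling cuts the steps to halve cross-channel validation L1 from ~40 to
~10 on the phantom task). Two
deliberate deviations from a uniform stack: the encoder stem and the
outermost decoder level carry **no** normalization. Instance norm discards
per-frame absolute brightness, and with it normalized at every level the
network cannot restore output intensity scale — reconstruction error then
plateaus at the brightness spread of the data. Keeping the outermost layers
norm-free preserves an un-normalized full-resolution path from input to
output (this is also how the canonical 2D implementations arrange it).

Single-path ablation variants are first-class: mode `"xyz"` feeds the
XYZ-path features to the decoder twice (no XYT encoder is built), mode
`"xyt"` the converse. The XYT-only variant necessarily runs without skip
connections, since skips originate in the XYZ encoder.

## The 4D-consistency discriminator

The discriminator sees the input channel and a candidate output channel
flattened into XY(ZxT) view — Z*T 2D slices ordered z-fastest (slice index
`k = t*Z + z`) — stacked as two channels of one 3D block, and emits a map of
patch-wise realness logits (PatchGAN, no global pooling). Convolutions
extend along the flattened axis with kernel `zt_kernel` (default 4) and each
block halves all extents, so a logit's receptive field along Z*T grows with
depth; once it exceeds Z it straddles consecutive time points. One
discriminator therefore judges localization, volumetric consistency,
temporal consistency and input-output correspondence at once. The z-fastest
flattening order is a design choice; the inverse operator is exported so the
choice stays encapsulated.

## Training

Standard conditional-GAN objective: the discriminator classifies real
(input, target) against (input, prediction) pairs; the generator minimizes
the adversarial term plus `lambda_l1 *` mean absolute error. Defaults
(lambda 100, Adam lr 2e-4, betas (0.5, 0.999), vanilla GAN loss, batch 1)
are the published Pix2Pix values and are defaults, not tuned constants —
users should not mistake them for values validated on any particular
dataset. Training alternates one D and one G update per step on a single
randomly drawn pair, is bit-reproducible from the config seed, and aborts on
non-finite losses. Validation is mean L1 on normalized intensities; optional
early stopping ends training when validation L1 reaches an absolute level or
a fraction of its initial value, with `steps` as the hard cap.

The whole network stack is implemented in numpy (`fluoro4d.nn`): im2col +
GEMM 3D convolutions chunked to a fixed memory budget, manual
backpropagation, Adam. All layer gradients are verified against central
finite differences in the test-suite.

## Synthetic epithelial phantom

The phantom emulates live imaging of a contracting epithelial sheet with
three channels tied to one latent geometry:

* **Geometry.** A jittered-grid Voronoi tessellation of `n_cells` cells
  (mirrored seeds make every region finite with edges on the domain
  boundary; neighbouring regions share vertex indices). A fraction
  `activation_fraction` of cells receives a rising logistic activation
  `a_c(t)` whose onset precedes the movie — imaging starts during, not
  before, constriction. Activated cells pull their vertices toward their
  centroid by `shrink_rate * a_c(t)` per frame; shared vertices average the
  pulls of all incident activated cells, boundary vertices slide along the
  border. The tessellation stays gap-free at every frame and the summed cell
  area equals the domain area exactly. One known interaction effect: when
  two activated cells share vertices, one cell's contraction donates a
  sliver of area to the other, so per-cell area monotonicity holds only up
  to ~1-2% of cell area; the net movie-level contraction and the
  activated-vs-inactive contrast are robust.
* **Membrane channel** (adhesion-protein-like): a Gaussian-profile line
  image computed from exact point-to-segment distances (subpixel crest
  placement) at low gain, plus high-gain junctional cluster puncta drawn as
  a Poisson process along cell edges. Cluster points ride on their edge as
  vertices move.
* **Contractility channel** (myosin-like): a uniform cytoplasmic floor, a
  bright medial texture in activated cells, and a weak junctional lining.
  Medial brightness scales as `a_c(t) * (A_c(0)/A_c(t))^2` — the same
  contractile material concentrates as the apical area shrinks, with a
  quadratic exponent standing in for recruitment feedback. This makes
  intensity *rise* a consequence of *contraction*, which is what the
  area-change/intensity-change statistic measures.
* **Puncta channel** (tension-reporter-like): spots on a random subset
  (`jub_subset_fraction`) of the membrane clusters, scaled by local
  activation, over a very low diffuse floor.

All structural signal decays as `exp(-z_decay * z)` (apical concentration);
Poisson shot noise (`poisson_scale` = expected photons at unit intensity)
and Gaussian read noise are applied last. Geometry coordinates are offset
half a pixel so the continuous domain coincides with pixel-center coverage;
rasterized areas then agree with shoelace polygon areas without a boundary
band artifact.

Phantom defaults: 64x64x8x6 grid, 25 cells, 40% activated, shrink rate 0.06
per frame at full activation, membrane width 1.5 px, cluster rate 0.25 per
px of edge, z-decay 0.25 per slice, noise (50, 0.01). Calibration semantics
follow a typical confocal setup for this tissue: 0.124 um pixels, 0.5 um
z-steps, 10 s frame interval.

**What the phantom does not model:** photobleaching, drift, a realistic
PSF (membranes are Gaussian lines, puncta are Gaussian blobs), curved
3D tissue geometry, cell rearrangement or division, and any optical
cross-talk between channels. Passing tests on the phantom demonstrates that
the pipeline's mechanics (reslicing, training, editing, evaluation,
quantification) behave as specified under known ground truth; they do not
certify prediction quality on real recordings.

## DA / DI manipulations

Edits operate on the input channel before re-prediction. `erase` replaces
in-region voxels with the per-(z,t)-slice median *outside* the mask — the
diffuse inactive pool level — rather than zero, because a predictor trained
on real channels has never seen true zeros (a zero background is available
via an override for comparison). `gain` maps in-region voxels to
`gain*v + (1-gain)*bg` (exactly the identity at gain 1); an optional clip
keeps edited normalized inputs inside the predictor's training range
(the pipeline passes (-1, 1); the raw-intensity API default is no clip so
the affine contract stays exact). `freeze` holds a region at its frame-t0
content; `draw` max-composites a Gaussian-profile polyline into a membrane
channel, matching the phantom's membrane renderer, for digital cell
splitting. All edits are local: voxels outside mask x t-range are
bit-identical. Responses are read out as the signed after-minus-before
difference with in/out-of-mask summaries.

## Multi-view Frechet-distance evaluation

Prediction quality is scored as the Frechet distance between Gaussian fits
of embedded samples, in three views: every (z,t) 2D slice (XY appearance);
every time point's XYZ volume (volumetric consistency); every z-slice's XYT
movie (temporal consistency). A prediction that looks right frame by frame
but flickers in time degrades only the XYT view — the failure mode the
multi-view design separates. The matrix square root in the distance is
computed as `sqrt(S1) S2 sqrt(S1)` via symmetric eigendecomposition with
roundoff-negative eigenvalues clipped at zero; an independent Schur-method
route is kept as a numerics cross-check. Covariances use the unbiased
estimator and sample counts are recorded; slices are pooled across all
volumes of a set (per-image averaging is a possible alternative; pooling is
the declared default and is stated in the report).

Embeddings are injected through a minimal contract (deterministic callable,
fixed output dimension) rather than bundled: FID values are
embedding-relative, and shipping pretrained classifier weights is out of
scope. The provided `RandomProjectionEmbedding` (resize, seeded Gaussian
projection, tanh) satisfies the contract for distributional comparisons in
tests; it makes no claim of perceptual alignment.

## Quantification

Cells are segmented per 2D membrane slice by marker-controlled watershed:
Gaussian smoothing (sigma 1.0), interior markers from the darkest 40% of
pixels (connected components, minimum-area filtered), watershed of the
smoothed ridge image, and a 30 px final minimum area (~0.46 um^2 at
0.124 um/px — far below any real cell apex). On noise-free phantoms this
recovers exact cell counts and areas within a few percent of the polygon
oracle. Tracking links label images frame-to-frame by greedy maximum IoU
with threshold 0.5; unmatched cells end their track. Per-cell signal splits
into a junctional band (inner boundary band, default width 3 px ~ 0.37 um,
roughly the junctional complex scale) and the medial remainder; the split is
an exact partition, so intensity decompositions conserve in-cell totals.
Intensity profiles along Z (fixed t) or T (fixed z), pooled area-vs-mean-
intensity statistics with equal-count area bins and Spearman rank
correlation, and the change-ratio statistic (among cells whose area
decreased over a short window — default 3 frames, 30 s at the default frame
interval — the fraction whose mean intensity rose by more than 10%) complete
the analysis suite. How the original analyses segmented cells or defined the
medial/junctional split is not specified anywhere; both are parameterized
and the geometry-oracle path is exposed alongside the pipeline path so
method error stays measurable.

## Numerical and testing choices

* Desk-scale problem sizes: training tests use 32x32x8x4 blocks with
  base 8 / depth 2 networks and at most a few hundred steps;
  quantification tests use 96x96 noise-free phantoms with 16 cells.
  These sizes were chosen so the whole suite runs on one CPU core in
  minutes while still exercising every code path at non-trivial extents.
* The identity-task training fixture follows the identity-regularization
  convention of image-to-image translation: the generator is fed
  *target-domain* samples and asked to reproduce them (G(y) ~ y). It uses
  noise-free renders, because under shot noise the fixed point of L1
  training is the denoised signal and the residual would measure the noise
  floor rather than the training loop. The cross-channel fixture keeps the
  default noise and is scored relative to its own starting error.
* Degenerate inputs: constant volumes are rejected by `normalize` (no
  dynamic range); constant membrane images yield zero cells with a warning;
  an erase/gain mask covering a whole slice is rejected (background
  inestimable); collinear Voronoi seeds are re-seeded internally.
* Reslicing operators are tested against explicit index-iteration oracles
  and for bit-exact round trips over randomized shapes; the Frechet distance
  is tested against closed forms and an independent Schur-method oracle on
  random SPD pairs up to dimension 16.
* Known limitations: no GPU path (pure numpy; paper-scale *training* is out
  of reach, only forward passes are exercised at 256x256x16x10); no
  multi-input conditioning; no learning-rate schedules or early-stopping
  heuristics beyond the validation-target stop; OME-TIFF round trips are
  bit-exact for float32 but other dtypes are converted on write.
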