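# Methods

This note documents the models, procedures and numerical choices behind
`plateseg`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, which knobs
matter, and what the synthetic tests do and do not demonstrate.

## Problem setting

Serial block-face scanning electron microscopy (SBF-SEM) produces anisotropic
3D grayscale volumes — here 50 nm axial (z) vs 10 nm lateral (y, x) sampling —
in which every voxel is to be assigned one of seven classes: background (0),
cell (1), mitochondrion (2), canalicular channel (3), alpha granule (4), dense
granule (5) and dense granule core (6). This *dense cellular segmentation*
task is a multiclass semantic segmentation problem with heavy class imbalance
(background and cell dominate; granule cores are orders of magnitude rarer)
and strong anisotropy, which motivates every design element below.

Axis order is (z, y, x) throughout, 0-based with half-open ranges. Volumes are
stored as multi-page TIFF (one page per z-slice) or a single HDF5 dataset;
labels are unsigned 8-bit, images 32-bit float. Images are z-scored (mean 0,
population standard deviation 1) per processed subvolume before use, and can
be laterally binned by block averaging (block mean preserves intensity
statistics; the binning operator is otherwise a free choice).

## Hybrid 2D–3D network

The flagship architecture composes:

1. **A "2D" U-Net-style encoder–decoder** operating on a 3D window through
   1×3×3 convolutions and 1×2×2 max-pooling / transposed convolutions, so
   each z-slice is processed identically and independently — except for
   optional 3×3×3 convolutions at the start of the first two encoder blocks
   and the last two decoder blocks, which are the only cross-z couplings in
   the module. All convolutions are zero-padded (shape-preserving), biased,
   and followed by ReLU.
2. **An intermediate 2D predictor**: a 1×1×1 convolution from the module's
   output features to 7 channels, followed by a per-voxel softmax, giving
   intermediate class predictions `x̂_2D`.
3. **A 3D spatial pyramid** consuming the concatenation of the 2D features
   and `x̂_2D`: scale 0 processes the input directly and scale 1 its 1×2×2
   max-pooled version, each through its own block of 3×3×3 convolutions; the
   scale-1 output is nearest-neighbour upsampled and added residually to the
   scale-0 output. A final 1×1×1 convolution plus softmax yields `x̂_3D`, and
   the voxelwise argmax of `x̂_3D` is the segmentation (ties break toward the
   lowest class index — a deterministic convention).

Default geometry: encoder channels (64, 128, 256), two same-scale 1×3×3
convolutions per block plus the optional block-initial 3×3×3, a mirrored
decoder, 64 output features, 64 pyramid channels and two 3×3×3 convolutions
per pyramid block. These widths satisfy all the architectural constraints
stated above; since all convolutions are shape-preserving, the (5, 300, 300)
→ (7, 5, 296, 296) input/output geometry is realized by a final symmetric
centered spatial crop (2 voxels per lateral side), applied to both heads.
Heads emit probabilities (not logits) so that ensembling is a plain voxelwise
average; the loss consumes clamped log-probabilities for stability.
Initialization is Xavier-uniform from a single seed, making instances fully
reproducible.

Ablation toggles mirror the three distinguishing design features: replacing
the 3×3×3 block-initial convolutions with otherwise-identical 1×3×3 ones,
dropping the 2D loss term, and removing the pyramid entirely (then `x̂_2D` is
the output). Two fully-3D U-Net baselines are available as optional hooks: a
"thin" variant whose pooling never touches z ((5,300,300) → (5,296,296)) and
a "thick" variant pooling all axes with shape-preserving windows
((16,180,180) → (16,180,180)); both use three convolutions per block and two
pooling stages.

`plateseg` implements these networks on a small numpy reverse-mode autodiff
core (`plateseg.nn`) providing exactly the required operations (same-padded
conv3d as one GEMM per kernel tap, strided transposed convolution, max
pooling, nearest upsampling, channel softmax, weighted cross-entropy, ADAM).
Activations carry no batch axis; training uses minibatch size 1. Gradients
are verified against finite differences in the test suite.

## Loss

For an output window of N voxels with one-hot truth `x` and per-voxel weights
`W`:

```
L = (1/N) Σ W ⊙ H(x, x̂_3D) + (c_2D/N) Σ W ⊙ H(x, x̂_2D)
    + λ_2D Σ_{θ∈Θ_2D} ||θ||² + λ_3D Σ_{θ∈Θ_3D} ||θ||² + λ_P (||θ_2DP||² + ||θ_3DP||²)
```

with `H` the voxelwise cross entropy `−log x̂_v(ℓ_v)` (log-probabilities
clamped at 1e−12), `⊙` the elementwise product, `c_2D = 0.33`,
`λ_2D = 10^−4.7`, `λ_3D = 10^−5`, `λ_P = 10^−9`. The trainable variables are
partitioned exhaustively into the 2D module (Θ_2D), the pyramid (Θ_3D) and
the two 1×1×1 predictors; the L2 penalties run over every variable of each
subset, biases included. Disabling the multi-loss drops the `x̂_2D` term;
removing the pyramid drops the `x̂_3D` term and leaves the (still
`c_2D`-scaled) 2D term as the sole data term — a constant rescaling of the
data term that ADAM largely absorbs.

### Weight volume

`W = w + W_cb + W_ep` with floor `w = 0.01`.

* **Class balancing** `W_cb`: inverse-frequency weights per class,
  `W_cb,i ∝ 1/N_i`, rescaled so the maximum over classes present in the
  training volume is 1; classes absent from the labels get weight 0 (1/N_i is
  undefined and they never occur). Counts are taken once over the entire 3D
  training volume.
* **Edge preservation** `W_ep`, computed independently per 2D z-slice as a
  rectified sum of four directed diffusion terms with class subsets
  bkgd = {0}, cell = {1}, org = {2..6}:
  `W_ep = R_α(W_bkgd→cell + W_cell→bkgd + W_cell→org + W_org→cell)`. Each
  directed term blurs the binary indicator of the source subset with a
  unit-sum Gaussian kernel (σ = 6 lateral pixels of the binned volume), scales
  it by c = 0.882, and keeps it only on voxels labeled in the target subset.
  The rectification `R_α(W) = ReLU(W − α)·max(W)/(max(W) − α)` with α = 0.25
  zeroes weak responses while mapping the slice maximum to itself; when the
  slice maximum does not exceed α the result is defined as identically zero
  (the rescale factor would otherwise be undefined or negative). A single
  (c, σ) pair is shared by all four terms.

Numerical choices for the diffusion: the 2D Gaussian kernel is separable,
unit-sum, truncated at 4σ, with reflective boundary handling — reflection
keeps an all-one source mask at exactly c. Implementation uses
`scipy.ndimage.gaussian_filter`; the test suite validates it (and the whole
weight construction) against a dense direct-summation convolution oracle to
1e−6. The weight volume is precomputed over the full training volume and
cropped per window; weights therefore deform together with image and labels
under augmentation.

## Augmentation

Per epoch, one elastic displacement field is sampled and applied to the
entire training volume before window extraction, followed by independent
axis reflections (probability 1/2 each) and photometric jitter. The field is
a (20, 20, 2) grid of i.i.d. Gaussians (mean 20, standard deviation 0.6
pixels per component) bilinearly upsampled to the lateral shape; the same 2D
field displaces every z-slice. Images and weights resample with linear
interpolation, labels with nearest (so label values remain in the schema);
out-of-range source coordinates reflect. Note the nonzero mean makes the
default deformation a near-rigid ~20-pixel translation plus a small warp;
the parameters are applied literally, and a visually elastic preset
(mean 0, std 10) is available via configuration.

Photometric jitter on z-scored data: brightness is an additive shift
γ_b ~ U(±12%), contrast scales about the mean by 1 + γ_c with γ_c ~ U(±20%).
The per-epoch order is elastic → flips → photometric.

## Windowing, tiling and stitching

Training windows sit on a strided corner grid: corners {0, s, 2s, ...} per
axis up to the last in-bounds start, i.e. floor((S − w)/s) + 1 positions per
axis with no flush-end extra. The default geometry — (50, 800, 800) volume,
(5, 300, 300) windows, (2, 100, 100) spacing — gives 23·6·6 = 828 windows
per epoch, which pins this convention. Label and weight windows are the
centered output-shaped crops of the co-located input window; presentation
order is shuffled per epoch.

Inference tiles a volume with corners strided by the output shape, shifting
the final corner per axis flush to the end so that the union of output
windows covers the whole crop interior; overlapping voxels average the
contributing probability vectors (consistent with ensembling semantics). The
global crop margin (2 lateral voxels per volume face by default) is covered
by no output window; stitching returns a validity mask and evaluation
restricts itself to it.

## Optimization, experiments, ensembling

ADAM with learning rate 10^−3, β₁ = 1 − 10^−1.5, β₂ = 1 − 10^−2.1,
ε = 10^−7, and continuous exponential decay by 0.75 every 10^3.4 steps
(staircase decay is flag-selectable). Default training is 40 epochs at
minibatch size 1. Evaluation MIoU over all 7 classes is computed once per
epoch from stitched full-volume predictions of the network's output head
(the 3D head when the pyramid is present); the best and final checkpoints
are kept. Instances failing to reach MIoU 0.3 after 10 epochs halt early.

An *experiment* trains several instances that differ only in the RNG seed
(initialization, augmentation stream, window order) and ranks them by best
evaluation MIoU. A Top-k ensemble averages the stitched per-voxel class
distributions of the k best instances (member-level stitching first; when
members share a tiling this commutes with stitching) and segments by argmax.
`binarize_segmentation` merges classes 1–6 for binary cell/background
comparisons, and `threshold_probability_map` applies a strict `prob > t`
cutoff supporting sweeps over t ∈ {0, 0.1, ..., 1}.

## Evaluation

`IoU(A, B) = |A∩B| / |A∪B|`; `MIoU^(D)` is the unweighted mean of per-class
IoU over a class subset D (all 7 classes, or the 5 organelle classes), which
deliberately emphasizes rare classes. Classes absent from both segmentations
(within the evaluation mask) have an undefined 0/0 IoU and are excluded from
the mean; a strict mode scoring them 1 instead is flag-selectable because the
choice changes `MIoU^(org)` on sparse volumes. Classes present in exactly one
segmentation contribute 0. An optional boolean mask restricts all counts —
used both for the stitching validity region and for single-cell test
protocols where labels cover only one cell. Confusion matrices, per-organelle
volume fractions (organelle voxels divided by cell-mask voxels), pairwise
annotator-style MIoU matrices, and an approximate cell mask (reference mask
dilated with the 6-connected structuring element, default radius 2,
intersected with the non-background prediction) complete the reporting.

## Synthetic phantoms

The phantom generator provides download-free, fully labeled data emulating
the *structure* of the platelet task: ellipsoidal non-overlapping cells on
background with organelles strictly inside (a one-voxel cellular rim is
enforced); elongated mitochondria, thin tortuous canalicular tubes, round
alpha granules and dense granules whose class-6 cores are built by 26-
connected erosion of the granule mask — which guarantees, by the opening
property, at least a one-voxel granule shell around every core. Anisotropy
is emulated by making axial extents ~5× smaller in voxels than lateral ones
and blurring more strongly along z (blurring rather than subsampling keeps
image/label alignment exact). The image is a per-class intensity mean plus
Gaussian noise, anisotropically blurred, then z-scored. Default intensities
(0.90, 0.55, 0.32, 0.75, 0.42, 0.18, 0.04 for classes 0–6), noise 0.08 and
z-blur 0.8 were chosen once to give clearly distinct but noise-overlapping
class appearances; organelle densities (8%, 5%, 7%, 5% of the cell for
classes 2–5, cores derived) keep all seven classes present at frequencies
close enough to exercise the class balancing.

What the phantom does *not* emulate: EM texture (membranes, cristae, stain
granularity), intensity gradients and shading, imaging artifacts, true
axial subsampling, or realistic organelle morphology variation. Passing the
scaled-down learning check therefore demonstrates that the pipeline's
mechanics (weighting, augmentation, windowing, optimization, evaluation) are
sound and that the architecture can exploit intensity-plus-context cues — it
says nothing quantitative about accuracy on real SBF-SEM data, whose headline
results require GPU-scale training on the original datasets.

`perturb_labels` emulates annotator disagreement for the pairwise-comparison
machinery: per-component boundary erosions/dilations and small random region
flips with strength scaled by a severity parameter (severity 0 is the
identity; organelle-level disagreement grows monotonically with severity on
average).

## Scaled-down study sizes

Desk-scale checks use a (32, 96, 96) two-cell training phantom, a
(16, 96, 96) held-out phantom, a 2-scale 8/16-channel network (8 feature and
pyramid channels), (5, 64, 64) → (5, 60, 60) windows with (3, 32, 32)
spacing (40 windows per epoch), no augmentation (held-out phantoms come from
the same distribution, so augmentation only slows convergence at this scale),
and at most 1000 ADAM steps per instance with training halting once held-out
MIoU^(all) reaches 0.4 — about three times the ~0.14 expected from the
class-marginal baseline. Three pinned seeds are required to pass. The
full-size default network is exercised for its (1, 5, 300, 300) →
(7, 5, 296, 296) output-geometry contract.

## Known limitations

* The numpy substrate is single-device and unbatched; it is meant for
  desk-scale verification and small studies, not GPU-scale training.
* Lateral input sizes must be divisible by 2^(encoder depth − 1) (and even
  when the pyramid is present); inference tiling handles arbitrary volumes
  by flush-shifted windows instead.
* Per-window recomputation of the edge-preserving weights (numerically
  different near window borders from precompute-then-crop) is not
  implemented; the precomputed full-volume weights are cropped per window.
* Heterogeneous-architecture ensembles and instance-level (per-object)
  metrics are out of scope.
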