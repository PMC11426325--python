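# Methods

## Problem and pipeline

The package estimates the beach area covered by stranded *Sargassum* from
very-high-resolution RGB orthophotos. The estimate is produced in five
stages: overlapping-window tiling, per-tile semantic segmentation with a
conditional GAN, majority-vote mosaic reassembly, fβ/bootstrap evaluation,
and pixel-count area quantification with vector export. Class indices are
fixed package-wide as `0 = other` (water, vegetation, people, …), `1 =
sand`, `2 = sargassum`; one ordering everywhere prevents confusion-matrix
axis bugs.

## Segmentation model

Segmentation is framed as image-to-image translation: the network regresses
a palette-colored class image (default palette: other = cyan, sand = yellow,
sargassum = red; configurable) from the RGB tile, and class indices are
recovered afterwards by nearest-palette-color quantization. Quantization
rather than thresholding is used because the generator's RGB output is
continuous and unconstrained; ties break toward the lower class index.

**Generator.** A U-Net of eight 4×4 stride-2 convolution blocks with widths
64-128-256-512-512-512-512-512 (LeakyReLU slope 0.2; batch normalization on
every block except the first) mirrored by seven transposed-convolution
blocks 512-512-512-512-256-128-64 (ReLU; batch norm; dropout 0.5 on the
first three), with mirror-wise skip concatenations and a final transposed
convolution to 3 channels through tanh. Images are normalized to [−1, 1].

**Discriminator.** A PatchGAN over the channel-concatenated (input, target)
pair: 4×4 convolutions C64-C128-C256 at stride 2 and C512 at stride 1
(LeakyReLU; batch norm except the first block), then a 1-channel 4×4
stride-1 head. For 256×256 input the output is a 30×30 grid of patch
logits, each judging roughly a 70×70 receptive field.

**Bias and normalization conventions.** Convolutions followed by batch
normalization carry no bias (the norm's shift absorbs it); the four
non-normalized layers (both input blocks, the generator output, the
discriminator head) do. The innermost encoder block keeps its batch norm.
With these conventions the parameter tallies are exactly: generator
54,415,043 trainable + 10,880 non-trainable (batch-norm running
statistics), discriminator 2,768,705 + 1,792, total 57,196,420. Weights are
initialized from a Gaussian with mean 0 and standard deviation 0.02;
batch-norm scale/shift start at 1/0.

**Losses.** Two generator objectives are provided. `standard` (default) is
the classic conditional-GAN objective: BCE of the discriminator's patch
grid against all-ones plus λ·L1 between output and target, λ = 100.
`paper_literal` is the pure mean-absolute-error regression; in this mode
the discriminator is not updated (the adversarial term is absent, so its
updates would be dead weight) and its logged loss is 0. The discriminator
loss is always BCE(real, 1) + BCE(fake, 0). Public loss functions are
defined on post-sigmoid probabilities; training uses the numerically stable
logit forms, which agree to ≤1e-6.

**Numpy implementation.** `sargmap.nn` implements the layer set with
hand-written backward passes: im2col convolutions, transposed convolutions
as the exact adjoint (col2im) of the matching convolution, batch norm with
full batch-statistics gradients, and Adam. Backward passes are verified
against central finite differences in the test suite. Float32 throughout.

## Training and inference

Adam with lr 2e-4, β₁ 0.5, β₂ 0.999, batch size 1, constant schedule, 30
epochs by default; no data augmentation. The optimizer settings are the
conventional pix2pix choices. One integer seed drives initialization,
shuffling and dropout, so two single-threaded runs produce identical loss
logs; across BLAS configurations agreement is best-effort. Checkpoints are
npz weight archives with a JSON architecture fingerprint (spec plus
parameter counts) that loaders verify before use.

With batch size 1, batch normalization behaves as instance normalization
during training: each sample is normalized by its own statistics.
Inference must match that regime — normalizing by accumulated running
statistics instead degrades segmentations catastrophically (we measured
macro f0.5 dropping from ≈0.99 to ≈0.25 on synthetic scenes). `segment_scene`
therefore forwards tiles one at a time using each tile's own statistics
(dropout off, running buffers untouched); running-statistics inference
remains available via `norm_stats="running"`.

**Desk scale.** The full-width model is impractical to train on one CPU, so
`GeneratorSpec.scaled(width_multiplier, depth)` shrinks every channel width
by a common factor and optionally truncates the schedule: depth D uses the
first D encoder widths and (512,)·(D−4) + (256, 128, 64) decoder widths.
Depth 8 is the canonical 256-px model; depth 6 fits 64-px tiles (an input
must be divisible by 2^depth). The package's reference desk configuration —
used by the acceptance tests — is width 1/8, depth 6, 64×64 tiles, 200
training pairs, 5 epochs, which trains in well under a minute per seed and
reaches macro f0.5 ≈ 0.99 on held-out synthetic scenes.

## Tiling and reassembly

Windows form a full Cartesian grid with stride `tile·(1−overlap)` (the
stride must come out an integer); each axis is padded to the smallest
`tile + k·stride ≥ dim` by edge reflection, so the grid always ends exactly
at the padded border and every pixel is covered by at least one tile.
Reflection is chosen over zero padding to avoid fabricating a spurious
fourth "border" class. Fusion is a per-pixel hard-label majority vote over
covering tiles; ties break by the fixed priority sargassum > sand > other,
favoring recall of the positive class. The vote is used (rather than
averaging scores) because tile outputs are quantized labels without
calibrated probabilities. Extract→reassemble is the identity on masks for
any size and any valid overlap.

## Dataset characterization and splitting

Tiles are characterized by the Shannon entropy of the 256-bin gray-level
histogram, H = Σ p·log₂(1/p) ∈ [0, 8] bits, computing luminance with the
BT.601 weights (0.299, 0.587, 0.114) — a deterministic reading of "gray
levels" for RGB input — and by per-class pixel counts. The random train/test
split takes ⌊n·0.8⌋ training items (floor rounding reproduces the canonical
12,214/3,054 partition of 15,268 tiles) and is a deterministic function of
its seed. Pure random splitting over tiles is the default; because 50%
overlap makes neighboring tiles share half their pixels, spatially grouped
splitting is a known improvement but is not claimed to match any published
protocol.

## Evaluation

Confusion matrices count pixels with rows = predicted, columns = truth.
Precision and recall follow the usual row/column definitions. fβ combines
them with β = 0.5 and β = 2; β = 0 degenerates to precision, and p = r = 0
returns 0. Merging sand and other into a single negative class sums
rows/columns, conserving totals, so binary sargassum metrics equal the
three-class ones exactly. The merged class order is [other, sargassum].

Zero-denominator convention (images without a class are common): a class
absent from both prediction and truth scores 1; absent from only the
denominator's side scores 0. Records are always flagged degenerate so the
summary policy (include flagged values, the default, or exclude them) is
explicit — silent NaNs would poison dataset-level summaries.

Summaries report mean, sample sd (n−1), median, raw MAD (a flag applies the
1.4826 normal-consistency factor) and max; values are sorted before
reduction so summaries are exactly permutation-invariant. Uncertainty on a
metric's mean uses the percentile bootstrap — the minimal, seedable reading
of "bootstrapping": 2,000 resamples of the original size with replacement,
CI from the 5th/95th percentiles of resampled means at the 90% level.
Coverage at these defaults is verified by simulation in the test suite.

## Mapping

Areas obey the pixel-count identity: n pixels at ground sample distance g
cover n·g² m² (2 cm/px ⇒ 0.0004 m²/px). Connected components
(8-connectivity by default, because windrows run diagonally along the wrack
line) are vectorized as unions of pixel squares: staircase outlines with
holes, no smoothing, so geometric areas agree with the pixel-count identity
(conservation is exact in integer pixel counts; scaled by g² the floating
sums agree to ~1e-12 relative). Optional simplification is deliberately
omitted from the default path because it breaks that identity. Zone reports
assign pixels by their centers to half-open [min, max) rectangles so
tilings partition the scene exactly. Outputs are RFC 7946 GeoJSON (class,
area_m2, pixel_count per feature) and georeferenced single-band rasters;
styling is left to GIS clients.

Georeferencing carries gsd (square pixels), top-left corner origin, and a
CRS identifier; northing decreases with row index. GeoTIFF tags
(pixel-scale/tiepoint) and ESRI world files are both understood;
ungeoreferenced rasters are accepted everywhere except area operations,
which fail loudly.

## Synthetic scenes

The generator emulates what matters statistically about beach orthophotos:
a wavy shoreline separating water from sand with a zero-mean undulation (so
the requested water share is preserved), elongated anisotropic sargassum
ellipses deposited along the wrack line (aspect ≈ 4 parallel to the shore,
placed until the requested share is reached), and per-class base colors
plus blurred Gaussian texture noise (sd = amplitude/3, hard-clipped at the
amplitude, default 12 gray levels over a σ = 3 px blur). Correlated rather
than white noise keeps tiles low-entropy, matching the
homogeneous-region character of real beach imagery, while leaving scenes
non-trivially segmentable. Default class fractions (other 0.55, sand 0.35,
sargassum 0.10) encode the characteristic imbalance: sargassum rarest.
Scenes are deterministic per seed; the truth mask is the exact generative
partition; the noise bound guarantees a nearest-base-color classifier
recovers the truth with high precision, a separability floor that makes
desk-scale training learnable.

What the generator does **not** model: drone optics (vignetting, glare,
motion blur), wet-sand gradients, shadows, people and debris, floating
sargassum under water-surface distortion, and inter-date illumination
drift. Passing tests therefore demonstrate the pipeline's correctness and
trainability, not field accuracy on real surveys; models trained on
synthetic scenes must not be applied to real imagery, and the package makes
no claim about segmenting floating sargassum over water.

Tiles are emitted in a seeded shuffled order per scene so that truncating a
dataset to n tiles does not spatially bias it toward the top of the scene.

## Known limitations

- Training determinism is bitwise only on a fixed platform/thread count.
- Batch sizes > 1 change the batch-norm regime; the package defaults to 1.
- The polygonizer unions pixel squares per component; for components of
  millions of pixels this is slower than a contour tracer, though run
  lengths keep typical scenes fast.
- Bootstrap CIs are percentile (not BCa); for strongly skewed per-image
  metric distributions percentile intervals can undercover slightly.
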