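# Methods

## Model

`microstain` learns an image-to-image transformation from two-channel
autofluorescence stacks x (DAPI-like and Texas-Red-like bands) to
bright-field stained appearances z, conditioned on a per-pixel digital
staining matrix c̃ = [c₁, …, c_N] concatenated to the input. The model is a
conditional GAN. The generator loss combines a pixel term, a smoothness
regularizer and an adversarial term,

    ℓ_G = L₁{z, G(x, c̃)} + λ·TV{G(x, c̃)} + α·(1 − D(G(x, c̃), c̃))²,

and the discriminator minimizes the squared-error adversarial loss
ℓ_D = D(G(x, c̃), c̃)² + (1 − D(z, c̃))². The operators are

- L₁(z, g) = mean over pixels and channels of |z − g| (the `l1_distance`
  operator);
- TV(z) = Σ_p Σ_q |z_{p+1,q} − z_{p,q}| + |z_{p,q+1} − z_{p,q}|, channels
  summed, boundary terms omitted (the `total_variation` operator).

**TV normalization in the loop.** As printed, TV is an unnormalized sum
while L₁ is a per-pixel mean — on a 256×256 patch the sum is four orders of
magnitude larger, and λ = 0.02 would make the TV term dominate rather than
sit at the intended few percent of the L₁ term. The training loop therefore
divides the TV term by the pixel-and-channel count, putting both terms on a
per-pixel scale; with λ = 0.02 the TV contribution then lands at roughly
1–5% of the L₁ loss over a converged run, the balance the schedule was
designed around. The public `total_variation`/`generator_loss` operators
keep the literal forms.

**Color space.** The generator regresses targets in YCbCr scaled to [0, 1]
(the discriminator's image planes are YCbCr); conversion to 8-bit RGB uses
the ITU-R BT.601 full-range matrix and happens only at export. The same
matrix backs the YCbCr difference metrics, so metric space and model space
agree.

## Architectures

Generator: a fully convolutional U-net with `levels` down/up blocks and stem
width `base_channels` (s). Down-block ℓ: three 3×3 convolutions (the first
doubles channels to s·2^ℓ) each followed by Leaky ReLU (slope 0.1), then 2×2
average pooling, stride 2. Up-block ℓ: bilinear 2× upsampling (implemented
as a fixed separable linear operator, so its adjoint is exact in backprop),
concatenation with the same-level down-block output — by construction the
two halves have equal width s·2^ℓ — then three convolutions reducing the
concatenated channels by 4×, restoring s·2^(ℓ−1). A final 3×3 convolution
maps to 3 channels. Same-padding everywhere, so spatial sizes follow the
stated halving/doubling exactly and the network runs at any size divisible
by 2^levels. The stem width is not architecturally constrained; 32 is the
full-scale default, 8 the desk-scale value.

Discriminator: 6 input planes (YCbCr + staining matrix), a stem convolution
to `stem_channels`, `blocks` blocks of two convolutions (the second doubling
channels at stride 2), flatten, two fully connected layers to one sigmoid
unit. The flatten ties it to a fixed patch size (256 full scale, 64 desk
scale).

Weights are initialized from a truncated normal (std 0.02, resampled beyond
2 std), seeded. All parameters train with Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8).

**Numpy engine.** No GPU framework is assumed: convolutions, pooling,
upsampling, dense layers and their gradients are implemented directly over
float32 NHWC arrays (im2col GEMM for narrow layers, shifted GEMMs for wide
ones), verified against float64 finite differences in development. This
bounds practical model sizes but makes the desk-scale study run in minutes
on one CPU with no dependencies beyond numpy.

## Training schedule

Reference (full-scale) conditions: λ = 0.02, α = 2000, learning rates 1e-4
(G) and 2e-6 (D), ten generator updates per discriminator update, batch 8,
21,000 discriminator steps on 256×256 patches. These are the
`TrainingConfig` defaults.

Desk-scale study (`presets.py`): generator (levels 2, stem 8), discriminator
(stem 8, 3 blocks) on 64×64 patches; 30 synthetic slides of 192×192 px split
21/4/5 by slide (slide-disjoint, mirroring patient-disjoint test sets);
overlapping patches at stride 32 with ≥50% tissue, dihedral-augmented
(~300 patches); 150 discriminator steps = 1,500 generator updates. The
learning rates are scaled to the shortened run: the reference schedule
performs 210,000 generator updates at 1e-4, so the 1,500-update study uses
2e-3 (discriminator 4e-5, keeping the 1:50 ratio) to give Adam — whose
per-step displacement is bounded by the rate — a comparable total parameter
movement. With the reference rates a 1,500-update run cannot even shift the
output biases the ~0.5 needed to reach the target mean. These sizes were
fixed once as the package's CPU-scale study and are used unchanged by the
test suite and the acceptance script.

The discriminator sees fakes regenerated from the current generator (not
stale ones); losses reduce by batch mean; a non-finite loss restores the
last snapshot and raises. All shuffling derives from one config seed, and
repeated runs with the same seed produce bit-identical loss histories on a
fixed machine.

## Registration

`block_shift` trims a quarter-block margin from the moving block and slides
the central region over the full reference block with normalized
cross-correlation (`skimage.feature.match_template`), so every candidate
offset up to a quarter block is scored with properly normalized statistics;
the peak is refined by 1-D parabolic fits (±0.5 px clamp) and ties break
toward the smallest row, then column. Constant blocks are degenerate:
shift 0, confidence 0.

`elastic_pyramidal_register` starts from a 5×5 block grid, interpolates
per-block shifts into a dense map by Gaussian-weighted averaging
(σ = half the block spacing; evaluated on a stride-4 lattice and bilinearly
upsampled — the map is smooth by construction), composes it additively with
the running field, re-warps the moving image, and halves the block size per
level until the next level would drop below `min_block` (100 px default, so
a 512-px image gets one level and a 2048-px image three). Blocks with peak
correlation below 0.2 are excluded and inherit the interpolated shift of
their neighbours. Images smaller than one matchable block fall back to a
single global shift. The field convention is out(p) = moving(p − f(p)); a
moving image equal to the reference translated by t recovers f ≈ t.

The bright-field/autofluorescence coarse alignment slides a
contrast-reversed DAPI image over the bright-field image (valid-mode NCC)
and returns the best offset and crop. A small rigid refinement maximizes a
32-bin mutual information over ±5° and ±20 px (coarse grid, then Powell);
when nothing improves on identity — including near-constant inputs — it
returns identity with a warning. The full-scale workflow of training on
coarsely matched pairs, virtually staining, and elastically re-registering
the histochemical image to the virtual stain is supported by these pieces
but not automated end-to-end.

## Preprocessing

Tissue masks come from Otsu's threshold on the 3×3-median-smoothed DAPI-like
channel, keeping connected components of at least 64 px; whole-slide
normalization subtracts the tissue mean and divides by the tissue standard
deviation (channels treated independently), which is idempotent and leaves
background pixels on the same affine scale. Patches are cut on a stride grid
(default stride 128 at size 256 — 50% overlap; the desk-scale study uses
64/32) with optional seeded jitter; patches under 50% tissue are discarded.
Augmentation applies one of the eight dihedral transforms identically to
input, target and per-pixel staining matrix, which preserves the sum-to-one
rule exactly.

## Staining matrix and rasterization

A pixel belongs to a polygon when its center — at integer (x, y) = (col,
row) coordinates — lies inside (shapely point-in-polygon; simple polygons
only, validated on construction); later polygons overwrite earlier ones on
overlap, making malformed overlapping input deterministic. Weights are
floats in [0, 1] so one type serves one-hot, blended and ROI-structured
conditions; every construction path and every inference entry point
validates the sum-to-one rule to 1e-6 and rejects violations with a
specific error. Behaviour exactly at ROI boundaries follows the
rasterization rule; inside the rendered image, stain mixing is confined to
a receptive-field-wide band around each boundary.

## Metrics

`ssim_global` computes SSIM from whole-patch statistics — population means,
variances and cross-covariance — with C₁ = (0.01·255)², C₂ = (0.03·255)²;
multi-channel images average the per-channel values. A sliding-window mean
SSIM is available (`ssim_windowed`) but is not the default path. YCbCr
percentage differences are per-channel mean absolute differences divided by
the full 8-bit range (255); normalization by the reference channel mean is
available as an option, since the field uses both conventions. Reports tile
pairs into non-overlapping 1224×1224 blocks (configurable; partial edge
blocks discarded) and aggregate mean and sample standard deviation.

## Synthetic data

Phantoms place elliptical nuclei, curvilinear membrane ridges (tissue-region
boundaries plus band-limited internal ridges) and textured cytoplasm on a
background, then render two channels: the DAPI-like channel is bright on
nuclei with moderate tissue signal; the Texas-Red-like channel emphasizes
membranes and cytoplasm. Additive Gaussian noise (σ = 0.02 of the intensity
scale) perturbs the channels the network sees; oracle targets are rendered
from the noise-free channels, so training has a clean signal at desk scale.
Oracle stains map each structure label to a fixed colour (H&E: purple
nuclei, pink cytoplasm; trichrome: blue membranes, red cytoplasm; silver:
dark membranes on a pale counterstain), pulled toward white by the local
clean-channel intensity. The palettes are interpretability aids, not stain
chemistry. Blended oracles are pixel-wise convex combinations of the pure
renderings, which is what makes blend-monotonicity a well-posed check.

What the phantoms do **not** emulate: optics (PSF, vignetting, stitching
seams), autofluorescence spectra, staining variability between
histotechnologists, tissue deformation during staining, and scanner colour
profiles. Passing the desk-scale study therefore demonstrates that the
architecture, conditioning mechanism, losses and pipeline are implemented
correctly and can learn a stain-conditional rendering — not that the model
reaches clinical-quality virtual staining on real tissue, which requires
the full-scale data and training budget.

## Numerical choices and degenerate inputs

- Sum-to-one tolerance 1e-6; validation reports per-pixel violations.
- Constant registration blocks: confidence 0, excluded from interpolation;
  all-excluded levels contribute no increment.
- Parabolic sub-pixel offsets clamped to ±0.5 px; zero-curvature peaks fall
  back to the integer offset.
- Warping samples out-of-bounds positions at the nearest edge value.
- Normalization raises on empty masks or zero tissue variance; patching
  raises on slides smaller than one patch, suggesting padding.
- Tile feathering uses linear ramps over a 32-px overlap band; tile steps
  stay multiples of 2^levels so tiled and single-pass outputs agree away
  from seams.
- Checkpoints store spec, weights and stain ordering; loading refuses a
  checkpoint whose stain ordering differs from the run configuration.

## Known limitations

- The numpy engine is single-device and unsuited to the full-scale
  (21,000-step, 256×256, 32-stem) configuration; that configuration is
  expressed but not exercised end-to-end.
- The elastic model is per-block translation only — no affine or
  diffeomorphic components — matching its intended use for small inter-band
  misalignments.
- Whole-patch SSIM is a global statistic; it saturates on images with
  matching global statistics and is deliberately not a perceptual score.
- Oracle stains are deterministic functions of the phantom, so desk-scale
  results quantify conditional fidelity, not generalization across staining
  variability.
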