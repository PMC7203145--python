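# microstain

Micro-structured, multiplexed **virtual histological staining** of label-free
tissue images with a single class-conditional GAN.

## The problem

Histochemical staining (H&E, Masson's trichrome, Jones' silver, ...) is slow,
costly and destroys the section: once a slide is stained one way it cannot be
stained another. Virtual staining replaces the chemistry with a deep network
that transforms *autofluorescence* images of the unlabelled section — here a
two-channel stack from DAPI-like and Texas-Red-like filter bands — into the
bright-field appearance of the stained tissue. `microstain` implements the
multiplexed variant: **one** network renders **several** stains, decided per
pixel at inference time, which also enables stain *blending* (fractional
mixtures that synthesize new digital stains) and *micro-structured* staining
(different stains in user-drawn regions of one section).

## The model

The conditioning object is the **digital staining matrix**
c̃ = [c₁, …, c_N]: one plane per stain, concatenated to the two
autofluorescence channels at the network input. At every pixel (j, k) the
weights obey the encoding rule

    Σᵢ c_i,j,k = 1 ,  c_i,j,k ≥ 0 .

A one-hot c̃ selects a single stain, fractional constant planes blend stains,
and spatially varying planes (rasterized from polygon annotations) stain
different regions differently.

The generator G is a U-net (down-blocks of three 3×3 convolutions doubling
the channel count followed by 2×2 average pooling; up-blocks of bilinear 2×
upsampling, skip concatenation, and three convolutions reducing channels 4×;
Leaky ReLU slope 0.1 throughout), emitting the stained image in YCbCr. The
discriminator D scores six planes — the YCbCr image and the staining matrix —
through a 64-channel stem, five two-convolution blocks (the second of each
doubling channels with stride 2), and two fully connected layers to a sigmoid.
Training minimizes

    ℓ_G = L₁{z, G(x, c̃)} + λ·TV{G(x, c̃)} + α·(1 − D(G(x, c̃), c̃))²
    ℓ_D = D(G(x, c̃), c̃)² + (1 − D(z, c̃))²

with λ = 0.02, α = 2000, Adam (1e-4 generator / 2e-6 discriminator), ten
generator updates per discriminator update, batch 8. Because no GPU deep
learning framework is assumed, the conv-net engine (forward, backprop, Adam)
is implemented in numpy and trains desk-scale models in minutes on one CPU.

The package also provides the surrounding pipeline:

- **Registration** — elastic pyramidal block matching: the image is split
  into a 5×5 grid of blocks, block-wise normalized cross-correlations give
  per-block translations (sub-pixel via parabolic fits), a Gaussian-weighted
  average interpolates them into a dense translation map, and the procedure
  repeats with halved blocks down to 100 px. Plus coarse cross-correlation
  placement of bright-field targets against contrast-reversed DAPI and an
  optional rigid mutual-information refinement.
- **Preprocessing** — tissue masking (Otsu), whole-slide standardization over
  tissue statistics, overlapping 256×256 patch extraction, dihedral
  augmentation.
- **Metrics** — whole-patch SSIM and YCbCr percentage differences aggregated
  over 1224×1224 evaluation patches.
- **Synthetic data** — tissue phantoms (nuclei / membranes / cytoplasm) with
  two emulated autofluorescence channels and deterministic per-stain oracle
  renderings, so the whole pipeline is testable with known ground truth.

## Worked example

Compare two oracle stain renderings of the same synthetic section, and
recover a known elastic deformation:

```python
import numpy as np
from microstain.synthetic_data import generate_phantom, oracle_stain, synthetic_warp
from microstain.metrics import evaluate
from microstain.registration import elastic_pyramidal_register

phantom = generate_phantom(seed=0, height=256, width=256)
he = oracle_stain(phantom, "HE")        # uint8 RGB, H&E palette
mt = oracle_stain(phantom, "MT")        # Masson's trichrome palette
report = evaluate(he, mt, patch=128)
for name, (mean, std) in report.summary().items():
    print(f"{name:8s} mean {mean:7.4f}  sd {std:7.4f}  (n={report.n_patches})")

dapi = phantom.channels[..., 0]
warped, truth = synthetic_warp(dapi, seed=7, amplitude=5.0)
field = elastic_pyramidal_register(dapi, warped, min_block=32)
err = np.sqrt(((field.shifts - truth) ** 2).sum(-1))[24:-24, 24:-24]
print(f"mean interior endpoint error: {err.mean():.3f} px")
```

Output:

```
ssim     mean  0.8143  sd  0.0250  (n=4)
y_pct    mean  5.5414  sd  2.8416  (n=4)
cb_pct   mean  2.0144  sd  0.9655  (n=4)
cr_pct   mean  2.3650  sd  1.0885  (n=4)
mean interior endpoint error: 0.308 px
```

The SSIM of 0.81 and Y difference of 5.5% quantify how differently the two
stains render the same structures; the registration recovers a 5-px-amplitude
smooth warp to a third of a pixel.

Command-line equivalents (`microstain simulate | register | train | stain |
evaluate`) cover the same pipeline; `microstain stain --rois annotations.json
--labels labels.yaml` applies micro-structured staining from labelme-style
polygon annotations.

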