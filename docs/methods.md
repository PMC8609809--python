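# Methods

This note documents the models and numerical choices behind `wfcnseg`: a 2D
wavelet filter bank, a synthetic multimodal phantom generator, a two-class
U-Net segmentation network with wavelet-injection paths (WFCN), the Dice-based
metric suite, and the kernel/architecture benchmark harness.

## Wavelet bank

One analysis level of the separable 2D discrete wavelet transform filters an
image along rows and then columns with a low-pass/high-pass pair and
downsamples each output dyadically, producing four half-side subbands:
approximation (LL) and horizontal (LH), vertical (HL) and diagonal (HH)
details. Level *k+1* transforms level *k*'s approximation, so a side-240
input yields approximation sides 120, 60, 30 and 15 after four levels —
precisely the spatial sizes of the encoder feature maps the injected network
consumes. (The tumor-MRI literature this design follows sometimes quotes
250-pixel inputs, but the 120/60/30/15 chain forces a side of 240; the
package standardizes on sides divisible by 2⁴.)

**Boundary handling** is periodic (circular) extension. No padding mode is
canonical for this application; periodization is chosen because it keeps
subband sizes exactly dyadic at every level, makes orthogonal transforms
exactly norm-preserving, and admits exact perfect reconstruction. The
conventions are, for an even-length filter `h` of length `L` on a signal of
even length `N`:

    analysis:   a[n] = Σ_k h[k] · x[(2n + L/2 − k) mod N]
    synthesis:  zero-upsample, circularly convolve with the
                synthesis filters at phase L/2 − 1, and sum

which matches the *periodization* mode of the widely used reference wavelet
software, so coefficients are directly comparable (the test suite asserts
equality to 1e-10).

**Filter provenance.** Analysis low-pass coefficients for `db1`–`db10` and
`sym2`–`sym8`, and the analysis/synthesis low-pass pairs of the biorthogonal
splines `bior1.1/1.3/2.2/3.1/4.4` and `rbio1.1/2.2`, are embedded as static
full-double-precision tables (`_filters.py`); nothing is generated
numerically at run time. High-pass filters follow the quadrature-mirror
relations

    dec_hi[k] = (−1)^(k+1) · rec_lo[k]
    rec_hi[k] = (−1)^k · dec_lo[k]

with `rec_lo = reverse(dec_lo)` for orthogonal kernels. This sign convention
(rather than the equally valid `(−1)^k` variant) is adopted deliberately so
detail-subband signs reproduce the reference implementation exactly.
`haar` is an alias of `db1`.

**Registry scope.** The registry is extensible (`register_kernel`,
JSON round trip) and the benchmark iterates whatever is registered. The
discrete Meyer kernel (`dmey`) is deliberately not registered by default:
its published 62-tap filter is a truncation that is only approximately
orthogonal, with round-trip reconstruction error near 5e-3 — incompatible
with the package-wide perfect-reconstruction guarantee of 1e-8.

**Invariants maintained** (all tested): perfect reconstruction < 1e-8 for
every registered kernel; linearity; dyadic size law (side/2^k at level k);
energy conservation within 1e-8 relative for orthogonal kernels; degenerate
inputs (odd side, side smaller than the filter, indivisible side for the
requested depth) raise dimension errors rather than silently padding.

## Phantom generator

Each phantom is a four-modality (T1, T2, T1C, FLAIR) slice: a bright
elliptical brain (semi-axes 0.82·side/2 and 0.70·side/2) on a dark
background (intensity 0.05), one elliptical tumor with semi-axes drawn
uniformly from `tumor_radius_range` (default 5 %–12.5 % of the side) at a
uniform random position such that the whole tumor fits inside the brain, a
shared smooth background texture (white noise blurred at scale side/8,
peak amplitude 0.06), and independent per-modality Gaussian noise
(default sd 0.03). Default class means (tumor, background) are
T1 (0.30, 0.62), T2 (0.80, 0.45), T1C (0.92, 0.40), FLAIR (0.85, 0.48) —
tumor hyperintense on T2/T1C/FLAIR and hypointense on T1, so the four
channels carry complementary signal as in glioma MRI. The binary mask marks
tumor pixels exactly.

The amplitudes are chosen so the noiseless T1C phantom is *exactly*
separable by thresholding at the midpoint of its class means (tested); this
makes the phantom an honest oracle for the whole pipeline. What the phantom
does **not** emulate: MR physics (bias fields, partial volume, coil
inhomogeneity), anatomy, multi-focal or infiltrative tumors, and the
multi-label tumor substructure of real benchmark data. Tests passing on
phantoms therefore demonstrate that the machinery is correct and that
wavelet injection helps on brightness-contrast tumors; they do not certify
clinical performance.

Datasets derive per-case seeds from a master seed and carry a seeded 80/20
train/validation split. Real data can replace phantoms through the
MetaImage/NIfTI slice readers (min–max normalized to [0, 1]; any nonzero
ground-truth label counts as tumor) — the normalization is this package's
choice, stated here because upstream preprocessing conventions vary.

## WFCN architecture

The base network is a plain U-Net: a stem block at full resolution, four
encoder blocks each preceded by 2×2 max-pooling, and a mirrored decoder
using nearest-neighbour upsampling followed by a 3×3 convolution
("up-convolution"), skip concatenation and a double-convolution block; a
1×1 head yields two-class per-pixel softmax. All convolutions are 3×3
(He-initialized), activations are ReLU, channels double per level from
`base_channels` (default 8 — sized for single-CPU training; increase for
larger studies). There is no batch normalization; at these widths and data
sizes plain SGD-family training is stable without it.

**Injection.** Path *k* concatenates, to the input of encoder block *k*,
the level-*k* wavelet subbands of every input modality (default kernel
`db1`; either all four subbands, the default, or the approximation only).
Subband maps have exactly the block's spatial side, so no resampling is
involved; each injected channel is min–max normalized to [0, 1] to match
the scale of the image channels. Channel-wise concatenation was chosen as
the fusion operator because it is the least invasive option: it widens one
convolution's input and provably changes nothing else — the layer plans of
base and injected variants differ only in that block's input width (tested
structurally and on the instantiated weights). The presets `wfcn1`–`wfcn4`
each activate the single path of the matching level, `base` none; arbitrary
subsets are supported.

The network engine itself is a compact numpy implementation with
hand-written backward passes (im2col convolutions, pooling argmax routing,
block-sum upsampling gradients), verified against float64 central
differences. It is single-threaded-deterministic: the same seed and config
reproduce training bit-for-bit.

**Initialization** is seeded-random. A hook for loading pretrained encoder
weights exists at the checkpoint level (`load_state_dict`), but transfer
learning from classification backbones is out of scope.

## Training and evaluation

Training is seeded mini-batch backpropagation with pixelwise cross-entropy
on the softmax output and the Adam optimizer (default learning rate 1e-3,
batch 8). Optional inverse-class-frequency loss weighting addresses tumor
sparsity; optional early stopping monitors validation Dice with a patience
counter. The canonical protocol length is 100 epochs; the scaled-down runs
in the tests and acceptance script use 30 epochs on 200 side-64 phantoms,
which single-CPU training completes in minutes and which suffices for the
network to reach high held-out Dice on phantoms. Injection maps are
computed once per case before the first epoch and cached — the transform of
a fixed input never changes. The best-validation-Dice weights are
checkpointed and restored after training. Non-finite losses abort with an
error naming the epoch.

Metrics: per-case Dice (mean and population variance), pooled Dice over all
pixels (both conventions are reported because either may be meant by an
aggregate "Dice" figure), pixelwise pooled pixel accuracy, per-class mean
pixel accuracy, sensitivity, specificity, and pixelwise ROC AUC via the
tie-corrected Mann–Whitney rank statistic on pre-argmax tumor
probabilities. Degenerate conventions, all tested: Dice(∅, ∅) = 1 so
perfect prediction on tumor-free slices is not penalized; a class absent
from the ground truth scores 1.0 on its own accuracy; AUC on single-class
ground truth raises an undefined-metric error.

## Benchmark harness

`compare_kernels` decomposes every modality of every slice with every
requested kernel and reports filter length, mean wall time (reported, never
asserted — it is hardware-dependent), and an edge-energy statistic: the
mean absolute level-1 detail coefficient over tumor-boundary pixels
(boundary = mask minus its erosion, at subband resolution), with the
interior statistic as a contrast. Kernels are ranked by boundary edge
energy divided by filter length — a stated, deterministic proxy for the
"edge response per unit cost" trade-off that motivates short kernels such
as `db1`, whose two-tap filter acts like a derivative operator at
intensity steps.

`make_mosaic` produces the 4-column × 5-row panel (columns: modalities,
default order FLAIR, T1C, T2, T1; rows: approximation, horizontal,
vertical, diagonal, ground truth). The two modality orders in circulation —
acquisition order T1, T2, T1C, FLAIR versus the panel-caption order — are
both supported; the caption order is the default. Tiles are min–max scaled;
zero-range tiles (e.g. details of a constant image) render mid-gray by
convention.

`run_injection_experiment` enforces a fair-comparison contract: within one
experiment, every architecture sees bit-identical phantom data, split and
seed schedule, so held-out Dice differences are attributable to the
architecture alone. The report has one row per architecture (Dice mean and
variance pooled over the held-out cases of all seeds) with per-seed means
retained, a hash of the full experiment config, and a failure record that
lets the remaining architectures complete if one run errors.

## Scale of the shipped experiments

Full-scale training of this family of models on real multimodal benchmark
data is a GPU-scale undertaking; this package's experiments are desk-scale
analogs on phantoms (side 64, 200 cases, 30 epochs, `base_channels` 8) that
exercise the identical code path end to end. Reported numbers from
`scripts/acceptance.py` are therefore phantom-scale results, not
reproductions of published benchmark scores.

## Known limitations

- The phantom's simplicity means segmentation is learnable with small
  models; architecture rankings on phantoms need not transfer to real data.
- The numpy engine targets clarity and determinism, not throughput; it is
  single-threaded GEMM-bound and has no GPU path.
- Only binary (whole-tumor) segmentation is implemented; multi-class tumor
  substructure is out of scope.
- `dmey` and very long kernels are excluded from the default registry or
  limited by the requirement that the image side be at least the filter
  length at every decomposition level.
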