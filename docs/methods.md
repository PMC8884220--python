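# Methods

## Scope and data model

`edofuse` fuses brightfield z-stacks into extended-depth-of-field (EDoF)
images. A stack (`ZStack`) is an ordered array of D RGB planes (index 0 is
the shallowest; plane *i* sits at *i*·`axial_step` µm), with an explicit
declared pixel range — `(0, 1)` float or `(0, 255)` 8-bit — carried on the
object so the mapping onto the network's tanh range is never re-inferred.
Stacks are read and written as plain multi-page TIFF (page order = axial
order); proprietary microscope formats, stitching and stage metadata are out
of scope.

Acquisition geometry helpers implement the thin-specimen sampling
arithmetic: depth of field DoF = λ/NA² and required plane count
Np = ⌈St·NA²/(2λ)⌉ for a slab of thickness St. For green light (λ = 0.53 µm)
and a 100x/1.4 NA objective, DoF ≈ 0.27 µm and a 3.5 µm smear needs 7
planes. These are the printed formulas; some vendors quote a ~2x larger
practical DoF using a different convention, which we do not model.

Pre-processing: white balancing divides each plane, per channel, by the
empty-field reference normalised to its per-channel spatial mean
(flat-field style). The mean normalisation makes the operation invariant to
uniform per-channel exposure of the reference and the identity for uniform
references; zero reference pixels are clamped to a small epsilon with a
warning. Axial undersampling is emulated by `decimate_stack`, which keeps
every k-th plane *starting from the k-th*, so D' = ⌊D/k⌋: a 14-plane 0.5 µm
stack becomes 7 planes at 1 µm (k = 2) or 3 planes at 2 µm (k = 4), and a
7-plane stack becomes 3 planes at k = 2. (Starting from the first plane
instead would give ⌈D/k⌉ = 4 planes at k = 4, inconsistent with those
counts.)

## Wavelet multi-scale-decomposition fusion

The classical route and the source of training targets. Each plane is
decomposed with a separable DWT (`pywt`, symmetric extension; images are
padded to a multiple of 2^levels and cropped back). At every detail band the
fused coefficient is taken from the plane maximising an activity criterion —
either |coefficient| or its 3x3 local energy (default) — with ties going to
the lowest plane index; the coarsest approximation band is the pixelwise
mean across planes. A majority-vote consistency filter (window radius 1 by
default, ties keep the original label) smooths the plane-selection maps to
suppress isolated mis-selections. In the default `luminance_guided` colour
mode the selection maps are computed once on Rec.709 luminance and applied
identically to all three channels, avoiding colour fringing at selection
boundaries.

Defaults: `sym4` wavelet, 4 levels (capped at the wavelet's maximum useful
level for small images), local-energy selection, radius-1 consistency,
luminance-guided colour. The wavelet family is pluggable; nothing in the
package depends on a specific choice beyond ≥4 vanishing moments and near
symmetry. Perfect reconstruction of the transform holds to < 1e-8, so a
stack of identical planes fuses to that plane to machine precision.

Known behaviour: coefficient max-selection is noise-seeking. In flat
regions it picks the largest noise coefficient across planes, so with
additive noise the fused image can score *below* a mildly defocused single
plane against a noise-free reference (defocus blur suppresses noise). This
is the documented weakness of content-agnostic MSD fusion that motivates
the learned route; the fusion-usefulness property (fused beats every single
plane) is therefore asserted on noise-free, depth-diverse scenes where it
isolates the depth-fusion effect.

## Fusion network

Architecture (all convolutions 3x3 unless stated):

- **Encoder** E₂D: NL stride-2 convolution stages with leaky-ReLU (slope
  0.2), channels 3 → Ed/2^(NL−1) → … → Ed, output
  W/2^NL × H/2^NL × Ed. The same encoder weights are applied to every
  plane, so the parameter count is independent of D and one model fuses
  stacks of any depth.
- **Residual blocks** ℜ₂D: `n_res_blocks` = 5 channel-preserving blocks,
  each x + conv(lrelu(conv(x))).
- **Fusion**: elementwise maximum across the plane axis (ties to the lowest
  plane index), making the output exactly invariant to plane order.
- **Decoder** C₂D: NL transposed convolutions (kernel 4, stride 2, pad 1 —
  exact 2x upsampling) with leaky-ReLU between stages, final tanh to
  (−1, 1); channels Ed → … → 3.

Inputs are mapped linearly from their declared range to [−1, 1] to match
the tanh output; targets are mapped identically before the loss. At
inference, stacks with sizes not divisible by 2^NL are padded symmetrically
and cropped back, and outputs are unmapped to [0, 1].

The full-scale defaults are NL = 2, 256-px patches, batch 2, Adam with
learning rate 1e-4 and loss weights λ = (1.0, 0.1, 0.5). The encoder depth
Ed defaults to 64 and is configuration.

**Loss.** l = λ₁·l_MAE + λ₂·l_SSIM + λ₃·l_FFT, computed in network space
([−1, 1]):

- l_MAE: mean |output − target| over pixels and channels.
- l_SSIM: 1 − mean SSIM with the standard 11x11 Gaussian window (σ = 1.5),
  K₁ = 0.01, K₂ = 0.03, data range 2, valid windows only. The 1 − SSIM form
  makes the term non-negative and zero at the optimum.
- l_FFT: mean over all frequency bins and channels of the modulus of the
  *complex* difference of the unnormalised 2-D DFTs. Operating on the
  complex difference (not the difference of moduli) penalises phase errors
  and vanishes iff the images are equal; its gradient is the bin-phase
  back-projection (H·W/M)·Re(ifft2(F/|F|)).

**Autodiff.** The network runs on a purpose-built numpy reverse-mode engine
(`edofuse.nn.autograd`): strided conv / transposed conv (im2col forward,
exact adjoints), leaky-ReLU, tanh, |·| (subgradient 0 at 0), broadcasted
arithmetic, max-over-axis with argmax routing (ties to the lowest index),
fixed-kernel valid correlation whose adjoint is the full convolution (for
the SSIM window), and the spectral term above. All gradients are verified
against central differences in the test suite to ~1e-8. Everything is
float64 and fully deterministic: one master seed derives initialisation
(He-normal), pair order and crop positions, so identical seeds give
identical loss histories.

**Training.** Random co-located patch crops across all planes and the
target; Adam (β = 0.9/0.999, ε = 1e-8) with global gradient-norm clipping
at 1.0. The final decoder layer is initialised at 0.1x the He scale so the
tanh starts in its linear regime — without these two stabilisers, short
high-learning-rate runs can collapse into a saturated-output local minimum
for some initialisations. A non-finite loss aborts with a diagnostic.
Checkpoints store parameters plus the full configuration in one npz
archive.

## Similarity metrics

- **SSIM**: windowed formula with the original defaults (11x11 Gaussian,
  σ = 1.5, K₁ = 0.01, K₂ = 0.03), mean over all complete windows, computed
  on Rec.709 luminance in [0, 1]. Verified against both a per-window
  brute-force oracle (≤1e-7) and scikit-image's implementation.
- **Pearson correlation**: over flattened luminance; undefined (NaN with a
  warning) for constant images.
- **HaarPSI**: per its defining reference — 2x2-mean subsampling, Haar
  magnitudes at scales 1–2 for local similarity in two orientations, scale-3
  magnitudes as weights, logistic mapping with C = 30 and sharpening
  exponent α = 4.2 on the [0, 255] scale; colour images add the YIQ chroma
  mean-similarity channel. Whether the source analyses used luminance or
  RGB is unreported; this package computes SSIM/CORR on luminance and
  HaarPSI on RGB (its native colour definition).

## Synthetic blood-film simulator

Scenes place non-overlapping objects at uniform random depths inside the
slab [0, St]: erythrocyte-like pale annuli with central pallor (radius
3.5–4 µm), parasite-like dark-violet rings with an off-centre chromatin dot
(1–1.5 µm), leukocyte-like lobed textured blobs (4.5–6 µm), and dark dust
specks — all sizes in pixels via the pixel pitch (default 0.065 µm/px, from
the nominal field-of-view arithmetic of a 100x large-format camera).
Parasites may overlap erythrocytes (ring stages sit on cells); other class
pairs are kept apart. Objects are rendered as premultiplied colour + alpha
patches and composited opaquely over the background — adequate for thin
smears where cells rarely stack.

Defocus uses a Gaussian PSF: sigma(dz) = sigma0 + slope·|dz| with
sigma0 = 0.8 px and slope = 1.5 px/µm at the nominal pitch. This is not a
physical Airy/defocus kernel; it reproduces the statistical structure
fusion needs (per-object sharpness maximal at the nearest plane, monotone
decay with axial distance), which the test suite asserts. Additive Gaussian
read noise (default σ = 0.01 of full scale) is applied per plane; Poisson
shot noise and optical aberrations are out of scope. The paired
all-in-focus reference renders every object at sigma0, noise-free.

`make_dataset` renders fully sampled stacks, computes their wavelet-EDoF
targets, and decimates the inputs — the triplet (undersampled stack,
target, reference) that drives training and evaluation. Presets: `tbf`
(14 planes x 0.5 µm, St = 6.5 µm), `pbs` (7 x 0.5 µm, St = 3 µm), and
`desk` (the pbs geometry on a 160 px field: one erythrocyte, two parasites,
one dust speck — roughly the areal cell density of a thin film at this
field size).

What passing synthetic tests does **not** show: robustness to staining
variation, optical aberrations, shot noise, overlapping cells, or real
textures; the simulator establishes correctness of the machinery and the
qualitative undersampled-fusion result, not clinical performance.

## The desk-scale benchmark

`edofuse.experiments.desk_benchmark` is the scaled-down core experiment:
50 desk-preset stacks (40 train / 10 test), inputs decimated k = 2 (7 → 3
planes, 1 µm step), network NL = 2, Ed = 16, 64-px patches, batch 2, 500
Adam steps. Short runs use learning rate 1e-3 — ten times the full-scale
default, which is tuned for long training on large data and is still far
from convergence after 500 steps at this scale. The trained network is
scored against the all-in-focus reference on the held-out stacks alongside
wavelet fusion of the same undersampled stacks (typical means: SSIM ≈ 0.99
vs ≈ 0.94). These problem sizes are the package's standard quick-experiment
configuration; the full-scale settings (256-px patches, lr 1e-4, hundreds
of stacks) remain the defaults of `FusionNetConfig`.

## Numerical choices and edge cases

- Decimation requires 1 ≤ k ≤ D; k = 1 is the identity.
- Wavelet fusion of a D = 1 stack returns the plane; levels are capped by
  the wavelet's maximum useful level for the image size.
- Consistency filter ties (non-unique majority) keep the original label;
  windows are clipped at borders.
- Coefficient-selection ties go to the lowest plane index (deterministic).
- max-fusion gradient routes entirely to the first maximal plane on exact
  ties.
- SSIM losses require images at least as large as the 11-px window.
- normalize → denormalize round-trips to <1e-6; integer TIFF round-trips
  are bit-exact.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; no global state.

## Known limitations

- The wavelet baseline is a documented stand-in for complex-wavelet MSD
  implementations; it does not claim numerical equivalence to any specific
  published implementation.
- Pure-numpy training is practical at desk scale (≈60 ms/step on one CPU
  for the small configuration) but not for 256-px patches on large
  datasets.
- HaarPSI on heavily saturated synthetic images compresses toward its upper
  range more slowly than SSIM; cross-metric magnitudes are not comparable.
- The simulator's opaque compositing under-represents overlapping cells in
  thick films.
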