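# Methods

## Problem setting

MRI acquires samples of the 2D Fourier transform of a slice (k-space),
one `k_y` line per readout. The acquisition is corrupted in practice:
the subject moves between line readouts, sensor noise contaminates every
sample, and scans are deliberately undersampled to save time. The
classical reconstruction — the inverse DFT of whatever was measured —
converts each local k-space defect into a global image artifact.
`jointmri` implements network layers that process *both* representations
at every depth, the simulators that produce the three corruption
processes, and the data-consistency machinery used for undersampled
reconstruction, all runnable on synthetic phantoms with no external data.

## Fourier conventions

All transforms are centered (DC at index `(H//2, W//2)`) and orthonormal
(`1/sqrt(HW)` in both directions). Orthonormal scaling makes Parseval's
identity exact and keeps feature magnitudes comparable between spaces,
which matters because the network streams are mixed additively. Complex
rasters are carried as interleaved real channel pairs `(re0, im0, re1,
im1, ...)`; the per-pair DFT of a feature stack is unitary, so
backpropagation through it applies the inverse transform to the incoming
gradient.

## Joint layers

Two variants couple a frequency stream `u` and an image stream `v`:

* **Interleaved**: learned scalar mixing coefficients `s(alpha), s(beta)`
  (sigmoid-squashed logits, initialized to 0.5) blend each stream with
  the (inverse) DFT of the other, then each stream applies batch norm, a
  3×3 convolution, a space-specific activation, and a residual add of the
  2-channel network input. Saturating the mixing recovers a pure
  frequency-space or pure image-space network exactly, which the tests
  assert bit-for-bit.
* **Alternating**: each layer convolves in frequency space, hops to image
  space through the inverse DFT (residual added before the transform,
  following the layer definition's parenthesization), convolves there,
  and hops back.

The image-space activation is ReLU per real channel. The frequency-space
activation must grow in magnitude for inputs of *both* signs (k-space
values are large and signed, and ReLU would discard half of them); it is
the odd, strictly increasing piecewise-linear map

    sigma(x) = x            for |x| <= 1/2
    sigma(x) = 2x - 1/2     for x > 1/2
    sigma(x) = 2x + 1/2     for x < -1/2.

An alternative composition sometimes written for this activation,
`x + ReLU(x - 1/2) + ReLU(-x + 1/2)`, evaluates to the constant 1/2 on
the whole half-line x ≤ 1/2 — neither odd nor increasing — so the
package uses the three-piece form above and keeps the literal
composition available (`freq_activation_literal`) as a pluggable
alternative for comparison. The residual add of the 2-channel input onto
64-channel features tiles the input across the 32 complex channel pairs,
preserving the skip connection for every feature pair without adding
parameters.

Convolutions are zero-padded 'same' (a periodic mode exists for
shift-equivariance testing). Batch normalization acts per channel on each
convolution's *input*, with trainable scale and shift; inference mode
uses running statistics (momentum 0.9, eps 1e-5).

## Architectures and parameter accounting

The default networks stack 10 joint layers (3×3 kernels, 64 features)
followed by one final 3×3 convolution down to 2 channels; the
single-space ablations (`frequency`, `image`) use 20 convolutions to
match the joint networks' convolution count. Counting convolution
weights and biases, batch-norm scale/shift, and mixing logits — and
excluding BN running statistics — gives exactly 670,622 trainable
parameters for Interleaved and 706,438 for Alternating, Frequency and
Image. The final convolution must be 3×3 for these totals to come out;
1×1 would fall 1,024 short. Weights are He-normal initialized, biases
zero, mixing logits zero.

## Corruption simulators

* **Rigid motion**: pose parameters `(dx, dy, phi)` are piecewise
  constant over line acquisitions; `ceil(gamma_m * n_lines)` change
  points are placed uniformly without replacement, each new state drawn
  uniformly from ±8 px translations and ±11° rotations (deliberately
  extreme motion; `gamma_m = 0.03` by default). Lines before the first
  change point keep the identity pose, so the target image is the
  reference pose; each state holds from its change line up to (and
  excluding) the next. Each corrupted line is the corresponding line of
  the DFT of the transformed image; one transform + DFT is computed per
  distinct state. The transform translates then rotates the sampling
  coordinates about the image center pixel `(H//2, W//2)` with bilinear
  interpolation and zero fill. Bilinear interpolation is the
  tolerance-limiting component: pure integer translations are validated
  against the exact phase-ramp theorem at 1e-8, while rotation
  cross-checks in k-space hold to about 2e-2 on spectrally smooth images
  and degrade on off-center content whose k-space phase oscillates
  faster than the resampling grid.
* **Noise**: i.i.d. complex Gaussian, `eps1 + j*eps2`, each component
  `N(0, sigma^2)` per k-space sample (the Rician magnitude model). The
  default `sigma = 0.25` in normalized signal units is chosen so that a
  unit-peak phantom acquires an aggressively noisy magnitude image
  (signal-to-noise on the order of 1.5), mirroring the heavy-noise
  regime the networks are meant to handle.
* **Undersampling**: per-`k_y`-line masks. `random` keeps
  `floor(gamma_s * width)` lines uniformly with no low-frequency bias
  (default 25%, i.e. 4x acceleration); the equispaced schemes keep a
  contiguous central band (8% or 4% of lines, rounded to an even count so
  the band is symmetric about DC) plus every 4th or 8th outer line; the
  combined motion+undersampling task keeps the full central 8% band plus
  random outer lines to reach 25% overall.

Each training pair is normalized by the peak magnitude of the corrupted
zero-filled reconstruction, applied to both the corrupted k-space and
the target image.

## Data consistency and unrolled reconstruction

Acquired lines are exact samples of the desired output, so `hard`
consistency copies them verbatim (idempotent, bit-exact). The soft
update solves `argmin_x ||M F x - b||^2 + lam ||x - z||^2`; single coil
the problem decouples per k-space coefficient with closed form
`x = F^-1[(M b + lam F z) / (M + lam)]`, and a conjugate-gradient solver
(also covering coil-sensitivity-weighted operators) matches it to 1e-5.
The unrolled network repeats K = 5 blocks of (shared regularizer,
analytical DC update) from the zero-filled initialization; `lam` is a
trainable scalar initialized to 0.05 and clamped positive. Because the
DC update scales the acquired-line residual of the regularizer output by
`lam/(1+lam) < 1`, the residual after the final solve never exceeds the
pre-DC residual and grows monotonically with `lam` — the tests assert
this closed-form direction.

## Training

Losses: L1 on real/imaginary channels in image space or k-space, their
joint combination (image + 0.1 × frequency; under the orthonormal DFT
the k-space L1 of typical slices runs an order of magnitude larger than
the image-space L1, so 0.1 puts the two terms on comparable scales — the
weight is exposed as a config knob), L2,
and negated SSIM / multiscale SSIM / PSNR on magnitude images. All
losses are differentiable on the package's autodiff tape and
finite-difference checked; the differentiable SSIM mirrors the reference
implementation (11×11 Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03,
population covariances, data range = ground-truth peak magnitude) and
matches `skimage.metrics.structural_similarity` to machine precision.
MS-SSIM uses the standard 5-scale weights, truncating scales (and
renormalizing weights) when the image is too small and clamping the
per-scale contrast-structure means at 1e-6 before the fractional powers.
Optimization is Adam at learning rate 0.001 by default; training is
deterministic given the seed, aborts on NaN loss, supports exact resume
from a returned state, and can stop early on a validation-SSIM plateau
(patience 10, off by default).

## Synthetic phantoms

Phantoms superpose 5–12 random ellipses (random centers, semi-axes
0.08–0.5 of the half-width, rotations, intensities 0.2–1), rescaled to
unit peak magnitude over a zero background, with a random low-order
polynomial phase (coefficients ±1.5 rad) so the images are genuinely
complex and exercise conjugate-asymmetric code paths; a `real` flag
restores the Hermitian-symmetric regime. Default size 64×64 — a
desk-scale resolution at which CPU training is feasible. What phantoms
do *not* emulate: MR tissue contrast, anatomical texture, coil noise
correlation, k-space zero-padding of clinical archives. Passing tests
therefore certify the mechanics (simulators, layers, optimization,
metrics) and qualitative trends, not clinical reconstruction quality.

## Desk-scale training benchmark

The training property suite runs on 200 undersampled 64×64 phantoms
(random 25% masks, fixed seed). At this scale the package uses a reduced
Interleaved network (3 joint layers × 16 features), learning rate 0.01
and batch size 16 — the full-scale 10×64 network at learning rate 0.001 needs
thousands of optimizer steps to leave its initialization, which is far
beyond a 20-epoch CPU budget, and the reduced configuration reaches a
test-set SSIM clearly above the zero-filled baseline within 20 epochs
while the loss decreases monotonically over the first epochs for all
four architectures. A scaled-down trend comparison (joint vs.
image-space networks over 3 seeds at reduced epochs) is reported
alongside, without a hard assertion: at these sizes the variance between
seeds is comparable to the gap between architectures.

## Numerical choices

* float64 throughout the autodiff core (oracle tests at 1e-6..1e-12).
* `|.|` in magnitude losses uses `sqrt(re^2 + im^2 + 1e-16)` to keep the
  gradient finite at exact zeros; the L1 losses use the sign
  subgradient with value 0 at the origin.
* PSNR of identical pairs reports a finite 300 dB sentinel.
* Correlation maps mark zero-variance pixels (below 1e-10 of the data
  scale, which absorbs the roundoff of the mean) as NaN.
* CG data-consistency solves run to a 1e-12 relative tolerance, max 500
  iterations.

## Known limitations

Single-coil formulation is primary (coil sensitivity maps are supported
only through the CG path); no interslice or non-rigid motion; no colored
noise; no non-Cartesian sampling; bilinear interpolation bounds the
fidelity of rotational motion simulation; the desk-scale benchmark
demonstrates trends, not full-scale reconstruction quality.
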