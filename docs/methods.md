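# Methods

`mpnrage` reconstructs multicontrast inversion-recovery radial MRI and
estimates quantitative T1 maps from the result. This note records the
models the package implements, the parameters that matter, the numerical
choices made where several were defensible, and what the synthetic test
bed does and does not establish about real data.

## Signal model

One acquisition block is an adiabatic inversion pulse followed by a
spoiled gradient-echo train of `n_views_per_block` small-flip readouts
at repetition time `TR`, then a free recovery delay `TD`. Every readout
after the inversion carries its own effective inversion time, so a block
samples the whole recovery curve once. The longitudinal magnetization
follows the standard Look-Locker recursion (equilibrium normalized to
1):

```
inversion:  Mz <- -eff * Mz
view n:     s_n = m0 * Mz * sin(b1 * alpha_n)
            Mz <- Mz * cos(b1 * alpha_n)
            Mz <- 1 + (Mz - 1) * exp(-TR / T1)
recovery:   Mz <- 1 + (Mz - 1) * exp(-TD / T1)
```

Assumptions: perfect spoiling (no transverse coherence between
readouts), an instantaneous inversion whose imperfection is summarized
by the scalar efficiency `eff` in [0, 1], and no off-resonance or slice
profile effects. The first readout of each block is discarded (spoiling
is still incomplete right after the inversion), so a 385-view block
yields 384 contrasts.

Because every step of a block is affine in `Mz`, the periodic steady
state over blocks is computed in closed form as the fixed point of the
block map (two broadcast passes per parameter set) rather than by
iterating blocks to tolerance; the two agree to machine precision and
the closed form is what makes dictionary construction over thousands of
parameter combinations cheap.

Reference timing: TR = 4.88 ms, 385 views per block (flip 4 deg for the
first 304 views, 8 deg for the last 81 — the high-flip tail is what
makes B1 and inversion efficiency separable from T1), inversion pulse
12 ms, TD = 503.5 ms; 224 blocks then take 536.3 s, i.e. about 9
minutes.

## Temporal subspace

A dictionary of steady-state signal shapes is simulated on a grid of
(T1, B1, efficiency): by default T1 log-spaced 100–5000 ms (60 points),
B1 0.8–1.2 (5), efficiency 0.7–1.0 (4), 1200 atoms. The rank-16 left
singular subspace of the (contrasts x atoms) matrix captures every atom
to a relative residual below 1e-6, so the image series can be modeled as
`eta = U V` with 16 spatial coefficient images `U` and the fixed
orthonormal temporal basis `V`.

## Sampling and operators

Spokes are full diameters through k-space center, readout-oversampled
at 2 samples per pixel, with coordinates in Nyquist-normalized
cycles/pixel. Two view orderings are provided: golden-angle
(111.24611 deg increments in 2D; a two-golden-mean spiral phyllotaxis in
3D) and a pseudorandom bit-reversed interleave on a uniform base comb.
The interleave assigns view `v` of block `b` to base spoke
`(v*B + bitrev(b)*V) mod (B*V)`; when `gcd(V, B) = 1` this is a
bijection onto the uniform full set, any prefix of blocks is
near-uniform, and — the property retrospective undersampling needs —
the spokes of a fixed view across the first `m` blocks are near-uniform
too (for `m` a power of two they are exactly uniform). Non-power-of-two
block counts fall back to a coprime-stride permutation with a warning.

The NUFFT is Kaiser-Bessel gridding: oversampling 2.0, kernel width 7,
Beatty shape parameter, numerically integrated deapodization. The
interpolation is stored as gather indices + weights, so the adjoint is
the exact transpose (adjoint identity at machine precision) and the
forward matches a direct discrete Fourier sum to ~1e-6 on small grids.
Width 7 was chosen because width 4 at this oversampling leaves ~1e-3
aliasing error, far above the 1e-5 accuracy the operator tests demand.

Density compensation is the radial area weight `|k|^(d-1)` with a
center floor of `dr/8` (2D) or `dr^2/24` (3D) — each spoke contributes
one exact-center sample, and without the small shared floor those
duplicates dominate the DC term and brighten broad objects by tens of
percent. Weights are scaled so the point-spread function of the
density-compensated adjoint has unit transfer at k = 0 (sum of the PSF,
not its peak: the peak also absorbs the unsampled-corner deficit of
radial coverage and would bias the in-band gain by ~27%).

Multicoil data are compressed to 4 virtual coils by PCA of the sample
matrix; the sensitivities are projected with the same components, which
keeps the forward model exactly consistent. K-space is normalized so
the composite (all-view) gridded image has unit peak before any
reconstruction.

## Deep factor model

The image at normalized inversion time `tau` in [0, 1] is the output of
a conditional CNN applied to a fixed input `gamma`: the eight TI-binned
zero-filled volumes, fed as 16 real channels. A three-layer MLP
(1 -> 64 -> 64 -> 64, leaky-ReLU 0.1) maps `tau` to 64 gains that
modulate the CNN's two hidden feature blocks channelwise (FiLM-style);
the CNN is three convolutions (16 -> 32 -> 32 -> 2, kernel 3 per axis,
Tanh after the first modulated block, leaky-ReLU 0.2 after the second),
and the two output channels form the complex image. In the reference 3D
configuration this is exactly 51,714 trainable parameters. Convolutions
zero-pad by 1 to preserve the grid so the output aligns with the
forward operator.

Training is single-shot and self-supervised: minimize the k-space
data-consistency residual of the scan being reconstructed, one TI
subgroup at a time (render the subgroup's central-`tau` image, compare
against all the subgroup's measured views), with Adam and a temporal
annealing schedule that refines the subgroup count over stages. Weights
carry across stages (and across matrix sizes in 3D-style schedules,
since parameter count is resolution-independent). Transfer learning
runs only the final stage starting from another scan's weights.

Desk-scale optimization choices (all of them matter at a ~270-step
budget and are no-ops for the model itself):

* **Density-weighted residual.** The training loss weights each sample
  by its calibrated density-compensation weight. On consistent data
  this is a reweighted least squares with the same minimizer, but it
  preconditions the normal operator toward the identity; without it the
  heavily oversampled k-space center dominates every gradient and the
  model learns only low frequencies in any reasonable step budget.
* **Minibatched subgroup steps.** The per-contrast stage aggregates two
  subgroups per Adam step. This halves the number of updates per epoch
  and therefore doubles the data passes available inside a fixed
  optimizer-step budget, besides averaging down gradient noise.
* **EMA rendering.** The final stage keeps an exponential moving
  average (decay 0.9) of the weights and renders from it, removing most
  of the residual SGD jitter.
* **Initialization.** He-normal convolutions; the MLP's first-layer
  bias is drawn at scale 0.5 and the gain-layer bias starts at 1 — the
  raw scalar input makes the gains collapse to exactly zero at
  `tau = 0` otherwise, which silences the network for early inversion
  times.
* **Schedule.** Stage 1: 8 subgroups, 4 epochs, lr 5e-3 (decay 0.2 at
  epoch 3). Stage 2: 48 subgroups, 10 epochs, batch 2, lr 2e-3 (decay
  at epoch 7), reduce-on-plateau (factor 0.5, patience 3) and early
  stop after 6 epochs without 0.1% relative improvement. 272 optimizer
  steps total.

## Baselines

All four baselines share the same normalized k-space and the same
rank-16 temporal basis and differ only in how the spatial factors `U`
are regularized: (1) a deep-image-prior CNN on the zero-filled factor
estimate (three convolutions, 32 channels throughout, 83,040 parameters
in 3D, trained with the same annealing schedule); (2) conjugate
gradients on the Tikhonov normal equations, lambda = 1e-3, 30
iterations by default; (3) FISTA with orthogonal Daubechies-4
(periodized, 3 levels, complex magnitude soft-thresholding),
lambda = 2e-4, step from 12 power iterations, monotone restart; (4) the
density-compensated zero-filled back-projection `U = A^H(b) V^H` with no
reconstruction at all, relying on the regularized multipass fit
downstream. Methods 1–3 use the raw (uncompensated) adjoint inside
their normal equations; Method 4 and the Method-1 network input use the
density-compensated adjoint, which is the better-conditioned zero-filled
estimate. Non-dyadic grids reduce the wavelet depth (identity transform
in the worst case).

## Quantitative fitting

Each voxel's complex series is fit with `s = m0 * s_hat(T1, B1, eff)`
where `s_hat` is the real signal shape and `m0` a complex scale solved
in closed form at every step. Initialization is an exhaustive
dictionary search with the per-atom optimal scale; refinement is
bounded trust-region least squares over the free shape parameters (T1
in [50, 6000] ms, B1 in [0.5, 1.5], efficiency in [0, 1]). On
noiseless model-generated signals the fit recovers T1 to well under
0.5% with residuals at solver tolerance.

The multipass variant used with zero-filled inputs: pass 1 fits all
four unknowns; pass 2 Gaussian-smooths B1 (sigma 3 voxels, normalized
convolution restricted to the support) and refits with B1 fixed; pass 3
smooths the efficiency within tissue labels only (never across tissue
boundaries) and refits with both fixed; finally the T1 map is lightly
TV-denoised, the weight calibrated by bisection so the within-region T1
standard deviation drops by about 5% (weight 0 disables the pass). The
smoothing widths are configuration, not physics.

ROI analysis mimics vial-phantom practice: a centered disk of 6 mm
radius per vial (at the desk voxel size of 4 mm this is a handful of
voxels), reporting mean, standard deviation, and percent error against
the known value.

## The synthetic test bed

The desk-scale study conditions, frozen in
`phantom.standard_desk_acquisition`: 2D 64x64 grid, six vials with T1
log-spaced 300–2000 ms in a bath, a 49-view block (48 contrasts) with
TR stretched by 385/49 so the readout train still spans the ~1.9 s
recovery window of the full protocol, 128 inversion blocks of
pseudorandom-interleaved spokes (128 spokes per contrast — Nyquist
at this grid), 8 Gaussian-lobe coils compressed to 4 virtual coils, and
complex Gaussian noise with standard deviation 0.5% of the peak k-space
magnitude (a visually clean but not noise-free regime; zero-filled
images show clear noise at 4x undersampling). Retrospective 4x
acceleration keeps the first 32 blocks. A 2D setting keeps every
algorithmic property testable at interactive cost; the 3D code paths
(kernels, orderings, operators) exist and are exercised on small grids.

What passing tests show: operator and solver correctness against
brute-force oracles, exact architecture/timing arithmetic, inverse-crime
parameter recovery through the full pipeline, and the *relative*
ordering of the reconstruction methods under these conditions. What
they do not show: performance on real scanner data — the simulator has
no B0/eddy-current trajectory errors, no motion, no slice profile or
magnetization-transfer effects, piecewise-constant anatomy rather than
texture, and known (simulated) sensitivities rather than estimated
ones. Absolute PSNR values here also sit close to the radial
band-limit of a sharp-edged digital phantom and should not be compared
against in-vivo figures.

## Degenerate inputs and tie-breaks

All-zero voxels are flagged as background rather than fit; empty TI
bins grid to zero volumes with a warning; a trajectory with all samples
at k = 0 is rejected; dictionary grid-search ties break to the lowest
atom index; `tau` outside [0, 1] is clamped with a warning; CG returns
its best iterate with a warning if the residual tolerance is not met;
training aborts with stage/epoch context if the loss goes non-finite.
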