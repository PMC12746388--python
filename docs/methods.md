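# Methods

## Signal model and simulation

A gradient-echo train with repetition time TR applies identical excitations
(flip angle alpha) whose RF phases follow the quadratic schedule
`phi(n) = phi(n-1) + n*theta` (equivalently
`phi(n) = phi(0) + theta*n(n+1)/2` mod 360).  The unbalanced spoiler
gradient at the end of each TR dephases intravoxel magnetization by one full
cycle, so the measured steady state is a superposition of FID, spin-echo and
stimulated-echo pathways.  Two simulation routes are implemented and
cross-validated against each other:

* **Isochromat ensemble** (`simulate_steady_state_isochromat`): N spins with
  spoiler phases uniformly spaced over [0, 2 pi) per TR, evolved with exact
  3x3 Bloch rotations (Rodrigues form) and exponential relaxation.  The
  reference route; default N = 1000.
* **Extended phase graph** (`simulate_steady_state_epg`): configuration
  states F(k), Z(k) on the full dephasing-order axis, truncated at k_max
  (default 128).  The production route, used everywhere else in the package;
  it agrees with the isochromat route to better than 1e-3 relative over
  theta in {0, 1.5, 4, 117} deg, T2 from 0.11 ms (bone-like) to 2000 ms
  (CSF-like).  Both routes were additionally validated to machine precision
  against the closed-form unbalanced-SSFP steady state at theta = 0
  (Hanicke/Freeman-Hill form), which is an independent analytic oracle.

Conventions and assumptions:

* RF pulses are instantaneous; excitation-efficiency loss for sub-millisecond
  T2 species is out of scope.  Off-resonance is zero by default, so the two
  echoes differ exactly by `exp(-dTE/T2)` and the normalized echo
  subtraction equals `tanh(dTE/(2 T2))` for every RF increment — the
  property that makes bone imaging insensitive to the phase schedule.
* The receiver is demodulated by the excitation phase of the acquiring pulse
  plus 90 degrees, so an ideally spoiled on-resonance signal is real and
  positive.  With this convention the T2-encoded phase starts at zero,
  flipping the sign of theta conjugates the signal exactly, and contrast
  extraction needs no global phase bookkeeping.  (Some receiver convention
  must be fixed; without demodulation by the pulse phase the phase encoding
  is destroyed.)
* Steady state is declared when the demodulated signal changes by less than
  1e-8 relative between pulses, capped at 5000 pulses.  CSF-like T1 (4 s) at
  TR 5.5 ms does not fully settle within the cap; the simulator returns the
  last value with a convergence flag and warning.  The residual transient is
  below the tolerances of every downstream consumer.
* Default sequence parameters are the head protocol: TR 5.5 ms,
  TE (80 us, 2.38 ms), flip 24 deg, theta +/-1.5 deg.

### Known deviation from the ideal-spoiling folklore

At theta = 117 deg the steady-state magnitude is commonly equated with the
Ernst (ideally spoiled) value.  Without diffusion this is only approximate:
at flip 24 deg, TR 5.5 ms, T1 1000 ms, T2 80 ms both simulation routes give
a magnitude 8.3% below the Ernst value — a real property of quadratic RF
spoiling at flip angles far above the Ernst angle, not a numerical artifact
(the two independent routes agree to 3e-10 and match the theta = 0 closed
form to machine precision).  Similarly, the 117-degree signal *phase* is not
perfectly flat versus T2: the residual coherence leaves a non-monotonic
excursion of ~0.38 rad over T2 in [10, 2000] ms at flip 24 deg (it drops to
0.05 rad at flip 10 deg).  The package's declared flatness tolerance is
0.5 rad at the default flip; "flat" is to be read relative to the
deliberate small-theta encoding, which spans several times more phase and is
strictly monotonic in T2.

## Phantom and study conditions

The default fixture is a concentric head-like 2D/3D phantom: outer fat ring,
cortical-bone shell (T1 300 ms, T2 0.35 ms, proton density 0.2 — the
collagen-bound bone-water pool), gray-matter ribbon, white-matter interior
with seeded CSF pockets, air outside.  Relaxation values are representative
3 T brain numbers (WM 800/70 ms, GM 1300/90 ms, CSF 4000/2000 ms, fat
380/110 ms).  The bone shell is deliberately several voxels wide even at the
default 64x64 test grid so that class-mean metrics are not pure
partial-volume noise.  Everything (phantom, coil maps, background phase,
noise) is a pure function of (config, seed).

Coil sensitivities are synthetic smooth Gaussian lobes with random linear
phases — a stand-in for calibrated maps; estimating maps from data is out of
scope.  The background phase is a seeded low-order polynomial plus filtered
noise, scaled to a chosen maximum amplitude (default pi/3) and shared by
both passes — the model's key assumption.  Noise is i.i.d. complex Gaussian
per k-space sample and coil with sigma = peak image magnitude / SNR
(default SNR 30); with the package's unitary Fourier convention that equals
the image-domain peak SNR of a fully sampled single-coil scan.

What the generator does **not** emulate: anatomical geometry, B0/B1
inhomogeneity beyond a smooth phase, motion, flow, eddy currents, fat
chemical shift, coil noise correlations.  Passing tests therefore
demonstrate the correctness of the signal model, encoding and inversion
machinery — not robustness to those real-world effects.

## Encoding

The forward model per coil is a unitary centered (N)DFT of the
sensitivity-weighted image, sampled on the trajectory; coordinates are in
cycles/sample with components in [-0.5, 0.5].  Fully sampled Cartesian
encoding is an exact FFT.  Non-Cartesian sampling uses a Kaiser-Bessel
gridding NUFFT (oversampling 2.0, kernel width 8, Beatty beta, analytic
sinh-form deapodization); measured accuracy against a direct DFT is ~1e-7
relative, inside the declared 1e-6.  The adjoint is exact (same kernel,
conjugate spreading), verified by inner-product identities.

Radial trajectories are center-out with golden-angle ordering (111.246 deg
in 2D; the two-angle generalized golden means on the sphere in 3D) and a
ramp-up readout: radius quadratic over the ramp fraction of samples, linear
afterwards, continuous in value and slope, reaching |k| = 0.5 at the last
sample.  Because spoke m depends only on m, any prefix of a longer scan *is*
the shorter scan (nesting), which is what enables retrospective scan-time
reduction.  Density compensation (ramp |k|^(d-1) times local radial spacing)
is provided for adjoint previews only, never inside iterative solvers.

## Reconstruction

Unregularized: conjugate gradients on the normal equations `A^H A x = A^H y`
per dataset.  The tracked residual is the data-consistency norm `||Ax - y||`
(monotone for CG on the normal equations), obtained free of extra operator
applications from `||Ax-y||^2 = ||y||^2 - Re<x, b + r>`.

Joint: the four (echo, pass) images are coupled only by a joint-L0 wavelet
penalty — at each coefficient location the root-sum-of-squares across the
four images is hard-thresholded, so all four share one support (this is what
preserves thin bone in the subtraction).  With threshold zero the problem
decouples and is solved exactly by four CG solves.  With a positive
threshold a fixed-iteration primal-dual (PDHG) scheme is run with the joint
hard threshold as the (nonconvex) proximal step, warm-started from the CG
solutions; an optional diagonal k-space preconditioner (inverse sample
density on the dual step) accelerates convergence on radial data and is on
by default.  Because the objective is nonconvex and iterations are capped,
algorithmic variants are only expected to agree to a declared solver
tolerance of 0.1 relative NRMSE between iterates with matching data
fidelity.  Wavelet default: Daubechies-4, 3 levels, periodized; threshold
default: 0.01 x the maximum coefficient RSS of the density-compensated
adjoint images.  All iteration counts are configuration, not convergence
guarantees.

## Background phase, extraction, bone

The pass product `x_+ x_- = exp(2 i phi) |x|^2` yields
`phi = angle(x_+ x_-)/2` on the principal half-angle branch (-pi/2, pi/2];
voxels whose product magnitude is below 1e-6 of the maximum are masked and
counted.  (A printed form of this estimator that conjugates the negative
pass is algebraically inconsistent with the two-pass forward model — it
yields x^2 instead of exp(2 i phi)|x|^2 — so the product form is used.)
The combination `x = (x_+ e^{-i phi} + conj(x_- e^{-i phi}))/2` recovers the
multi-contrast image up to a per-voxel sign tied to the half-angle branch;
extraction `x_psi = |Re(x e^{i psi})|` carries an absolute value precisely
so that this sign, and the pi-periodicity in psi, are harmless.  Independent
pass noise averages down by 2x in variance.

Bone maps operate on magnitudes (insensitive to residual phase): the direct
ratio with a denominator floor of 1e-6 x peak, and the weighted
least-squares variant `min_u ||W^(1/2)((|x_U|+|x_C|) u - (|x_U|-|x_C|))||^2`
with W = Hanning-smoothed |x_U - x_C| (width 5), solved by CG from zero with
early termination (default 10 iterations).  The system is voxelwise
diagonal; the weights steer CG convergence so that air voxels stay near the
zero initialization — early termination is the suppression mechanism, not a
shortcut.  Contrast extraction defaults to the CTE image and the pipeline's
default bone method is WLS.

## Resolution ceiling on the bone class mean

Voxelwise, the bone value is `tanh(2.3/0.7) ~ 0.995` and the package
verifies it to 1e-6.  Through any *imaging* chain, however, the bone shell
is a dim structure (UTE magnitude ~0.011, CTE ~2e-5) flanked by bright soft
tissue (~0.07): point-spread leakage of a few percent of the neighbors into
the shell inflates |x_CTE| to ~3e-3 and caps the *class-mean* normalized
subtraction well below the voxelwise value.  The ceiling is a property of
the bandlimit, not the solver: applying the ideal disc bandlimit directly to
the noiseless ideal images gives mean xs over bone of ~0.41 at 64^2, ~0.63
at 128^2, ~0.66 at 192^2 (k-space apodization makes it worse — a wider PSF
mixes in more neighbor signal).  High bone specificity of the class mean
therefore requires the bone structure to be thick relative to the PSF,
i.e. fine grids (the in-vivo protocol uses 1 mm^3 over a 280^3 matrix).
Desk-scale runs should read the bone map through its contrast with soft
tissue (mean xs in soft tissue stays ~0.015, and WLS suppresses air by more
than an order of magnitude relative to the direct ratio under noise), not
through the absolute class mean.

## Default problem sizes

Tests and the acceptance script run 2D at 48-64 voxels per side with a
200-spoke (~Nyquist) golden-angle acquisition, 4 coils and peak SNR 30, and
exercise the 3D path once at 32^3 with 120 spokes; these sizes were chosen
as the package's desk-scale defaults.  The pipeline scales to larger grids
unchanged.

## Known limitations

* No diffusion damping of coherence pathways; spoiling quality at large
  theta is therefore slightly pessimistic relative to tissue.
* Background-phase recovery is principal-branch only (|phi| < pi/2); no
  unwrapping.
* The joint-L0 solver has no convergence theory; results are reported at
  fixed iteration counts.
* The 3D golden-means scheme is one of several reasonable uniform center-out
  orderings; only the nesting property is contractual.
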