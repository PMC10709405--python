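# Methods

## Forward model

The acquisition is parallel-beam: a slice `x` (n x n, values in [0, 1],
support restricted to the inscribed circle) maps to a sinogram `b` of line
integrals at each rotation angle.  The discrete Radon operator is built
once per geometry as a scipy CSR matrix using Joseph's method: every ray is
traversed along the image axis it is most aligned with, the image is
sampled by linear interpolation between the two pixels adjacent to the ray
at each step, and samples are weighted by the path length per step,
`1/max(|cos phi|, |sin phi|)`.  Materialising the matrix makes the adjoint
(unfiltered backprojection) its exact transpose, so the inner-product
identity `<Ax, y> = <x, A^T y>` holds to machine precision — a property the
conjugate-gradient solver and the training gradients rely on.  Pixels
outside the inscribed circle are excluded from the operator and forced to
zero in every image; all metrics are evaluated inside the circle.

Conventions: pixel and detector-bin centres sit on an integer grid centred
on the geometric image centre `(n-1)/2`; angle 0 projects along image
columns and the detector coordinate of a pixel at centred position (x, y)
under angle phi is `t = x cos(phi) + y sin(phi)`.  (scikit-image's `radon`
agrees with this operator to ~0.3% once its opposite rotation sense and its
`n//2` rotation centre are accounted for; the cross-check is in the test
suite.)  Acquisitions cover the full turn (e.g. 720 angles at 0.5°), so
each ray is measured twice; FBP averages the redundancy.

Angular undersampling at acceleration factor R keeps
`floor(n_angles_full / R)` equispaced indices starting from a (optionally
random) initial index, rounded to the nearest grid position with ties
toward the smaller index.  Zero-padding masks zero the discarded sinogram
rows while retaining the array shape; by linearity, backprojecting a masked
sinogram equals backprojecting the retained rows with the subset operator.
Note one quirk of equispaced subsets of a 360° scan: when the retained
count is odd the two half-turns interleave, doubling the number of distinct
ray directions, so reconstruction quality is not strictly monotone in R.

## Filtered backprojection

Per-row frequency-domain filtering (rows zero-padded to the next power of
two, ramp filter `2|f|` normalised to 1 at Nyquist; Shepp-Logan and Hann
apodisations available) followed by the adjoint and scaling by
`pi / (2 n_angles)`, which is amplitude-correct for uniformly spaced angles
spanning either 180° or 360°.  On the 100x100 Shepp-Logan phantom with 720
angles this inverts the forward projection to ~28.6 dB inside the circle.

## Centre-of-rotation correction

A rotation axis off the detector centre shifts every projection and
produces "double wall" artefacts.  The correction rigidly shifts the
sinogram along the detector axis (linear interpolation, zero fill) over a
grid (default ±10 px in 0.5 px steps) and keeps the shift maximising the
intensity variance of the reconstruction inside the circle — misalignment
blurs the reconstruction and blur lowers variance.  FBP is the default
scoring reconstruction (the unfiltered adjoint is available); variance is
computed on the FBP image because the blur penalty is sharpest there.  Ties
break toward the smallest |shift|.  On noiseless phantoms with injected
shifts in [-8, 8] px the injected value is recovered within one grid step
in ≥95% of cases.  The benchmark keeps a clearance of the maximal expected
misalignment between the object and the field-of-view rim, as a real
acquisition must: a shift that pushes the sample off the detector truncates
signal no correction can restore, and the truncation itself biases the
variance score toward smaller shifts.

## The unrolled reconstructor

K iterations (default 8) alternate

1. data consistency: `x_k = (A^T A + lambda I)^{-1} (A^T b + lambda z_{k-1})`,
   solved by conjugate gradients (default tol 1e-6, 30 iterations), then
   min–max rescaled to [0, 1] over the inscribed circle;
2. denoising: `z_k = D_theta(x_k) = x_k - N_theta(x_k)`.

`z_0` is the normalised unfiltered backprojection, and the output is the
final data-consistency iterate `x_K` (the denoiser therefore sits between
consecutive DC blocks; with K=0 the initialisation is returned).  The
internal normalisation exists because the Radon operator is far from
unitary: without it the iterate magnitude drifts across iterations and
gradients explode or vanish.  Min–max over the circle was chosen because it
matches the [0, 1] convention of the training images; a constant image
passes through unchanged.  The same rule normalises the FBP training
targets.

`N_theta` stacks N_L (default 8) 3x3 convolution layers: 1 -> n_filters
(ReLU), interior layers n_filters -> n_filters (batch norm then ReLU;
conv -> BN -> ReLU ordering), final layer n_filters -> 1 with no ReLU so
negative noise patterns are not truncated.  Weights are He-normal
initialised, shared across all K iterations, and `lambda` is parameterised
as `exp(rho)` with `rho` trainable (init 0.05), which keeps the DC system
positive definite throughout training.  The default configuration (N_L=8,
64 filters, batch norm, learnable lambda) has 223,554 trainable parameters.

### Differentiation

The package includes a small reverse-mode autodiff engine on numpy arrays
(`tomodl.grad`): channels-last tensors, im2col/BLAS convolutions, batch
normalisation (batch statistics in training, running averages at
inference), ReLU, a min–max normalisation differentiated by subgradients at
the extrema, and the CG solve differentiated through the implicit-function
identity — with `M = A^T A + lambda I` and `s = M^{-1} g`, the backward
pass is `dL/dz = lambda s`, `dL/d(A^T b) = s`, `dL/dlambda = s·(z - x)`,
i.e. one extra CG solve per DC block.  The implicit form was preferred over
backpropagating through the CG loop because it is exact at convergence,
costs half the memory, and keeps the loop implementation free of tape
bookkeeping.  Finite-difference checks of the full unrolled map pass at
1e-3 relative; the checks are run with biases perturbed off zero, since at
exactly zero whole flat regions of the input sit on the ReLU kink where
central differences straddle the two one-sided derivatives.

## Training

Training pairs couple the normalised `A^T b` of a zero-pad-masked sinogram
(random initial angle per slice, drawn from the run's seeded generator)
with the FBP reconstruction of the same slice's fully sampled sinogram.
The loss is the MSE between `x_K` and the reference (batch-mean for
optimisation; the summed form is also exposed).  Optimisation uses Adam
(default lr 1e-4 over 50 epochs; batch size 5), best weights selected by
validation MSE over a seeded 80/20 slice-level split.  Cross-validation
partitions volumes — never slices — across folds (12 volumes, 4 folds:
9 train / 3 test each).  One network is trained per acceleration factor.
A NaN loss aborts with a diagnostic rather than continuing.

## Baselines

**TwIST** minimises `||Ax - b||^2 + lambda_tv TV(x)` (isotropic TV, forward
differences, zero-gradient boundary; default lambda_tv 0.01) with the
two-step iterative shrinkage recursion.  The operator is rescaled by its
spectral norm (30 power iterations) so the normal-operator spectrum lies in
(0, 1]; the over-relaxation parameters follow the standard recipe from the
assumed spectral bounds (xi_min 1e-3 for the severely ill-posed subset
operators), and a monotone safeguard falls back to the plain IST step
whenever the two-step update would increase the objective.  The TV proximal
step is Chambolle's dual projection (20 inner iterations, step 0.125, the
stability bound of the discrete Laplacian).  Stopping: relative objective
change below 1e-5 or max_iter (default 200).

**FBP / unfiltered backprojection** reuse the forward-model module at the
retained angles.

## Evaluation

PSNR is `10 log10(data_range^2 / MSE)` inside the circle with data_range 1
(images are [0, 1]-normalised); identical images report a 100 dB cap.  SSIM
uses an 11x11 Gaussian window (sigma 1.5, K1=0.01, K2=0.03, sample
covariance), averaged over the circle eroded by the 5-pixel filter radius;
it matches scikit-image's implementation to <1e-6 on the shared region.
Benchmarks score every (method, R, slice) against the fully sampled FBP
reconstruction as the reference image — the convention a real instrument
without ground truth forces — and optionally against the phantom itself.

## Synthetic data

Phantoms are either the Shepp-Logan head phantom resampled to the requested
size or seeded random-ellipse scenes (centres uniform in a 0.8-radius disk,
semi-axes 3–30% of the side, orientations uniform, intensities additive
then clipped to [0, 1]) mimicking overlapping organ cross-sections.  The
acquisition protocol follows a full turn at 0.5° (720 projections) with
optional additive Gaussian noise (sigma = level x max) or Poisson noise
(peak photon count `1/level^2`) and a known injected centre-of-rotation
shift.  The generator emulates the geometry and sampling of real
transmission OPT but not its optics: no refraction, depth of field,
scattering, registration jitter between slices, or intensity drift.
Passing tests therefore demonstrate correctness of the algorithms under the
stated forward model, not robustness to those instrument effects.

## Scaled experiment sizes

The benchmark experiments (`tomodl.experiments`) run at sizes chosen for a
single CPU: training uses 200 random-ellipse slices at 64x64 with the full
720-angle protocol at R=20, a K=4 / N_L=4 / 32-filter network, Adam at
lr 1e-3 for 20 epochs with batch 5, and CG relaxed to tol 1e-5 / 10
iterations inside the unroll (the DC systems are warm enough that further
CG refinement does not change the training signal).  Held-out evaluation
uses 20 fresh phantoms.  Under these conditions the trained model exceeds
36-projection FBP by several dB PSNR and a wide SSIM margin; most of that
gap is contributed by the data-consistency structure itself, with training
of the denoiser adding refinement on top — consistent with the motivation
for building the physics into the network rather than learning a direct
inverse.

## Known limitations

- Parallel-beam geometry only; one global centre-of-rotation shift per
  volume (no tilted-axis correction).
- The interpolating projector has a small angular anisotropy (~0.2–0.5%
  in projection values), visible as edge-bin differences between angles for
  binary objects.
- Batch-norm running statistics are updated whenever the denoiser runs in
  training mode, including inside the unrolled loop; inference always uses
  the stored averages.
- The numpy engine is single-threaded BLAS-bound; training beyond ~10^3
  slices or 128x128 images is impractical without a GPU operator backend
  behind the `ForwardModel` contract.
- The U-Net post-processing baseline is not included; the benchmark
  compares the unrolled method against FBP, unfiltered backprojection and
  TwIST-TV.
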