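# Methods

This note documents the models, algorithms and numerical choices behind
`sosvn`: pulse-echo speed-of-sound (SoS) image reconstruction with an
unrolled variational network (VN), posterior sampling by Monte Carlo Dropout
(MCD) and Bayesian Variational Inference (BVI), and the use of the resulting
uncertainty maps to select one acquisition among several repeats.

## Imaging model

Pulse-echo SoS imaging tracks apparent speckle displacements between frames
beamformed from different virtual-source (VS) transmits.  A local deviation
of the slowness `x` (inverse SoS, s/mm) from the beamforming slowness
`x0 = 1/c0` shifts an echo by the path integral of the deviation along the
round-trip propagation path; tracking between a *pair* of transmits senses
the difference of the two round-trip integrals.  Stacking the discretized
differential path integrals of all pairs gives a sparse matrix `L` (entries
in mm), so that measured time delays are `d = L x + noise` (seconds).

Geometry conventions:

* grid `(n_ax, n_lat)` with the aperture at the top edge, pixel centers at
  `(i + 0.5) * pitch`; the default full-scale grid is 84 axial x 64 lateral
  pixels (0.5 x 0.6 mm pitch), the default sequence 17 VS transmits paired
  with index offset 2, giving 15 displacement maps.
* virtual sources sit 25 mm behind the aperture, laterally placed so the
  central ray crosses the aperture center at the steering angle; default
  angles are evenly spaced over +-20 degrees.
* rays are straight (refraction-free) and truncated at the field-of-view
  boundary; per-pixel traversal lengths are computed exactly (Siddon-style
  edge crossing), which the test suite verifies against a fine-step
  ray-marching integrator.

Straight rays are the single largest modeling simplification; bent-ray or
full-wave propagation, element-level delays and learned operator calibration
are out of scope.

## Inverse problem and analytical baseline

Reconstruction solves

    x_hat = argmin_x || L x - d ||_p + lambda * TV_eps(x),

with the total-variation prior expressed through lateral/axial difference
filters and every l1 term smoothed as `sqrt(t^2 + eps)` so LBFGS applies
(`scipy.optimize.minimize(method="L-BFGS-B")` with the analytic gradient).
The SoS map is `c = 1 / (x + x0)`.

The problem is nondimensionalized before optimization: measurements are
scaled by `d_unit = max|d|` and slowness by `x_unit = d_unit / sigma_max(L)`
(largest singular value, computed once by sparse SVD with a fixed start
vector so results are bit-reproducible).  `lambda` is therefore
dimensionless; the default `lambda = 0.002` was chosen by an L-curve-style
sweep of the mean test-set RMSE on the synthetic test preset (the sweep is
reproducible from the package; 0.002 minimized RMSE among
{0, 0.001, ..., 0.01, 0.02, 0.05}).  Initialization is `x = 0` (i.e. `c =
c0`); non-convergence within the iteration budget sets a flag on the result
rather than raising.

## Variational network

The VN unrolls K gradient-descent steps with learnable data and
regularization terms:

    x_k = x_{k-1} - [ (s_k L)^T psi_k( s_k (L x_{k-1} - d) )
                      + sum_j rbar_k^j * ( w_k^j . phi_k^j( r_k^j * x_{k-1} ) ) ]

* `r_k^j`: convolution kernels (o x o); `rbar` is the flipped kernel, and the
  adjoint identity `<r*a, b> = <a, rbar*b>` holds exactly for the zero-padded
  "same" convolution used (unit-tested, even and odd kernel sizes).
* `w_k^j`: per-pixel prior weights.  The standalone regularization weight of
  the plain gradient-descent view is absorbed into `w` (it is redundant with
  a learnable per-pixel weight).
* `phi`, `psi`: continuous piecewise-linear functions parameterized by
  control-point ordinates on fixed uniform knots in [-1, 1], clamped outside.
  Responses are mapped into the knot interval by per-filter scales
  (`out = scale * f(v / scale)`, so the identity parameterization is exact).
* `s_k`: per-pair data weights (one scalar per displacement map; a per-pixel
  variant is deliberately not the default).

Response-scale calibration: `psi` scales are set from the running max of the
data residual along the initial forward trajectory (the residual is largest
at the zero start); `phi` scales from filter responses of the ground-truth
maps of the first batch (responses grow toward converged-map magnitude
during training), both times a 1.5 safety margin.  Calibrating `phi` on the
initial trajectory instead leaves roughly half of the responses clamped
after training, which measurably degrades reconstruction quality.

Normalization: the operator is rescaled to unit spectral norm and slowness /
measurement arrays by dataset-derived units (`x_unit` = std of ground-truth
slowness deviations; `d_unit = sigma_max(L) * x_unit`), so all responses,
parameters and optimizer steps are O(1) although physical slowness
deviations are ~1e-8 s/mm.

Initialization: the first two priors start as axial/lateral difference
kernels and `phi`/`psi` as identities, so the untrained network is already a
plain TV-regularized gradient-descent scheme; a dedicated test pins this
limit against a hand-rolled descent loop (agreement to 1e-8 over K=10
steps).  Remaining kernels start as small zero-mean Gaussian draws (zero
mean is enforced at initialization only, not projected during training).

Training minimizes the exponentially layer-weighted L1 loss

    sum_k exp(-tau (K - k)) ||x_k - x*||_1
      + lambda_r * sum sqrt((y_{j-1} - 2 y_j + y_{j+1})^2 + eps)

(the second term keeps the control-point curves smooth) by mini-batch ADAM
with a cosine-annealed learning rate.  Gradients are computed by a
hand-written reverse-mode pass through the unrolled recursion — the full
backward pass is verified against central finite differences for every
parameter family — and the convolution machinery is batched: one einsum over
sliding windows covers a whole mini-batch, or a whole stack of posterior
samples with per-sample kernels.  Training is deterministic given the seed;
a non-finite loss aborts with the last finite checkpoint attached.

## Uncertainty estimation

**MCD** draws independent Bernoulli(1 - p) keep-masks over the regularizer
filters (default p = 0.25, per-filter granularity: a dropped filter removes
its entire prior component on that side; analysis and synthesis masks are
independent; per-element masks are available by config).  No 1/(1-p)
rescaling is applied — the masked update is used as written, which deviates
from standard inverted dropout and is documented as such.  The MCD network
is trained from scratch *with* the same per-filter dropout active (gradients
chain through the masks; verified by finite differences): dropout posterior
sampling presumes a dropout-trained network, and with only 6 priors per
layer, masking a dropout-naive network removes a large fraction of its
learned regularizer — its posterior mean was ~70% worse than the
deterministic reconstruction.  At desk scale the dropout network also gets
two extra unrolled layers and a 4/3 iteration budget (dropout removes
expected capacity and slows convergence); with that compensation its
posterior mean comes within a few percent of the deterministic VN's
reconstruction RMSE.

**BVI** learns a Gaussian posterior over the concatenated filter
coefficients, `N(mu, Sigma)` with `Sigma = D D^T` and `D` block-diagonal
lower-triangular (one o^2 x o^2 block per filter; filters mutually
uncorrelated).  Samples are `mu + D y`, `y ~ N(0, I)`.  The KL divergence
toward the isotropic prior `N(mu, alpha^{-1} I)` reduces (dropping
constants) to

    KL ~ alpha * tr(D D^T) - 2 * tr(log D),

evaluated without forming `Sigma` or any determinant; the identity
`2 tr(log D) = log det(D D^T)` is pinned against a dense log-determinant
oracle.  Training adds `beta * KL` to the VN loss, draws one reparameterized
filter sample per forward pass per batch element, initializes `mu ~ N(0,
1e-4)` and the factor diagonal Uniform(0.9, 1.1), and keeps the diagonal
positive by optimizing its logarithm (off-diagonal entries unconstrained).
Non-filter parameters are trained jointly as point estimates; defaults
`alpha = 0.1`, `beta = 10`, kernel size `o = 8` at full scale.

At desk scale the cold start (random means, unit-scale covariance) cannot
work: with a few thousand iterations instead of ~1e5, the unit covariance
keeps sampled filters in the unstable regime of the unrolled recursion (the
loss rises and samples diverge for any KL weight tried over two orders of
magnitude).  The scaled-down protocol (`experiments.train_bvi_scaled`)
therefore warm-starts the posterior mean at the trained deterministic
filters — the standard practice of initializing variational inference at a
point estimate — initializes the factor diagonal at 0.02 (about 10% of the
filter scale), uses `beta = 0.1`, a 5e-3 learning rate and half the
deterministic iteration budget.  Under this protocol the loss decreases,
the covariance settles at an interior equilibrium (median diagonal ~0.16),
and all posterior samples are finite.  `train_bvi` itself keeps the
full-scale initialization as its default.

Either scheme is sampled S times (default S = 100); the per-pixel sample
mean is the reconstruction and the ddof-1 standard deviation the
uncertainty map.

## Frame selection

For each acquired frame, the uncertainty map is reduced to the mean over the
operator-annotated inclusion and the mean over the 5 mm ring around it
(morphological dilation with an axis-aligned rectangular structuring element
of half-width `ceil(5 mm / pitch)` per axis, minus the inclusion; the
rectangle makes pixel counts exactly testable, a disc is available).  The
*relative* uncertainty is the absolute difference of the two means.  Policy
SI_rel selects the frame minimizing relative uncertainty, SI_inc the frame
minimizing inclusion uncertainty; baselines are the first frame (S1), third
frame (S3) and a uniformly random frame (SR).  Ties break to the lowest
index; informed selection is permutation-equivariant.

The synthetic selection experiments score frames with the MCD posterior of
the dropout-trained network.  A central desk-scale finding, stated plainly:
**in this simulation family, posterior uncertainty does not flag corrupted
acquisitions.**  For the dropout-naive VN and the warm-started BVI
posterior, uncertainty on heavily corrupted frames is systematically
*lower* than on clean frames — weight-perturbation spread scales with the
reconstructed lesion amplitude, severe corruption suppresses the lesion,
and the corruption artifacts are data-term driven and insensitive to the
filters — so uncertainty-minimizing selection anti-selects (clean-frame hit
rates 0.11-0.19 against the 0.25 chance level).  Dropout-*trained*
ensembles can show the opposite, informative behavior (hit rates up to
~0.36, which clears the 99% binomial bound over 200 cases), but whether a
given trained instance carries the signal depends on the training seed:
identical protocols produced an informative ensemble at one seed (hit rate
0.365, and an informed-vs-random cohort AUC advantage of ~5 points) and an
anti-selecting one at another (hit rate 0.18).  The desk-scale conclusion
is therefore instability, not presence or absence: the
uncertainty-corruption association is not a robust property of these small
dropout ensembles.  Whether full-scale posteriors (120k iterations, 16
priors, finer grids) track corruption reliably is an open question that
desk-scale training cannot settle.

## Evaluation

The diagnosis statistic is the SoS contrast `delta_c = |median(c_inc) -
median(c_ring)|` with the same 5 mm ring; carcinoma (CA) is the positive
class, assumed to show the larger contrast.  Classification is summarized by
ROC/AUC (rank statistic, ties at half credit — equal to exhaustive
concordant-pair counting, which is how it is tested), F1, and
sensitivity/specificity at the operating point maximizing their sum (ties
resolve to the lower threshold; predictions there use `score >= threshold`).
Group differences use the two-sided Wilcoxon rank-sum test: the null is
enumerated exactly over rank assignments (midranks for ties) for combined
n <= 12, and a tie-corrected normal approximation is used otherwise.
Reconstruction accuracy against ground truth uses pixelwise RMSE in m/s.

## Synthetic data

The generator emulates the study conditions: single-inclusion phantoms built
from random ellipses whose boundary radius is modulated by a periodic
Gaussian-filtered random field; half of the inclusions are low-pass filtered
to smooth edges; 5% of samples are inclusion-free; the background SoS varies
uniformly over 1490-1540 m/s between samples and the signed inclusion
contrast is drawn from +-(10-60) m/s (plausible for breast tissue; both
configurable).  Measurements are simulated on an `hr_factor = 2` finer grid
with an independently built high-resolution operator plus i.i.d. Gaussian
noise, then block-averaged to the coarse grid — the reconstruction operator
is never the operator that generated the data (inverse-crime guard; the
generator refuses `hr_factor < 2`).  The default noise std (3.4e-9 s at the
fine grid) makes the displacement SNR of a 40 m/s contrast phantom about
20 dB after downsampling.

Multi-frame lesion cases simulate repeated acquisitions of one phantom.
Corrupted frames get their noise std multiplied by `corruption_scale` plus a
smooth random displacement offset (hand/body-motion surrogate) of std
`(corruption_scale - 1) * noise_std`, so `corruption_scale = 1` is exactly
the null case of exchangeable frames.  Synthetic cohorts label a case CA
when the inclusion contrast magnitude exceeds 35 m/s, so the two classes are
contrast-separable by construction; cohort lesions are additionally confined
to the shallow-to-mid depth window (0.2-0.55 of the axial extent) because
the limited-angle geometry loses essentially all contrast sensitivity below
~60% depth — a cohort with deep lesions is unclassifiable from *any* frame,
clean or corrupted, and cannot probe frame selection.

A caveat worth stating plainly: the advantage of informed over random
selection in this simulation is fragile.  The median-based contrast is
robust to the broad artifacts our corruption model produces, so a corrupted
frame's contrast is largely a common shrinkage of the clean one — and AUC
is invariant under common scaling — while the dominant contrast-estimate
spread comes from lesion-geometry-dependent recovery, which is
frame-independent.  Whether informed selection beats random selection on
the cohort therefore depends on how much rank-disrupting noise corruption
adds for a particular trained reconstructor and on whether that instance's
uncertainty is informative (see the selection section): across study seeds
the comparison swings from a clear informed-selection advantage to a tie or
worse.  In vivo, corruption presumably disrupts ranking through mechanisms
(anatomy shifts, mask misregistration, tracking outliers) outside the
noise-plus-smooth-offset surrogate.

What the generator does **not** model: full-wave propagation (aberration,
multiple scattering), RF speckle and displacement-tracking errors,
depth-dependent SNR, anatomical background texture, multiple inclusions, or
frame-to-frame viewing-direction changes (all frames share one ground
truth).  Passing tests therefore demonstrate internal consistency of the
method under its own forward model with realistic noise — not clinical
performance.

## Scaled-down study conditions

Full-scale training (120k iterations, GPU, 84 x 64 grid) is replaced by a
CPU-sized preset used across the tests and the acceptance script, as the
package's own study conditions:

* grid 28 x 20 (1.5 x 2.0 mm pitch, ~42 x 40 mm field of view), 9 transmits
  / 7 pairs;
* VN with K = 8 layers, 6 priors of 5 x 5 kernels, 13 knots; the MCD
  variant K = 10 with a 4/3 iteration budget (see above);
* 500 ray-based training samples, 32 test samples; ADAM, batch 8,
  cosine-annealed lr 1e-2, 3000 iterations;
* posterior sample counts reduced to 25 (test-set RMSE) and 32 (frame
  selection experiments); the config default remains S = 100.

The paper-scale geometry (84 x 64, 17 transmits) and architecture defaults
(K = 10, 16 priors, o = 8, 31 knots) remain the package defaults for
full-scale use.

## Known limitations

* The straight-ray operator ignores refraction; real displacement maps also
  contain tracking failures that the Gaussian-noise model does not mimic.
* MCD uncertainty reflects only filter removal; BVI restricts the posterior
  to the filters — neither captures data-term or weight uncertainty.
* At desk scale the BVI covariance is balanced against a much smaller data
  term than at paper scale, so the absolute uncertainty magnitudes are not
  comparable to full-scale training, only their spatial structure and
  ranking are exercised.
* The synthetic cohorts make CA/FA separable by construction; cohort AUCs
  quantify how much frame corruption and selection policy degrade or
  preserve that separability, nothing about in vivo discrimination.
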