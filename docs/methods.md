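# Methods

## Problem

A renal contrast-enhanced CT (CECT) exam acquires four co-registered images
of the same slice at different times after contrast injection: pre-contrast,
corticomedullary (~30-40 s), nephrographic (~100 s) and excretory (5-10 min).
When one phase is missing (motion artifact, protocol deviation), it must be
inferred from the other three.  Because several plausible images are
consistent with the observed phases, the package treats imputation as
sampling from the conditional distribution P(x | y) of the complete
sequence x given the observed data, rather than as a point prediction.

## Model

Sequences are treated as random vectors.  A conditional Wasserstein GAN is
trained on pairs (x, y), where x is a complete 4-phase sequence and y is x
with one phase j removed and refilled by a linear reconstructor R^j
(pixel-shared affine map of the three observed phases, fitted by least
squares on the training split; one model per j).  The generator
G(z, y) maps a latent vector z ~ N(0, I) and the filled sequence y to a
complete sequence; the critic D(x, y) scores joint pairs.  Training solves

    min_G max_D  E[ D(x, y) - D(G(z, y), y) ]  -  lambda_gp * GP(D)

where GP is the two-sided gradient penalty E[(||grad_xhat D(xhat, y)|| - 1)^2]
on random interpolates xhat between real and generated sequences, a soft
form of the 1-Lipschitz constraint under which the optimum minimizes the
mean (over y) Wasserstein-1 distance between the true and generated
conditionals.

At inference, S latent draws produce an ensemble of complete sequences; the
pixel-wise mean of the missing phase is the best guess, the pixel-wise
standard deviation the uncertainty map (population convention, divide by S —
the literal empirical average of (x - xbar)^2).  The total SD (summed over
pixels) screens imputations: an image is labelled acceptable when its NMSE
against the truth is at or below 0.1 (ties inclusive), and the ROC treats
"acceptable" as the positive class with score -total_sd.

## Architecture

The generator is a U-Net over the 4-channel sequence built from dense
blocks DB(k, n): n sub-blocks of normalization -> activation -> 3x3
convolution with concatenative connectivity, k growth features in all but
the last sub-block.  Down blocks coarsen resolution by p (strided
convolution) and multiply channels by q; Up blocks do the reverse
(nearest-neighbour upsample + convolution) and concatenate skip features.
The latent vector enters at every scale of both branches through
conditional instance normalization (CIN): each channel is instance-
normalized, then scaled and shifted by affine functions gamma(z), beta(z).
An outer skip connection adds the U-Net output to y, so the network learns
a residual perturbation Delta(y, z) — with small final-layer weights the
untrained generator starts at the linear fill.  The critic shares the
dense-block downsampling trunk with layer normalization (no latent input)
and ends in a fully connected head with one scalar output.  The pix2pix
baseline uses the same pair of networks but no latent input, batch
normalization instead of CIN, and adds lambda_l1 * E||G(y) - x||_1 to the
generator objective; it is deterministic by construction.

All networks run on a small numpy reverse-mode autodiff engine written for
this package (`phasegan.autodiff` / `phasegan.nn`).  Every
vector-Jacobian product is itself built from differentiable primitives, so
the gradient penalty (a function of the critic's input gradient) can be
differentiated again with respect to the critic parameters.  Convolution is
im2col (`unfold`/`fold`, an adjoint pair), and parameters default to
float32 for speed; gradient-accuracy tests run the same layers at float64.

## Synthetic phantoms

Real renal CECT cohorts cannot be redistributed, so training and evaluation
use 2-D phantoms (`phasegan.phantom`) with the statistical structure the
method relies on: nested elliptical compartments (soft tissue, renal
cortex, medulla, pelvis/calyx, tumor) following distinct enhancement curves
over the four phases on a pseudo-Hounsfield scale.  Defaults (all
config-exposed, values in pseudo-HU):

* base curves — cortex peaks corticomedullary (185), medulla nephrographic
  (135), pelvis excretory (330); soft tissue enhances mildly (35→60-70);
  tumors are solid-enhancing (peak 115), fat-density (~ -95, flat) or
  cystic-septated (fluid ~15 with enhancing septa), drawn 50/25/25;
* per-subject contrast-amplitude factors exp(N(0, sigma_p)) on each
  post-contrast phase's enhancement (shared component sd 0.10; phase
  components sd 0.20 / 0.12 / 0.30 for corticomedullary / nephrographic /
  excretory), emulating injection-timing and dose variability.  This is the
  low-dimensional, genuinely irreducible ambiguity the posterior should
  spread over, and it makes the corticomedullary and excretory phases the
  hardest to impute — mirroring where timing variability acts in practice;
* additive per-compartment enhancement jitter (sd 10) and i.i.d. Gaussian
  pixel noise with a per-subject level drawn uniformly from 20-160,
  spanning standard-dose to very noisy acquisitions.  The wide noise range
  is deliberate: the noisiest subjects carry an irreducible NMSE floor well
  above the 0.1 acceptability threshold, so every cohort contains clearly
  unacceptable imputations alongside easy ones — the two classes the
  total-SD screening experiment requires.

Preprocessing matches the clinical pipeline: clip to [-150, 1000] HU, map
affinely to [-1, 1], optional augmentation (rotations by +/-10, 20, 30
degrees and 4 axis shifts, at most 11 variants, identical transform on all
four phases; shift magnitude 5% of the image side — a choice that preserves
the tumor-centred crop; bilinear interpolation with background padding at
-1).  Each subject contributes all four decimations, so K complete
sequences yield M = 4K training pairs.

What the phantoms do **not** emulate: CT reconstruction physics (beam
hardening, streaks, correlated noise), anatomical diversity beyond
ellipses, 3-D structure, and registration error.  Passing tests on
phantoms therefore demonstrate that the machinery recovers known
conditional structure and uncertainty at small scale, not clinical
performance.

## Verification problems

* **Gaussian 1x1 toy** (`phasegan.toy`): a 4-vector x ~ N(0, Sigma) treated
  as four 1x1 images, run through the identical pipeline.  The conditional
  mean and SD of the missing component are known in closed form, so the
  trained generator's ensemble statistics can be checked against exact
  values.  (At 1x1 resolution instance normalization reduces CIN to its
  latent shift beta(z); the outer skip carries the conditioning, which is
  exactly the structure of the Gaussian conditional: linear fill plus
  y-independent noise.)
* **Linear critics**: for D(x, y) = <c, x> the gradient penalty is
  lambda_gp (||c|| - 1)^2 exactly; asserted to 1e-6.
* **Sorted-sample W1**: a 1-Lipschitz-by-construction piecewise-linear
  critic on 1-D samples attains (within 20%) the sorted-sample Wasserstein-1
  distance, connecting the critic objective to the distance it estimates.

## Training defaults and problem sizes

Adam with momentum pair (0.5, 0.9); two-time-scale learning rates (critic
2-2.5x the generator's) with linear decay to zero over the epoch budget; an
exponential moving average (decay 0.999) of generator weights is used at
evaluation time — both standard stabilizers of the adversarial
equilibrium at small scale.  lambda_gp = 10, lambda_l1 = 100 (pix2pix).
Defaults at full scale follow common WGAN-GP practice (lr 1e-4,
n_critic 5, latent dim 50, S = 800 ensemble draws).

The bundled experiments are sized for a single CPU:

* toy problem — 2000 subjects, batch 64, n_critic 5, lr 5e-4 / 2e-3,
  360 epochs (~2500 generator steps, ~2 min);
* phantom study — 60 subjects at 32x32 (48/6/6 split), latent dim 8, two
  scales, batch 8, n_critic 2, lr 2e-4 / 5e-4, ~1000 generator steps;
  ensembles of S = 50 for evaluation.

## Numerical choices and edge cases

* Variance convention: population (1/S); swapping to 1/(S-1) rescales the
  SD image by sqrt(S/(S-1)) (tested).
* Generated samples are clipped to [-1, 1] before statistics, keeping
  ensemble members in the normalized intensity domain.
* The linear fill is clipped to [-1, 1]; observed phases are copied
  bit-exactly into the conditioning and never modified by R^j.
* NMSE = ||x_true - x_hat||^2 / ||x_true||^2 (the most common convention; a
  mean-subtracted variant is available).  SSIM uses an 11x11 Gaussian
  window (sigma 1.5), K1 = 0.01, K2 = 0.03, data range 2.0.  PSNR of
  identical images is reported as +inf rather than raised.
* Acceptability ties (NMSE exactly at threshold) count as acceptable.
* ROC/AUC follow the trapezoidal (Mann-Whitney) convention; the AUC is
  undefined and reported as such when one acceptability class is empty.
* A linear-fit design is rejected as singular only when every observed
  phase is constant across the training set; mere collinearity falls back
  to the least-squares minimum-norm solution.
* Training aborts with a divergence error when any loss becomes non-finite
  or exceeds a configurable bound.
* Checkpoints capture network parameters, both optimizer states, batch-norm
  running statistics, the EMA weights and the RNG state, making runs
  exactly resumable.

## Known limitations

2-D only; single missing phase (the method conditions on exactly three
observed phases); the affine family for R^j is pixel-shared (a per-pixel
variant is a config hook, not implemented); CPU-scale instances are far
below the capacity regime of the clinical problem, so phantom metric values
are not comparable to values reported on patient cohorts; at 1x1 resolution
CIN degenerates as noted above.
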