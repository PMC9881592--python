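# Methods

`lesionqr` estimates aleatoric (data-inherent) uncertainty for lesion
detection with conditional quantile regression, in two settings: an
unsupervised quantile-regression variational autoencoder (QR-VAE) for anomaly
detection, and a supervised binary-quantile-regression (BQR) U-Net for
multi-rater segmentation. This note records the models, the assumptions, the
numerical choices, and what the synthetic benchmarks do and do not show.

## The variance-shrinkage problem and the quantile alternative

A Gaussian-decoder VAE models each output pixel as N(mu_theta(z),
sigma_theta(z)^2) and maximizes the ELBO: the Gaussian log-likelihood plus
the KL of the encoder posterior from the N(0, I) prior. When the decoder has
enough capacity to drive training residuals toward zero, the likelihood term
`-log sigma - r^2 / (2 sigma^2)` rewards collapsing sigma, and the
per-pixel variance shrinks below the true noise level ("variance
shrinkage"): the log-likelihood grows without bound while calibration
deteriorates. Anomaly detection built on such a variance flags most of the
image.

The QR-VAE replaces the Gaussian likelihood with pinball (check) losses for a
small set of quantile levels. The pinball loss at level alpha,
`alpha * r` for r > 0 and `(1 - alpha) * (-r)` otherwise, has bounded
gradients and its expected-risk minimizer is the conditional alpha-quantile;
there is no term whose supremum diverges as the spread collapses, and no
interaction between levels (each head is penalized independently). Under a
Gaussian output assumption two quantiles characterize the distribution:
with the median Q_0.5 and the 0.15-quantile Q_0.15,

    mu = Q_0.5,      sigma = (Q_0.5 - Q_0.15) / |Phi^-1(0.15)|,

with |Phi^-1(0.15)| = 1.0364 (carried at double precision, displayed 1.036).

All quantile heads share the network except the final layer; this restricts
the flexibility of independent per-level regressions and empirically keeps
the quantile-crossing fraction small (it is measured and logged every epoch,
never silently repaired; an optional per-pixel sort is available but off by
default).

## Detection pipelines

*Model-free*: train at levels (0.025, 0.975) and flag pixels outside
[Q_L, Q_H]. On in-distribution data the nominal per-pixel false-positive
rate is 5%.

*Gaussian*: train at (0.15, 0.5), convert to (mu, sigma), z-score the image,
apply a 7x7 median filter (reflect padding — avoids edge-darkening bias),
convert to two-sided normal p-values (two-sided because lesions may be hypo-
or hyper-intense depending on contrast), and threshold with
Benjamini-Hochberg at alpha = 0.05, pooled per image. Per-image pooling is
the minimal-assumption default; a caller can pool across images by
concatenating p-values before `bh_fdr`.

*Conformal calibration*: split-conformal CQR with the two-sided score
`E = max(Q_L - y, y - Q_H)` on a held-out calibration set; the offset is the
ceil((n+1)(1-miscoverage))-th order statistic of the scores, applied
symmetrically to both interval ends. One scalar offset pooled over all
calibration pixels is the default (pixels treated as exchangeable); a
per-pixel mode exists. For the Gaussian pipeline the implied central 95%
interval is conformalized and the offset folded back into sigma
(`sigma + offset / 1.96`). Adjusted image-intensity intervals are clipped to
[0, 1] with a logged count.

## Binary quantile regression for multi-rater masks

With binary labels Y = 1{Y* >= 0}, the tau-quantile of Y given X is the
indicator that P(Y=1|X) > 1 - tau. The smoothed maximum-score objective
rewards `sum_i [y_i - (1 - tau)] * K(f_tau(x_i))` with K the sigmoid; the
network minimizes its negation, one head per level, body shared. Training
samples pair each image with one rater's mask, so each rater annotation is a
draw of the binary label field; in expectation each head's optimum is the
agreement-threshold region above. Default levels 0.125/0.375/0.625/0.875 sit
at the centroids of the agreement intervals of a four-rater panel, away from
the grid boundary points, and head tau is evaluated against the agreement
region {fraction >= smallest grid multiple > 1 - tau}.

Heads emit one logit map each with a sigmoid smoothing in the loss. A
"softmax over a single logit" is degenerate, so per-head sigmoid is used; the
baseline comparison network is a single-head U-Net trained with binary
cross-entropy whose probability map is thresholded at the levels.

Cold-started BQR (and BCE) training on extremely imbalanced masks collapses
to the all-background solution; a warm-up phase with weighted cross-entropy
(positive-class weight computed from the observed label imbalance with +1
smoothing, never hard-coded) precedes the BQR objective. At production
dataset sizes one warm-up epoch is thousands of optimizer steps; at desk
scale an epoch is a dozen steps, so `warmup_epochs` scales the warm-up's
share of the optimization correspondingly (experiments here use 6-8 warm-up
epochs on 24-image training sets). The trivial-solution outcome is detected
after training and flagged in the log, not silently corrected.

## Networks and training

No deep-learning framework is assumed: the models run on a compact numpy
layer library (`lesionqr.nn`) with explicitly derived backpropagation
(dense, 3x3 convolution via im2col, batch normalization, nearest-neighbor
upsampling, sigmoid/ReLU, Adam). Every layer is finite-difference
gradient-checked in the test suite and the convolution forward pass is pinned
against scipy. Architectures are deliberately small (CPU desk scale):

* conv VAE — three conv(stride 2)+BN+ReLU blocks to a dense bottleneck
  (default latent 32, widths 32/64/128 for 64x64 inputs; tests use 16/32/64
  at 32x32); decoder mirrors with upsample+conv blocks ("resize
  convolution") and one final conv head per output, sigmoid for image
  intensities;
* dense VAE — 64-64 MLP encoder/decoder for the 4-D simulation, latent 2,
  unbounded linear heads;
* BQR U-Net — two-scale U-Net (base width 8) with skip connections and 1x1
  conv heads.

Training uses Adam at 1e-3 (2e-3 to 3e-3 in the experiments), batch 16,
1-sample reparameterization. The reconstruction term is a per-element mean,
so the per-sample KL is divided by the per-sample data size — the standard
summed ELBO up to a constant factor; without this the KL is over-weighted by
the data dimension and the encoder collapses on low-dimensional data.

Batch-normalization statistics are recalibrated at the end of VAE training
with one momentum-1 pass on the deterministic inference path (z = posterior
mean): during training the decoder sees sampled z, so its running statistics
are biased for the z = mu path used at prediction; without the recalibration
eval-mode quantile maps carry a visible offset.

The Gaussian NLL clamps sigma at 1e-4 of the data range — low enough for
shrinkage to be observable, high enough for training to survive it; clamping
is counted. A non-finite loss raises a training-diverged error carrying sigma
statistics, since variance collapse is the documented failure mode.

*KL weight.* Both VAE and QR-VAE use the same KL weight. For the image
experiments it is 1. For the 4-D simulation both models use 0.1: at desk
scale (500 training points, small MLPs) a weight of 1 leaves both models
underfit and the generative comparison measures noise; 0.1 puts both in a
well-fit regime. The weight is always identical across the compared arms.

## Synthetic data

*Two-moon 4D* — 500 latent points on two interleaved unit half-circles
(jitter 0.05), mapped to (v1..v4) = (z1 - z2, z1^2 - z2/2, z1 z2 - z1,
z1 + z2) plus centered Gaussian noise with per-coordinate scales
(0.03 + 0.05(3 + z1), 0.03 + 0.03 z1^2, 0.03 + 0.05 z1^2,
0.03 + 0.03 sqrt(0.02 + z1^2)). The v4 scale expression is reconstructed
from the pattern of the others (the source's rendering is ambiguous); the
deterministic part is unambiguous and is what the tests pin.

*Images* — a fixed per-pixel Gaussian law: smooth random mean field in
[0.25, 0.75] and sigma field in [0.04, 0.10] (Gaussian-filtered seeded
noise), optional lesion blobs with Gaussian radial profile and peak shift 4
local sigma (>= 3 sigma by design so detection operating points are
meaningful), clipped to [0, 1] with a logged clipping fraction (negligible
at these field ranges). The exact law is returned with every batch, so
coverage, sigma recovery and false-positive rates are computed against
ground truth, not against another estimate. What this emulates is the
statistical skeleton of co-registered, histogram-equalized MRI slices —
smooth spatial structure, spatially varying noise, sparse hyper-intense
lesions. What it does not emulate: anatomy, inter-subject variability, MRI
physics (bias fields, partial volume), registration error, or multi-contrast
channel correlation. Passing tests therefore validate the statistical
machinery (calibration, FDR control, quantile recovery), not clinical
performance.

*Raters* — k = 4 annotators; each dilates or erodes the true mask by
|N(0, jitter)| pixels (jitter 1.5 in the experiments) and misses the lesion
entirely with probability 0.1, concentrating disagreement at the boundary as
observed in human panels; agreement fractions land on multiples of 1/4.

*k-NN KL estimator* — the nearest-neighbor divergence estimator
`(d/n) sum log(nu_k / rho_k) + log(m/(n-1))` with k = 1; biased at finite n
(the identical-distribution estimate is slightly negative), consistent as
samples grow; zero radii from duplicates are floored with a tiny jitter and
logged.

## Problem sizes in the shipped tests and acceptance script

Chosen as the package's desk-scale defaults: image experiments use 32x32 (or
16x16) single-channel images, 24-64 training images, <= 120 epochs; the
simulation uses 500 points and 400 epochs; the acceptance script evaluates
the model-free false-positive rate on 163,840 lesion-free pixels against
exact generator quantiles and the BH false-discovery proportion over 300
seeded replicates (100 of 1024 pixels per image shifted 4 sigma — enough
rejections for a low-variance FDP estimate).

## Known limitations

* The shrinkage demonstration requires the overparameterized regime (latent
  dimension comparable to the pixel count, small training set); with a
  bottlenecked latent the Gaussian VAE on these stationary synthetic images
  is close to calibrated, because little of the pixel noise can leak through
  the code.
* Conformal guarantees are marginal over pixels pooled as exchangeable, not
  conditional per pixel.
* The k-NN KL estimates carry finite-sample bias; only orderings and
  near-zero checks are interpreted, not absolute values.
* Extreme-level BQR heads (tau = 0.125, paired with the full-agreement
  region) converge slowest — the positive coefficient tau is small and the
  sigmoid saturates — mirroring the poor high-agreement performance reported
  for human-rater data at production scale.
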