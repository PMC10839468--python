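# Methods

## Model

`diffsr` implements conditional image super-resolution by denoising
diffusion.  The generative model is the standard DDPM pair of Markov
chains.  The forward chain corrupts a high-resolution image y₀ with
Gaussian noise: each step keeps a fraction αₜ ∈ (0,1) of the signal, and
with γₜ = ∏ᵢ≤ₜ αᵢ the state at any step has the closed-form marginal
yₜ = √γₜ·y₀ + √(1−γₜ)·ε.  The reverse chain is parameterized by a network
f_θ(x, yₜ, γₜ) that predicts ε from the noisy state and the
bicubic-upsampled low-resolution condition x; one reverse step computes the
posterior mean implied by the ε-estimate and adds Gaussian noise with the
constant per-step variance 1−αₜ, except at the final step, which is
deterministic.  Training minimizes the mean-squared ε-prediction error with
the timestep drawn uniformly per example — the unbiased stochastic version
of averaging the objective over all T steps.  The squared error is averaged
over pixels and batch, so a predictor that outputs zeros scores ≈ 1
regardless of image size.

Intensities are mapped affinely from the storage range (e.g. [0,255]) to
[−1,1] before diffusion, and back — with clipping — on output, so that the
unit-scale Gaussian noise is commensurate with the signal.

## Noise schedule

The schedule family is a deliberate design choice, since only the chain
length is externally prescribed (T = 5000 at full scale; any T ≥ 1 is
accepted and desk-scale runs use T = 100).  The default is **linear-β**:
αₜ = 1−βₜ with βₜ linear from 0.1/T to 20/T (end capped at 0.5), which
keeps the total noise budget Σβ ≈ 10 — hence γ_T ≈ e⁻¹⁰ — at every T.

The reason is quantitative.  The sampler's constant per-step variance
1−αₜ always exceeds the true denoising-posterior variance
(1−γₜ₋₁)(1−αₜ)/(1−γₜ); the excess per step is ≈ βₜ²γₜ₋₁/(1−γₜ), so it is
negligible only where β is small while γ is close to 1.  A schedule with
constant α (e.g. γ interpolated geometrically) has 1−α ≈ 10/T at *every*
step, and at short T the late reverse steps inject orders of magnitude more
noise than the posterior allows: at T = 100 on clean phantoms this left
samples with a residual noise floor of several intensity units and sample
quality far below the bicubic baseline.  The linear-β family, whose β is
smallest exactly where γ ≈ 1, removes most of the excess.  A
geometric-in-γ schedule and fully explicit α-lists remain available for
experimentation; schedules serialize inside checkpoints so any sample is
reproducible from (checkpoint, seed).

The convention γ₀ ≔ 1 makes the posterior formulas exact at t = 1, where
they collapse to (y₀, 0).

## Network and training

f_θ is a U-Net: the condition and the noisy state are concatenated as two
channels; encoder levels of width `base_channels × depth_multipliers[i]`
(64 × (1,2,4,8,16) at full scale, 16 × (1,2,4) in the desk profile) are
linked by 2× average-pool/nearest-upsample and skip connections; each level
is a residual block of two 3×3 convolutions with SiLU activations; the
scalar γₜ enters every block as a learned bias computed by a small MLP on
sinusoidal features of log γₜ; the output 1×1 convolution is
zero-initialized so the untrained network predicts ε̂ = 0 (loss ≈ 1).

The network, backpropagation and the Adam optimizer (lr 2e-3 in the desk
profile, β₁ 0.9, β₂ 0.999, global gradient-norm clip 1.0) are implemented
directly on numpy arrays; backpropagation is verified against central
finite differences to ~1e-10 relative error in the test suite.  Single
precision is the training default; double precision is used where
exactness matters.  Two refinements that are standard for diffusion models
are applied because the sampling chain compounds small parameter errors
over T steps: cosine learning-rate decay and an exponential moving average
of the parameters (decay 0.998) swapped in at the end of training.  Both
measurably reduce the residual noise of generated samples at desk scale.

## Noise estimation and the acceptance gate

The estimated noise level (ENL) of a single image is σ = √λ_min(Σ_y),
where Σ_y is the covariance of the flattened 7×7 patches (all fully
contained patches on a stride grid; stride 3 by default at full scale,
stride 1 on small images).  Patches are mean-centered before the
outer-product average: a raw second moment folds overall brightness into
every eigenvalue, while centering leaves the noise floor unchanged and
makes σ = 0 exact on constant images.  λ_min is computed with a dedicated
smallest-eigenvalue symmetric solver and clamped at zero against round-off.

Two biases matter and are documented rather than hidden.  (1) Finite
sampling shrinks the smallest eigenvalue below σ² (the Marchenko–Pastur
edge): with M patches of dimension p², the estimate is ≈ σ(1−√(p²/M)).
At 256×256 and stride 3 (M ≈ 7000) the factor is ~0.92 — the calibration
measurement in `scripts/acceptance.py` recovers injected σ = 10 as ≈ 9.3.
On very small images the estimate collapses (at 32×32 and stride 3,
M ≈ 81 against 49 dimensions), which is why the desk profile uses
stride 1.  (2) The estimator is resolution-sensitive: interpolation makes
noise locally low-rank, so an upsampled image's ENL underestimates the
noise that was present on the native grid.  The gate therefore exposes the
grid choice (`sigma_x_grid="upsampled"` default, `"native"` available).

The gate itself estimates σ_x once, then runs fresh reverse chains until a
candidate's ENL is ≤ σ_x (equality accepted).  The loop is bounded
(`max_attempts`, default 10) because an unconditioned rejection loop need
not terminate; on exhaustion the lowest-ENL candidate is returned flagged
as not accepted, with a logged warning.  On noiseless synthetic inputs
σ_x is near zero and the gate operates permanently in this fallback
regime — it then acts as a best-of-N selector by estimated noise, which is
well-motivated: in the desk study the per-sample ENL correlates strongly
and negatively (r ≈ −0.8) with PSNR against ground truth.

## Synthetic data

Phantoms are piecewise-smooth stand-ins for anatomy: overlapping random
ellipses at tissue-like intensity plateaus on a dark background, edges
softened by a small Gaussian blur, a smooth random texture field inside
structures, and optional additive Gaussian noise, composed and clipped to
[0,255].  They reproduce the statistics the method depends on — sharp
boundaries between smooth regions, sub-Nyquist detail, bounded range — and
deliberately omit MR physics (k-space sampling, bias fields, Rician noise);
conclusions from phantom studies therefore transfer to real data only at
the level of orderings and mechanisms, not absolute metric values.

Degradation is anti-aliased bicubic down-sampling (nearest/bilinear
selectable); the full-scale geometry is 256×256 → 86×128, an ~6× pixel
reduction that is anisotropic (the phase-encoding-like axis degrades
more), and under-sized sources can be zero-padded (centered, floor
offsets) onto the working grid.

## The desk-scale study

`diffsr.study.run_tiny_study` fixes the reference experiment end to end:
32×32 phantoms with ten structures, 0.2 px edge blur and texture amplitude
7 (content rich in detail below the low-resolution Nyquist limit — the
regime super-resolution addresses); degradation to 11×16 (the 6× ratio
scaled); 200 training and 20 test pairs; T = 100; the 16 × (1,2,4) U-Net;
150 epochs at batch 8; gating with `max_attempts=5` and stride-1 ENL.  One
master seed drives data, training and sampling.  Problem sizes were chosen
so the full study runs in minutes on a single CPU while still training the
model to convergence (ε-loss ≈ 0.7 → 0.035).

Under these conditions the gated sampler exceeds bicubic upsampling on both
mean PSNR and mean MS-SSIM over the held-out set, with margins of a few
tenths of a dB and a few 10⁻³ of MS-SSIM.  The margins are real but small:
at this scale the dominant error of the diffusion output is stochastic
trajectory jitter of the T=100 chain, not blur, and the deterministic
variant of the chain (all εₜ = 0) scores several dB higher — included as a
diagnostic observation, not as part of the method.

## Metrics

MAE and PSNR (10·log₁₀(peak²/MSE), peak 255 by default, `inf` sentinel on
identical inputs) are direct.  MS-SSIM follows the multi-scale
construction: per-scale mean contrast/structure terms and top-scale
luminance with exponent weights (0.0448, 0.2856, 0.3001, 0.2363, 0.1333),
11×11 Gaussian window (σ 1.5), K₁ = 0.01, K₂ = 0.03; the window-radius
border is excluded from the averages, which makes the single-scale term
agree with scikit-image's SSIM to machine precision (a cross-check in the
tests); negative contrast/structure means are clamped at zero before the
geometric combination, so anti-correlated images score 0.  Five scales
need image sides ≥ 176; smaller images use fewer scales with renormalized
weights.

NQM follows the degradation-model construction: both images are decomposed
into octave bands by cosine-log filters (partition of unity in the
frequency plane), converted to band-limited contrast against the
accumulated low-pass, gated by a Barten-style contrast threshold at each
band's frequency (cycles/degree at a declared viewing angle, default 4°)
with threshold elevation where the reference carries supra-threshold
contrast, resynthesized from the visible bands, and compared by SNR in dB.
The masking model is a single-exponent elevation rather than the full
inter-band masking of the original formulation; the implementation is
validated by identity, monotone-degradation and frozen-value regression
tests.  LPIPS is not computed natively (it requires pretrained perceptual
weights); `evaluate_pairs` accepts only the four native metrics.

Cohort reporting keeps per-image records and derives mean ± SD rows from
them on demand.  Enhancement over a baseline is reported both as the mean
of per-image percentages and as the percentage of cohort means — the two
differ whenever the baseline varies across images, and neither is
canonical.  Paired comparisons use the two-sided Wilcoxon signed-rank test
(exact for n ≤ 25 without ties), with p = 1 when all differences vanish.

## Known limitations

* The ENL gate is only informative when the input carries estimable noise;
  on clean synthetic inputs it degenerates to best-of-N selection (see
  above).  Real low-resolution acquisitions carry noise, which is the
  regime the gate is designed for.
* The constant-variance sampler is intrinsically over-dispersed at short
  chain lengths; T = 100 results carry a stochastic quality floor that
  T = 5000 would not.
* Phantom studies validate orderings and mechanisms, not clinical metric
  values.
* Training is single-device and full precision; no attention blocks,
  self-conditioning or accelerated (non-ancestral) samplers are provided.
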