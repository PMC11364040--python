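# Methods

## Model and loss

A half-map pair (M₁, M₂) is modelled as two independent noise
realizations of one signal, Mᵢ = S + Nᵢ, with signal and noise
uncorrelated in expectation and the two half-sets on the same intensity
scale. Under these assumptions the half-map Fourier shell correlation is
FSC_half(s) = SSNR(s)/(1 + SSNR(s)), and the correlation between the
noise-free map and the full-dataset map (the half-map average, whose
noise amplitude is reduced by √2) is

    C_ref(s) = sqrt(2 · FSC_half(s) / (1 + FSC_half(s))).

The denoiser is trained to make FSC_FD — the FSC between its input (the
half-map average) and its output — trace C_ref, by minimizing the mean
absolute difference of the two curves over all non-DC shells up to
Nyquist. An output whose FSC_FD sits above C_ref is under-denoised;
below C_ref it has lost signal. The loss constrains only per-shell
correlations, so the minimizer is not unique; like other self-supervised
denoisers the network converges toward a mean-like solution among the
maps consistent with the constraint.

The loss gradient with respect to the denoised volume is computed in
closed form. With F₂ = FFT(denoised), per shell

    ∂FSC/∂F₂*(r) = ½ [ F₁(r)/√(P₁P₂) − FSC(s) · F₂(r)/P₂ ],

and for a real input volume the chain rule through the DFT gives
grad = 2N³ · Re[IFFT(G)], with G the per-voxel accumulation of the shell
terms. The implementation is verified against central finite differences
(relative error ≲ 1e−4 in the tests).

## Fourier-shell conventions

* Shells are concentric: a Fourier voxel with centered radius |k| (index
  units) belongs to shell round(|k|); shells run 0..N/2 and voxels
  beyond the Nyquist radius are ignored. `freq_axis[s] = s/(N·voxel)`.
* The FSC numerator is real for real inputs by Hermitian symmetry; the
  imaginary residue is discarded explicitly.
* Shells where either map has zero power get FSC = 0 (logged), keeping
  curves total; volumes with zero power everywhere are rejected.
* The DC shell is computed but excluded from the integrated FSC and from
  the loss: maps are standardized to near-zero mean, so shell 0 is
  numerically meaningless.
* C_ref is evaluated after clamping FSC_half to [0, 1]; negative
  half-map correlations are pure noise and map to C_ref = 0.
* The loss weights all non-DC shells equally (unweighted mean).
* FSC_half for the loss is computed per training patch, which is
  self-consistent and always available; `cref_override` lets a caller
  supply an external curve (e.g. the whole-map FSC_half) instead.
* Non-cubic volumes are rejected for shell operations rather than
  silently reshaped.

## Variance decomposition

Writing a denoised half-map as Dᵢ = S + B + Nᵢᵈ — signal, a bias field
shared between the two independently denoised halves, and leftover
noise — per-shell covariances of the four maps give

    var S  = cov(M₁, M₂)
    var N  = ½[cov(M₁,M₁)+cov(M₂,M₂)] − cov(M₁,M₂)
    var B  = cov(D₁,D₂) − cov(D₁,M₂) − cov(D₂,M₁) + cov(M₁,M₂)
    var Nᵈ = ½[cov(D₁,D₁)+cov(D₂,D₂)] − cov(D₁,D₂).

Covariances use the plain Hermitian product per shell (orthonormal FFT,
mean over shell voxels) without mean subtraction for s ≥ 1 — per-shell
means of Fourier coefficients vanish for stationary fields — while the
DC entry carries the mean-subtracted real-space covariance. The var B
combination cancels every cross term algebraically (including
cov(S, B)), so the identity denoiser returns var B = 0 to machine
precision; var S + var N equals the mean auto-power exactly by
construction. Negative per-shell estimates are sampling noise: ratio
curves clamp them (and flag the shell), raw values are always retained
and should be used when averaging across maps. When a mask is supplied
it multiplies the volumes before decomposition and is never resampled.

The estimates assume S, B, Nᵢ, Nᵢᵈ mutually independent. A denoiser
that multiplies both half-maps by a shared per-shell factor c(s) < 1
(signal and noise dampened together) violates this and produces spurious
var B = (1−c)²·var S. The `shrinkage_diagnostic` detects the regime by
regressing each denoised map on its own input, ĉᵢ = cov(Dᵢ,Mᵢ)/cov(Mᵢ,Mᵢ),
and flagging shells where both ĉᵢ < 0.95 and cov(D₁,D₂) matches the
pure-shrinkage prediction ĉ₁ĉ₂·cov(M₁,M₂) within 10 %; the summary trips
when ≥ 25 % of eligible shells (≥ 100 voxels, positive half-map
covariance) are flagged. A genuine denoiser with independent leftover
noise leaves cov(D₁,D₂) ≈ var S + var B well above the shrinkage
prediction and does not trip; neither does the identity map (ĉ = 1).

## Network

A 3D U-Net on single-channel volumes: `depth` (default 5) contracting
blocks of conv → LeakyReLU → 2³ max-pool, a conv + LeakyReLU bottleneck,
`depth` expanding blocks of 2× upsample → skip concatenation → two
conv + LeakyReLU pairs, and a final single-filter conv. Choices the
architecture description leaves open and how they are fixed here:

* kernel 3³ with same-size zero padding everywhere; pool/upsample
  factor 2 per level; LeakyReLU slope 0.01; nearest-neighbour upsampling
  by default (cheap and checkerboard-free ahead of the following convs),
  with separable ×2 linear interpolation (`trilinear`) as the
  alternative — both implemented as exact linear operators so the
  backward pass is the true adjoint.
* 16 filters at every convolution (the stated contracting width, reused
  for bottleneck and expanding convs; concatenation makes the first
  expanding conv 32→16). This plan has 139,361 trainable parameters;
  every width is configurable and `count_parameters` reports the actual
  total.
* He-normal weight initialization, fully determined by the config seed.

The network is fully convolutional: whole maps of any size are
reflect-padded per axis to the next multiple of 2^depth, processed, and
cropped back (zero padding would darken borders). An axis that cannot be
reflect-padded that far (shorter than the required pad) is an error.
`receptive_margin` bounds the half-width of the output's dependence on
the input; outside that margin, denoising a patch and cropping the same
region from a whole-map pass agree exactly when the patch offset is
aligned to the pooling grid (the integration tests use offset 32 for a
depth-2 model).

The engine is plain numpy: convolutions are im2col matrix products
(slab-chunked along one axis at inference to bound memory), max-pool
routes gradients to per-block argmaxes, and Adam is implemented
directly. Runs are bit-reproducible for fixed seeds on a given platform;
only a CPU backend exists.

## Data preparation

Half-maps are masked (voxelwise multiplication; mismatched mask geometry
is an error) and standardized to mean 0, standard deviation 1, with the
statistics taken over all voxels of the masked volume (an option
restricts them to in-mask voxels). Standardized maps are tiled into
non-overlapping cubic patches (default edge 96; tests use 32 so shells
retain a few hundred voxels); a final partial window on any axis is
shifted back flush with the boundary — full-size, possibly overlapping
its neighbour — rather than zero-padded, so every patch holds genuine
data. Windows whose mask content is identically zero are dropped; both
half-maps are always cut at identical offsets. Train/test splitting is
done at the map level, so no source map contributes patches to both
sides; the split, like everything else, is a pure function of its seed.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at an initial learning rate of
3e−4, decayed by a staircase factor 0.7 every 10 epochs (multiplication
at epochs 10, 20, ..., the literal reading of "reduced every ten
epochs"); 195 epochs, batch size 6. Batches reduce per-patch losses by
arithmetic mean; no gradient clipping — a non-finite loss aborts with a
diagnostic. An evaluation loss on held-out patches is recorded per epoch
for monitoring only; by default the final-epoch weights are returned
(best-checkpoint selection exists but is off, since the model is not
tuned on held-out data). The loss inside the loop is the same public
`cref_loss` function, bit for bit.

The suite's smoke configuration scales this down to a depth-2,
4-filter network on 60 synthetic 32³ patch pairs for 20 epochs
(200 optimizer steps). At that schedule the full-scale learning rate is
too conservative for the real-space correlation gain to emerge, so the
smoke run uses lr₀ = 3e−3, a one-time short-schedule scaling choice; the
same run must halve its training loss, beat the identity model on the
squared-curve RMSE to C_ref, and correlate better with the known truth
than its input does.

## Synthetic data

The generator reproduces the second-order statistics the analysis
machinery assumes, at desk scale: a ground-truth density of seeded
Gaussian blobs (centers in the central 2/3 of the box), two half-maps
with independent Gaussian noise — white, or Fourier-shaped per shell so
that var N(s) = var S(s)/SSNR(s) hits a requested SSNR exactly in
expectation — a soft spherical mask, and optional denoised-like maps
Dᵢ = S + B + a·Nᵢ. The bias field B is drawn independently of S and N:
either low-pass-filtered white noise (variance concentrated at low
frequency, the shape real denoisers tend to produce) or per-shell
matched to a fraction of the signal spectrum, which is the configuration
the closed-loop decomposition tests use. Gaussianity is the standard
reconstruction-noise assumption and is what the SSNR relation requires
in expectation. All substreams derive from one seed; realized per-shell
spectra are recorded alongside the volumes for closure checks.

What the generator does *not* model: CTF, projection geometry, B-factor
envelopes, alignment errors, or structured (non-stationary) noise.
Passing tests therefore demonstrate the correctness of the shell
statistics, the decomposition algebra and the training mechanics — not
performance on experimental maps, which additionally depends on those
unmodelled effects.

## Evaluation metrics

* Threshold resolution: scan outward from shell 1, linearly interpolate
  the first downward crossing of the threshold between shell centers,
  report the reciprocal frequency in Å; re-risings after the first
  crossing are ignored. A curve that never falls below the threshold
  returns the Nyquist-limit sentinel (flagged, resolution = 2·voxel).
  0.143 is the gold-standard half-map threshold — the value at which
  C_ref reaches 0.5 — and 0.5 the usual map-to-reference threshold.
* Curve agreement: RMSE between the *squared* FSC_FD and C_ref curves
  over non-DC shells; squaring stabilizes the statistic where curves
  approach zero.
* `fsc_threshold_change` compares resolution before/after denoising one
  half-map, masking all inputs before every FSC (masking convention
  fixed here; negative changes mean improvement).

## Problem sizes and tolerances in the test suite

Closure tests run on 64³ volumes at flat SSNR 1 (a fixed generator
seed), asserting on shells with ≥ 500 voxels: measured FSC_half within
±0.05 of 1/2, FSC(full, truth) within ±0.05 of C_ref, injected
var B/var S and var Nᵈ/var N ratios recovered within 15 %. The flat-
spectrum recovery test uses per-shell 4σ bounds calibrated once by a
resampling oracle (σ·√n_s ≈ 6.0 for var S at spectrum (4, 1), 1.4 for
var N). FSC itself is checked to 1e−10 against a brute-force per-voxel
oracle on 16³–32³ volumes. The smoke training run and whole-map
inference checks use the scaled-down network described above; whole-map
padding is exercised at 100³ (padded to 128³ for a depth-5 model).
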