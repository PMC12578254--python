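# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `eegcvae`, in the order the pipeline runs.

## Preprocessing

All recordings are harmonized before any feature is computed.

* **Montage.** Analysis is confined to 11 sensorimotor electrodes (C3, Cz,
  C4, FC3, FCz, FC4, CP3, CPz, CP4, F3, F4) in a fixed order; channel-major
  feature stacking depends on that order. Matching is case-insensitive and a
  missing electrode is a hard error — no interpolation is attempted.
* **Filtering.** A second-order IIR notch (quality factor Q = 30) at the
  mains frequency (50 or 60 Hz), then an 8–50 Hz fourth-order Butterworth
  band-pass, both applied forward–backward (zero phase; the band-pass is
  eighth-order in magnitude). Signals are mirror-padded by 3 s per side
  before filtering and cropped afterwards; signals shorter than the pad fall
  back to a full-signal mirror with a warning. The notch design is a
  conventional choice; only its mains frequency and zero-phase application
  are constrained by the procedure.
* **Resampling** to 125 Hz: decimation by 4 for 500 Hz input, polyphase
  25/32 resampling with a Kaiser-windowed FIR for 160 Hz, identity at
  125 Hz; other rates resample rationally with a warning. Event sample
  indices are rescaled with the data.
* **Epoching.** Non-overlapping 1 s windows (125 samples) tile each MI
  interval *from its onset*; trailing partial windows are dropped and
  baseline intervals produce nothing, so no window can straddle an event
  boundary. Sample indices are 0-based; intervals are half-open
  [onset, offset).
* **Amplitude QC.** A window is rejected iff any sample on any channel
  exceeds 100 µV in magnitude, strictly — a window peaking at exactly
  100 µV survives. QC runs after filtering/resampling and before
  normalization.
* **Normalization.** Per recording and channel, x → (x − m)/s with m, s
  estimated from the *training-split* windows of that recording only and
  applied unchanged to its held-out windows. s is floored at 1e-12; a
  floored (numerically constant) channel z-scores to exactly zero. A
  recording with no training windows falls back to its own window
  statistics with a warning.
* **Balancing.** Within each class every subject is undersampled (seeded,
  uniform, without replacement) to the class's minimum per-subject count.
  If the remaining class imbalance |N₀ − N₁|/N is below 5%, the windows are
  kept and inverse-frequency weights ω_c = N/(2 N_c) are attached to the
  classification loss; otherwise the larger class is further undersampled
  to equality (per-subject proportional, largest-remainder rounding), after
  which the weights are exactly 1.

## Feature bank

Eight scalars per channel per window, in fixed order (BP_α, BP_β, BP_γ, Ĥ,
α_DFA, KolmEn, CD, LLE); 11 channels give an 88-dimensional vector.
Parameters live in `FeatureConfig`, are fixed a priori, and are never
adapted to data. All logarithms are natural.

* **STFT band power.** Hann frames of 64 samples at hop 16 — exactly
  ⌊(125 − 64)/16⌋ + 1 = 4 complete frames; incomplete frames are not taken.
  128-point DFT (zero-padded), one-sided, |X|² without 1/N normalization
  (band powers are only ever compared, so the constant is immaterial). Band
  membership is evaluated on bin frequencies f_k = k·125/128 with α and β
  half-open and γ closed at 50 Hz, giving 5/17/21 bins; the per-band value
  is the frame-mean of Σ_k log(|X|² + ε) with ε = 1e-8.
* **Rescaled-range Hurst exponent.** Scales {8, 16, 32, 64, 125} at 50%
  overlap (stride s/2, trailing partials discarded); per demeaned segment,
  R = range of the cumulative deviates and S = √(Σx²/(s−1)); the exponent
  is the OLS slope of log mean[R/S] vs log s. The shortest scale is dropped
  when fewer than two cycles of the window's dominant rhythm (periodogram
  argmax) fit inside it. Numerically constant segments (S below 1e-12
  relative to the signal scale) are skipped; fewer than two usable scales
  flags the estimate and substitutes the memoryless value 0.5.
* **DFA.** The integrated profile is cut into ⌊N/s⌋ forward segments per
  scale, a least-squares line is removed from each, and F(s) is the RMS
  residual over the covered samples (the uncovered tail of non-divisible
  scales contributes nothing — the printed 1/N convention is replaced by
  the covered-sample count, which changes F(s) by a constant factor and the
  slope not at all). Scales with F(s) ≤ 1e-10 are dropped (a constant
  signal has a zero profile everywhere); fewer than two valid scales flags
  the estimate to 0.5. Note that a linear *signal* is not degenerate: its
  profile is quadratic and leaves nonzero residuals.
* **Permutation entropy.** Ordinal patterns of length m = 3 at delay 1 (123
  patterns per window), −Σ p ln p without normalization by ln 3!. Rank ties
  break by stable ordering (earlier index ranks lower) — deterministic, and
  measure-zero on continuous data.
* **Correlation dimension.** Delay embedding (m, τ) = (6, 1) gives 120
  points; pairs closer than the Theiler window W = 6 in time are excluded
  from both the correlation sum and the radius percentiles. 20 log-spaced
  radii span the 5th–95th percentile of the retained distances; CD is the
  OLS slope of ln C vs ln r over the contiguous span of ≥ 5 radii with the
  highest R² (ties → longer span, then earlier). Radii with C(r) = 0 are
  dropped; an all-zero distance set (constant signal) flags CD = 0.
  *Caveat:* the percentile radius range measures structure at the scales
  the data actually occupy. For clean deterministic systems (a sinusoid's
  limit cycle, the fully chaotic logistic map) the true unit-dimension
  scaling regime lies below the 5th-percentile radius, and the estimator
  reports the macroscopic-scale slope instead (≈1.4 for a sinusoid, ≈1.7
  for the logistic map). On 1 s EEG windows — short, noisy, without a
  microscopic scaling regime — the percentile range is the appropriate
  operating regime; the estimator is used as a comparative complexity
  index, not an absolute dimension.
* **Largest Lyapunov exponent** (Rosenstein). Same embedding and Theiler
  window; each point is paired with its nearest neighbor at temporal
  separation > W (restricted to points whose full horizon fits in the
  series), and d̄(t) is the mean log separation t steps ahead. The exponent
  is the OLS slope of d̄(t) on t ∈ [3, 25] *truncated before saturation*:
  exponential divergence only holds while separations are small relative to
  the attractor, so when the curve rises past 10% of its plateau separation
  the fit stops there (minimum 5 points). Curves that never rise by that
  factor — noise, limit cycles, typical EEG windows — keep the full range.
  Zero initial separations are floored at 1e-12; no valid reference points
  flags LLE = 0. Units are 1/sample; multiply by f_s for 1/s.
* **Degenerate substitutions** keep vectors rectangular: Ĥ = α_DFA = 0.5,
  CD = LLE = 0, each with a per-scalar QC flag serialized alongside the
  values.

## The conditional VAE

* **Inputs.** The model assumes z-scored continuous features (that is what
  makes a homoscedastic Gaussian likelihood — MSE per feature dimension —
  appropriate). The pipeline therefore standardizes each feature column
  with training-split mean/sd before training and persists the scaler. The
  raw 88-D vector mixes scales (log band powers in the tens against
  exponents near 0.5), and without this step the reconstruction term
  dominates the objective by two orders of magnitude.
* **Architecture.** Dual label concatenation: x′ = [x; y] ∈ ℝ⁸⁹ at the
  encoder, z′ = [z; y] ∈ ℝ³³ at the decoder; the label is a single scalar
  in {0, 1}, which the printed layer widths force. Encoder 89→64→32 (ReLU)
  with linear 32-unit heads for μ and log σ²; reparameterization
  z = μ + σ ⊙ ε; decoder 33→32→64→88 (ReLU, linear output); linear 2-class
  head on z. 18,938 parameters. Initialization is fan-in-scaled uniform
  U(±1/√fan_in) for weights and biases, fully seed-determined.
* **Objective.** Recon = MSE per feature dimension; divergence D is either
  the closed-form KL ½Σ(μ² + σ² − log σ² − 1) or the unbiased Gaussian
  MMD² estimator (diagonal terms excluded, so slightly negative values are
  possible) with the median heuristic bandwidth computed on the pooled
  batch + prior sample and treated as a constant in the gradient; prior
  sample count = batch size. A multi-kernel MMD sum is available behind a
  config switch and off by default. Weights: β = 4 (fixed, no annealing),
  λ_div = 2.5×10⁻⁴ (so the divergence multiplier is 1e-3), λ_clf = 1.
  Class weights from the balancing stage enter the CE as a weighted mean
  normalized by the summed weights.
* **Optimization.** Adam (η = 10⁻³, β₁ = 0.9, β₂ = 0.999), batch 128, 50
  epochs, no weight decay or dropout, one ε draw per example per step. The
  whole model is plain numpy with hand-written gradients; a finite-
  difference check over every layer is part of the test suite. Training is
  bit-deterministic given the config seed (init, shuffling, ε, prior
  draws). Non-finite losses abort with diagnostics.
* **Prediction convention.** The classifier consumes the sampled z during
  training (its gradient flows through the reparameterization) and the
  posterior mean at evaluation. The encoder requires a label input, but
  feeding the *true* label at evaluation would leak it straight into the
  latent (a label-blind model then scores far above chance on pure noise).
  Predictions therefore fix the conditioning input to the neutral midpoint
  0.5, so the classifier sees feature content only. The label-conditioned
  encoder/decoder paths are unchanged for training and generation.
* **Generation.** z ~ N(0, I) decoded with the requested label. With the
  default divergence weight (1e-3) the aggregate posterior is only weakly
  pulled toward the prior, so prior samples decode with attenuated class
  contrast: the per-feature *direction* of the class difference is
  reproduced reliably (the package's conditioning test checks the sign of
  every injected feature shift in generated class means), but individual
  generated vectors land near the decision boundary. Stronger divergence
  weighting trades reconstruction quality for crisper conditional
  generation; the defaults are kept as stated.

## Evaluation statistics

* **Split.** Window-level stratified 80/20: (class, subject) cells receive
  train quotas by largest-remainder rounding (ties by cell label order) so
  the train total is exactly round(0.8·N); the within-cell split is a
  seeded shuffle. The split is deliberately not subject-exclusive — the
  protocol measures within-cohort generalization, and windows of one
  subject appear on both sides. A leave-one-subject-out protocol would be
  stricter and is out of scope.
* **Metrics.** Confusion matrix, accuracy, macro-averaged precision,
  recall and F1 (unweighted means of per-class values). A class absent
  from the truth reports 0 for its metrics, with a flag.
* **Wilson interval** with z the normal quantile at (1 + conf)/2; always
  inside [0, 1]. **Two-proportion z-test** with pooled-proportion standard
  error, identical group sizes, two-sided normal p-value; degenerate pooled
  proportions (0 or 1) return p = 1 for equal inputs and p = 0 otherwise.
  This unpaired test understates power relative to a paired analysis and is
  used as a conservative comparison.
* **Redundancy check.** Pearson correlations between per-window descriptor
  summaries (channel means; the three band powers pooled for the STFT
  group); reported as the full 6×6 matrix plus the max off-diagonal |r|.

## Synthetic data

The generator emulates the study conditions so every stage is testable
offline: 7 subjects per class by default (cohort sizes and per-class run
counts configurable), 11 canonical channels, 125/160/500 Hz, runs tiled by
alternating 4 s MI / 2 s rest blocks (rest = 0 makes the whole run MI, used
for bookkeeping runs). Per channel the signal is band-limited Gaussian
noise in α/β/γ (5/3/2 µV rms) + 1/f background (3 µV) + fractional Gaussian
noise (3 µV, H = 0.55) — every descriptor in the feature bank has a
controllable ground truth. Class 1 applies per-band log-power shifts
(default −0.4/−0.2/+0.4) and a Hurst shift (+0.1), chosen as a moderate,
physiologically plausible contrast (ERD-like mu/beta suppression with gamma
increase). Artifacts are single-channel 150 µV bursts (0.4 s square
envelope on a 25 Hz carrier, centered in the window) injected into a
configured fraction of MI windows; the in-band carrier ensures the
excursion survives the 8–50 Hz band-pass and unambiguously trips the
100 µV rule, which a DC-dominated square pulse would not.

fGn synthesis is exact circulant embedding of the fGn autocovariance
γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}); negative circulant
eigenvalues (an indefinite embedding) are clipped to zero deterministically.
Everything is byte-reproducible from the spec seed via spawned
`SeedSequence` children.

What the generator does *not* emulate: volume conduction and realistic
spatial covariance between electrodes (channels are independent draws),
eye-blink/EMG artifact morphology, subject-level random effects, and
nonstationarity across a run. Passing tests on this data show the pipeline
machinery and estimator behavior are correct under known ground truth —
not that the classifier's synthetic accuracy transfers to real cohorts.
One consequence worth knowing: the mandated 8–50 Hz band-pass removes most
of the sub-8 Hz spectral mass that carries fGn long-range dependence, so
the class-1 Hurst shift is clearly measurable on raw generated signals but
is strongly compressed after filtering; class separation in the filtered
pipeline is carried mainly by the band-power shifts.

## Problem sizes

The test suite and the acceptance script choose sizes that keep full runs
in the minutes range on one CPU: the bookkeeping run uses the full cohort
(13,440 one-second epochs), estimator ensembles use 200–500 windows of 125
samples, reference-process checks use 1,000–5,000 samples, CVAE behavior
checks use 2,000 windows of synthetic 88-D features, and end-to-end
pipeline runs use 2–3 subjects per class with 1–2 runs of 45–90 s.

## Known limitations

* The correlation-dimension radius convention reports macroscopic-scale
  slopes for clean deterministic systems (see the caveat above).
* The stratified split is not subject-exclusive; reported accuracies are
  within-cohort.
* Conditional generation at the default divergence weight reproduces class
  directions, not well-separated class clusters.
* EDF support covers the 16-bit EDF+C files the package writes (one
  annotations channel, integer sampling rates); it is not a general EDF
  feature-complete reader/writer.
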