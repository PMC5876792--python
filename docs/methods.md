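# Methods

## Problem and signal model

A lensed optical-fiber tweezer traps one microparticle and collects the
back-scattered laser light on a photodetector. The laser is modulated by
a 1 kHz sinusoid and the detector is sampled at 5 kHz for 120 s per
particle. Four conditions are studied: empty trap ("no particle"), 8 µm
PMMA bead, 8 µm polystyrene bead, and living yeast (6–7 µm). The
analysis reduces each particle's recording to one discriminant score and
asks whether that score separates the classes and tracks the physical
scattering driver Δn·d = (n_particle − n_medium) · diameter.

## Synthetic acquisition generator

No raw acquisitions are publicly available, so the pipeline is exercised
on synthetic recordings with the statistical structure the analysis
assumes:

    s[t] = (baseline + A·e·(1 + δ·w[t])) · sin(2π f_mod t) + n[t]

* `A = gain · Δn·d` — scattering amplitude proportional to the
  refractive-index contrast times diameter. Table values: PS
  n = 1.5731, d = 8 µm; PMMA n = 1.4843, d = 8 µm; yeast midpoints
  n = 1.51 (of 1.49–1.53) and d = 6.5 µm (of 6–7 µm); water n = 1.327.
  A single representative yeast value is required for amplitude scaling
  and the calibration-curve correlation; range midpoints are the
  neutral choice.
* `e` — per-particle log-normal amplitude effect (σ = 0.1), modelling
  positive multiplicative biological/positioning variability.
* `w` — zero-mean, unit-variance, low-pass-filtered (2nd-order
  Butterworth, 10 Hz) Nakagami(µ, ω = 1) noise; `δ` is the fluctuation
  depth. Heterogeneity is encoded here: yeast gets the lowest shape
  (µ = 1.5, strong fading) and deepest fluctuation (δ = 0.35); the two
  polymer beads share identical texture (µ = 6, δ = 0.10) so that only
  refractive index separates them; the empty trap is nearly steady
  (µ = 10, δ = 0.05). The empty trap keeps a baseline carrier of 0.2 V
  (the fiber facet itself reflects light).
* `n` — white Gaussian noise, SD 0.05 V. `gain = 10⁶ V/(RIU·m)` puts
  the bead amplitudes at 1.2–2.0 V.
* Artifacts: Poisson(2 per acquisition) single-sample spikes of 10
  signal-SDs, the simplest event that trips the |z| > 5 rejection rule;
  with ~2 spikes per 60 epochs this reproduces the study-like tally of
  ~57–59 accepted portions per particle.

Default design: 16/16/18/16 particles × 120 s = 66 acquisitions,
7920 s of signal. A global seed fans out to per-particle child seeds via
`SeedSequence([seed, crc32("label:index")])`, so subsetting the design
never reshuffles other particles' signals.

What the generator does **not** emulate: Mie/electromagnetic scattering,
trap mechanics and Brownian motion, detector nonlinearity, drift, or any
class-specific spectral texture beyond the Nakagami-envelope model.
Passing tests therefore demonstrate that the pipeline recovers the
structure this model encodes — amplitude ordering and
heterogeneity-driven envelope statistics — not that it would classify
any real recording.

## Preprocessing

Whole-acquisition filtering precedes epoching. The high-pass is a
2nd-order 500 Hz Butterworth applied forward–backward (zero phase).
Zero-phase filtering squares the magnitude response; the features below
are phase-insensitive and alignment with the raw recording is preserved.
The exact amplitude gain of the implemented digital filter is
`1/(1 + (tan(π·fc/fs)/tan(π·f/fs))^4)` (bilinear prewarped form), which
the filter tests use as the closed-form oracle.

Epochs are non-overlapping 2 s windows (10 000 samples); a trailing
partial window is dropped. An epoch is rejected when any within-epoch
|z| exceeds 5, with the sample SD (n−1) convention, or when SD = 0.
Rejection is decided on a single exceedance — the most literal reading
of a magnitude threshold rule.

## Feature registry (45)

* **Time statistics (7)** on the filtered epoch: mean, SD (n−1), RMS,
  skewness and non-excess kurtosis (bias-corrected sample forms,
  Gaussian kurtosis → 3), IQR with linear-interpolation quantiles
  (type 7), and Shannon entropy in bits of the 100-bin equal-width
  amplitude histogram spanning [min, max].
* **Nakagami (2)**: the filtered signal is signed while the Nakagami
  support is positive, so the fit targets the Hilbert-envelope
  magnitudes — standard backscatter-envelope practice. Moment
  estimators (ω̂ = mean(x²), µ̂ = ω̂²/Var(x²), population variance) are
  used instead of MLE for determinism and speed; recovery is within 5%
  at n = 10⁵ across µ ∈ {0.5, 1, 2, 5}.
* **DCT (24)**, all on the Hilbert envelope: orthonormal DCT-II,
  coefficients sorted by descending magnitude with signed values kept
  and ties broken by original index; the 20 leading coefficients;
  N_DCT = smallest k whose leading-coefficient norm reaches 98% of the
  total; and, mapping coefficient l to frequency l·fs/(2N) over
  0–2.5 kHz: trapezoidal area of |coefficient| (AUC), maximum magnitude
  (Peak), and total squared-coefficient power (P).
* **Wavelets (12)** on the filtered epoch: 6-level dyadic (Mallat)
  decomposition for Haar and Db10 — one relative power per detail
  level, E_j = ‖detail_j‖²/‖epoch‖². The epoch is truncated to a
  multiple of 2⁶ samples (10 000 → 9984) so the periodization-mode
  transform is exactly orthogonal; detail-coefficient energies then
  equal reconstructed-subband energies (verified by a test), and
  details plus the final approximation partition the epoch energy to
  machine precision. A full wavelet-packet tree would yield 2^j values
  per level; one value per level matches the dyadic detail ladder.

Scale behavior is audited: Skew, Kurt, E, µ_Nakagami, N_DCT and the 12
relative powers are invariant under epoch rescaling; SD, RMS, IQR, AUC,
Peak and the sorted coefficients scale linearly; P_DCT and ω
quadratically.

## Discriminant

RMS (redundant with SD) and ω_Nakagami (outlier-prone) are excluded,
leaving 43 features. Features are z-scored **before** fitting (a
normalization applied after a projection cannot change it, and
standardization makes the weight entries comparable); the stored
means/SDs project new samples. Scatter matrices: S_W = Σ_c Σ_{x∈c}
(x−x̄_c)(x−x̄_c)ᵀ and S_B = Σ_c p_c (x̄_c−x̄)(x̄_c−x̄)ᵀ with p_c the class
row-proportions (priors are not modelled). The direction is the
eigenvector of the **largest** eigenvalue of
S_B φ = λ (S_W + ridge·tr(S_W)/d·I) φ — the Rayleigh-quotient maximizer;
a relative ridge of 10⁻⁶ keeps the solve determinate when S_W is
near-singular (S_B has rank ≤ 3 with four classes). ‖φ‖ = 1.

The model is fitted on epoch-level rows (thousands of rows stabilize
the 43×43 scatter estimates); hypothesis tests run on per-particle
averages. Because the projection is linear and the standardization
shared, the score of a particle's mean feature vector equals the mean of
its epoch scores.

Sign convention: a discriminant axis has no intrinsic orientation. By
default the largest-|weight| entry of φ is made positive. The pipeline
instead anchors orientation physically: when a `no_particle` reference
class is present, the sign is fixed so that its mean score lies at or
below the mean of the other class means — stronger back-scatter maps to
larger scores, which is the orientation a calibration curve of score
against Δn·d displays.

## Statistics

All tests run at particle granularity (n = 16/16/18/16). Kruskal–Wallis
(tie-corrected, χ² approximation, df = 3) screens each feature and the
score across the four classes; pairwise Mann–Whitney (two-sided; exact
enumeration when both groups are below 8 and tie-free, otherwise the
tie-corrected normal approximation) covers the six class pairs.
Significance is flagged at 0.05 and 0.001 with no multiple-testing
correction — the raw-p */** reporting style of exploratory screening.

Bhattacharyya separability between class pairs uses the univariate
Gaussian closed form per feature, averaged over the chosen subset
(comparing the 3 top-LDA-weighted features against the 3
bottom-weighted); the full multivariate Gaussian form is available via
``mode="multivariate"``. The Spearman correlation of per-class mean
score against Δn·d uses the four class values (empty trap contributes
Δn·d = 0) with a two-sided p.

## Numerical conventions and degenerate inputs

* z-scores, SD features and standardization use ddof = 1; Nakagami
  moment variance uses ddof = 0.
* Kruskal–Wallis on all-identical data returns H = 0, p = 1 rather than
  erroring; single-particle classes skip the Bhattacharyya report with a
  warning (the smoke-scale configuration).
* Constant epochs are rejected upstream (SD = 0); all-zero coefficient
  vectors raise rather than return NaN.
* DCT tie-break and the stable sort make feature vectors bit-reproducible.

## Problem sizes and runtime

The default study (66 × 120 s, ≈ 4.7 M samples per stage; ~3800 accepted
epochs × 45 features) runs end to end in under a minute on one CPU, so
tests exercise the full-scale design directly; unit tests use 2–20 s
acquisitions. Estimator-recovery tests use 10⁵ draws; the type-I-error
calibration uses 2000 simulated null datasets.

## Known limitations

* The generator is one consistent reading of the acquisition physics;
  class-specific spectral texture beyond the Nakagami envelope model is
  not represented, and absolute feature values are not comparable to
  real hardware.
* Whether the DCT summary features (AUC/Peak/P) should be computed on
  the envelope or the raw signal is ambiguous in the source protocol;
  the envelope is used throughout for consistency with the sorted
  coefficients. Swapping to the raw signal is a one-line change in
  `featurize` if a sensitivity analysis is wanted.
* Only one discriminant component is produced by design; non-linearly
  separable class structures would need kernel or multi-component
  extensions.
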