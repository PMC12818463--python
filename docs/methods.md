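# Methods

This note documents the models implemented in `spafnirs`, the choices made
where the design was genuinely open, and what the synthetic study does and
does not establish about real recordings.

## Forward model (synthetic data)

All signal composition happens in chromophore-concentration space (μM),
per channel, on the 5.1 Hz acquisition clock; optical density follows as
`OD(λ,t) = [ε_HbO(λ)·ΔHbO(t) + ε_HbR(λ)·ΔHbR(t)]·d·DPF(λ)` and intensity as
`I = exp(−OD)` with unit baseline. Only relative intensity changes are
meaningful, so the baseline is fixed at 1 per channel/wavelength. The
natural-log convention is used on both the forward and inverse sides, which
makes the preprocessing chain the exact algebraic inverse of the generator —
the basis of the machine-precision round-trip tests.

Components:

- **Neural response.** ROI-specific speech amplitudes (defaults IFG 0.4,
  primary auditory 1.2, secondary auditory 0.7 μM HbO; HbR = −0.35 × HbO;
  silence 0), shaped as the canonical double-gamma HRF convolved with the
  6 s stimulus boxcar and peak-normalized, so betas read as μM of peak
  evoked response. Subject × ROI random effects (sd 0.5 μM) and session
  effects (sd 0.1 μM) define the true reliability of the study.
- **Scalp component.** Stimulus-locked vasoconstriction with negative HbO
  sign (mean −1.5 μM, sd 0.5 across subject-sessions) plus a slow
  0.04–0.12 Hz scalp oscillation (0.8 μM). Short channels carry it at full
  gain, long channels at 0.5. This is the component that biases
  uncorrected speech betas negative and that short-channel regression is
  designed to remove.
- **Systemic physiology.** Six latent unit-variance processes: a ~0.25 Hz
  respiration oscillator and ~1.1 Hz cardiac oscillator (both with slowly
  drifting rate), and band-limited Gaussian processes for heart-rate
  variability (≲0.05 Hz), palm temperature (≲0.03 Hz), skin conductance
  (≲0.08 Hz) and SpO2 (≲0.01 Hz). Several latents additionally carry
  task-evoked autonomic responses (delayed gamma kernels, amplitudes 0.03–
  0.25 z with 50% session-to-session variation) — the mechanism by which
  listening tasks modulate breathing and arousal. Channels receive each
  latent at a per-channel lag (subject-level base lag uniform in 2–8 s,
  ±0.5 s channel jitter, clipped to [0, 10] s) and gain (signal-level gains
  0.12–0.7 μM/z for the slow signals, lognormal per-channel modulation).
  The cardiac latent is injected at 1.5 μM (×3 in the highly pulsatile
  short channels) and is what gives coupled channels their scalp coupling
  index; "decoupled" channels replace the optical signal with independent
  noise. Body physiology leaks into short channels only weakly (factor
  0.05): the scalp expression of systemic processes is small relative to
  local scalp hemodynamics, which is precisely why short-channel regression
  cannot remove them and the tCCA stage has a role.
- **Sensors.** The auxiliary sensors record the *same* latents (resampled
  to each sensor's own rate, 1–25 Hz, plus 0.05 z sensor noise and
  unit offsets), which makes physiology-informed denoising identifiable
  and lets tests assert that channel noise and aux traces share a process.
- **Measurement noise.** White OD noise, sd 1e-3 per sample.
- **Digitization.** Optode coordinates come from a 10-10 template computed
  on an 85 mm spherical head (standard angular layout; chains interpolated
  on circles through their endpoints and midline anchor). Per subject the
  template is scaled (sd 3%), and each session's scan adds a rigid cap
  translation (sd 3.2 mm/axis) plus isotropic per-optode jitter
  (sd 2.0 mm), both scaled by a subject-level lognormal digitization-quality
  factor (sd 0.45) — hair and cap fit make placement error strongly
  subject-dependent. These defaults emulate the ~9 mm cross-session optode
  drift typical of cap re-placement in adults; fiducials are anatomical and
  never jittered.

Event schedules randomize 40 speech + 10 silence trials with uniform
15–30 s inter-stimulus gaps and 90 s lead-in/lead-out rest, giving ~26 min
recordings. All generator outputs are pure functions of (config, seed);
the study seed is expanded through per-subject/per-session substreams so
adding subjects does not perturb existing ones.

## Preprocessing

OD conversion references each channel's temporal mean (gauge-invariant
under intensity rescaling). The scalp coupling index is the zero-lag
correlation of the two wavelengths' 0.7–1.5 Hz band-passed OD (3rd-order
zero-phase Butterworth); convention fixes only the 0.7 retention
threshold, and the cardiac band here follows the standard definition. SCI
is computed on OD at the native rate, before any other filtering. Pruned
channels are dropped, not interpolated; short channels failing SCI are
excluded from the nuisance means.

Beer–Lambert inversion solves the per-channel 2×2 system with bundled
molar extinction coefficients (Prahl compilation values at 760/850 nm) and
DPF 6.0 at both wavelengths (configurable); nominal separations (30/8 mm)
are used as pathlengths. Hemoglobin is computed first and then resampled
to 0.6 Hz (polyphase FIR, exact 2/17 rational ratio, mean-padded edges so
constants pass through exactly).

Physiology conditioning z-scores each sensor on its native grid, low-passes
at 0.5 Hz (skipped when the sensor's Nyquist is below the cutoff), linearly
interpolates onto the fNIRS grid, and flags constant signals as unusable.

## Design matrix and GLM

Task regressors are built at the acquisition rate and passed through the
*same* resampling operator as the data ("filter the design like the data");
this is what makes noise-free recovery exact rather than merely close.
Drift is a discrete-cosine basis with frequencies below 0.015 Hz
(K = ⌊2·T·f_c⌋ columns, orthogonal by construction); a single constant
column completes the model; nuisance columns are appended raw, without
orthogonalization — the OLS fit handles shared variance, which is the
correct treatment when nuisance and task regressors genuinely overlap.
Fitting is multi-target OLS via QR (ridge fallback with a warning on rank
deficiency); standard errors come from σ²·diag((XᵀX)⁻¹).

ROI aggregation weights channels by 1/SE (the convention adopted here,
deliberately not the inverse-variance 1/SE²); degenerate zero SEs are
clipped so noise-free fits reduce to unweighted means. Group summaries use
the balanced two-stage estimator — subject-level ROI means, then a
one-sample t-test — which for a balanced design is the random-intercept
mixed-model estimate of the group response; sessions are summarized
separately rather than pooled. Block averages use a (−2, 15) s window with
pre-onset baseline subtraction.

## Denoising models

- `none`: task + drift + constant.
- `ss`: adds the mean retained short-channel HbO and HbR series.
  Near-constant columns (degenerate montages, or zero scalp signal) are
  dropped with a warning rather than poisoning the design.
- `ss_tcca`: screening first — a physiology signal enters if its maximum
  absolute Pearson correlation with the mean retained long-channel HbO
  series, over relative lags up to 10 s *in either direction* (autonomic
  signals may lead or lag the hemodynamics), reaches 0.3. Included signals
  are lag-embedded (0–10 s, 1-sample steps at 0.6 Hz → 7 columns each) and
  one global canonical decomposition is fitted against the retained
  long-channel HbO block (Cholesky-whitened SVD; ridge 1e-4 × mean block
  variance on rank deficiency). Aux-side variates with canonical
  correlation ≥ 0.3 join the SS columns. The 0.3 criterion is applied at
  both stages (screening and component retention), each separately
  configurable, since per-signal correlations and canonical correlations
  are different quantities. One tCCA is fitted per session (global across
  channels) with per-(channel, signal) optimal lags recorded from the
  lagged cross-correlations — a deliberate interpretation; a per-channel
  CCA would multiply parameters ~40-fold for little identifiable gain at
  ~1000 working-rate samples.

A caveat the tests document explicitly: at the working dimensions (42
embedded aux columns × 38 channels × ~1000 samples) the *null* largest
canonical correlation concentrates near 0.39, so the 0.3 retention
criterion admits a few chance components even for independent blocks.
These cost degrees of freedom but do not bias the task betas; raising the
retention threshold is a config knob, not a default.

## Reliability and geometry

ICC(3,1) is computed from the explicit two-way ANOVA decomposition without
interaction (consistency form: additive session shifts do not reduce it),
with subject × ROI rows and the two sessions as raters; the pooled value is
the headline number and per-ROI ICCs are reported alongside. Bands use
half-open intervals (poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent),
closing the gaps the conventional verbal definition leaves open; negative
estimates are reported as computed and banded poor.

Geometry: Euclidean shift per optode and channel midpoint between sessions;
per-optode cross-subject dispersion as the composite SD (square root of the
summed per-axis sample variances, n−1; per-axis SDs are also emitted so
either reading of a composite-SD convention is recoverable). Both the
pooled grand mean over subject × optode shifts and the mean of per-optode
means are reported, since the two differ under unbalanced data. The
shift-vs-|Δβ| association uses Pearson correlation over pooled
channel × subject pairs (Spearman optional). Coordinates are consumed as
fiducial-anchored MNI; no re-registration is performed. Note that pooling
clustered channels makes the nominal p anti-conservative — in the
generator, where shift and beta change are independent by construction,
single-study r estimates scatter widely around a zero mean.

## What the simulations show — and what they cannot

Passing tests establish that the pipeline's inferential machinery is
correct (exact inverses, calibrated SEs, ICC matching its ANOVA oracle and
the theoretical variance ratio) and that under the modeled noise structure
the denoising hierarchy behaves as designed: beta RMSE against ground
truth and cross-session ICC both order none ≤ ss ≤ ss_tcca, the ordering
being strict in roughly 80–100% of 20-study replicates, with all three
models in the excellent ICC band. The screening stage reproduces the
expected sensor hierarchy (respiration and temperature far above the 0.3
criterion; SpO2 and the pulse waveform lowest, the latter because the
0.5 Hz low-pass removes cardiac-rate content).

The generator is a structural emulation, not a biophysical one: no photon
transport or layered head model, sinusoidal-plus-drift physiology rather
than measured autonomic dynamics, Gaussian placement error rather than
digitizer artifacts, and coupling gains chosen for plausibility since no
measurement of them exists in the study design being emulated. Results on
real recordings depend on those unmodeled features; what the synthetic
study guarantees is that when the assumed signal structure holds, the code
measures what it claims to measure.

## Problem sizes

Default analyses use the full study structure (15 subjects × 2 sessions,
46 channels, ~26 min at 5.1 Hz, ~950 working-rate samples). Replicate-based
checks use 20 studies; the ICC calibration uses 1000 simulated 500×2
tables; null-distribution checks use 200–500 Monte-Carlo draws. A full
study runs in a few seconds, the complete replicate battery in under two
minutes on one CPU.
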