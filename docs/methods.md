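# Methods

## Problem and signal model

During resuscitation from cardiac arrest, rescuers must pause chest
compressions to check for a pulse; pausing is harmful when the patient is
pulseless. Among *organized* rhythms (discrete, repetitive QRS complexes),
the clinically urgent distinction is between a perfusing rhythm (pulse)
and pulseless electrical activity. `pulsewave` implements an ECG-only
classifier of pulse presence that works both during ongoing CPR — when the
ECG is contaminated by compression artifact — and during the compression
pause.

Each pulse check contributes a *segment pair*: a 10 s single-lead ECG strip
recorded during CPR immediately followed by a 5 s strip recorded during the
pause, sharing one binary label. Models for the two phases are trained and
evaluated separately, since the during-CPR strips carry a quasi-periodic
artifact concentrated at the manual compression rate (~2 Hz, i.e.
100–120 compressions/min) with harmonics reaching ~20 Hz — squarely inside
the QRS band, which is why the artifact is *not* filtered out but handed to
the feature stage.

## Pipeline

1. **Conditioning.** Resample to a common 250 Hz (devices record at 125 or
   250 Hz; polyphase, exact rational factor, Kaiser β=8 window), low-pass
   at 40 Hz (4th-order Butterworth, zero phase) so every device contributes
   the same usable bandwidth (the slowest device's Nyquist is 62.5 Hz),
   then band-pass 1–40 Hz with a 4th-order Butterworth applied
   forward–backward. Zero-phase filtering preserves QRS timing; the 1 Hz
   corner removes drift and DC.

2. **Scalogram.** Continuous wavelet transform with a *bump* mother
   wavelet, defined in the frequency domain as
   `Ψ̂(ω) = exp(1 − 1/(1 − ((ω−μ)/σ)²))` on `(μ−σ, μ+σ)`, zero elsewhere
   (defaults μ=5, σ=0.6 in normalized angular frequency). The transform
   uses the `1/a` kernel normalization
   `Ψ_{a,b}(t) = (1/a) Ψ((t−b)/a)` (an L² `1/√a` variant is available).
   The scale grid is logarithmic, 10 voices per octave, spanning
   pseudo-frequencies 0.5–40 Hz (65 scales). The feature image is the
   energy surface `E(a,b) = |W(a,b)|²`.

3. **Vectorization.** Energy is log-transformed (`log(E + 1e−12)`),
   mean-pooled to a fixed 64 × 128 (scales × times) grid and flattened
   column-major. The log is essential: the compression band carries orders
   of magnitude more energy than the QRS band, and without compression the
   leading PCA modes merely track artifact loudness (on synthetic cohorts
   the log raises CPR-phase grouped CV AUC by ≈0.08). Pooling makes 5 s
   and 10 s strips, and 125 vs 250 Hz devices, commensurable and bounds
   the pixel dimension at m = 8192.

4. **PCA modes.** Training-split vectors form the columns of `A` (m × n).
   After per-pixel centering and unit-variance scaling (zero-variance
   pixels pass through), the SVD `A = U Σ Vᵀ` ranks spatial modes by
   variance fraction `σᵢ²/Σσⱼ²`. Modes above a 1% cutoff are retained
   (at most 10), and the production model fixes r = 3 for parsimony.
   A segment's features are `U_rᵀ((x − mean)/scale)`.

5. **Classification.** Linear discriminant analysis on the 3 mode
   coordinates: `w = S⁻¹(μ₁ − μ₀)` with pooled covariance `S`; the score
   `w·x + b` is the signed distance to the separating hyperplane and
   monotone in the posterior log-odds. A numerically singular `S` is
   ridge-regularized by `1e−6·trace(S)` with a warning. The binary
   operating threshold is set on training scores at the Youden-optimal
   point. QDA, SVM (RBF, small grid search), logistic regression, random
   forest (tree count by out-of-bag error) and a generative
   Gaussian-mixture classifier are available for the model-comparison
   harness; neural networks are deliberately excluded at this data scale.

6. **Evaluation.** AUC by the Mann–Whitney rank formulation (ties ½);
   95% CIs by stratified percentile bootstrap (B = 2000, resampling
   within class); sensitivity/specificity at the Youden-optimal operating
   point, ties broken toward specificity; correlated AUCs compared with
   the DeLong placement-value test. Cross-validation is 5-fold and
   *patient-grouped*: folds partition patients (stratified by label,
   seeded shuffle), and the PCA basis and classifier are refit inside
   every training fold, so no validation statistic leaks into a fit.

## Numerical choices

- **CWT evaluation.** The transform is a frequency-domain
  cross-correlation: `W = ifft(fft(x_pad) · Ψ̂(aω))`. Because the bump
  kernel is exactly band-limited, sampling it on the FFT grid is exact and
  the only approximation is circular wrap-around of the wavelet's time
  tails. Zero-padding by `pad_tail_mult` multiples of the largest scale
  controls this: the default (16) is accurate to ~1e−4 of the peak
  coefficient — ample for classification — while the quadrature-
  equivalence tests use 200, where the FFT route matches a naive O(n²)
  Riemann-sum of the transform integral to better than 1e−6 relative
  error. Kernels are cached per (spec, length, rate).
- **Zero-phase filtering** pads by the larger of 3× the filter length and
  two time constants of the slowest corner (the 1 Hz edge rings for ~2 s;
  the default 3×-order pad would leak startup transients into 5 s clips).
- **SVD sign convention.** Each mode is oriented so its largest-magnitude
  pixel loading is positive; otherwise archived bases would not be
  byte-reproducible.
- **Determinism.** Every stochastic step (cohort synthesis, fold
  assignment, bootstrap, RF/SVM/GMM fits) is driven by an explicit seed;
  per-patient streams are spawned from a root `SeedSequence`, so cohorts
  are byte-identical given a spec.

## Synthetic cohort generator

The defibrillator recordings the pipeline targets are not publicly
available, so the package ships a generator that emulates their structure:
paired 10 s + 5 s strips per pulse check with the beat train continuous
across the boundary; 1–6 checks per patient (mean ≈ 2, capped at 3 per
label per patient); ~38% of checks labelled pulse; device rates 125 or
250 Hz; a 60/40 patient-level train/test split.

Beats are parametric: the QRS is a biphasic Gaussian-derivative pulse,
P/T waves are Gaussian bumps at fixed fractional RR offsets. Class
presets encode the reported contrast between perfusing and pulseless
rhythms — Pulse: 90 bpm, 0.08 s QRS, 1.0 mV; No-Pulse: 45 bpm, 0.16 s,
0.5 mV — with per-patient lognormal variation (sd 10%) and RR jitter.
Compression artifact is a harmonic series at 2 Hz (amplitude 2.0 mV,
geometric decay 0.5 per harmonic, overtones to 20 Hz) whose per-cycle
phase (sd 0.3 rad) and depth (lognormal sd 0.15) vary smoothly between
cycle centers; stepped jitter was rejected because its discontinuities
inject non-physiologic broadband clicks. Baseline wander (0.2 mV at
0.3 Hz) and white noise (0.02 mV) complete the model. No quantitative
class-conditional distributions are published, so the presets are
descriptive, not calibrated.

**What passing tests do and do not show.** The generator reproduces the
*structure* of the clinical data (pairing, caps, prevalence, rates,
artifact spectrum), not its difficulty: the presets separate the classes
far more cleanly than real patients do, and with them the end-to-end
synthetic task saturates (grouped CV and test AUCs near 1.0 in both
phases, versus 0.79–0.89 reported clinically). Green end-to-end tests
therefore demonstrate that the pipeline extracts and generalizes a
morphology/rate/amplitude signal under heavy in-band artifact without
leakage — not that it would attain any particular accuracy on clinical
recordings. Ventricular fibrillation and asystole waveforms, thoracic
impedance and audio channels are out of scope; the pipeline assumes an
organized rhythm.

## Problem sizes used by the test suite and acceptance script

End-to-end checks use 100-patient cohorts (~220 pairs) for the headline
run and seed sweep, 30-patient cohorts for the 20-seed null (label
permutation at the patient level), and 14–20-patient cohorts for
pipeline/CLI contract tests. Bootstrap coverage is assessed with 200
replications at test-split-like sizes (138 positives / 234 negatives,
true AUC 0.85). The quadrature-equivalence oracle runs on 256- and
512-sample clips.

## Known limitations

- The bump wavelet's exact shape parameters and the pooling resolution
  used in the original analysis are unpublished; defaults here are the
  standard parameterization (μ=5, σ=0.6) and a 64×128 grid, both
  configurable.
- "Optimal operating point" is implemented as Youden's J (unit costs);
  cost-weighted operating points are not built in.
- The candidate-model harness reports CV AUCs only; it does not implement
  the earlier hand-crafted-feature algorithm it would be compared against
  in a clinical study — the DeLong harness accepts any two score files on
  a shared case manifest.
- WFDB-format ingestion is not included; CSV segments plus a cohort
  manifest are the interchange format.
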