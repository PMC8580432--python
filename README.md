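# pulsewave

Detecting a spontaneous pulse from the ECG **during ongoing chest
compressions**. Resuscitation protocols interrupt CPR to check for a
pulse, but pausing compressions harms patients who turn out to be
pulseless. Among organized rhythms, `pulsewave` classifies single-lead
defibrillator ECG strips as *pulse* vs *no pulse* — both during CPR
(artifact-contaminated 10 s strips) and during the pulse-check pause
(clean 5 s strips) — for researchers in resuscitation science and
biomedical signal processing.

## Method

For an ECG segment f(t), the pipeline computes

1. **Conditioning** — resample to 250 Hz, low-pass 40 Hz, zero-phase
   4th-order Butterworth band-pass 1–40 Hz. Compression artifact
   (~2 Hz fundamental, harmonics to ~20 Hz) is deliberately left in band.
2. **Scalogram** — continuous wavelet transform with a bump mother
   wavelet, Ψ_{a,b}(t) = (1/a) Ψ((t−b)/a),
   W(a,b) = ∫ f(t) Ψ̄_{a,b}(t) dt, energy E(a,b) = |W(a,b)|²,
   on a logarithmic scale grid spanning 0.5–40 Hz.
3. **PCA modes** — log-energy scalograms are pooled to a 64×128 grid,
   vectorized into the columns of A, centered/normalized per pixel, and
   decomposed as A = U Σ Vᵀ; modes with >1% variance are retained
   (max 10), with r = 3 in the production model.
4. **Classification** — linear discriminant analysis on the three mode
   coordinates: score(x) = wᵀx + b with w = S⁻¹(μ₁−μ₀).
5. **Evaluation** — Mann–Whitney AUC, stratified percentile-bootstrap
   95% CIs, Youden-optimal sensitivity/specificity, DeLong tests for
   correlated AUCs, and patient-grouped 5-fold cross-validation with the
   full feature basis refit inside each fold.

Because the clinical defibrillator recordings are not publicly
deposited, the package includes a first-class synthetic cohort generator
(paired 10 s + 5 s strips per pulse check, ≤3 periods per label per
patient, ~38% pulse prevalence, 125/250 Hz devices, 60/40 patient-level
split, harmonic CPR artifact with cycle-to-cycle phase/depth jitter).
See `docs/methods.md` for the model, every default, and what the
synthetic results do and do not establish.

## Worked example

```sh
pulsewave simulate --n-patients 30 --seed 11 --out demo/cohort
pulsewave train    --manifest demo/cohort/manifest.csv --out demo/model --seed 11
pulsewave evaluate --archive demo/model --manifest demo/cohort/manifest.csv --out demo/eval
```

prints

```text
wrote 57 segment pairs (18 train / 12 test patients) -> demo/cohort/manifest.csv
cpr: train CV AUC 1.000
pause: train CV AUC 1.000
archived -> demo/model
cpr: AUC 1.000 (95% CI 1.000-1.000), sens 1.00 spec 1.00
pause: AUC 1.000 (95% CI 1.000-1.000), sens 1.00 spec 1.00
```

Reading the output: `train CV AUC` is the patient-grouped 5-fold
cross-validated AUC on the training split (basis and classifier refit
per fold); the `evaluate` lines give test-split AUC with bootstrap CI
and the sensitivity/specificity at the Youden-optimal threshold, per
phase. The default synthetic presets separate the two classes much more
cleanly than real patients do, so AUCs saturate near 1.0 here — the
clinical problem is far harder. Narrow the morphology gap via
`CohortSpec.class_params` to make the task arbitrarily difficult.

Other verbs: `predict` scores new segment CSVs with an archived model
(refusing phase or sampling-rate mismatches), `compare` runs a DeLong
test between two score files on a shared case manifest, and `benchmark`
grids train CV AUC over registered mother wavelets × classifier kinds
(LDA, QDA, SVM, GMM, logistic regression, random forest).

The same stages are available as a library:

```python
import pulsewave as pw

cohort = pw.generate_cohort(pw.CohortSpec(n_patients=100, seed=1))
table = pw.featurize_phase([r.pair.cpr for r in cohort], pw.PipelineConfig())
res = pw.cv_auc(table.X, table.labels, table.patients, k=5, seed=1)
print(f"CPR-phase grouped CV AUC: {res.mean_auc:.3f}")
```

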