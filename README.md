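# skinraman

Depth-resolved confocal Raman chemometrics for discriminating atopic-eczema
from healthy skin.

Atopic dermatitis disrupts the stratum corneum: natural moisturizing factor
(NMF) and ceramide content drop, trans-epidermal water loss (TEWL) rises, and
these changes leave fingerprints in the 400–1800 cm⁻¹ Raman spectrum of the
skin surface. `skinraman` implements the full analysis chain used in such
studies — in-vivo depth stacks in, biomarker bands out:

1. **Simulation** — a synthetic cohort generator producing per-subject depth
   stacks (10 depths × 10 µm, 1384-point grid) of Lorentzian constituent
   peaks on a fluorescence background, with class-dependent band intensities,
   detector noise, and TEWL covariates (eczema 17.77 ± 9.09 vs healthy
   10.58 ± 2.80, n = 52 vs 20).
2. **Preprocessing** — asymmetric least squares (AsLS) baseline removal,
   Savitzky–Golay smoothing, skin-surface localization at the keratin
   amide-I (1655 cm⁻¹) depth maximum, and standard normal variate (SNV)
   normalization of the selected surface spectrum.
3. **Classification** — PLS-DA via NIPALS on the centered 0/1-coded class
   response: for each latent variable *a*,
   `w_a = X'y/‖X'y‖`, `t_a = X w_a`, `p_a = X't_a/t_a't_a`,
   `q_a = y't_a/t_a't_a`, with deflation `X ← X − t_a p_a'`,
   `y ← y − q_a t_a`, and regression vector `B = W(P'W)⁻¹q`. The number of
   latent variables is chosen by the first minimum of the stratified
   K-fold cross-validated misclassification rate.
4. **Evaluation** — stratified K-fold confusion matrices, sensitivity /
   specificity, vertically averaged ROC with trapezoid AUC, Welch's t-test
   for covariates, and a PCA-reduced reference-classifier comparison
   (LDA, logistic regression, naive Bayes, KNN, linear SVM).
5. **Biomarkers** — variable importance in projection,
   `VIP_j = sqrt(p · Σ_a SS_a w_ja² / Σ_a SS_a)` with
   `SS_a = q_a² t_a't_a`; wavenumbers with VIP ≥ 1 are flagged important and
   annotated against a packaged stratum-corneum peak library.

Everything is exposed as scikit-learn-style estimators (`PLSDAClassifier`,
`SpectralPCA`, `AslsBaseline`, `SavitzkyGolaySmoother`, `SNVNormalizer`)
that compose with sklearn pipelines, plus thin functional wrappers and a
command-line interface.

## Worked example

```python
import skinraman as sr

config = sr.CohortConfig(seed=0)                  # 52 eczema / 20 healthy
records = sr.generate_cohort(config)              # depth stacks + covariates
dataset = sr.preprocess_cohort(records)           # 72 x 1384 surface spectra

curve = sr.select_num_lvs(dataset, A_max=10, K=10, seed=0)
report = sr.cross_validate_plsda(dataset, A=curve.chosen_A, K=10, seed=0)
print(f"latent variables: {curve.chosen_A}")
print(f"sensitivity {report.sensitivity:.2f}, specificity {report.specificity:.2f}")

model = sr.pls_fit(dataset, curve.chosen_A)
table = sr.annotate_vip_peaks(model.vip(), sr.load_peak_library(), dataset.grid)
print(table[table.important].head(6).to_string(index=False))
```

prints

```
latent variables: 2
sensitivity 1.00, specificity 1.00
 center_cm1                                            assignment  max_vip  important
      702.0                                           cholesterol 1.215557       True
      855.0 nu(C-C) of proline, delta(CCH) of protein; NMF region 3.722025       True
      885.0                     pyrrolidone carboxylic acid (NMF) 2.345003       True
      906.0                                 tyrosine (amino acid) 2.008134       True
      937.0            nu(C-C) alpha-helix conformation (protein) 1.024090       True
     1003.0               nu(C-C) ring breathing of phenylalanine 2.474648       True
```

The default synthetic cohort separates cleanly (two latent variables,
perfect 10-fold CV recovery), and the VIP profile flags exactly the bands
where the generator makes the classes differ: the NMF / amino-acid region
(855–906 cm⁻¹), amide III and the ceramide III twist (1270–1296 cm⁻¹), the
CH₂/CH₃ deformation shoulder (1420–1452 cm⁻¹), and amide I
(1645–1655 cm⁻¹) — the biomarker bands reported for eczematous stratum
corneum. Clinical spectra carry more uncorrelated subject variability, so
real-cohort metrics are lower (sensitivity/specificity around 0.9).

The same pipeline from a shell:

```sh
skinraman simulate   --out-dir run/sim --seed 0
skinraman preprocess --spectra run/sim/cohort_spectra.csv \
                     --metadata run/sim/cohort_metadata.csv --out-dir run/pre
skinraman analyze    --dataset run/pre/processed_dataset.csv --out-dir run/ana
skinraman report     --run-dir run/ana
```

## Layout

- `src/skinraman/simulate.py` — cohort generator, peak library, cohort CSV dialect
- `src/skinraman/preprocess.py` — AsLS / Savitzky–Golay / surface / SNV transformers
- `src/skinraman/chemometrics.py` — `PLSDAClassifier`, `SpectralPCA`, VIP, annotation
- `src/skinraman/evaluate.py` — folds, CV reports, ROC/AUC, Welch test, reference classifiers
- `src/skinraman/cli.py` — `skinraman` console commands
- `docs/methods.md` — model assumptions, parameter choices, limitations
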