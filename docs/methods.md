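# Methods

## The analysis problem

The pipeline classifies subjects as eczema or healthy from one Raman
spectrum of the skin surface per subject, acquired as a depth stack
(10 spectra, 10 µm apart) on the volar forearm, and then asks *which
wavenumbers carry the discrimination*. Because clinical spectra of this
kind are not publicly deposited, the package ships a synthetic cohort
generator that reproduces the statistical structure the analysis relies
on; every downstream stage is developed and tested against it.

## Synthetic cohort model

A subject's clean spectrum is a sum of Lorentzian lines
`a·w²/((ν−c)²+w²)` over a packaged stratum-corneum peak library
(31 bands, 543–1768 cm⁻¹). Line positions and assignments are standard
skin-Raman band values; **widths (4–12 cm⁻¹ HWHM) and base amplitudes are
invented defaults**, not measurements. The Lorentzian is the natural Raman
line shape; its heavy tails mean "the class effect is confined to the
discriminative bands" holds up to tails below 0.1 % of the peak effect.

Class structure. The healthy profile is the unit reference. The eczema
profile multiplies peak amplitudes inside four discriminative intervals —
850–930 (NMF / amino acids, ×0.80), 1240–1330 (amide III / ceramide III,
×0.82), 1410–1480 (CH₂/CH₃ deformation, ×1.12), 1640–1680 cm⁻¹ (amide I,
×1.22). Directions follow the biology (NMF and ceramide depletion in
eczema); the magnitudes were calibrated once so that the full pipeline
recovers the class structure robustly, and are not claimed to be
physiological.

Per-subject variability: lognormal peak-amplitude jitter
(`peak_jitter_sd` = 0.10) and a lognormal global intensity scale
(`subject_scale_sd` = 0.15, removed by SNV). Acquisition effects: a
decaying-exponential fluorescence baseline `2.0·exp(−(ν−400)/400)` and
i.i.d. Gaussian detector noise (σ = 0.02, about 2 % of a strong peak).
Poisson shot noise, cosmic rays, and wavelength-calibration error are out
of scope. TEWL is drawn from untruncated normals (eczema 17.77 ± 9.0891,
healthy 10.58 ± 2.7964) so the printed moments are exactly recoverable;
physical non-negativity is not enforced. The depth response is a Gaussian
in depth index (σ = 1.5 rows, maximum 1 at the true surface row), which
makes surface localization exact in the noiseless limit.

All randomness flows from a single `seed` through a splittable
`numpy.random.SeedSequence`; an identical `CohortConfig` reproduces the
cohort bit for bit.

### What the generator does *not* emulate

Within-class covariance in real cohorts is richer (age, hydration,
site-to-site variation, instrument drift), and real class effects are far
subtler. Passing recovery tests on this generator demonstrates that the
pipeline machinery is correct and unbiased — not that clinical
sensitivity/specificity of a given level is attainable. The default
cohort is deliberately well separated; clinical data sit closer to the
decision boundary.

### lv_recovery mode

A controlled factor-model variant used to validate latent-variable
selection. The class band multipliers and the jitter/scale nuisance are
switched off; instead four mutually orthogonal unit-norm spectral factors
(raised-cosine bumps on disjoint windows: 1020–1140, 1340–1460, 415–535,
1462–1542 cm⁻¹) carry the entire class signal. Factor scores are normal
with class-mean offsets ±(0.54, 0.39, 0.30, 0.27) — descending effect
size — and within-class standard deviations (1.60, 0.75, 0.38, 0.014).
Each factor additionally carries a constant positive offset
(effect + 3·sd) so that the asymmetric baseline corrector, which follows
dips but ignores peaks, transfers the class modulation linearly; without
the offset, negative-going factor deviations are partially absorbed into
the baseline and the factor geometry is distorted. These values were
calibrated once so that the first-minimum rule recovers exactly four
latent variables reliably (24/24 generator seeds during development), and
then frozen. The large-variance factors force the classifier to spend one
component per factor; the fourth, low-variance factor is decisive for the
last few subjects, so the CV error curve reaches its minimum at exactly
four components.

## Preprocessing

Order: per-depth AsLS baseline removal → Savitzky–Golay smoothing →
surface localization → SNV of the selected surface spectrum only.
Rationale: baseline and smoothing are per-spectrum operations needed
before the amide-I depth profile is meaningful; SNV is applied last and
only to the spectrum that enters classification.

* **AsLS** — the baseline `z` minimizes
  `Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²zᵢ)²`, `wᵢ = p` above the baseline and `1−p`
  below, iterated from uniform weights until the weights change by less
  than `tol` (max |Δw|) or `max_iter` sweeps. Defaults λ = 10⁵, p = 0.01,
  max_iter = 10, tol = 10⁻⁶ — canonical ranges for Raman fluorescence
  backgrounds; all exposed in `PreprocessConfig`. The pentadiagonal system
  is solved with a symmetric banded Cholesky factorization per iteration.
  Known limitation: with λ = 10⁵ the baseline partially rides up under
  *broad, overlapping* bands (e.g. the 1645/1655 amide-I cluster), so
  exact idempotence holds only when baseline and peak length scales are
  separated; on crowded spectra a second correction pass can move the
  signal by a few percent of its range. Negative intensities after
  subtraction are retained — clipping would bias SNV.
* **Savitzky–Golay** — window 11 points, order 3 by default; edges are
  handled by fitting the polynomial on the truncated window.
* **Surface localization** — argmax over depths of the intensity at the
  grid point nearest 1655 cm⁻¹ (exact keratin amide-I marker); a
  `surface_halfwindow_cm1` option averages a window instead, since "the
  intensity profile at 1655" is ambiguous between point and band. Ties
  break toward the shallowest depth.
* **SNV** — per-spectrum standardization with the sample (n−1) standard
  deviation; constant spectra raise a degenerate-input error.

## PLS-DA

Classes are coded healthy = 0, eczema = 1 (eczema is the positive class),
centered before NIPALS; no column scaling (the response is already
mean-centered and SNV equalizes spectra row-wise). NIPALS with deflation
of both X and y is used — rather than SIMPLS or kernel PLS — because the
VIP score is defined on NIPALS weight vectors, which are normalized to
unit length at extraction. Components whose score variance falls below
10⁻¹² of the first component's are truncated with a warning; zero
covariance at the first component is a degenerate-fit error. The decision
threshold is fixed at 0.5, the midpoint of the coding, and the boundary
itself counts as positive. The implementation agrees with an independent
NIPALS PLS regression and, in the full-component limit, with ordinary
least squares (both asserted in the test suite at 10⁻⁸).

Latent-variable count: the first-minimum rule — the smallest A whose
stratified K-fold CV misclassification rate ties the curve minimum within
10⁻¹². A one-standard-error rule was considered and rejected as default
to keep the selection criterion identical to the error curve it is read
from. Calibration (training) error is also reported; it is non-increasing
in A.

VIP: `VIP_j = sqrt(p · Σ_a SS_a w_ja² / Σ_a SS_a)` with
`SS_a = q_a² t_a't_a`, so the mean squared score is 1 and `Σ VIP² = p`;
wavenumbers with VIP ≥ 1 are important. The published verbal description
of VIP ("weighted sum correlation between latent variables") is not a
formula; the standard VIP of the PLS literature is adopted. VIP is
computed on the full-data model by default; a fold-averaged variant can
be obtained by fitting per training fold and averaging profiles.

## Evaluation

* **Folds** — within each class, indices are shuffled (seeded) and dealt
  round-robin, so per-fold class counts deviate from proportionality by
  at most one; with 52/20 at K = 10 every fold holds exactly 2 healthy
  and 5–6 eczema subjects.
* **Metrics** — per-fold confusion matrices are summed into the aggregate;
  accuracy is also reported as the across-fold mean ± SD (matching the
  "0.92 ± 0.05" presentation style). Sensitivity = tp/(tp+fn),
  specificity = tn/(tn+fp). Summaries round to 2 decimals; JSON reports
  keep full precision.
* **ROC/AUC** — thresholds sweep the unique continuous scores; curves are
  anchored at (0,0) and (1,1); AUC is the trapezoid area and equals the
  pairwise concordance statistic. The mean ROC is a vertical average:
  per-fold TPR interpolated on a common 101-point FPR grid. Folds whose
  test split contains a single class are excluded from AUC aggregation
  with a warning.
* **Welch's t-test** is used for TEWL because the group SDs differ more
  than threefold; degrees of freedom by Welch–Satterthwaite.
* **Reference classifiers** — PCA (fit on training folds only, never on
  test data) followed by LDA, logistic regression, or a linear SVM from
  scikit-learn, plus natively implemented Gaussian naive Bayes and
  k-nearest-neighbors (k = 4; the published comparison table's
  "naive Bayes (nearest neighbors = 4)" row is internally inconsistent
  and is treated as a KNN row). SNV is per-spectrum and therefore
  leak-free across folds; centering and PCA are refit inside folds.

Null behaviour: on label-permuted noise data, mean CV accuracy approaches
the majority-class rate only while the held-out score spread is small
relative to the 0.22 margin between the class-mean coding and the 0.5
threshold. With many noise features the spurious fitted directions widen
the held-out score distribution and null accuracy falls below the
majority rate (≈0.61 at 60 features and 2 components vs 0.72 majority);
this is inherent to PLS-DA with a fixed threshold, not an implementation
artifact.

Nested cross-validation (selecting A inside each outer fold) is not
performed — the selection and the error estimate share folds, so the
reported CV error of the selected model carries a mild optimism bias;
this mirrors common practice in the application area and is flagged here
as a caveat.

## Problem sizes and determinism

Default experiments use the full emulated design: 72 subjects × 10
depths × 1384 wavenumbers, 10-fold CV, A up to 10; TEWL moment checks use
100,000 draws. A complete pipeline run takes a few seconds on one CPU.
Every stochastic routine takes an explicit seed or generator; configs
round-trip through YAML/JSON and rerunning a command overwrites its
outputs identically.
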