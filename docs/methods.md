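# Methods

## Signal model and inversion

Each voxel's DWI signal is modeled as a non-negative mixture of four
monoexponential diffusion decays with fixed apparent diffusion
coefficients D = (1.1e−4, 1.8e−3, 3.6e−3, 0.1220) mm²/s (restricted,
hindered, free, vascular flow).  Replicate samples at each b-value are
arithmetically averaged before fitting; the per-voxel contributions C1..C4
are then the non-negative least-squares (NNLS) solution against the
averaged signal-vs-b curve.  Both bundled protocols sample five distinct
b-values, one more than the number of compartments, so the design is
(mildly) overdetermined.

`fit_volume` solves the unconstrained least-squares problem for all in-mask
voxels in one batched operation and falls back to per-voxel NNLS
(`scipy.optimize.nnls`) only where the unconstrained solution has a
negative coefficient; by the KKT conditions a feasible unconstrained
optimum *is* the NNLS optimum, so the fast path is exact.  The test suite
checks both routes against an independent brute-force oracle that
enumerates every compartment subset and keeps the feasible solution of
least residual.

Out-of-mask voxels carry NaN, never 0, so masked medians and maxima are
uncontaminated.  Fitting a volume without a prostate mask is allowed but
logged as a warning.

## Compartmental T2 and RSIrs

With exactly two echo times the monoexponential T2 fit has the closed form
T2 = ΔTE / ln(C(TE₁)/C(TE₂)); this is mathematically identical to an
iterative two-point fit and is verified against a dense 1-D grid search in
the tests.  Estimates are *censored, not clamped*: a voxel/compartment is
valid only when the pair decays (C(TE₁) > C(TE₂) > ε, ε at machine scale)
and the estimate lies in a configurable window, default 1–2000 ms.
Censoring to absent keeps medians unbiased by arbitrary caps; the number of
valid voxels is monotone in the window width.

RSIrs divides the C1 map by the median b = 0 signal inside the whole
prostate.  Both numerator and denominator are taken from the shorter-TE
acquisition by default (configurable), following the convention that
displayed maps derive from the shorter-TE scan; the denominator is stored
on the result for provenance.  RSIrs is invariant to global rescaling of
the raw signal, which is the property that lets it outperform raw C1 at
patient level.

## Group statistics

All comparisons are two-sample t-tests at α = 0.05 on per-patient medians
over valid voxels; Welch's unequal-variance form is the default (a pooled
option exists).  Three analyses: all six compartment pairs of
whole-prostate median T2; lesion medians of csPCa patients versus
prostate-minus-lesion medians of csPCa patients pooled with whole-prostate
medians of non-csPCa patients; and csPCa versus non-csPCa whole-prostate
medians, whose significant compartments are flagged for the classifier.
Zero-variance groups short-circuit to p = 1 (equal means) or p = 0 with a
logged warning.  No multiple-testing correction is applied; each test is
read at α per comparison.

## Classifier and evaluation

The voxel-level logistic model uses RSIrs and the compartmental T2 of
C1–C3 (the compartments with voxel-level lesion contrasts) as raw-unit
features, fitted by maximum likelihood (`LogisticRegression` with C = 1e6,
i.e. a vanishing ridge kept purely as a separation guard).  Labeling
follows the lesion-contour rules: lesion voxels of csPCa patients are
positive, their remaining voxels are excluded, and all in-prostate voxels
of non-csPCa patients are negative.  Rows with any invalid feature are
dropped and counted.

Two robustness choices are ours:

* **T2 feature winsorization.**  The two-point T2 estimator has heavy
  noise tails — a near-equal pair of C values yields an estimate near the
  censoring cap — and a single such voxel, multiplied by even a small
  positive coefficient, can contribute several logits and hijack a
  patient's maximum probability.  T2 features are therefore clipped at the
  training set's 0.5th/99.5th percentiles; the bounds are stored on the
  model and reapplied at prediction.  RSIrs is never clipped (clipping it
  would saturate every high-scoring voxel to one probability).
* **Prediction-time imputation.**  Probability maps fill invalid T2
  features with the patient's median valid in-prostate value, so the map
  covers the same support as the RSIrs map.  Without this, the maximum
  probability is taken over fewer voxels than the maximum RSIrs and the
  model's patient-level AUC is biased downward by construction.

Cross-validation for the voxel-level AUC partitions *patients*
(`StratifiedGroupKFold`, shuffled with the run seed): voxel-level splits
would leak patient identity, and unstratified grouped folds shift each
fold's intercept with its training prevalence, which biases the pooled
out-of-fold AUC when features are weak.  Patient-level predictors are the
maxima over valid in-prostate voxels of the model probability, RSIrs, and
C1.  Confidence intervals are percentile bootstraps over patients (default
10,000 resamples; single-class resamples are redrawn and counted), and AUC
pairs are compared with a two-sample t-test on the two bootstrap
distributions.  All predictors share one bootstrap resample stream per
evaluation, so comparisons reflect ranking differences rather than
resampling noise.

## The synthetic cohort generator

The generator emulates post-correction clinical data: volumes are born
co-registered (registration, eddy-current, B0 and gradient-nonlinearity
corrections are upstream of this package's scope), with every replicate
sample materialized so replicate averaging is a real pipeline step.
Geometry is an ellipsoidal prostate (inner transition zone, rest
peripheral zone) with an embedded ellipsoidal lesion for csPCa patients;
geometry enters no formula.  Per voxel, ground-truth compartment fractions
and T2s are stored, and the signal is the composed decay law
S(b, TE) = gain · Σ fᵢ·exp(−TE/T2ᵢ)·exp(−b·Dᵢ) plus Rician (default) or
Gaussian noise.

Default study conditions (all configurable):

| parameter | value | why |
|---|---|---|
| benign PZ fractions / T2 | (0.10, 0.30, 0.45, 0.15); (60, 120, 350, 90) ms | encodes the benign ordering T2(C3) > T2(C2) > T2(C4) > T2(C1) |
| benign TZ fractions / T2 | (0.13, 0.37, 0.33, 0.17); (55, 110, 300, 90) ms | more stromal, less luminal than PZ |
| lesion fractions / T2 | (0.22, 0.30, 0.30, 0.18); (66, 130, 280, 90) ms | larger restricted fraction; higher T2 in C1/C2, lower in C3, C4 unchanged |
| grade scaling of lesion f1 | +35 % per grade group above 2 | higher-grade tumors are more restricted; low-grade csPCa overlaps benign |
| voxel dispersion (fractions) | σ = 0.30 benign / 0.25 lesion (lognormal) | tissue heterogeneity |
| voxel dispersion (T2) | σ = 0.12 | T2 is spatially more homogeneous than composition |
| patient multipliers | σ = 0.35 fractions, σ = 0.04 T2, per tissue class | compartment fractions vary far more across patients than T2s |
| field effect (csPCa benign tissue) | T2 × (1.05, 1, 0.88, 1) | whole-prostate T2 differs by csPCa status even though lesions are small |
| scanner gain | lognormal σ = 0.40 per patient | un-normalized signal scale; RSIrs cancels it, raw C1 does not |
| noise | Rician, σ = 0.004 of mean b=0 signal | post-noise-correction data; at this SNR the 14–20 ms TE spread resolves T2 up to the C3 range |

The magnitudes are illustrative, chosen once to make the encoded
qualitative structure detectable at the study's sample sizes; they are not
literature values (the source distributions are published only as violin
plots).  The noise level matters more than most: well above σ ≈ 0.01 the
censoring of non-decaying pairs biases long-T2 estimates down severely
enough to destroy the compartment ordering, which is how we learned that a
two-point T2 protocol puts a hard SNR floor on C-map quality.

Two named alternative configurations support specific claims:

* `null_tissue_parameters()` — all three classes identical (independent
  per-patient multipliers per region): the simulator null used to verify
  that the lesion-vs-rest test rejects at its nominal 5 % rate.
* `t2_independent_tissue_parameters()` — the csPCa effect acts only
  through the restricted fraction and compartmental T2 is constant across
  voxels, patients and classes (still ordered across compartments).  Here
  voxelwise T2 carries no information beyond RSIrs by construction, and
  the combined model's patient ranking equals RSIrs exactly — the headline
  null result in its sharpest in-silico form, and a self-check that the
  pipeline manufactures no spurious difference.

On the default cohort, where lesions *do* carry real T2 contrasts, the
fitted model legitimately uses them and its patient ranking can differ
from RSIrs by a few pair swaps (|ΔAUC| of order 0.005); with 10,000
bootstrap samples the distribution t-test resolves differences of ~0.002,
so the model-vs-RSIrs comparison on the default cohort may come out
significant in either direction depending on the seed.  This is a real
property of the estimator under these conditions, not a defect, and it is
why the exact null statement is made under the T2-independent
configuration.

What the generator does **not** emulate: scanner artifacts corrected
upstream (distortion, eddy currents, motion), partial-volume mixtures at
tissue boundaries, spatial correlation of noise or biology, multi-focal or
non-ellipsoidal lesions, PI-RADS reading, or biopsy sampling error.
Passing tests therefore show the pipeline's correctness and its behavior
under controlled, plausible conditions — not clinical performance on real
data, whose AUCs depend on data we cannot ship.

## Problem sizes

Tests and the acceptance script use reduced grids chosen as the smallest
that leave every estimate well-conditioned: 32×32×12 for the 46-patient
default cohort (≈ 2,300 in-prostate voxels per patient), 32³ for the
noise-free recovery check, 16×16×8 with 16 patients × 500 replicates for
the calibration study.  The acquisition presets default to 64×64×16; grids
are a `with_grid` call away from the clinical 128×128×32+.

## Numerical notes

* Forward/inverse consistency is machine-exact on noiseless data (relative
  errors ~1e−14 for C, ~1e−11 ms for T2); tolerances in the tests (1e−6,
  0.1 ms) leave headroom for conditioning.
* The b = 3000 s/mm² column of the flow compartment underflows to zero
  (exp(−366)); NNLS handles the resulting near-singular column without
  special casing.
* All randomness flows from `numpy.random.default_rng` seeds; cohorts
  derive per-patient seeds from the cohort seed, and reruns are bitwise
  identical.
* Degenerate inputs are rejected with validation errors (negative
  fractions, non-positive T2, lesion outside prostate, single-class
  training sets, empty masks) or handled with logged guards (zero-variance
  t-tests, all-zero signals, missing masks).
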