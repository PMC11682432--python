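# rsict2 — multi-TE restriction spectrum imaging with compartmental T2

`rsict2` implements a quantitative prostate-MRI analysis for clinically
significant prostate cancer (csPCa, Gleason grade group ≥ 2) detection from
multi-b-value diffusion-weighted imaging (DWI) acquired at **two echo
times**.  It is aimed at imaging scientists who want a tested, end-to-end
reference implementation of the method — from raw 4-D DWI volumes to
statistical tables and patient-level ROC analysis — together with a seeded
synthetic-cohort generator, so the whole pipeline runs and is validated
without any clinical data.

## The model

Restriction spectrum imaging (RSI) decomposes the DWI signal at each voxel
into four diffusion compartments with fixed apparent diffusion
coefficients,

```
S(b) = Σᵢ Cᵢ · exp(−b·Dᵢ),   Dᵢ = (1.1e−4, 1.8e−3, 3.6e−3, 0.1220) mm²/s
```

representing restricted (C1), hindered (C2), free (C3) and vascular-flow
(C4) water.  The per-voxel contributions Cᵢ are obtained by non-negative
least squares on the replicate-averaged signal-vs-b curve.  Acquiring the
same protocol at two echo times TE₁ < TE₂ makes each compartment's
transverse relaxation observable, since Cᵢ(TE) = Aᵢ·exp(−TE/T2ᵢ); with two
points the monoexponential fit is the closed form

```
T2ᵢ = (TE₂ − TE₁) / ln( Cᵢ(TE₁) / Cᵢ(TE₂) )     [ms]
```

The scalar biomarker **RSIrs** divides C1 by the median b = 0 signal within
the whole prostate, removing global scanner scaling.  Downstream analyses
reproduce a standard evaluation battery: pairwise two-sample t-tests of
whole-prostate median compartmental T2 (α = 0.05), lesion-vs-non-lesion and
csPCa-vs-non-csPCa comparisons, and a voxel-level logistic regression model
(predictors: RSIrs, C1-T2, C2-T2, C3-T2) evaluated with patient-grouped
ten-fold cross-validation and 10,000-sample bootstrap AUC confidence
intervals at voxel and patient level.

Two bundled acquisition presets reproduce the clinical protocols the
package is modeled on: `cohort1` (b = 0×7, 200×6, 1000×6, 2000×6, 3000×6
s/mm² at TE 80/100 ms) and `cohort2` (b = 0×2, 50×6, 800×6, 1500×12,
3000×18 s/mm² at TE 76/90 ms).

## Worked example

```python
import rsict2 as r
from rsict2.pipeline import RunConfig, run_pipeline

cfg = RunConfig(protocol="cohort1", grid_shape=(32, 32, 12),
                n_patients=46, prevalence=22/46, seed=0,
                out_dir="demo")
run_pipeline(cfg)
```

simulates 46 patients (22 csPCa, matching a 47.8 % prevalence), fits the
compartment model to both TE volumes of every patient, maps compartmental
T2 and RSIrs, and writes `demo/report.md`.  With seed 0 the report reads,
in part:

```
## Lesion vs non-lesion compartmental T2

| compartment | mean diff (ms) | t | p | significant |
|---|---|---|---|---|
| C1 | 4.7 | 5.45 | 4.15e-06 | True |
| C2 | 11.7 | 3.52 | 0.00156 | True |
| C3 | -67.2 | -6.36 | 1.16e-06 | True |
| C4 | 1.2 | 0.56 | 0.576 | False |

## csPCa-detection AUCs

- lrm: AUC 0.744 [95% CI 0.583, 0.883] (10000 bootstrap samples)
- rsirs: AUC 0.731 [95% CI 0.569, 0.873] (10000 bootstrap samples)
- c1: AUC 0.636 [95% CI 0.472, 0.794] (10000 bootstrap samples)
```

Reading: lesion tissue shows higher compartmental T2 in the restricted and
hindered compartments and lower T2 in the free-water compartment (the
luminal-space signature), while T2 of the flow compartment does not differ;
all six compartment-vs-compartment T2 contrasts are significant with the
ordering C3 > C2 > C4 > C1.  At the patient level, maximum RSIrs and the
combined model both detect csPCa clearly better than maximum C1 (diffusion
alone), because RSIrs cancels the per-patient scanner gain that confounds
raw C1.

Every stage is also exposed on the command line:

```bash
rsict2 simulate --protocol cohort2 --n 10 --seed 1 --out cohort/
rsict2 fit     --patient-dir cohort/p000 --out maps/
rsict2 t2map   --patient-dir cohort/p000 --out t2/
rsict2 rsirs   --patient-dir cohort/p000 --out rs/
rsict2 run     --n 20 --seed 1 --out run/
```

Volumes are NIfTI-1 with JSON b-value/TE sidecars; tables are CSV; the run
configuration round-trips through YAML.

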