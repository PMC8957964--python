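# methylbmi

Body mass index is a whole-body surrogate for obesity; it says nothing about
how much adipose tissue sits in a particular tissue sample, or what the
obesity process has done to that tissue's epigenome. `methylbmi` builds a
**DNA-methylation-based BMI score (DM-BMI)** for breast-tissue methylomes:
a sparse linear predictor of a transformed BMI fitted to Illumina
450K-style beta values, together with the surrounding analysis stages —
probe QC, reference-based adipose deconvolution, predictor-CpG
characterization, and immune/immunotherapy-response scoring. It is aimed at
computational epigenomics researchers who want the full pipeline runnable
and testable on synthetic cohorts with known ground truth.

## The model

BMI (kg/m²) is first mapped to a trait scale that is logarithmic below a
healthy anchor *h* = 25 and linear above it:

```
F(b) = ln(b + 1) − ln(h + 1)    if b ≤ h
F(b) = (b − h) / (h + 1)        if b > h
```

F is continuously differentiable at the anchor (both one-sided derivatives
equal 1/(h+1)), strictly increasing, and F(h) = 0. The predictor is a lasso
regression of F(BMI) on the probes-by-samples beta matrix:

```
F(BMI_j) ≈ β₀ + Σ_p w_p · beta_pj ,   penalty λ Σ_p |w_p|
```

with λ chosen by 10-fold cross-validation over a 100-point pathwise grid
(the `lambda.min` rule). Predictions are mapped back to kg/m² with the
exact inverse of F. Intra-sample adipose content is estimated by
two-component constrained least squares against epithelial and adipose
reference methylomes, restricted to probes whose reference betas differ by
more than 0.7; for two components the constrained optimum has a closed
form. Tumor mutation burden is non-synonymous mutations / 38 Mb, and
expression signatures (the 6-gene IFN-γ set, the 18-gene antigen-processing
machinery set) are unweighted means.

## Worked example

```python
import numpy as np
from methylbmi import (SynthConfig, simulate_cohort, simulate_reference_profiles,
                       DMBMI, TwoComponentDeconvolution)

refs = simulate_reference_profiles(n_probes=2000, n_discriminating=30,
                                   delta=0.75, seed=42)
cohort = simulate_cohort(SynthConfig(n_samples=221, n_probes=2000, n_causal=20,
                                     missing_rate=0.0, n_batches=1,
                                     batch_shift_sd=0.0, seed=42), refs)

res = DMBMI(cohort.beta, cohort.true_bmi).fit(cv_folds=10, seed=0)
print(res.summary())

dec = TwoComponentDeconvolution(cohort.beta, refs).fit()
print("adipose fraction MAE vs truth:",
      np.abs(dec.adipose_fraction - cohort.true_adipose_fraction).mean())
```

prints (header of the summary):

```
DM-BMI lasso fit
==============================================
samples:            221
probes offered:     2000
probes selected:    61
lambda (lambda.min): 0.00206765
CV folds / seed:    10 / 0
healthy BMI anchor: 25.0
intercept:          -2.09033
in-sample Spearman r: 0.9968
paired t vs BMI:    t=-0.0328, df=220, p=0.9739

adipose fraction MAE vs truth: 0.0033
```

Reading the numbers: the lasso kept 61 of 2000 probes (19 of the 20 truly
causal CpGs are among them); predicted DM-BMI tracks true BMI with Spearman
r ≈ 0.997, and a paired t-test finds no systematic offset between DM-BMI
and BMI (p ≈ 0.97). The deconvolution recovers each sample's true adipose
fraction to within ~0.003 on average.

## Command line

Every stage is also a `methylbmi` subcommand operating on TSV/JSON files:

```
methylbmi simulate   --config cohort.yaml --out DIR --seed 7
methylbmi preprocess --beta beta.tsv --ann annotation.tsv --batches clinical.tsv --out clean.tsv
methylbmi fit        --beta clean.tsv --clinical clinical.tsv --out model.json
methylbmi predict    --model model.json --beta clean.tsv --out dmbmi.tsv
methylbmi deconv     --beta clean.tsv --refs references.tsv --out frac.tsv
methylbmi run        --config pipeline.yaml --out rundir --seed 7
```

`methylbmi run` executes the whole chain and writes a manifest with sha256
checksums of every output; reruns with the same config and seed reproduce
identical checksums.

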