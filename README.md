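# bloodvar

Variability analysis of whole-blood gene expression in population cohorts.

Peripheral blood is the most accessible tissue for biomarker studies, but
expression signals in it are subtle: technical processing (array lot, RNA
extraction batch, time from blood draw to freezing) can explain several-fold
more variance than the biology of interest, and covariates such as smoking,
BMI, fasting, hormone therapy (HT) and other medication (MED) overlap and
interact. `bloodvar` implements, as a tested and reusable library, the full
analysis chain such a study needs — from raw probe × sample matrices with
per-cell signal-to-noise (S/N) and quality flags, through to curated
gene-set enrichment — together with a synthetic cohort generator that
reproduces the statistical structure of a ~300-array postmenopausal cohort
so every stage can be validated against known ground truth.

## The methods

**QC cascade.** Cells with flag > 8191 become missing; among technical
replicates of a subject, the array with the most probes at S/N > 3 is kept;
arrays where fewer than 40% of probes reach S/N ≥ 3 are removed; probes with
S/N > 3 in fewer than 50% of samples are dropped; then log2 transform,
missing-aware quantile normalization, and 10-nearest-neighbour imputation.

**Global ANCOVA.** Whole-matrix association between expression and
covariates by the extra sum of squares principle: with per-probe OLS fits of
nested designs,

    T = Σ_g (RSS_g^reduced − RSS_g^full) / Σ_g RSS_g^full,

calibrated by permutation (Freedman–Lane residual permutation when
covariates are adjusted for). Used to screen technical variables
(multivariate permuted p < 0.001) and to test the HT × MED interaction.

**Eigen-R2.** The fraction of overall variation explained by a variable
set: SVD of the probe-centered matrix, per-eigengene regression R², averaged
with eigenvalue-share weights — a high-dimensional analogue of classic R²,
with an optional degrees-of-freedom adjustment.

**Gene-wise mixed-model BIC selection.** Per probe, forward–backward search
over ten candidates (age class, BMI class, fasting, smoking, HT, MED,
HT × MED, time-to-freezing as fixed effects; array lot and extraction date
as crossed random intercepts) minimizing BIC = −2ℓ̂_ML + k·log n, fitted by
profiled maximum likelihood over the variance ratios.

**Core probes.** The global test scores each probe's contribution
Q_i = (x_iᵀ r)² to a set's association with an outcome; permutation moments
give z-scores, and core probes are members whose |z| clears the cutpoint
maximizing 2·TP̂ − FP̂ with Benjamini–Hochberg FDR estimates (selection is
gated on set-level significance).

**Gene-set enrichment.** Curated sets (GMT) are scored by the global test,
FDR-adjusted across sets, and given a competitive *comparative p-value*:
the fraction of random same-size probe sets with a larger standardized
statistic.

## Worked example

`examples/04_eigenr2_variance.py` builds a 150-sample, 1000-probe cohort
whose designed variance split is 46.5% technical / 8.1% biological, and
recovers that split:

```
designed technical fraction: 0.465, realized 0.465
eigen-R2 technical estimate: 0.466
designed biological fraction: 0.081, realized 0.081
eigen-R2 biological estimate: 0.083
top eigengene carries 8.1% of the variance
```

The three processing variables explain nearly half the expression variance;
all six biological covariates together explain under a tenth — the reason
technical adjustment must precede any biological claim from blood arrays.

`examples/03_technical_screen.py` shows the permutation screen isolating
the three genuinely injected processing variables among five decoys:

```
variable            univariate p  multivariate p
array_lot                 0.0005          0.0005
extraction_date           0.0005          0.0005
freeze_days               0.0005          0.0005
tech_decoy_0              0.4805            0.99
...
passed at p<0.001: ['array_lot', 'extraction_date', 'freeze_days']
```

and `examples/05_probe_model_selection.py` runs the per-probe BIC search
(mean 3.43 selected variables per probe, SD 0.85, on its fixture) and pulls
out probes uniquely associated with smoking: 28 probes, 26 of which truly
carry the planted smoking effect.

The other examples cover the QC cascade, cohort simulation, and core-probe
selection with gene-set enrichment; each prints the numbers it computes and
a line on what they mean. The CLI mirrors the library:

```sh
bloodvar simulate --seed 1 --out cohort/
bloodvar run --config pipeline.yaml
```

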