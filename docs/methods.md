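# Methods

This note records the models, parameter choices, numerical decisions and
known limitations behind `bloodvar`, in the order the pipeline runs.

## Synthetic cohort generator

The generator produces the inputs the analysis assumes, with known ground
truth. Its model for probe *g*, array *j* (log2 intensity scale):

    y_gj = μ_g + lot_g,lot(j) + date_g,date(j) + β_f · s_g · d_j
           + Σ_v δ_gv · x_vj + ε_gj

* **Baselines** μ_g ~ `baseline_mean` + Exponential(`baseline_scale`)
  (default 7.0 + Exp(1.6)): a long right tail so quantile normalization has
  genuine work to do.
* **Batch effects.** Array lot and RNA extraction date are *crossed* (not
  nested) categorical factors; each probe draws its own intercept per level,
  lot_g,l ~ N(0, `sd_lot`²), date_g,d ~ N(0, `sd_extraction`²). This is the
  structure the per-probe crossed random-intercept models assume.
* **Degradation gradient.** Time from blood draw to freezing d_j ~
  U(0, 3 days) (samples frozen later than 3 days are assumed excluded
  upstream); each probe responds with slope ±`beta_freeze` (random sign).
* **Covariates.** Six binary variables at cohort-realistic prevalences —
  smoking 0.25, fasting 0.10, BMI ≥ 25 0.46, age above median 0.50, HT use
  0.30, other medication 0.582. Each shifts a configured fraction of probes
  (`effect_fraction`, default 0.10) by ±`effect_size` log2 units. Keys of
  the form `"HT:MED"` inject interaction effects on the product regressor.
* **Residual** ε ~ N(0, `sd_resid`²), default 0.5 log2 units.

**Variance calibration.** The default scales are solved so that the
probe-centered variance splits 46.5% technical / 8.1% biological / the rest
residual — the regime in which technical adjustment is decisive. The sample
variance contributed by an L-level random intercept is sd²·(1 − 1/L), and
`CohortConfig.with_variance_fractions` applies that finite-level correction
so realized fractions land on target; `CohortTruth` records the *realized*
fractions computed from the simulated components.

**Replicates and detection.** `spike_replicates` duplicates chosen subjects
with fresh technical noise (half the median probe-wise SD); the default
design is 289 subjects + 15 replicate arrays = 304 hybridizations. S/N is
linear-scale intensity over a per-array noise constant with log-normal
jitter — monotone in intensity, as a detection statistic should be; the
generator never defines more than the filters consume. A configurable
fraction of cells fails outright (flag > 8191, S/N below detection).

**What it does not emulate:** probe sequences and cross-hybridization,
correlated probe blocks (co-expression modules), heavy-tailed or
heteroscedastic residuals, covariate correlation structure (covariates are
drawn independently; the real cohort has, e.g., age–smoking association),
and array spatial artifacts. Passing tests therefore demonstrate that the
statistics recover the designed structure under the assumed model, not that
they are robust to every failure mode of real arrays.

## QC cascade

Order is fixed: flag mask → replicate resolution → array filter → probe
filter → log2 → quantile normalization → kNN imputation, and stage counts
reconcile in `QCReport`. Two detection comparators coexist deliberately:
the replicate rule and the probe filter count S/N strictly above 3, the
40%-array rule uses S/N ≥ 3; both thresholds and comparators are
configurable.

* **Quantile normalization, missing-aware.** Normalization runs before
  imputation, so missing cells must be handled: each array's observed
  quantile function is interpolated onto a common grid of G quantile ranks,
  the reference is the across-array mean on that grid, and each observed
  cell maps through its within-array rank. With complete data this reduces
  exactly to the classic mean-of-order-statistics scheme; it is idempotent,
  preserves the grand mean, and leaves missing cells missing. Ties get
  distinct ranks (stable sort) rather than averaged values.
* **kNN imputation** is probe-neighbour: for a missing cell, the k = 10
  nearest probes by Euclidean distance over co-observed samples (scaled by
  the observed fraction, so distances are comparable across missingness
  patterns) contribute an inverse-distance-weighted mean at that sample.
  Distance ties break by probe order; zero-distance twins get uniform
  weight; a probe with no observed neighbour at a sample falls back to its
  own mean, and those probes are reported.

## Global ANCOVA

The statistic pools evidence across all probes:
T = Σ_g ΔRSS_g / Σ_g RSS_g^full, computed via thin orthonormal bases of the
two design spaces (cost G·n·p, not G·n²). T is invariant to probe
duplication and common rescaling; nesting guarantees T ≥ 0.

Permutation calibration uses plain sample permutation when the reduced
model is intercept-only and Freedman–Lane otherwise (permute reduced-model
residuals, add back the reduced fit), with the add-one rule
p = (1 + #{T* ≥ T}) / (n_perm + 1). Null calibration at α = 0.05 was
verified at 0.045 over 200 replicates with a strong adjusted covariate.
Resolving p < 0.001 in the technical screen requires n_perm ≥ 1000; the
default test count is 10,000 for reporting at the 10⁻⁴ scale.

The screen tests each candidate univariately and by drop-one from the joint
technical design; survivors are labelled `random` (categorical batch
factors) or `fixed` for the downstream mixed models. Inside this module all
terms are fixed-effect encoded — the ANCOVA is a screen, not the final
model. Categorical terms use first-level-reference dummy coding, recorded
in the result.

## Eigen-R2

SVD of the probe-centered (not standardized; configurable) matrix;
eigen-R2 = Σ_k share_k · R²_k over all eigengenes. Unadjusted R² per
eigengene is the default — the simplest estimator matching the
"high-dimensional R²" idea — and carries a positive bias of roughly
(p − 1)/(n − 1) per null eigengene (p design columns). With the 20+ columns
of two batch factors at n = 150 that bias is material, so
`eigen_r2(..., adjusted=True)` applies the degrees-of-freedom adjustment
1 − (1 − R²)(n − 1)/(n − p); recovery tests and the acceptance script use
the adjusted form, and it is the right choice whenever variable sets of
different sizes are compared. The statistic is invariant to orthogonal
rotation of probe space and monotone under design nesting.

## Per-probe mixed-model BIC selection

For fixed-effect set F and random factors R with variance ratios
γ_r = σ_r²/σ_e², V₀ = I + Σ_r γ_r Z_r Z_rᵀ. The likelihood is profiled:
given γ, GLS coefficients and σ̂_e² = RSS_V/n are closed-form, so only the
(≤ 2) ratios are optimized — bounded Brent for one component, Nelder–Mead
with warm starts from neighbouring models for two. All inner algebra runs
on sufficient statistics (cross-products of a shared column bank) through
the Woodbury identity, making one fit a q × q problem (q = total random
levels); a 10-candidate stepwise search over 2000 probes takes a couple of
minutes on one CPU. ML fits match `statsmodels` MixedLM (ML, variance
components) to 4 decimals on single and crossed designs; balanced one-way
fits match the closed-form profile likelihood.

Choices: maximum likelihood (not REML) so BIC is comparable across fixed
sets; n_params = fixed coefficients + 1 residual variance + 1 per random
component; search starts from the intercept-only model, alternating the
best single addition with backward sweeps, any strict BIC decrease counts,
ties break by pool order — fully deterministic. The interaction is addable
only once both mains are in; mains are not droppable while it remains.
Random candidates compete in the same search, each costing one parameter.
Variance ratios hitting the optimizer floor (γ < 1e-10) are reported as 0.
A model whose fit fails is skipped with a warning rather than aborting the
probe.

Operating characteristics at the study's sample size (n = 286, effect
0.8·σ_e): sensitivity ≈ 1.0 for a 0.25-prevalence covariate, per-variable
false-pick rate ≈ 0.017 on null probes (the BIC penalty log 286 ≈ 5.66
corresponds to a per-variable χ²₁ test at ≈ 1.7%). A pure-noise probe keeps
the intercept-only model with probability ≈ (1 − 0.017)^10 ≈ 0.84 under the
10-candidate pool — per-variable error is controlled; family-wise pickup is
not, and is not meant to be (the core-probe filter exists precisely because
BIC selection ignores multiplicity).

"Uniquely associated" probes: selected set equals {v} after removing
permitted technical terms — by default only the dominant batch factor
(array lot), configurable, since filtering on a factor that most probes
select would empty every list.

## Global test and core probes

After residualizing outcome and probes on the adjustment design, probe
contributions are Q_i = (x_iᵀ r)² with x_i standardized; the set statistic
is their mean. Moments come from outcome-residual permutations (default
n_perm = 1000, seeded): z_i = (Q_i − E*Q_i)/SD*Q_i, with permutation
p-values under the add-one rule; an exact mode enumerates all distinct
outcome arrangements for n ≤ 9. The engine caches the permutation
contribution matrix for the whole platform, so scores for any subset —
including thousands of random sets for comparative p-values — are row
means.

Core selection maximizes U(t) = 2·S(t)(1 − FDR(t)) − S(t)·FDR(t) over
achievable |z| cutpoints, FDR estimated by Benjamini–Hochberg on two-sided
normal p-values from z; ties go to the stricter cutpoint, and cutpoints
cannot split groups of tied |z|. Exactness against brute-force cutpoint
search is asserted in the test suite on every run. One design choice
matters for null behavior: any rule that selects whenever an FDR estimate
dips below w_tp/(w_tp + w_fp) = 2/3 fires on pure noise with probability
≈ 1 − e^(−2/3) ≈ 0.49 (a Simes-type event at level 2/3), regardless of
probe count or p-value flavour. Core refinement therefore presumes set
association: if the set-level permutation p exceeds `set_alpha` (default
0.05; `None` disables) the core set is empty. This caps null selection at
~5% while leaving genuinely associated sets untouched, and reflects the
pipeline's logic — the global test establishes that a set is associated,
the z-threshold refines *within* it.

Direction of association is the sign of the residualized probe–outcome
covariance; exact zero reports "undetermined". Multi-level outcomes are
handled per level by callers; the two-level case codes the
lexicographically second level as 1.

## Gene-set enrichment

Gene-to-probe mapping uses a two-column table; multi-probe genes contribute
every probe, unmapped members are recorded on the set, never silently
dropped. Set p-values come from the global test; FDR is BH across the batch
of sets tested together. The comparative p-value draws n_random = 1000
same-size sets uniformly from all measured probes (no expression matching)
and reports the plain fraction with a larger set z — deliberately without
an add-one correction, so a dominant signature can report values at the
0.1% scale; it is a competitive statistic, invariant to duplicating a set's
probes.

## Pipeline runner and formats

Stages run in the fixed order QC → screen → eigen-R2 → selection → core →
unique → enrichment; each stage persists its table (tab-delimited,
bit-stable ordering), a checkpoint file names completed stages, and a
provenance record stores config, seed and package versions. All randomness
flows from the single config seed; re-runs are bit-identical. Formats:
TSV matrices (probe rows), annotation CSV with `#role`/`#subject` header
lines, GMT gene sets, and a read-only GEO Series Matrix table reader.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically sharp: ANCOVA
calibration at 300 null cohorts (n = 60, G = 200, 200 permutations);
eigen-R2 recovery over 20 seeds at G = 1000, n = 150; selection operating
characteristics on 200 probes at n = 286; core null behavior over 100
seeds; the end-to-end run at n = 120, G = 2000. The full study design
(304 arrays × 16185 probes) is the generator default and runs the same
code paths.

## Known limitations

* Eigen-R2's unadjusted default overstates small fractions for wide
  designs; use `adjusted=True` when comparing variable sets.
* Freedman–Lane permutation is asymptotically exact, not finite-sample
  exact, under correlated covariates.
* The z-derived normal p-values feeding BH in core selection are an
  approximation to the permutation distribution of Q (right-skewed at
  small n); a permutation-p alternative is available on the scores.
* Multi-class outcome support in the global test is per-level and flagged
  experimental.
* The kNN imputer computes distances only for probes with missing cells;
  fully dense missingness across tens of thousands of probes would warrant
  a blocked implementation.
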