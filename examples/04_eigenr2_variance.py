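"""Estimate variance explained by technical vs biological variables.

Eigen-R2 regresses each eigengene (sample-space singular vector) on the
design and averages the R2 values weighted by eigenvalue share.
"""

from bloodvar import CohortConfig, generate_annotations, generate_expression
from bloodvar.eigenr2 import eigen_r2

cfg = CohortConfig.with_variance_fractions(
    0.465, 0.081, n_samples=150, n_probes=1000, n_lots=8,
    n_extraction_dates=15, n_replicate_pairs=0, seed=4,
)
ann = generate_annotations(cfg)
expr, truth = generate_expression(ann, cfg)

tech = eigen_r2(expr, ann, ["array_lot", "extraction_date", "freeze_days"], adjusted=True)
bio = eigen_r2(expr, ann,
               ["age_class", "bmi_class", "fasting", "smoking", "HT", "MED"],
               adjusted=True)

print(f"designed technical fraction: 0.465, realized {truth.variance_fraction_technical:.3f}")
print(f"eigen-R2 technical estimate: {tech.eigen_r2:.3f}")
print(f"designed biological fraction: 0.081, realized {truth.variance_fraction_biological:.3f}")
print(f"eigen-R2 biological estimate: {bio.eigen_r2:.3f}")
print(f"top eigengene carries {tech.eigenvalue_shares[0]:.1%} of the variance")
# Technical processing noise explains several-fold more expression variance
# than all biological covariates together, matching the designed structure.
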