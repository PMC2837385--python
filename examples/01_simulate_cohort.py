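"""Generate a synthetic blood-expression cohort with the study's design.

289 subjects plus 15 technical replicate arrays (304 hybridizations),
crossed array-lot / extraction-date batch effects, a freezing-time gradient,
and six binary covariates shifting a fraction of probes.
"""

from bloodvar import CohortConfig, simulate_cohort

cfg = CohortConfig(n_probes=2000, seed=1)  # probe count scaled down for speed
expr, ann, truth = simulate_cohort(cfg)

print(f"arrays: {expr.n_samples} ({len(truth.replicate_pairs)} technical replicates)")
print(f"probes: {expr.n_probes}")
print(f"designed variance fractions -> technical {truth.variance_fraction_technical:.3f}, "
      f"biological {truth.variance_fraction_biological:.3f}")
print(f"smokers: {int(ann.data['smoking'].sum())} of {len(ann.data)} rows")
print(f"probes carrying a smoking effect: {len(truth.affected_probes['smoking'])}")
# The variance fractions are the shares of probe-centered variance injected
# by batch/processing effects versus covariate effects; downstream stages
# are judged on recovering them.
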