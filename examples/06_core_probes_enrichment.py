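"""Global-test scoring, core-probe selection and gene-set enrichment.

Probe sets are scored by the permutation global test; core probes are the
members whose |z| clears the cutpoint maximizing 2*TP - FP under a BH-FDR
estimate; curated sets additionally get a competitive comparative p-value
against random same-size sets.
"""

import numpy as np

from bloodvar import CohortConfig, generate_annotations, generate_expression
from bloodvar.coreselect import GlobalTestEngine, select_core_weighted
from bloodvar.enrichment import GeneSet, enrichment_table

cfg = CohortConfig(n_samples=120, n_probes=600, n_lots=5, n_extraction_dates=8,
                   n_decoy_technical=0, n_replicate_pairs=0, seed=6,
                   effect_fraction={"smoking": 0.1}, effect_size={"smoking": 0.7})
ann = generate_annotations(cfg)
expr, truth = generate_expression(ann, cfg)

affected = sorted(truth.affected_probes["smoking"])
engine = GlobalTestEngine(expr, ann, "smoking", n_perm=1000, seed=6)
scores = engine.scores(affected)
core = select_core_weighted(scores, variable="smoking")
print(f"probe set of {len(affected)} smoking-affected probes: "
      f"set p = {scores.set_p:.4g}, set z = {scores.set_z:.1f}")
print(f"core probes: {len(core.core_probes)} at |z| >= {core.threshold:.2f} "
      f"(FDR {core.fdr_at_threshold:.3f})")

sets = [
    GeneSet("planted_signature", "synthetic", [], affected[:30]),
    GeneSet("random_set", "synthetic", [],
            [f"P{i:05d}" for i in np.random.default_rng(0).choice(600, 30, replace=False)]),
]
rows = enrichment_table(expr, ann, "smoking", sets, n_perm=1000, n_random=500, seed=6)
print(f"{'gene set':20s} {'n':>3s} {'p':>9s} {'FDR':>8s} {'comp. p':>8s} {'up-smk':>6s} {'up-non':>6s}")
for r in rows:
    print(f"{r.set_name:20s} {r.n_tested:3d} {r.p:9.3g} {r.fdr:8.3g} "
          f"{r.comparative_p:8.3f} {len(r.core_up_group1):6d} {len(r.core_up_group0):6d}")
# Both sets can reach the permutation floor when effects are strong (the
# random draw contains a few affected probes too); the competitive
# comparative p-value is what separates the planted signature (0.000) from
# an unremarkable same-size draw.
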