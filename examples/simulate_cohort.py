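"""Generate a synthetic paired tumor/normal cohort with planted ground truth.

The generator plants differential expression, lncRNA co-expression modules
(one tied to TNM stage), ceRNA triplets around eight candidate lncRNAs, and
a survival hazard on those candidates — everything the pipeline later tries
to recover.
"""

from lncsponge import CohortConfig, generate_cohort

config = CohortConfig(seed=1)
expr_mrna, expr_lnc, expr_mir, clinical, targets, truth = generate_cohort(config)

print(f"mRNA counts matrix:   {expr_mrna.shape[0]} genes x {expr_mrna.shape[1]} samples")
print(f"lncRNA counts matrix: {expr_lnc.shape[0]} genes x {expr_lnc.shape[1]} samples")
print(f"miRNA counts matrix:  {expr_mir.shape[0]} genes x {expr_mir.shape[1]} samples")
print(f"clinical rows: {len(clinical.data)} ({len(clinical.pairs())} tumor/normal pairs)")
print(f"target edges (planted + decoys): {len(targets)}")
print()
print(f"planted DE genes: "
      f"{sum(len(v) for v in truth.de_log2fc.values())} across the three roles")
print(f"planted modules: {sorted(set(truth.module_membership) - {'none'})}, "
      f"trait-linked module: {truth.trait_module_id}")
print(f"planted ceRNA triplets: {len(truth.triplets)}")
print(f"candidate (survival-risk) lncRNAs: {truth.risk_lncrnas}")
# Each candidate shares its private miRNAs with ~5 partner mRNAs; those
# shared-binding edges are what the ceRNA stage detects downstream.
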