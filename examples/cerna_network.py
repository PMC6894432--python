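"""Infer ceRNA (sponge) pairs from shared miRNA targeting + co-expression.

A lncRNA-mRNA pair is a ceRNA pair when (i) the miRNAs predicted to bind
both overlap more than chance (upper-tail hypergeometric p < 0.05 over the
DE-miRNA universe) and (ii) the two transcripts are positively correlated
across tumor samples (PCC > 0, p < 0.05).
"""

from lncsponge import (
    CohortConfig,
    build_cerna_network,
    centralities,
    generate_cohort,
    paired_de_test,
    score_cerna_pairs,
    select_de_genes,
    select_top_bottom_mirnas,
    shared_mirna_table,
    tmm_factors,
    to_log2cpm,
)
from lncsponge.cerna import pair_graph

expr_mrna, expr_lnc, expr_mir, clinical, targets, truth = generate_cohort(
    CohortConfig(seed=1)
)

log = {}
de = {}
for m in (expr_mrna, expr_lnc, expr_mir):
    log[m.role] = to_log2cpm(m, tmm_factors(m))
    de[m.role] = paired_de_test(log[m.role], clinical)

lnc_ids = select_de_genes(de["lncRNA"])
mrna_ids = select_de_genes(de["mRNA"])
universe = sorted(select_top_bottom_mirnas(de["miRNA"]) & set(targets.data["mirna_id"]))
print(f"DE lncRNAs: {len(lnc_ids)}, DE mRNAs: {len(mrna_ids)}, "
      f"miRNA universe: {len(universe)}")

pairs = shared_mirna_table(targets, lnc_ids, mrna_ids, universe)
tumor = clinical.tumor_samples()
scored = score_cerna_pairs(
    pairs,
    log["lncRNA"].subset_samples(tumor),
    log["mRNA"].subset_samples(tumor),
)
passing = [p for p in scored if p.passes]
print(f"candidate pairs sharing >= 1 miRNA: {len(scored)}; passing: {len(passing)}")

best = min(passing, key=lambda p: p.hyper_p)
print(f"strongest pair {best.lncrna_id}-{best.mrna_id}: shares m={best.m} of "
      f"K={best.K}/n={best.n} targeting miRNAs (N={best.N}), "
      f"hypergeometric p={best.hyper_p:.2e}, PCC={best.pcc:.2f}")

network = build_cerna_network(passing, targets, include_mirna_nodes=True)
cents = centralities(pair_graph(network))
hubs = cents[cents["node_type"] == "lncRNA"].nlargest(3, "degree")
print("top lncRNA hubs by ceRNA degree:")
print(hubs[["degree", "betweenness", "closeness"]].to_string())
# Hub lncRNAs with many significant sponge partners are the shortlist input.
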