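"""End-to-end orchestration of the candidate-nomination funnel.

Stages (simulate -> de -> cerna -> wgcna -> select -> survival -> enrich)
communicate only through flat files inside one output directory, so any
stage can be rerun independently and identical config + seed reproduce
byte-identical outputs. A JSON manifest records thresholds, the seed, and
the row count of every output (no timestamps, so reruns match exactly).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna as cerna_mod
from . import io as io_mod
from . import survival as survival_mod
from . import wgcna as wgcna_mod
from .candidates import (
    build_coexpression_network,
    candidate_target_table,
    select_candidates,
)
from .config import RunConfig
from .diffexpr import (
    paired_de_test,
    select_de_genes,
    select_top_bottom_mirnas,
    tmm_factors,
    to_log2cpm,
    unpaired_de_test,
)
from .enrichment import ora
from .simulate import CohortConfig, generate_cohort, truth_report
from .types import ClinicalTable, ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)

FILES = {
    "mrna_counts": "mrna_counts.tsv",
    "lncrna_counts": "lncrna_counts.tsv",
    "mirna_counts": "mirna_counts.tsv",
    "clinical": "clinical.tsv",
    "targets": "target_edges.tsv",
    "truth": "truth.tsv",
    "gmt": "gene_sets.gmt",
    "de_mrna": "de_mrna.tsv",
    "de_lncrna": "de_lncrna.tsv",
    "de_mirna": "de_mirna.tsv",
    "log2cpm_mrna": "log2cpm_mrna.tsv",
    "log2cpm_lncrna": "log2cpm_lncrna.tsv",
    "log2cpm_mirna": "log2cpm_mirna.tsv",
    "cerna_pairs": "cerna_pairs.tsv",
    "cerna_network": "cerna_network.sif",
    "cerna_centralities": "cerna_centralities.tsv",
    "cerna_top_mirnas": "cerna_top_mirnas.tsv",
    "wgcna_scan": "wgcna_soft_threshold.tsv",
    "wgcna_assignment": "wgcna_assignment.tsv",
    "wgcna_eigengenes": "wgcna_eigengenes.tsv",
    "wgcna_module_trait": "wgcna_module_trait.tsv",
    "wgcna_significant": "wgcna_significant.tsv",
    "coexp_edges": "coexp_edges.tsv",
    "candidates": "candidates.tsv",
    "candidate_targets": "candidate_targets.tsv",
    "survival": "survival_screen.tsv",
    "enrichment": "enrichment.tsv",
    "manifest": "manifest.json",
}


def _path(outdir, key) -> Path:
    return Path(outdir) / FILES[key]


def _read_expr(outdir, key, role, unit) -> ExpressionMatrix:
    return io_mod.read_expression_matrix(_path(outdir, key), role=role, unit=unit)


def stage_simulate(config: RunConfig, outdir) -> dict:
    """Generate the cohort (or copy external inputs into canonical files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.simulate is not None:
        sim = CohortConfig(**{**config.simulate.__dict__, "seed": config.seed})
        expr_mrna, expr_lnc, expr_mir, clinical, targets, truth = generate_cohort(sim)
        gmt = _demo_gene_sets(truth, expr_mrna, seed=config.seed)
    else:
        inp = config.inputs
        unit = inp.unit
        expr_mrna = io_mod.read_expression_matrix(inp.mrna, role="mRNA", unit=unit)
        expr_lnc = io_mod.read_expression_matrix(inp.lncrna, role="lncRNA", unit=unit)
        expr_mir = io_mod.read_expression_matrix(inp.mirna, role="miRNA", unit=unit)
        clinical = io_mod.read_clinical_table(inp.clinical)
        targets = io_mod.read_target_edges(inp.targets)
        truth = None
        gmt = None
    io_mod.write_expression_matrix(expr_mrna, _path(outdir, "mrna_counts"))
    io_mod.write_expression_matrix(expr_lnc, _path(outdir, "lncrna_counts"))
    io_mod.write_expression_matrix(expr_mir, _path(outdir, "mirna_counts"))
    io_mod.write_clinical_table(clinical, _path(outdir, "clinical"))
    io_mod.write_target_edges(targets, _path(outdir, "targets"))
    if truth is not None:
        truth_report(truth, _path(outdir, "truth"))
    if gmt is not None:
        io_mod.write_gmt(gmt, _path(outdir, "gmt"))
    return {
        "n_mrna": expr_mrna.shape[0],
        "n_lncrna": expr_lnc.shape[0],
        "n_mirna": expr_mir.shape[0],
        "n_samples": expr_mrna.shape[1],
        "n_target_edges": len(targets),
    }


def _demo_gene_sets(truth, expr_mrna, seed: int, n_random_sets: int = 10) -> GeneSetCollection:
    """Demo GMT for simulate mode: one set per planted candidate's partner
    mRNAs plus random same-size decoy sets."""
    rng = np.random.default_rng(seed + 1)
    sets, descriptions = {}, {}
    genes = expr_mrna.gene_ids
    for lnc, partners in sorted(truth.candidate_partners.items()):
        name = f"PARTNERS_{lnc}"
        sets[name] = set(partners)
        descriptions[name] = f"planted partner mRNAs of {lnc}"
    for i in range(n_random_sets):
        size = int(rng.integers(10, 40))
        name = f"RANDOM_{i + 1:02d}"
        sets[name] = set(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "random decoy set"
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def stage_de(config: RunConfig, outdir) -> dict:
    """Normalize each count matrix and screen DE genes per role."""
    clinical = io_mod.read_clinical_table(_path(outdir, "clinical"))
    counts = {
        "mRNA": _read_expr(outdir, "mrna_counts", "mRNA", "counts"),
        "lncRNA": _read_expr(outdir, "lncrna_counts", "lncRNA", "counts"),
        "miRNA": _read_expr(outdir, "mirna_counts", "miRNA", "counts"),
    }
    de_cfg = config.de
    summary = {}
    for role, key in (("mRNA", "mrna"), ("lncRNA", "lncrna"), ("miRNA", "mirna")):
        mat = counts[role]
        factors = tmm_factors(mat)
        log2cpm = to_log2cpm(mat, factors, prior=de_cfg.prior)
        io_mod.write_expression_matrix(log2cpm, _path(outdir, f"log2cpm_{key}"))
        if de_cfg.paired:
            de = paired_de_test(log2cpm, clinical)
        else:
            de = unpaired_de_test(log2cpm, clinical)
        if role == "miRNA":
            selected = select_top_bottom_mirnas(de, k=de_cfg.mirna_top_k)
        else:
            selected = select_de_genes(
                de, fdr_max=de_cfg.fdr_max, min_abs_log2fc=de_cfg.min_abs_log2fc
            )
        de["selected"] = de.index.isin(sorted(selected))
        de.index.name = "gene_id"
        de.sort_index().to_csv(_path(outdir, f"de_{key}"), sep="\t", float_format="%.8g")
        summary[f"n_de_{key}"] = int(len(selected))
    return summary


def _load_de(outdir, key) -> pd.DataFrame:
    return pd.read_csv(_path(outdir, f"de_{key}"), sep="\t", index_col="gene_id")


def _tumor_log2cpm(outdir, key, role, clinical) -> ExpressionMatrix:
    expr = _read_expr(outdir, f"log2cpm_{key}", role, "log2CPM")
    tumor = [s for s in clinical.tumor_samples() if s in expr.data.columns]
    return expr.subset_samples(tumor)


def stage_cerna(config: RunConfig, outdir) -> dict:
    """Shared-miRNA hypergeometric + co-expression ceRNA pair inference."""
    clinical = io_mod.read_clinical_table(_path(outdir, "clinical"))
    targets = io_mod.read_target_edges(_path(outdir, "targets"))
    de_lnc = _load_de(outdir, "lncrna")
    de_mrna = _load_de(outdir, "mrna")
    de_mir = _load_de(outdir, "mirna")
    lnc_ids = list(de_lnc.index[de_lnc["selected"]])
    mrna_ids = list(de_mrna.index[de_mrna["selected"]])
    mir_sel = set(de_mir.index[de_mir["selected"]])
    universe = sorted(mir_sel & set(targets.data["mirna_id"]))
    if not universe:
        raise ValidationError("no DE miRNA appears in the target table")
    pairs = cerna_mod.shared_mirna_table(targets, lnc_ids, mrna_ids, universe)
    cc = config.cerna
    if cc.tumor_only:
        expr_lnc = _tumor_log2cpm(outdir, "lncrna", "lncRNA", clinical)
        expr_mrna = _tumor_log2cpm(outdir, "mrna", "mRNA", clinical)
    else:
        expr_lnc = _read_expr(outdir, "log2cpm_lncrna", "lncRNA", "log2CPM")
        expr_mrna = _read_expr(outdir, "log2cpm_mrna", "mRNA", "log2CPM")
    scored = cerna_mod.score_cerna_pairs(
        pairs, expr_lnc, expr_mrna,
        hyper_p_max=cc.hyper_p_max,
        require_positive_pcc=cc.require_positive_pcc,
        pcc_p_max=cc.pcc_p_max,
        adjust_hyper_p=cc.adjust_hyper_p,
    )
    passing = [p for p in scored if p.passes]
    cerna_mod.pairs_to_frame(scored).to_csv(
        _path(outdir, "cerna_pairs"), sep="\t", index=False, float_format="%.8g"
    )
    network = cerna_mod.build_cerna_network(
        passing, targets, include_mirna_nodes=cc.include_mirna_nodes
    )
    io_mod.write_edge_list(network, _path(outdir, "cerna_network"))
    if network.number_of_nodes():
        cents = cerna_mod.centralities(cerna_mod.pair_graph(network))
    else:
        cents = pd.DataFrame(columns=["node_type", "degree", "betweenness", "closeness"])
        cents.index.name = "node"
    cents.to_csv(_path(outdir, "cerna_centralities"), sep="\t", float_format="%.8g")
    top = cerna_mod.rank_network_mirnas(network, de_mir, k=cc.top_mirna_k)
    pd.DataFrame({"mirna_id": top}).to_csv(
        _path(outdir, "cerna_top_mirnas"), sep="\t", index=False
    )
    return {
        "n_candidate_pairs": len(pairs),
        "n_passing_pairs": len(passing),
        "n_network_nodes": network.number_of_nodes(),
    }


def stage_wgcna(config: RunConfig, outdir) -> dict:
    """Signed co-expression modules of the lncRNAs + TNM correlation."""
    clinical = io_mod.read_clinical_table(_path(outdir, "clinical"))
    wc = config.wgcna
    if wc.tumor_only:
        expr = _tumor_log2cpm(outdir, "lncrna", "lncRNA", clinical)
    else:
        expr = _read_expr(outdir, "log2cpm_lncrna", "lncRNA", "log2CPM")
    scan, modules, module_trait, significant = wgcna_mod.wgcna_pipeline(
        expr, clinical,
        powers=tuple(wc.powers), r2_min=wc.r2_min, cut_height=wc.cut_height,
        min_module_size=wc.min_module_size, merge_diss_max=wc.merge_diss_max,
        module_p_max=wc.module_p_max, ordinal_trait=wc.ordinal_trait,
        fallback_power=wc.fallback_power,
    )
    scan.table.to_csv(_path(outdir, "wgcna_scan"), sep="\t", float_format="%.8g")
    assignment = modules.assignment.rename("module")
    assignment.index.name = "gene_id"
    assignment.sort_index().to_csv(_path(outdir, "wgcna_assignment"), sep="\t")
    eig = modules.eigengenes.copy()
    eig.index.name = "module"
    eig.to_csv(_path(outdir, "wgcna_eigengenes"), sep="\t", float_format="%.8g")
    if len(module_trait):
        flat = module_trait.copy()
        flat.columns = [f"{t}_{s}" for t, s in flat.columns]
        flat.index.name = "module"
    else:
        flat = pd.DataFrame()
    flat.to_csv(_path(outdir, "wgcna_module_trait"), sep="\t", float_format="%.8g")
    significant.to_csv(_path(outdir, "wgcna_significant"), sep="\t", float_format="%.8g")
    return {
        "n_modules": len(set(modules.assignment) - {wgcna_mod.UNASSIGNED}),
        "n_significant_modules": int(len(significant)),
        "chosen_power": scan.chosen_power,
    }


def stage_select(config: RunConfig, outdir) -> dict:
    """Intersect ceRNA hubs, significant modules and high-PCC co-expression."""
    clinical = io_mod.read_clinical_table(_path(outdir, "clinical"))
    expr_lnc = _tumor_log2cpm(outdir, "lncrna", "lncRNA", clinical)
    expr_mrna = _tumor_log2cpm(outdir, "mrna", "mRNA", clinical)
    coexp = build_coexpression_network(
        expr_lnc, expr_mrna, pcc_min=config.select.coexp_pcc_min
    )
    coexp.edges.to_csv(
        _path(outdir, "coexp_edges"), sep="\t", index=False, float_format="%.8g"
    )
    sif = io_mod.read_edge_list(_path(outdir, "cerna_network"))
    import networkx as nx

    graph = nx.Graph()
    cents = pd.read_csv(_path(outdir, "cerna_centralities"), sep="\t", index_col="node")
    for node, row in cents.iterrows():
        graph.add_node(node, node_type=row["node_type"])
    for _, row in sif.iterrows():
        if row["interaction"] == "cerna":
            graph.add_edge(row["source"], row["target"], interaction="cerna")
    assignment = pd.read_csv(
        _path(outdir, "wgcna_assignment"), sep="\t", index_col="gene_id"
    )["module"]
    significant = pd.read_csv(_path(outdir, "wgcna_significant"), sep="\t", index_col="module")
    modules = wgcna_mod.ModuleSet(assignment=assignment)
    report = select_candidates(
        graph, modules, significant, coexp, fraction=config.select.degree_fraction
    )
    table = report.table.copy()
    table.index.name = "candidate"
    table.to_csv(_path(outdir, "candidates"), sep="\t", float_format="%.8g")
    candidate_target_table(report).to_csv(
        _path(outdir, "candidate_targets"), sep="\t", index=False
    )
    return {
        "n_candidates": len(report.candidate_ids),
        "n_target_mrnas": len(report.all_target_mrnas()),
    }


def stage_survival(config: RunConfig, outdir) -> dict:
    """Median-split log-rank screen of the candidates."""
    clinical = io_mod.read_clinical_table(_path(outdir, "clinical"))
    expr_lnc = _read_expr(outdir, "log2cpm_lncrna", "lncRNA", "log2CPM")
    cand = pd.read_csv(_path(outdir, "candidates"), sep="\t")
    candidates = list(cand["candidate"]) if len(cand) else []
    screen = survival_mod.survival_screen(
        candidates, expr_lnc, clinical, p_max=config.survival.p_max
    )
    screen.index.name = "candidate"
    screen.to_csv(_path(outdir, "survival"), sep="\t", float_format="%.8g")
    return {
        "n_tested": int(screen["testable"].sum()) if len(screen) else 0,
        "n_flagged": int(screen["flagged"].sum()) if len(screen) else 0,
    }


def stage_enrich(config: RunConfig, outdir) -> dict:
    """ORA of candidate-linked mRNAs against the gene-set collection."""
    gmt_path = config.enrich.gmt or _path(outdir, "gmt")
    targets = pd.read_csv(_path(outdir, "candidate_targets"), sep="\t")
    universe = set(
        pd.read_csv(_path(outdir, "de_mrna"), sep="\t", index_col="gene_id").index
    )
    query = set(targets["mrna_id"]) & universe if len(targets) else set()
    if Path(gmt_path).exists() and query:
        sets = io_mod.read_gmt(gmt_path)
        result = ora(query, sets, universe)
    else:
        result = pd.DataFrame(
            columns=["set_name", "k", "K", "n", "N", "p", "fdr", "overlap_genes"]
        )
    result.to_csv(_path(outdir, "enrichment"), sep="\t", index=False, float_format="%.8g")
    n_sig = int((result["fdr"] < config.enrich.fdr_max).sum()) if len(result) else 0
    return {"n_sets_tested": int(len(result)), "n_sets_significant": n_sig}


STAGES = [
    ("simulate", stage_simulate),
    ("de", stage_de),
    ("cerna", stage_cerna),
    ("wgcna", stage_wgcna),
    ("select", stage_select),
    ("survival", stage_survival),
    ("enrich", stage_enrich),
]


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute every stage in order and write the JSON run manifest.

    Returns the manifest dict. Any stage failure aborts with the stage name
    prepended to the cause.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "lncsponge",
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "stages": {},
    }
    for name, fn in STAGES:
        t0 = time.monotonic()
        try:
            summary = fn(config, outdir)
        except Exception as exc:  # noqa: BLE001 - reraise with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.1fs: %s", name, time.monotonic() - t0, summary)
        manifest["stages"][name] = summary
    with open(_path(outdir, "manifest"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
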