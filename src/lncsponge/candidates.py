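"""Intersection-based candidate lncRNA nomination.

A lncRNA is shortlisted when it (i) is a high-degree hub of the ceRNA pair
network (top 20% of lncRNA degrees), (ii) belongs to a co-expression module
significantly correlated with TNM stage, and (iii) has at least one strong
co-expression partner (|PCC| >= 0.7 by default, positive edges only for the
lncRNA-mRNA layer semantics used here). The putative target set of each
candidate is the union of its ceRNA partners and its high-PCC mRNA partners.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ValidationError
from .wgcna import ModuleSet

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionNetwork:
    """Thresholded gene-gene correlation edges (lncRNA-lncRNA, lncRNA-mRNA)."""

    edges: pd.DataFrame  # columns: gene_a, gene_b, pcc, edge_type
    pcc_min: float

    def partners(self, gene_id: str) -> set:
        e = self.edges
        out = set(e.loc[e["gene_a"] == gene_id, "gene_b"])
        out |= set(e.loc[e["gene_b"] == gene_id, "gene_a"])
        return out

    def mrna_partners(self, lnc_id: str) -> set:
        e = self.edges[self.edges["edge_type"] == "lncRNA-mRNA"]
        out = set(e.loc[e["gene_a"] == lnc_id, "gene_b"])
        out |= set(e.loc[e["gene_b"] == lnc_id, "gene_a"])
        return out


def build_coexpression_network(
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    pcc_min: float = 0.7,
) -> CoexpressionNetwork:
    """All lncRNA-lncRNA and lncRNA-mRNA pairs with PCC >= pcc_min (inclusive).

    Edges are stored once with endpoints ordered (lexicographic within type)
    and sorted deterministically.
    """
    if list(expr_lnc.sample_ids) != list(expr_mrna.sample_ids):
        raise ValidationError("lncRNA and mRNA matrices must share sample ids, in order")
    lnc = expr_lnc.data
    mrna = expr_mrna.data
    rows = []
    # lncRNA-lncRNA
    lmat = lnc.to_numpy(dtype=float)
    keep = lmat.std(axis=1) > 0
    lids = np.array(expr_lnc.gene_ids)[keep]
    if len(lids) >= 2:
        lcor = np.atleast_2d(np.corrcoef(lmat[keep]))
        iu = np.triu_indices(len(lids), k=1)
        mask = lcor[iu] >= pcc_min
        for i, j, r in zip(iu[0][mask], iu[1][mask], lcor[iu][mask]):
            a, b = sorted((lids[i], lids[j]))
            rows.append((a, b, float(r), "lncRNA-lncRNA"))
    # lncRNA-mRNA (cross-correlation block)
    mmat = mrna.to_numpy(dtype=float)
    mkeep = mmat.std(axis=1) > 0
    mids = np.array(expr_mrna.gene_ids)[mkeep]
    lz = _standardize(lmat[keep])
    mz = _standardize(mmat[mkeep])
    cross = lz @ mz.T / lz.shape[1]
    li, mi = np.nonzero(cross >= pcc_min)
    for i, j in zip(li, mi):
        rows.append((str(lids[i]), str(mids[j]), float(cross[i, j]), "lncRNA-mRNA"))
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "edge_type"])
    df = df.sort_values(["edge_type", "gene_a", "gene_b"]).reset_index(drop=True)
    return CoexpressionNetwork(edges=df, pcc_min=pcc_min)


def _standardize(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    return (mat - mean) / sd


def top_degree_nodes(
    network: nx.Graph, fraction: float = 0.20, node_type: str = "lncRNA"
) -> set:
    """Nodes of the given type whose degree reaches the top-``fraction`` cut.

    The cut is the (1 - fraction) empirical quantile of same-type degrees;
    all boundary ties are kept and at least ceil(fraction * count) nodes are
    returned.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    nodes = [n for n, a in network.nodes(data=True) if a.get("node_type") == node_type]
    if not nodes:
        return set()
    degrees = pd.Series({n: network.degree(n) for n in nodes})
    cutoff = float(np.quantile(degrees.to_numpy(), 1.0 - fraction))
    chosen = set(degrees.index[degrees >= cutoff])
    minimum = math.ceil(fraction * len(nodes))
    if len(chosen) < minimum:
        ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        floor_degree = ranked[minimum - 1][1]
        chosen = {n for n, d in degrees.items() if d >= floor_degree}
    return chosen


@dataclass
class CandidateReport:
    """Shortlisted lncRNAs with the evidence behind each."""

    table: pd.DataFrame  # per candidate: degree, degree_percentile, module, module_p, n_targets
    targets: dict  # candidate -> {"cerna": set, "coexp": set}

    @property
    def candidate_ids(self) -> list[str]:
        return list(self.table.index)

    def all_target_mrnas(self) -> set:
        out: set = set()
        for t in self.targets.values():
            out |= t["cerna"] | t["coexp"]
        return out


def select_candidates(
    cerna_pair_graph: nx.Graph,
    modules: ModuleSet,
    significant: pd.DataFrame,
    coexp: CoexpressionNetwork,
    fraction: float = 0.20,
) -> CandidateReport:
    """Intersect the three evidence layers into the candidate shortlist.

    ``significant`` is the output of :func:`lncsponge.wgcna.significant_modules`.
    """
    columns = ["degree", "degree_percentile", "module", "module_p", "n_targets"]
    sig_modules = set(significant.index)
    if not sig_modules:
        logger.warning("no TNM-significant modules; candidate report is empty")
        return CandidateReport(
            table=pd.DataFrame(columns=columns), targets={}
        )
    hubs = top_degree_nodes(cerna_pair_graph, fraction=fraction, node_type="lncRNA")
    lnc_degrees = pd.Series(
        {
            n: cerna_pair_graph.degree(n)
            for n, a in cerna_pair_graph.nodes(data=True)
            if a.get("node_type") == "lncRNA"
        }
    )
    rows = []
    targets = {}
    for lnc in sorted(hubs):
        module = modules.assignment.get(lnc)
        if module not in sig_modules:
            continue
        coexp_partners = coexp.mrna_partners(lnc)
        if not coexp.partners(lnc):
            continue
        cerna_partners = {
            nb for nb in cerna_pair_graph.neighbors(lnc)
            if cerna_pair_graph.nodes[nb].get("node_type") == "mRNA"
        }
        linked = cerna_partners | coexp_partners
        percentile = float((lnc_degrees < lnc_degrees[lnc]).mean())
        rows.append(
            {
                "candidate": lnc,
                "degree": int(lnc_degrees[lnc]),
                "degree_percentile": percentile,
                "module": module,
                "module_p": float(significant.loc[module, "p"]),
                "n_targets": len(linked),
            }
        )
        targets[lnc] = {"cerna": cerna_partners, "coexp": coexp_partners}
    table = pd.DataFrame(rows, columns=["candidate"] + columns).set_index("candidate")
    return CandidateReport(table=table, targets=targets)


def candidate_target_table(report: CandidateReport) -> pd.DataFrame:
    """One row per (candidate, mRNA) with evidence in {cerna, coexp, both}."""
    rows = []
    for lnc in report.candidate_ids:
        t = report.targets[lnc]
        for mrna in sorted(t["cerna"] | t["coexp"]):
            if mrna in t["cerna"] and mrna in t["coexp"]:
                evidence = "both"
            elif mrna in t["cerna"]:
                evidence = "cerna"
            else:
                evidence = "coexp"
            rows.append({"lncrna_id": lnc, "mrna_id": mrna, "evidence": evidence})
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "evidence"])
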