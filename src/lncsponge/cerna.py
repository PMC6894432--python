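"""ceRNA pair inference from shared miRNA regulators.

A lncRNA and an mRNA are candidate competing endogenous RNAs when they share
predicted binding for the same miRNAs more often than chance (upper-tail
hypergeometric test over the differentially expressed miRNA universe) *and*
are positively co-expressed across tumor samples. Passing pairs form the
ceRNA network, whose node centralities feed candidate selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .types import ExpressionMatrix, TargetEdgeTable, ValidationError


@dataclass
class CeRNAPair:
    """One (lncRNA, mRNA) candidate with its shared-miRNA statistics.

    N = miRNA universe size, K = universe miRNAs targeting the lncRNA,
    n = universe miRNAs targeting the mRNA, m = shared.
    """

    lncrna_id: str
    mrna_id: str
    K: int
    n: int
    m: int
    N: int
    shared_mirnas: frozenset = field(default_factory=frozenset)
    hyper_p: float = np.nan
    pcc: float = np.nan
    pcc_p: float = np.nan
    passes: bool = False


def hypergeometric_upper_p(N: int, K: int, n: int, m: int) -> float:
    """P(overlap >= m) when drawing n of N items of which K are marked.

    Upper-tail hypergeometric probability
    ``sum_{k=m}^{min(K, n)} C(K,k) C(N-K, n-k) / C(N,n)``, evaluated via the
    log-space survival function for numerical stability.
    """
    if not (0 <= m <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(f"invalid hypergeometric margins N={N}, K={K}, n={n}, m={m}")
    if m == 0:
        return 1.0
    # sf(m-1) = P(X >= m)
    p = float(stats.hypergeom.sf(m - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-test p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("pearson_with_p needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector passed to pearson_with_p")
    r, p = stats.pearsonr(x, y)
    if 1.0 - abs(r) < 1e-14:  # exactly collinear up to float rounding
        return float(np.sign(r)), 0.0
    return float(r), float(p)


def shared_mirna_table(
    targets: TargetEdgeTable,
    lnc_ids,
    mrna_ids,
    mirna_universe,
) -> list[CeRNAPair]:
    """Candidate (lncRNA, mRNA) pairs sharing >= 1 universe miRNA.

    Edges to miRNAs outside the universe are ignored; K, n, m and N are all
    computed against the universe only.
    """
    universe = set(mirna_universe)
    if not universe:
        raise ValidationError("empty miRNA universe")
    N = len(universe)
    lnc_ids = sorted(set(lnc_ids))
    mrna_ids = sorted(set(mrna_ids))
    lnc_sets = {g: targets.mirnas_of(g) & universe for g in lnc_ids}
    mrna_sets = {g: targets.mirnas_of(g) & universe for g in mrna_ids}
    pairs: list[CeRNAPair] = []
    for lnc in lnc_ids:
        ls = lnc_sets[lnc]
        if not ls:
            continue
        for mrna in mrna_ids:
            ms = mrna_sets[mrna]
            shared = ls & ms
            if not shared:
                continue
            pairs.append(
                CeRNAPair(
                    lncrna_id=lnc,
                    mrna_id=mrna,
                    K=len(ls),
                    n=len(ms),
                    m=len(shared),
                    N=N,
                    shared_mirnas=frozenset(shared),
                )
            )
    return pairs


def score_cerna_pairs(
    pairs: list[CeRNAPair],
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    hyper_p_max: float = 0.05,
    require_positive_pcc: bool = True,
    pcc_p_max: float | None = 0.05,
    adjust_hyper_p: bool = False,
) -> list[CeRNAPair]:
    """Score every candidate pair and set its ``passes`` flag.

    passes = (hyper_p < hyper_p_max) AND (pcc > 0, if required) AND
    (pcc_p < pcc_p_max, if a threshold is given); all strict. Correlations
    are computed on the samples present in the supplied matrices (the
    pipeline passes tumor samples only). With ``adjust_hyper_p`` the
    hypergeometric p-values are BH-adjusted across pairs before thresholding.
    Returns all pairs, scored.
    """
    scored: list[CeRNAPair] = []
    lnc_data = expr_lnc.data
    mrna_data = expr_mrna.data
    if list(lnc_data.columns) != list(mrna_data.columns):
        raise ValidationError("lncRNA and mRNA matrices must cover the same samples, in order")
    for pair in pairs:
        if pair.lncrna_id not in lnc_data.index:
            raise ValidationError(f"pair member {pair.lncrna_id!r} missing from lncRNA matrix")
        if pair.mrna_id not in mrna_data.index:
            raise ValidationError(f"pair member {pair.mrna_id!r} missing from mRNA matrix")
        hyper_p = hypergeometric_upper_p(pair.N, pair.K, pair.n, pair.m)
        r, rp = pearson_with_p(
            lnc_data.loc[pair.lncrna_id].to_numpy(),
            mrna_data.loc[pair.mrna_id].to_numpy(),
        )
        scored.append(
            CeRNAPair(
                lncrna_id=pair.lncrna_id,
                mrna_id=pair.mrna_id,
                K=pair.K,
                n=pair.n,
                m=pair.m,
                N=pair.N,
                shared_mirnas=pair.shared_mirnas,
                hyper_p=hyper_p,
                pcc=r,
                pcc_p=rp,
            )
        )
    hyper = np.array([p.hyper_p for p in scored]) if scored else np.array([])
    if adjust_hyper_p and scored:
        hyper = benjamini_hochberg(hyper)
    for pair, hp in zip(scored, hyper):
        ok = hp < hyper_p_max
        if require_positive_pcc:
            ok = ok and pair.pcc > 0
        if pcc_p_max is not None:
            ok = ok and pair.pcc_p < pcc_p_max
        pair.passes = bool(ok)
    return scored


def filter_cerna_pairs(
    pairs: list[CeRNAPair],
    expr_lnc: ExpressionMatrix,
    expr_mrna: ExpressionMatrix,
    hyper_p_max: float = 0.05,
    require_positive_pcc: bool = True,
    pcc_p_max: float | None = 0.05,
    adjust_hyper_p: bool = False,
) -> list[CeRNAPair]:
    """Score candidate pairs (see :func:`score_cerna_pairs`) and return the
    passing subset, preserving input order."""
    scored = score_cerna_pairs(
        pairs, expr_lnc, expr_mrna,
        hyper_p_max=hyper_p_max,
        require_positive_pcc=require_positive_pcc,
        pcc_p_max=pcc_p_max,
        adjust_hyper_p=adjust_hyper_p,
    )
    return [p for p in scored if p.passes]


def pairs_to_frame(pairs: list[CeRNAPair]) -> pd.DataFrame:
    """Flatten pair records into a sorted DataFrame for TSV output."""
    rows = [
        {
            "lncrna_id": p.lncrna_id,
            "mrna_id": p.mrna_id,
            "K": p.K,
            "n": p.n,
            "m": p.m,
            "N": p.N,
            "shared_mirnas": ";".join(sorted(p.shared_mirnas)),
            "hyper_p": p.hyper_p,
            "pcc": p.pcc,
            "pcc_p": p.pcc_p,
            "passes": p.passes,
        }
        for p in pairs
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "lncrna_id", "mrna_id", "K", "n", "m", "N",
            "shared_mirnas", "hyper_p", "pcc", "pcc_p", "passes",
        ],
    )
    return df.sort_values(["lncrna_id", "mrna_id"]).reset_index(drop=True)


def build_cerna_network(
    passing_pairs: list[CeRNAPair],
    targets: TargetEdgeTable | None = None,
    include_mirna_nodes: bool = False,
) -> nx.Graph:
    """Graph over passing lncRNA-mRNA pair edges.

    With ``include_mirna_nodes`` the shared miRNAs become nodes connected to
    both partners (edges labeled ``targets``). Nodes carry a ``node_type``
    attribute; node insertion order is deterministic (sorted).
    """
    g = nx.Graph()
    seen = set()
    for pair in sorted(passing_pairs, key=lambda p: (p.lncrna_id, p.mrna_id)):
        key = (pair.lncrna_id, pair.mrna_id)
        if key in seen:
            continue
        seen.add(key)
        g.add_node(pair.lncrna_id, node_type="lncRNA")
        g.add_node(pair.mrna_id, node_type="mRNA")
        g.add_edge(pair.lncrna_id, pair.mrna_id, interaction="cerna",
                   hyper_p=pair.hyper_p, pcc=pair.pcc)
        if include_mirna_nodes:
            for mir in sorted(pair.shared_mirnas):
                g.add_node(mir, node_type="miRNA")
                g.add_edge(mir, pair.lncrna_id, interaction="targets")
                g.add_edge(mir, pair.mrna_id, interaction="targets")
    return g


def pair_graph(network: nx.Graph) -> nx.Graph:
    """The lncRNA-mRNA pair subgraph (miRNA nodes and target edges removed)."""
    g = nx.Graph()
    for node, attrs in network.nodes(data=True):
        if attrs.get("node_type") != "miRNA":
            g.add_node(node, **attrs)
    for u, v, attrs in network.edges(data=True):
        if attrs.get("interaction") == "cerna":
            g.add_edge(u, v, **attrs)
    return g


def centralities(network: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness for every node.

    Betweenness is the unnormalized undirected Brandes count (each unordered
    pair counted once); closeness is (reachable - 1) / sum of distances
    within the node's connected component; isolated nodes get closeness 0.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("centralities needs a network with >= 1 node")
    degree = dict(network.degree())
    betweenness = nx.betweenness_centrality(network, normalized=False)
    closeness = nx.closeness_centrality(network, wf_improved=False)
    df = pd.DataFrame(
        {
            "node": sorted(network.nodes),
            "node_type": [network.nodes[n].get("node_type", "") for n in sorted(network.nodes)],
            "degree": [degree[n] for n in sorted(network.nodes)],
            "betweenness": [betweenness[n] for n in sorted(network.nodes)],
            "closeness": [closeness[n] for n in sorted(network.nodes)],
        }
    )
    return df.set_index("node")


def rank_network_mirnas(network: nx.Graph, de: pd.DataFrame, k: int = 20) -> list[str]:
    """miRNAs participating in >= 1 passing pair, ranked by |log2FC|, top k.

    Ranking ties are broken lexicographically; may return fewer than k.
    """
    mirnas = sorted(
        n for n, attrs in network.nodes(data=True) if attrs.get("node_type") == "miRNA"
    )
    known = [m for m in mirnas if m in de.index]
    ranked = sorted(known, key=lambda m: (-abs(de.loc[m, "log2fc"]), m))
    return ranked[:k]
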