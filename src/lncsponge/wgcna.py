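"""Signed weighted co-expression network analysis.

The chain is the classic one: pick a soft-threshold power so the weighted
network is approximately scale-free, raise the signed correlation transform
``((1 + cor)/2)**beta`` to that power, convert adjacency to topological
overlap, cluster genes on 1 - TOM with average linkage, cut the tree at a
static height, relabel small clusters as unassigned, merge modules with
highly correlated eigengenes, and correlate each module eigengene with TNM
stage indicators over tumor samples.

Module labels are ``M1, M2, ...`` ordered by size (descending) then by the
lexicographically smallest member id; ``unassigned`` plays the role of the
conventional grey module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .types import ClinicalTable, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class SoftThresholdScan:
    """Scale-free fit per candidate power and the chosen power."""

    table: pd.DataFrame  # index = power; columns: signed_r2, mean_connectivity
    chosen_power: int
    satisfied: bool  # whether chosen power met the r2_min threshold


@dataclass
class ModuleSet:
    """Gene -> module assignment plus eigengenes and module sizes."""

    assignment: pd.Series  # index = gene ids, values = module labels
    eigengenes: pd.DataFrame = None  # modules x samples, unit variance each
    merge_heights: np.ndarray = field(default=None, repr=False)

    @property
    def module_ids(self) -> list[str]:
        return sorted(
            set(self.assignment) - {UNASSIGNED},
            key=lambda lab: int(lab[1:]) if lab[1:].isdigit() else lab,
        )

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts()

    def members(self, module_id: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module_id])


def _gene_correlation(expr: ExpressionMatrix) -> pd.DataFrame:
    mat = expr.data.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        names = [expr.gene_ids[i] for i in constant[:10]]
        raise ValidationError(f"constant gene rows (no correlation defined): {names}")
    cor = np.corrcoef(mat)
    return pd.DataFrame(cor, index=expr.data.index, columns=expr.data.index)


def signed_adjacency(cor_matrix, beta: float) -> np.ndarray:
    """Signed adjacency a_ij = ((1 + cor_ij)/2) ** beta, zero diagonal."""
    if beta <= 0:
        raise ValidationError(f"beta must be positive, got {beta}")
    cor = np.asarray(cor_matrix, dtype=float)
    if cor.ndim != 2 or cor.shape[0] != cor.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(cor, cor.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if cor.min() < -1 - 1e-12 or cor.max() > 1 + 1e-12:
        raise ValidationError("correlation entries must lie in [-1, 1]")
    adj = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Bins log10(k), regresses log10(bin frequency) on log10(mean k per bin),
    and returns R^2 with the sign flipped to the *negation* of the slope's
    sign, so a genuine power-law decay (negative slope) scores +R^2. Returns
    -1.0 when fewer than 3 non-empty bins exist.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.ptp(k) == 0:
        return -1.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return -1.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_min: float = 0.85,
    fallback: int | str = "argmax",
) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest with signed fit >= r2_min.

    When no power qualifies, ``fallback`` decides: ``"argmax"`` picks the
    power maximizing the fit; an integer picks that fixed power (the
    conventional choice for signed networks is 12, useful when the input has
    block structure with no power-law degree tail, where the argmax of a
    near-zero fit index is essentially noise). A warning is emitted either
    way.
    """
    if expr.shape[1] < 2:
        raise ValidationError("need >= 2 samples for co-expression")
    powers = [int(p) for p in powers]
    if any(p <= 0 for p in powers):
        raise ValidationError("candidate powers must be positive integers")
    cor = _gene_correlation(expr).to_numpy()
    rows = []
    for beta in powers:
        adj = signed_adjacency(cor, beta)
        k = adj.sum(axis=1)
        rows.append(
            {"power": beta, "signed_r2": scale_free_fit(k), "mean_connectivity": float(k.mean())}
        )
    table = pd.DataFrame(rows).set_index("power")
    qualifying = table.index[table["signed_r2"] >= r2_min]
    if len(qualifying):
        chosen, satisfied = int(qualifying[0]), True
    else:
        if fallback == "argmax":
            chosen = int(table["signed_r2"].idxmax())
        else:
            chosen = int(fallback)
            if chosen not in table.index:
                raise ValidationError(
                    f"fallback power {chosen} not among candidate powers"
                )
        satisfied = False
        logger.warning(
            "no candidate power reached signed R^2 >= %.2f; falling back to "
            "power %d (R^2 = %.3f)", r2_min, chosen, table.loc[chosen, "signed_r2"],
        )
    return SoftThresholdScan(table=table, chosen_power=chosen, satisfied=satisfied)


def topological_overlap(adjacency) -> np.ndarray:
    """TOM similarity: (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Diagonal is 1; dissimilarity for clustering is 1 - TOM.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    dissimilarity,
    min_module_size: int = 30,
    cut_height: float = 0.9,
    gene_ids=None,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Clusters smaller than ``min_module_size`` are relabeled ``unassigned``.
    Labels are deterministic: M1 is the largest module (ties broken by
    smallest member id). Eigengene-based merging is a separate step
    (:func:`merge_close_modules`) because it needs expression data.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("dissimilarity must be square")
    n = d.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    gene_ids = list(gene_ids)
    if len(gene_ids) != n:
        raise ValidationError("gene_ids length must match the dissimilarity size")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = _relabel(pd.Series(raw, index=gene_ids), min_module_size)
    return ModuleSet(assignment=labels, merge_heights=link[:, 2])


def _relabel(raw: pd.Series, min_module_size: int) -> pd.Series:
    """Size-descending deterministic module labels; small clusters dropped."""
    keep = []
    for cluster_id, members in raw.groupby(raw).groups.items():
        if len(members) >= min_module_size:
            keep.append((len(members), min(members), cluster_id, list(members)))
    keep.sort(key=lambda t: (-t[0], t[1]))
    labels = pd.Series(UNASSIGNED, index=raw.index, dtype=object)
    for rank, (_, _, _, members) in enumerate(keep, start=1):
        labels.loc[members] = f"M{rank}"
    return labels


def module_eigengene(expr: ExpressionMatrix, member_gene_ids) -> pd.Series:
    """First-principal-component summary profile of a module.

    Member rows are standardized, the leading left/right singular direction
    gives per-sample scores, scaled to unit variance, with the sign chosen so
    the eigengene correlates positively with the module's mean standardized
    expression.
    """
    members = list(member_gene_ids)
    if len(members) < 2:
        raise ValidationError("module_eigengene needs >= 2 member genes")
    if expr.shape[1] < 3:
        raise ValidationError("module_eigengene needs >= 3 samples")
    sub = expr.data.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    if (sd == 0).any():
        raise ValidationError("constant member gene rows in module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector of the standardized member x sample matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt[0]
    scores = scores / scores.std(ddof=1)
    mean_profile = z.mean(axis=0)
    if np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.data.columns)


def module_eigengenes(expr: ExpressionMatrix, modules: ModuleSet) -> pd.DataFrame:
    rows = {}
    for module_id in modules.module_ids:
        rows[module_id] = module_eigengene(expr, modules.members(module_id))
    return pd.DataFrame(rows).T


def merge_close_modules(
    expr: ExpressionMatrix, modules: ModuleSet, merge_diss_max: float = 0.25
) -> ModuleSet:
    """Iteratively merge module pairs whose eigengene dissimilarity
    (1 - correlation) is below ``merge_diss_max``, closest pair first,
    until stable; then relabel deterministically and recompute eigengenes."""
    assignment = modules.assignment.copy()
    while True:
        ids = sorted(set(assignment) - {UNASSIGNED})
        if len(ids) < 2:
            break
        eig = {m: module_eigengene(expr, assignment.index[assignment == m]) for m in ids}
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                diss = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if diss < merge_diss_max and (best is None or diss < best[0]):
                    best = (diss, a, b)
        if best is None:
            break
        _, a, b = best
        assignment[assignment == b] = a
    # deterministic relabel by size then smallest member id
    raw = pd.Series(
        pd.factorize(assignment)[0], index=assignment.index
    ).where(assignment != UNASSIGNED, other=-1)
    keep = raw[raw >= 0]
    relabeled = _relabel(keep, min_module_size=1) if len(keep) else pd.Series(dtype=object)
    out = pd.Series(UNASSIGNED, index=assignment.index, dtype=object)
    out.loc[relabeled.index] = relabeled
    merged = ModuleSet(assignment=out, merge_heights=modules.merge_heights)
    merged.eigengenes = module_eigengenes(expr, merged)
    return merged


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    clinical: ClinicalTable,
    ordinal: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with TNM stage over tumor samples.

    Default encoding is one binary indicator column per observed stage
    (mirroring a module-trait heatmap with one column per stage); with
    ``ordinal`` a single column codes I..IV as 1..4. Returns a DataFrame with
    a two-level column index (trait, {r, p}).
    """
    df = clinical.data
    tumor = df[(df["condition"] == "tumor") & df["tnm_stage"].notna()]
    samples = [s for s in tumor["sample_id"] if s in eigengenes.columns]
    if len(samples) < 3:
        raise ValidationError("need >= 3 staged tumor samples for module-trait correlation")
    stages = tumor.set_index("sample_id").loc[samples, "tnm_stage"]
    if ordinal:
        codes = {"I": 1, "II": 2, "III": 3, "IV": 4}
        traits = pd.DataFrame({"TNM": [codes[s] for s in stages]}, index=samples)
    else:
        observed = [s for s in ("I", "II", "III", "IV") if (stages == s).any()]
        dropped = set("I II III IV".split()) - set(observed)
        if dropped:
            logger.warning("TNM stage(s) with no tumor samples dropped: %s", sorted(dropped))
        traits = pd.DataFrame(
            {f"TNM_{s}": (stages == s).astype(float).to_numpy() for s in observed},
            index=samples,
        )
    results = {}
    for trait in traits.columns:
        t = traits[trait].to_numpy()
        if np.ptp(t) == 0:
            logger.warning("trait column %s is constant; dropped", trait)
            continue
        rs, ps = [], []
        for module_id in eigengenes.index:
            e = eigengenes.loc[module_id, samples].to_numpy(dtype=float)
            r, p = stats.pearsonr(e, t)
            rs.append(float(r))
            ps.append(float(p))
        results[(trait, "r")] = rs
        results[(trait, "p")] = ps
    out = pd.DataFrame(results, index=eigengenes.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["trait", "stat"])
    return out


def significant_modules(module_trait: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """Modules whose best (smallest) trait p-value is strictly below p_max.

    Returns a frame indexed by module with columns best_trait, r, p.
    """
    p_cols = module_trait.xs("p", axis=1, level="stat")
    rows = []
    for module_id in module_trait.index:
        best_trait = p_cols.loc[module_id].idxmin()
        best_p = p_cols.loc[module_id, best_trait]
        if best_p < p_max:
            rows.append(
                {
                    "module": module_id,
                    "best_trait": best_trait,
                    "r": module_trait.loc[module_id, (best_trait, "r")],
                    "p": best_p,
                }
            )
    return pd.DataFrame(rows, columns=["module", "best_trait", "r", "p"]).set_index("module")


def wgcna_pipeline(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_min: float = 0.85,
    cut_height: float = 0.9,
    min_module_size: int = 30,
    merge_diss_max: float = 0.25,
    module_p_max: float = 0.05,
    ordinal_trait: bool = False,
    fallback_power: int | str = 12,
):
    """Run the full co-expression chain on one expression matrix.

    Returns (scan, modules, module_trait, significant) where ``modules``
    carries both pre-merge counts (via merge_heights) and final eigengenes.
    """
    scan = pick_soft_threshold(expr, powers=powers, r2_min=r2_min, fallback=fallback_power)
    cor = _gene_correlation(expr).to_numpy()
    adj = signed_adjacency(cor, scan.chosen_power)
    tom = topological_overlap(adj)
    modules = detect_modules(
        1.0 - tom, min_module_size=min_module_size, cut_height=cut_height,
        gene_ids=expr.gene_ids,
    )
    n_premerge = len(set(modules.assignment) - {UNASSIGNED})
    if n_premerge >= 1:
        modules = merge_close_modules(expr, modules, merge_diss_max=merge_diss_max)
    else:
        modules.eigengenes = pd.DataFrame(columns=expr.sample_ids)
    logger.info(
        "modules: %d before merging, %d after", n_premerge,
        len(set(modules.assignment) - {UNASSIGNED}),
    )
    if len(modules.eigengenes):
        module_trait = module_trait_correlation(
            modules.eigengenes, clinical, ordinal=ordinal_trait
        )
        significant = significant_modules(module_trait, p_max=module_p_max)
    else:
        module_trait = pd.DataFrame()
        significant = pd.DataFrame(columns=["best_trait", "r", "p"])
    return scan, modules, module_trait, significant
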