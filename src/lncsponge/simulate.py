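"""Synthetic paired tumor/normal cohort with planted ground truth.

The generator emulates the statistical structure the pipeline is built to
detect, so every downstream stage can be validated against known answers:

* negative-binomial counts around log-normal per-gene baselines, one tumor
  and one normal sample per patient;
* planted differentially expressed genes whose tumor means shift by a fixed
  log2 fold change;
* latent-factor co-expression modules among the lncRNAs, with one module's
  factor tied to TNM stage in tumor samples;
* planted ceRNA triplets: candidate lncRNAs from the trait module, each with
  a private set of strongly differential miRNAs and a private set of partner
  mRNAs; shared binding edges appear in the emitted target table, lncRNA and
  mRNA co-vary positively with the trait factor in tumors, and the miRNAs are
  anti-correlated with both partners in tumors;
* exponential survival with hazard increasing for patients in the top
  expression half of each planted risk lncRNA, plus uniform censoring.

A single integer seed drives one root generator from which all stages draw
in a fixed order, so identical configurations reproduce byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import ClinicalTable, ExpressionMatrix, TargetEdgeTable, ValidationError


@dataclass
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults describe a 50-pair cohort with ~2,000 mRNAs, 500 lncRNAs and 150
    miRNAs, |log2FC| = 2 differential genes, five lncRNA modules of 50 genes,
    and eight candidate lncRNAs carrying 80 planted ceRNA triplets.
    """

    n_pairs: int = 50
    n_mrna: int = 2000
    n_lncrna: int = 500
    n_mirna: int = 150
    frac_de: float = 0.15
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    n_modules: int = 5
    module_size: int = 50
    module_noise_sd: float = 0.3
    n_triplets: int = 80
    n_candidates: int = 8
    mirnas_per_candidate: int = 2
    targets_per_mirna: float = 10.0
    decoy_edge_frac: float = 1.0
    trait_effect: float = 0.8
    cerna_mirna_loading: float = 0.8
    risk_hazard_ratio: float = 6.0
    base_median_survival_days: float = 700.0
    censor_low_days: float = 1000.0
    censor_high_days: float = 3000.0
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    baseline_min_mean: float = 10.0
    mirna_drop_last_pair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_lncrna", "n_mirna"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_de", "decoy_edge_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.trait_effect <= 1:
            raise ValidationError("trait_effect must lie in [0, 1]")
        if self.de_log2fc <= 0:
            raise ValidationError("de_log2fc must be positive")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.n_modules * self.module_size > self.n_lncrna:
            raise ValidationError(
                f"module_size * n_modules = {self.n_modules * self.module_size} "
                f"exceeds n_lncrna = {self.n_lncrna}"
            )
        if self.n_triplets > 0:
            per_cand = self.n_candidates * self.mirnas_per_candidate
            if per_cand == 0 or self.n_triplets % per_cand != 0:
                raise ValidationError(
                    "n_triplets must be a positive multiple of "
                    "n_candidates * mirnas_per_candidate"
                )
            if self.n_candidates > self.module_size:
                raise ValidationError("n_candidates cannot exceed module_size")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery scoring."""

    de_log2fc: dict  # role -> {gene_id: signed log2fc}
    module_membership: pd.Series  # lncRNA id -> module label ("none" if unplanted)
    trait_module_id: str | None
    triplets: list  # of (lncrna_id, mirna_id, mrna_id)
    risk_lncrnas: list
    candidate_partners: dict = field(default_factory=dict)  # lnc -> set of mRNA ids
    latent_factors: pd.DataFrame = None  # module x sample factor values

    def triplet_pairs(self) -> set:
        return {(lnc, mrna) for lnc, _, mrna in self.triplets}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_cohort(config: CohortConfig):
    """Draw one synthetic cohort.

    Returns ``(expr_mrna, expr_lncrna, expr_mirna, clinical, targets, truth)``
    with counts matrices of shape (n_genes, 2 * n_pairs).
    """
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_pairs
    patients = [f"P{i + 1:03d}" for i in range(n_pairs)]
    tumor_samples = [f"{p}-T" for p in patients]
    normal_samples = [f"{p}-N" for p in patients]
    samples = tumor_samples + normal_samples
    is_tumor = np.array([True] * n_pairs + [False] * n_pairs)

    mrna_ids = [f"MRNA{i + 1:05d}" for i in range(config.n_mrna)]
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(config.n_lncrna)]
    mir_ids = [f"MIR{i + 1:04d}" for i in range(config.n_mirna)]

    # --- clinical skeleton: stages uniform over I/II/III on tumor samples ---
    stage_codes = rng.integers(1, 4, size=n_pairs)  # 1..3
    stage_z = (stage_codes - stage_codes.mean()) / (stage_codes.std() or 1.0)

    # --- module structure on lncRNAs -------------------------------------
    module_labels = pd.Series("none", index=lnc_ids, dtype=object)
    factors = {}
    module_gene_lists = []
    if config.n_modules > 0:
        chosen = rng.choice(config.n_lncrna, size=config.n_modules * config.module_size,
                            replace=False)
        for m in range(config.n_modules):
            members = [lnc_ids[i] for i in
                       chosen[m * config.module_size:(m + 1) * config.module_size]]
            module_gene_lists.append(members)
            module_labels.loc[members] = f"PM{m + 1}"
        for m in range(config.n_modules):
            f = rng.standard_normal(2 * n_pairs)
            if m == 0 and config.trait_effect > 0:
                eps = rng.standard_normal(n_pairs)
                f[:n_pairs] = (
                    config.trait_effect * stage_z
                    + np.sqrt(1.0 - config.trait_effect ** 2) * eps
                )
            factors[f"PM{m + 1}"] = f
    trait_module_id = "PM1" if (config.n_modules > 0 and config.trait_effect > 0) else None

    # --- candidate lncRNAs, their miRNAs and partner mRNAs ----------------
    triplets: list = []
    candidate_partners: dict = {}
    candidates: list = []
    cand_mirnas: dict = {}
    mrnas_per_candidate = 0
    forced_up_lnc: set = set()
    forced_up_mrna: set = set()
    forced_mir: dict = {}
    if config.n_triplets > 0:
        mrnas_per_candidate = config.n_triplets // (
            config.n_candidates * config.mirnas_per_candidate
        )
        # candidates live in the trait module (fall back to first module)
        home = module_gene_lists[0] if module_gene_lists else list(lnc_ids)
        candidates = [str(g) for g in rng.choice(home, size=config.n_candidates, replace=False)]
        mir_pool = [str(g) for g in rng.choice(
            mir_ids, size=config.n_candidates * config.mirnas_per_candidate, replace=False
        )]
        mrna_pool = [str(g) for g in rng.choice(
            mrna_ids, size=config.n_candidates * mrnas_per_candidate, replace=False
        )]
        for c_idx, lnc in enumerate(candidates):
            mirs = mir_pool[
                c_idx * config.mirnas_per_candidate:(c_idx + 1) * config.mirnas_per_candidate
            ]
            parts = mrna_pool[
                c_idx * mrnas_per_candidate:(c_idx + 1) * mrnas_per_candidate
            ]
            cand_mirnas[lnc] = mirs
            candidate_partners[lnc] = set(parts)
            for j, mir in enumerate(mirs):
                # alternate miRNA fold-change direction; magnitude exceeds the
                # generic DE effect so these rank inside the top/bottom-k set
                forced_mir[mir] = (config.de_log2fc + 1.0) * (1 if j % 2 == 0 else -1)
                for mrna in parts:
                    triplets.append((lnc, mir, mrna))
        forced_up_lnc = set(candidates)
        forced_up_mrna = set().union(*candidate_partners.values())

    # --- differential expression assignment -------------------------------
    de_log2fc = {"mRNA": {}, "lncRNA": {}, "miRNA": {}}

    def assign_de(ids, role, forced_up, forced_signed):
        for g in forced_up:
            de_log2fc[role][g] = config.de_log2fc
        for g, lfc in forced_signed.items():
            de_log2fc[role][g] = lfc
        n_target = int(round(config.frac_de * len(ids)))
        remaining = max(0, n_target - len(de_log2fc[role]))
        free = [g for g in ids if g not in de_log2fc[role]]
        if remaining > 0 and free:
            extra = rng.choice(free, size=min(remaining, len(free)), replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(extra))
            for g, s in zip(extra, signs):
                de_log2fc[role][str(g)] = float(s) * config.de_log2fc

    assign_de(mrna_ids, "mRNA", forced_up_mrna, {})
    assign_de(lnc_ids, "lncRNA", forced_up_lnc, {})
    assign_de(mir_ids, "miRNA", set(), forced_mir)

    # --- expression matrices ----------------------------------------------
    def build_matrix(ids, role):
        n_genes = len(ids)
        baseline = np.exp(
            rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_genes)
        )
        baseline = np.maximum(baseline, config.baseline_min_mean)
        logfc_shift = np.zeros((n_genes, 2 * n_pairs))
        for i, g in enumerate(ids):
            lfc = de_log2fc[role].get(g)
            if lfc is not None:
                logfc_shift[i, is_tumor] += lfc
        if role == "lncRNA":
            for i, g in enumerate(ids):
                mod = module_labels[g]
                if mod != "none":
                    logfc_shift[i] += factors[mod]
        elif role == "mRNA" and trait_module_id is not None:
            f = factors[trait_module_id]
            for i, g in enumerate(ids):
                if g in forced_up_mrna:
                    logfc_shift[i] += f
        elif role == "miRNA" and trait_module_id is not None:
            f = factors[trait_module_id]
            for i, g in enumerate(ids):
                if g in forced_mir:
                    # sponge depletion: anti-correlated with partners in tumors
                    logfc_shift[i, is_tumor] -= config.cerna_mirna_loading * f[is_tumor]
        noise = rng.normal(0.0, config.module_noise_sd, size=(n_genes, 2 * n_pairs))
        mean = baseline[:, None] * 2.0 ** (logfc_shift + noise)
        counts = _nb_sample(rng, mean, config.nb_dispersion)
        return ExpressionMatrix(
            pd.DataFrame(counts.astype(float), index=ids, columns=samples),
            role=role, unit="counts",
        )

    expr_mrna = build_matrix(mrna_ids, "mRNA")
    expr_lnc = build_matrix(lnc_ids, "lncRNA")
    expr_mir = build_matrix(mir_ids, "miRNA")
    if config.mirna_drop_last_pair and n_pairs > 1:
        keep = [s for s in samples if not s.startswith(patients[-1])]
        expr_mir = expr_mir.subset_samples(keep)

    # --- target edge table -------------------------------------------------
    planted_edges = []
    for lnc, mirs in cand_mirnas.items():
        for mir in mirs:
            planted_edges.append((mir, lnc))
            for mrna in candidate_partners[lnc]:
                planted_edges.append((mir, mrna))
    n_decoys = int(round(config.decoy_edge_frac * config.n_mirna * config.targets_per_mirna))
    all_targets = mrna_ids + lnc_ids
    decoy_mirs = rng.choice(mir_ids, size=n_decoys)
    decoy_targets = rng.choice(all_targets, size=n_decoys)
    edges = planted_edges + list(zip(decoy_mirs, decoy_targets))
    targets = TargetEdgeTable.from_edges(
        pd.DataFrame(edges, columns=["mirna_id", "target_id"])
    )

    # --- survival ----------------------------------------------------------
    base_rate = np.log(2.0) / config.base_median_survival_days
    risk_frac = np.zeros(n_pairs)
    if candidates:
        tumor_expr = np.stack([
            expr_lnc.data.loc[c, tumor_samples].to_numpy() for c in candidates
        ])
        top_half = tumor_expr > np.median(tumor_expr, axis=1, keepdims=True)
        risk_frac = top_half.mean(axis=0)
    rate = base_rate * config.risk_hazard_ratio ** risk_frac
    raw_time = rng.exponential(1.0 / rate)
    censor = rng.uniform(config.censor_low_days, config.censor_high_days, size=n_pairs)
    time = np.minimum(raw_time, censor)
    event = (raw_time <= censor).astype(int)

    stage_names = {1: "I", 2: "II", 3: "III"}
    clinical = ClinicalTable(pd.DataFrame(
        {
            "sample_id": samples,
            "patient_id": patients + patients,
            "condition": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": patients + patients,
            "tnm_stage": [stage_names[c] for c in stage_codes] + [None] * n_pairs,
            "survival_time": np.concatenate([np.round(time, 1), np.full(n_pairs, np.nan)]),
            "event": np.concatenate([event.astype(float), np.full(n_pairs, np.nan)]),
        }
    ))

    truth = GroundTruth(
        de_log2fc=de_log2fc,
        module_membership=module_labels,
        trait_module_id=trait_module_id,
        triplets=sorted(triplets),
        risk_lncrnas=sorted(candidates),
        candidate_partners=candidate_partners,
        latent_factors=pd.DataFrame(factors, index=samples).T if factors else None,
    )
    return expr_mrna, expr_lnc, expr_mir, clinical, targets, truth


def truth_report(truth: GroundTruth, path) -> None:
    """Dump every planted structure as a tidy TSV (record_type + fields)."""
    rows = []
    for role in ("mRNA", "lncRNA", "miRNA"):
        for gene, lfc in sorted(truth.de_log2fc.get(role, {}).items()):
            rows.append(("de_gene", role, gene, f"{lfc:.6g}"))
    for gene, mod in truth.module_membership.items():
        if mod != "none":
            rows.append(("module_member", mod, gene, ""))
    if truth.trait_module_id is not None:
        rows.append(("trait_module", truth.trait_module_id, "", ""))
    for lnc, mir, mrna in truth.triplets:
        rows.append(("triplet", lnc, mir, mrna))
    for lnc in truth.risk_lncrnas:
        rows.append(("risk_lncrna", lnc, "", ""))
    df = pd.DataFrame(rows, columns=["record_type", "field1", "field2", "field3"])
    df.to_csv(path, sep="\t", index=False)


def read_truth_report(path, lncrna_ids=None) -> GroundTruth:
    """Rebuild a GroundTruth from :func:`truth_report` output."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    de = {"mRNA": {}, "lncRNA": {}, "miRNA": {}}
    membership = {}
    trait = None
    triplets = []
    risks = []
    for _, row in df.iterrows():
        kind = row["record_type"]
        if kind == "de_gene":
            de[row["field1"]][row["field2"]] = float(row["field3"])
        elif kind == "module_member":
            membership[row["field2"]] = row["field1"]
        elif kind == "trait_module":
            trait = row["field1"]
        elif kind == "triplet":
            triplets.append((row["field1"], row["field2"], row["field3"]))
        elif kind == "risk_lncrna":
            risks.append(row["field1"])
    index = list(lncrna_ids) if lncrna_ids is not None else sorted(membership)
    series = pd.Series("none", index=index, dtype=object)
    for g, m in membership.items():
        if g in series.index:
            series.loc[g] = m
        else:
            series.loc[g] = m
    partners: dict = {}
    for lnc, _, mrna in triplets:
        partners.setdefault(lnc, set()).add(mrna)
    return GroundTruth(
        de_log2fc=de,
        module_membership=series,
        trait_module_id=trait,
        triplets=sorted(triplets),
        risk_lncrnas=sorted(risks),
        candidate_partners=partners,
    )


def config_to_dict(config: CohortConfig) -> dict:
    return asdict(config)
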