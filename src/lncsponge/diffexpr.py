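"""Normalization and differential-expression screening.

Counts are TMM-normalized (trimmed mean of M-values, the standard edgeR-style
between-sample scaling), converted to log2 counts-per-million, and screened
with a paired two-sided t-test on per-pair tumor-minus-normal log differences.
The screening thresholds mirror the usual biomarker funnel: FDR < 0.01 and
|log2FC| > 1 for mRNAs/lncRNAs, and a top/bottom-k fold-change rule for
miRNAs.

The paired t-test is a deliberate, documented stand-in for a negative-binomial
exact test: the DE stage here is a screen whose thresholds, not whose exact
test, drive everything downstream, and the paired design matches the cohort
structure (tumor/normal pairs from the same patients).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ClinicalTable, ExpressionMatrix, ValidationError

import logging

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFactors:
    """Per-sample scaling factors with geometric mean 1."""

    factors: pd.Series  # index = sample ids
    method: str = "TMM"

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValidationError("normalization factors must be finite and positive")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference (log2 scale -> 2**f)."""
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic variance of M; precision weight = 1/v
    v = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0 ** f)


def tmm_factors(counts: ExpressionMatrix, ref_sample: str | None = None) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors.

    M (log ratio) and A (log abundance) values are computed against the
    reference sample on genes expressed in both libraries; 30% of M extremes
    and 5% of A extremes are trimmed; the factor is 2**(precision-weighted
    mean M); factors are rescaled to geometric mean 1.

    The reference defaults to the sample whose upper-quartile relative
    abundance is closest to the cohort mean.
    """
    if counts.unit != "counts":
        raise ValidationError(f"tmm_factors needs raw counts, got unit {counts.unit!r}")
    mat = counts.data.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = np.nonzero(lib <= 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero library for sample(s) {[counts.sample_ids[i] for i in zero]}"
        )
    samples = counts.sample_ids
    if ref_sample is None:
        f75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(len(samples))])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref_sample not in samples:
            raise ValidationError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = samples.index(ref_sample)
    factors = np.ones(len(samples))
    for j in range(len(samples)):
        if j == ref_idx:
            factors[j] = 1.0
        else:
            factors[j] = _tmm_pair_factor(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(pd.Series(factors, index=samples), method="TMM")


def to_log2cpm(
    counts: ExpressionMatrix,
    factors: NormalizationFactors | None = None,
    prior: float = 0.5,
) -> ExpressionMatrix:
    """log2((count + prior_j) / effective library size * 1e6).

    The effective library size is the raw library size times the sample's TMM
    factor. The pseudo-count is scaled per sample in proportion to its
    effective library size (prior_j = prior * lib_j / mean(lib)), which keeps
    zeros finite and makes the transform invariant to a pure depth change.
    """
    if counts.unit != "counts":
        raise ValidationError(f"to_log2cpm needs raw counts, got unit {counts.unit!r}")
    if prior <= 0:
        raise ValidationError(f"prior must be positive, got {prior}")
    mat = counts.data.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if factors is not None:
        f = factors.factors.reindex(counts.sample_ids)
        if f.isna().any():
            raise ValidationError("normalization factors missing for some samples")
        lib = lib * f.to_numpy()
    prior_j = prior * lib / lib.mean()
    log2cpm = np.log2((mat + prior_j[None, :]) / lib[None, :] * 1e6)
    out = pd.DataFrame(log2cpm, index=counts.data.index, columns=counts.data.columns)
    return ExpressionMatrix(out, role=counts.role, unit="log2CPM")


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_de_test(log_expr: ExpressionMatrix, clinical: ClinicalTable) -> pd.DataFrame:
    """Per-gene paired two-sided t-test on tumor-minus-normal log2 differences.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean per-pair
    difference, tumor minus normal), ``p_value``, ``fdr`` (BH over all genes),
    ``mean_log2_expr`` and ``selected`` (initialized False; set by the
    threshold helpers). Zero-variance genes get p = 1 with a warning.
    """
    if log_expr.unit not in ("log2CPM", "log2FPKM"):
        raise ValidationError(f"paired_de_test expects log2 expression, got {log_expr.unit!r}")
    pairs = clinical.pairs()
    matrix_samples = set(log_expr.sample_ids)
    covered = pairs[
        pairs["tumor_sample"].isin(matrix_samples) & pairs["normal_sample"].isin(matrix_samples)
    ]
    unpaired = matrix_samples - set(covered["tumor_sample"]) - set(covered["normal_sample"])
    if unpaired:
        raise ValidationError(
            f"samples without a complete tumor/normal pair in the matrix: {sorted(unpaired)}"
        )
    n_pairs = len(covered)
    if n_pairs < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {n_pairs}")
    tum = log_expr.data.loc[:, list(covered["tumor_sample"])].to_numpy()
    nor = log_expr.data.loc[:, list(covered["normal_sample"])].to_numpy()
    diffs = tum - nor
    log2fc = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d gene(s) with zero-variance paired differences; p set to 1",
                       int(zero_var.sum()))
    t = np.zeros_like(log2fc)
    np.divide(log2fc, sd / np.sqrt(n_pairs), out=t, where=~zero_var)
    p = np.where(zero_var, 1.0, 2.0 * stats.t.sf(np.abs(t), df=n_pairs - 1))
    p = np.minimum(p, 1.0)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "fdr": benjamini_hochberg(p),
            "mean_log2_expr": log_expr.data.to_numpy().mean(axis=1),
            "selected": False,
        },
        index=log_expr.data.index,
    )


def unpaired_de_test(log_expr: ExpressionMatrix, clinical: ClinicalTable) -> pd.DataFrame:
    """Welch two-sample variant for cohorts without usable pairing."""
    if log_expr.unit not in ("log2CPM", "log2FPKM"):
        raise ValidationError(f"unpaired_de_test expects log2 expression, got {log_expr.unit!r}")
    tumor = [s for s in clinical.tumor_samples() if s in log_expr.data.columns]
    normal = [s for s in clinical.normal_samples() if s in log_expr.data.columns]
    if len(tumor) < 3 or len(normal) < 3:
        raise ValidationError("need >= 3 tumor and >= 3 normal samples")
    tum = log_expr.data.loc[:, tumor].to_numpy()
    nor = log_expr.data.loc[:, normal].to_numpy()
    t, p = stats.ttest_ind(tum, nor, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "log2fc": tum.mean(axis=1) - nor.mean(axis=1),
            "p_value": p,
            "fdr": benjamini_hochberg(p),
            "mean_log2_expr": log_expr.data.to_numpy().mean(axis=1),
            "selected": False,
        },
        index=log_expr.data.index,
    )


def select_de_genes(de: pd.DataFrame, fdr_max: float = 0.01, min_abs_log2fc: float = 1.0) -> set:
    """Genes with fdr < fdr_max and |log2fc| > min_abs_log2fc (both strict)."""
    if fdr_max <= 0 or min_abs_log2fc <= 0:
        raise ValidationError("thresholds must be positive")
    mask = (de["fdr"] < fdr_max) & (de["log2fc"].abs() > min_abs_log2fc)
    return set(de.index[mask])


def select_top_bottom_mirnas(de: pd.DataFrame, k: int = 10) -> set:
    """Union of the k largest and k smallest log2FC miRNAs (2k total).

    Ties at the rank-k boundary are broken by lexicographic gene id, keeping
    the result deterministic.
    """
    if len(de) < 2 * k:
        raise ValidationError(f"need >= {2 * k} miRNAs for the top/bottom-{k} rule, got {len(de)}")
    # sort by (log2fc, gene id): ties at the boundary resolve to the
    # lexicographically smaller id on both ends
    order = de.assign(_gene=de.index).sort_values(["log2fc", "_gene"], ascending=[False, True])
    top = list(order.index[:k])
    order_low = de.assign(_gene=de.index).sort_values(["log2fc", "_gene"], ascending=[True, True])
    bottom = list(order_low.index[:k])
    return set(top) | set(bottom)
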